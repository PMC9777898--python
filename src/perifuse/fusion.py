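"""Phase 2: three-branch fusion classifier over image latents + tabular data.

The image latent vector passes through branch N1 and the eight tabular
features through branch N2, so the two feature sets enter the concatenation
at comparable widths (avoiding dominance of the much larger image latent).
The concatenated vector feeds N3, a dense stack with ReLU activations and
dropout between dense layers, ending in a single sigmoid output.  One such
binary classifier is trained per ICD-10 chapter (Adam, learning rate 1e-4,
batch size 50, 300 epochs by default).  Unimodal ablations drop one branch
entirely and are otherwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "FusionConfig",
    "TrainedFusion",
    "relu",
    "dense_layer",
    "build_fusion",
    "train_fusion",
    "predict",
    "unimodal_variant",
]


def relu(x):
    """Elementwise max(x, 0)."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def dense_layer(u_prev: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """One fully connected layer: ReLU(u_prev @ W + b)."""
    u_prev = np.atleast_2d(np.asarray(u_prev, dtype=float))
    if u_prev.shape[-1] != W.shape[0]:
        raise ValueError(f"dimension mismatch: input {u_prev.shape} vs W {W.shape}")
    return relu(u_prev @ W + b)


@dataclass
class FusionConfig:
    """Hyperparameters of the per-chapter fusion classifier."""

    n1_out: int = 32
    n2_out: int = 32
    n3_hidden: tuple[int, ...] = (64, 32)
    dropout_rate: float = 0.5
    lr: float = 1e-4
    batch_size: int = 50
    epochs: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n1_out", "n2_out"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if any(h < 1 for h in self.n3_hidden):
            raise ValueError(f"n3_hidden must be positive, got {self.n3_hidden}")
        ratio = max(self.n1_out, self.n2_out) / min(self.n1_out, self.n2_out)
        if ratio > 4:
            raise ValueError(
                f"branch widths {self.n1_out}/{self.n2_out} differ by more than 4x; "
                "the branches exist to keep the two feature sets comparable"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("lr must be > 0, batch_size >= 1, epochs >= 0")


@dataclass
class TrainedFusion:
    """Branch networks plus the fused head; ``mode`` marks ablations."""

    n1: nn.Sequential | None
    n2: nn.Sequential | None
    n3: nn.Sequential
    config: FusionConfig
    latent_dim: int
    n_tabular: int
    mode: str = "fused"  # fused | image-only | tabular-only
    chapter: str = ""
    history: list[dict] = field(default_factory=list)

    @property
    def modules(self) -> list[nn.Sequential]:
        return [m for m in (self.n1, self.n2, self.n3) if m is not None]


def build_fusion(
    latent_dim: int,
    n_tabular: int = 8,
    config: FusionConfig | None = None,
    mode: str = "fused",
    chapter: str = "",
) -> TrainedFusion:
    """Construct an untrained fusion model with seeded initialization."""
    config = config or FusionConfig()
    if latent_dim < 1:
        raise ValueError(f"latent_dim must be >= 1, got {latent_dim}")
    if mode not in ("fused", "image-only", "tabular-only"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF5]))
    drop_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD0]))

    n1 = n2 = None
    width = 0
    if mode in ("fused", "image-only"):
        n1 = nn.Sequential([nn.Dense(latent_dim, config.n1_out, rng), nn.ReLU()])
        width += config.n1_out
    if mode in ("fused", "tabular-only"):
        n2 = nn.Sequential([nn.Dense(n_tabular, config.n2_out, rng), nn.ReLU()])
        width += config.n2_out

    layers: list[nn.Layer] = []
    prev = width
    for h in config.n3_hidden:
        layers.append(nn.Dropout(config.dropout_rate, drop_rng))
        layers.append(nn.Dense(prev, h, rng))
        layers.append(nn.ReLU())
        prev = h
    layers.append(nn.Dropout(config.dropout_rate, drop_rng))
    layers.append(nn.Dense(prev, 1, rng))  # logit output
    n3 = nn.Sequential(layers)
    return TrainedFusion(
        n1=n1,
        n2=n2,
        n3=n3,
        config=config,
        latent_dim=latent_dim,
        n_tabular=n_tabular,
        mode=mode,
        chapter=chapter,
    )


def _forward(model: TrainedFusion, f_img, f_tab, train: bool):
    parts = []
    if model.n1 is not None:
        f_img = np.asarray(f_img, dtype=nn.DTYPE)
        if f_img.shape[1] != model.latent_dim:
            raise ValueError(
                f"image features have width {f_img.shape[1]}, expected {model.latent_dim}"
            )
        parts.append(model.n1.forward(f_img, train=train))
    if model.n2 is not None:
        f_tab = np.asarray(f_tab, dtype=nn.DTYPE)
        if f_tab.shape[1] != model.n_tabular:
            raise ValueError(
                f"tabular features have width {f_tab.shape[1]}, expected {model.n_tabular}"
            )
        parts.append(model.n2.forward(f_tab, train=train))
    fused = np.concatenate(parts, axis=1)
    widths = [p.shape[1] for p in parts]
    return model.n3.forward(fused, train=train), widths


def train_fusion(
    features_img,
    features_tab,
    labels,
    config: FusionConfig | None = None,
    mode: str = "fused",
    chapter: str = "",
) -> TrainedFusion:
    """Train one binary chapter classifier with Adam + BCE."""
    config = config or FusionConfig()
    y = np.asarray(labels, dtype=float).reshape(-1)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("labels must be 0/1")
    if min((y == 0).sum(), (y == 1).sum()) < 1:
        raise ValueError("both classes must be present in the training labels")
    f_img = None if features_img is None else np.asarray(features_img, dtype=float)
    f_tab = None if features_tab is None else np.asarray(features_tab, dtype=float)
    if mode in ("fused", "image-only") and f_img is None:
        raise ValueError(f"mode {mode!r} requires image features")
    if mode in ("fused", "tabular-only") and f_tab is None:
        raise ValueError(f"mode {mode!r} requires tabular features")
    latent_dim = 1 if f_img is None else f_img.shape[1]
    n_tabular = 8 if f_tab is None else f_tab.shape[1]
    model = build_fusion(latent_dim, n_tabular, config, mode=mode, chapter=chapter)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5B]))
    opt = nn.Adam(model.modules, lr=config.lr)
    n = y.size
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        tot = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            opt.zero_grad()
            logits, widths = _forward(
                model,
                None if f_img is None else f_img[idx],
                None if f_tab is None else f_tab[idx],
                train=True,
            )
            loss, d_logit = nn.bce_loss_grad(y[idx], logits)
            d_fused = model.n3.backward(d_logit)
            off = 0
            for mod, wd in zip([m for m in (model.n1, model.n2) if m is not None], widths):
                mod.backward(d_fused[:, off : off + wd])
                off += wd
            opt.step()
            tot += loss
            n_batches += 1
        model.history.append({"epoch": epoch, "bce": tot / n_batches})
    return model


def predict(trained: TrainedFusion, features_img, features_tab) -> np.ndarray:
    """Chapter-membership probabilities; dropout disabled, deterministic."""
    logits, _ = _forward(trained, features_img, features_tab, train=False)
    return nn.sigmoid(logits).reshape(-1)


def unimodal_variant(
    mode: str,
    features_img,
    features_tab,
    labels,
    config: FusionConfig | None = None,
    chapter: str = "",
) -> TrainedFusion:
    """Train an image-only or tabular-only ablation of the fusion model."""
    if mode not in ("image-only", "tabular-only"):
        raise ValueError(f"mode must be image-only or tabular-only, got {mode!r}")
    if mode == "image-only":
        return train_fusion(features_img, None, labels, config, mode=mode, chapter=chapter)
    return train_fusion(None, features_tab, labels, config, mode=mode, chapter=chapter)
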