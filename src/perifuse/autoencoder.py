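"""Phase 1: dual-loss convolutional autoencoder over radiograph images.

The encoder maps each image to a latent vector; the latent feeds two heads
trained jointly: a mirrored convolutional decoder under a mean-squared
reconstruction loss, and a three-layer Leaky-ReLU dense classifier under a
binary cross-entropy loss on the severe-periodontitis label.  The training
objective is the (optionally weighted) sum of the two losses; reconstruction
gradients flow through decoder + encoder and classification gradients
through head + encoder, jointly per batch.  Setting the cross-entropy
weight to zero gives the plain-autoencoder ablation used to quantify the
benefit of the dual loss.

Training follows a two-phase Adam schedule (by default 10 epochs at 1e-4
then 10 refinement epochs at 1e-5, batch size 32).
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .images import ImageTensor

__all__ = [
    "AEConfig",
    "TrainedAE",
    "mse_loss",
    "ce_loss",
    "total_loss",
    "build_ae",
    "train_ae",
    "encode",
    "predict_severity",
    "save_ae",
    "load_ae",
]

_EPS = 1e-7


@dataclass
class AEConfig:
    """Hyperparameters of the dual-loss autoencoder."""

    latent_dim: int = 128
    loss_weight_ce: float = 1.0
    batch_size: int = 32
    epochs_phase_a: int = 10
    lr_phase_a: float = 1e-4
    epochs_phase_b: int = 10
    lr_phase_b: float = 1e-5
    conv_depth: int = 3
    base_channels: int = 8
    leaky_slope: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("latent_dim", "batch_size", "conv_depth", "base_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("epochs_phase_a", "epochs_phase_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.loss_weight_ce < 0:
            raise ValueError(f"loss_weight_ce must be >= 0, got {self.loss_weight_ce}")
        for name in ("lr_phase_a", "lr_phase_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainedAE:
    """Encoder/decoder/classifier-head triple plus training history."""

    encoder: nn.Sequential
    decoder: nn.Sequential
    head: nn.Sequential
    config: AEConfig
    image_size: tuple[int, int]
    gradcam_layer: int  # encoder index of the last conv activation
    history: list[dict] = field(default_factory=list)


def mse_loss(images: np.ndarray, reconstructions: np.ndarray) -> float:
    """Mean over samples of the mean squared pixel error."""
    loss, _ = nn.mse_loss_grad(np.asarray(images, float), np.asarray(reconstructions, float))
    return loss


def ce_loss(true_labels, predicted_probs) -> float:
    """Mean negative log-likelihood of the true class, probs clipped at 1e-7."""
    y = np.asarray(true_labels, dtype=float).reshape(-1)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("labels must be 0/1")
    p = np.clip(np.asarray(predicted_probs, dtype=float).reshape(-1), _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def total_loss(l_mse: float, l_ce: float, weight_ce: float = 1.0) -> float:
    """Reconstruction loss plus weighted classification loss."""
    return float(l_mse) + float(weight_ce) * float(l_ce)


def _as_batch(images) -> np.ndarray:
    """Coerce ImageTensor list / (N,H,W) array to a float (N,1,H,W) batch."""
    if isinstance(images, np.ndarray):
        arr = images
    else:
        arr = np.stack(
            [im.pixels if isinstance(im, ImageTensor) else np.asarray(im) for im in images]
        )
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 3:
        arr = arr[:, None]
    if arr.ndim != 4 or arr.shape[1] != 1:
        raise ValueError(f"expected (N, H, W) grayscale batch, got shape {arr.shape}")
    return arr.astype(nn.DTYPE, copy=False)


def build_ae(config: AEConfig, image_size: tuple[int, int]) -> TrainedAE:
    """Construct the untrained model with seeded initialization."""
    h, w = image_size
    depth = config.conv_depth
    if h % (2**depth) or w % (2**depth):
        raise ValueError(
            f"image_size {image_size} must be divisible by 2^{depth} "
            f"(the encoder's downsampling depth)"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xAE]))
    slope = config.leaky_slope
    chans = [config.base_channels * (2**i) for i in range(depth)]

    enc_layers: list[nn.Layer] = []
    c_in = 1
    for c_out in chans:
        enc_layers.append(nn.Conv2d(c_in, c_out, rng, stride=2))
        enc_layers.append(nn.LeakyReLU(slope))
        c_in = c_out
    gradcam_layer = len(enc_layers) - 1  # last conv's activation
    hb, wb = h // 2**depth, w // 2**depth
    flat = chans[-1] * hb * wb
    enc_layers += [nn.Flatten(), nn.Dense(flat, config.latent_dim, rng)]
    encoder = nn.Sequential(enc_layers)

    dec_layers: list[nn.Layer] = [
        nn.Dense(config.latent_dim, flat, rng),
        nn.LeakyReLU(slope),
        nn.Reshape((chans[-1], hb, wb)),
    ]
    c_in = chans[-1]
    for c_out in reversed(chans):
        dec_layers += [nn.Upsample2x(), nn.Conv2d(c_in, c_out, rng), nn.LeakyReLU(slope)]
        c_in = c_out
    dec_layers += [nn.Conv2d(c_in, 1, rng), nn.Sigmoid()]
    decoder = nn.Sequential(dec_layers)

    head = nn.Sequential(
        [
            nn.Dense(config.latent_dim, 64, rng),
            nn.LeakyReLU(slope),
            nn.Dense(64, 32, rng),
            nn.LeakyReLU(slope),
            nn.Dense(32, 1, rng),  # logit; sigmoid applied at the loss/prediction
        ]
    )
    return TrainedAE(
        encoder=encoder,
        decoder=decoder,
        head=head,
        config=config,
        image_size=(h, w),
        gradcam_layer=gradcam_layer,
    )


def train_ae(images, severity_labels, config: AEConfig) -> TrainedAE:
    """Train the dual-loss autoencoder with the two-phase Adam schedule."""
    x = _as_batch(images)
    y = np.asarray(severity_labels, dtype=float).reshape(-1)
    if x.shape[0] != y.size:
        raise ValueError(f"{x.shape[0]} images but {y.size} labels")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("severity labels must be 0/1")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError(
            "need at least 2 subjects per severity class "
            "(cross-entropy loss is degenerate on a single class)"
        )
    model = build_ae(config, x.shape[2:])
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5F]))
    modules = [model.encoder, model.decoder, model.head]
    opt = nn.Adam(modules, lr=config.lr_phase_a)

    phases = [
        (config.epochs_phase_a, config.lr_phase_a),
        (config.epochs_phase_b, config.lr_phase_b),
    ]
    n = x.shape[0]
    bs = config.batch_size
    epoch = 0
    for n_epochs, lr in phases:
        opt.lr = lr
        for _ in range(n_epochs):
            order = rng.permutation(n)
            tot_mse = tot_ce = 0.0
            n_batches = 0
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                xb, yb = x[idx], y[idx]
                opt.zero_grad()
                z = model.encoder.forward(xb, train=True)
                recon = model.decoder.forward(z, train=True)
                logits = model.head.forward(z, train=True)
                l_mse, d_recon = nn.mse_loss_grad(xb, recon)
                l_ce, d_logit = nn.bce_loss_grad(yb, logits)
                dz = model.decoder.backward(d_recon)
                if config.loss_weight_ce > 0:
                    dz = dz + model.head.backward(config.loss_weight_ce * d_logit)
                model.encoder.backward(dz)
                opt.step()
                tot_mse += l_mse
                tot_ce += l_ce
                n_batches += 1
            model.history.append(
                {
                    "epoch": epoch,
                    "lr": lr,
                    "mse": tot_mse / n_batches,
                    "ce": tot_ce / n_batches,
                    "total": total_loss(
                        tot_mse / n_batches, tot_ce / n_batches, config.loss_weight_ce
                    ),
                }
            )
            epoch += 1
    return model


def encode(trained: TrainedAE, images) -> np.ndarray:
    """Latent features, one row per image; deterministic."""
    x = _as_batch(images)
    if x.shape[2:] != trained.image_size:
        raise ValueError(
            f"images have size {x.shape[2:]}, model expects {trained.image_size}"
        )
    return trained.encoder.forward(x, train=False)


def predict_severity(trained: TrainedAE, images) -> np.ndarray:
    """Severity probability from the classifier head."""
    z = encode(trained, images)
    return nn.sigmoid(trained.head.forward(z, train=False)).reshape(-1)


def reconstruct(trained: TrainedAE, images) -> np.ndarray:
    """Decoder reconstructions as an (N, H, W) array."""
    z = encode(trained, images)
    return trained.decoder.forward(z, train=False)[:, 0]


def save_ae(trained: TrainedAE, path) -> None:
    """Single-archive checkpoint with the config embedded."""
    meta = {
        "config": asdict(trained.config),
        "image_size": list(trained.image_size),
        "gradcam_layer": trained.gradcam_layer,
        "history": trained.history,
    }
    arrays = {}
    for prefix, mod in (("enc", trained.encoder), ("dec", trained.decoder), ("head", trained.head)):
        for key, arr in mod.state_dict().items():
            arrays[f"{prefix}:{key}"] = arr
    buf = io.BytesIO()
    np.savez(buf, meta=json.dumps(meta), **arrays)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_ae(path) -> TrainedAE:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        model = build_ae(AEConfig(**meta["config"]), tuple(meta["image_size"]))
        model.history = meta["history"]
        for prefix, mod in (("enc", model.encoder), ("dec", model.decoder), ("head", model.head)):
            state = {
                k.split(":", 1)[1]: data[k] for k in data.files if k.startswith(prefix + ":")
            }
            mod.load_state_dict(state)
    return model


def history_to_csv(trained: TrainedAE, path) -> None:
    """Export the loss trajectory as CSV (epoch, mse, ce, total)."""
    import pandas as pd

    pd.DataFrame(trained.history)[["epoch", "mse", "ce", "total"]].to_csv(path, index=False)
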