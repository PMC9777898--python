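"""Synthetic cohort generator with a planted, spatially localized lesion.

Emulates the statistical structure the two-phase model assumes, without any
anatomical realism: each subject has a hidden standard-normal severity score

    s = sqrt(w_img) * z_img + sqrt(w_tab) * z_tab + sqrt(1 - w_img - w_tab) * z_res

whose threshold exceedance defines the severe-periodontitis label (the
threshold is calibrated so 45.8% of subjects are severe).  The image is a
schematic "tooth row" texture whose alveolar-crest band is eroded in severe
subjects — depth modulated by the image-borne factor z_img — so the disease
signal is spatially localized (what Grad-CAM must find).  The eight tabular
features load linearly on the tabular-borne factor z_tab (gender is an
independent Bernoulli(0.61 female)).  Per-chapter systemic-disease labels
follow a logistic model on the two modality-borne risk components, with
intercepts calibrated to requested marginal prevalences.

Because the two factors are independent, the Bayes AUC of each modality and
of their fusion is known (see :mod:`perifuse.theory`), which gives the test
suite exact oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .images import ImageTensor, read_image, write_png
from .tabular import FEATURE_COLUMNS, LabelSet, SubjectRecord, SubjectTable
from .theory import SEVERE_FRACTION, severity_threshold

__all__ = [
    "CohortSpec",
    "SyntheticSubject",
    "default_chapter_prevalences",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: Chapter-model slopes on the image- and tabular-borne risk components.
BETA_IMG = 2.5
BETA_TAB = 2.5

#: Columns eligible for missingness injection (bone-level measurements).
MASKABLE_COLUMNS = ("extent_bone_loss", "bone_loss_max", "age_adj_bone_loss")

# stage-group ladder: cumulative population fractions on the latent score s.
# The last two rungs form the severe group (0.258 + 0.200 = 0.458).
_STAGE_LADDER = (
    ("health", 0.100),
    ("gingivitis", 0.220),
    ("Stage I", 0.350),
    ("Stage II", 0.470),
    ("Stage III localized", 0.542),
    ("Stage III generalized", 0.800),
    ("Stage IV", 1.000),
)
_STAGE_CODE = {name: float(i) for i, (name, _) in enumerate(_STAGE_LADDER)}

# linear loadings of each continuous feature on z_tab: (loading, mean, scale)
_TABULAR_LOADINGS = {
    "age": (0.30, 56.0, 11.0),
    "income": (-0.25, 30000.0, 14000.0),
    "n_teeth": (-0.50, 26.0, 3.0),
    "perio_stage": (0.80, 3.0, 1.6),
    "extent_bone_loss": (0.70, 30.0, 18.0),
    "bone_loss_max": (0.70, 40.0, 20.0),
    "age_adj_bone_loss": (0.75, 0.7, 0.35),
}

_FEMALE_RATE = 0.61


def default_chapter_prevalences() -> dict[str, float]:
    """Plausible marginal prevalences for the 14 ICD-10 chapters modelled."""
    return {
        "I": 0.12,
        "II": 0.10,
        "III": 0.30,
        "IV": 0.22,
        "V": 0.15,
        "VI": 0.25,
        "VII": 0.18,
        "VIII": 0.12,
        "IX": 0.40,
        "X": 0.20,
        "XI": 0.28,
        "XII": 0.15,
        "XIII": 0.25,
        "XIV": 0.18,
    }


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort draw."""

    n_subjects: int = 400
    image_size: tuple[int, int] = (32, 32)
    lesion_effect: float = 0.35
    image_signal_weight: float = 0.5
    tabular_signal_weight: float = 0.5
    chapter_prevalences: dict[str, float] = field(
        default_factory=default_chapter_prevalences
    )
    noise_sd: float = 0.05
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 20:
            raise ValueError(f"n_subjects must be >= 20, got {self.n_subjects}")
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValueError(f"image_size too small: {self.image_size}")
        if self.lesion_effect < 0:
            raise ValueError(f"lesion_effect must be >= 0, got {self.lesion_effect}")
        for name in ("image_signal_weight", "tabular_signal_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.image_signal_weight + self.tabular_signal_weight > 1.0 + 1e-12:
            raise ValueError(
                "image_signal_weight + tabular_signal_weight must be <= 1"
            )
        for ch, p in self.chapter_prevalences.items():
            if not 0.0 < p < 1.0:
                raise ValueError(
                    f"chapter_prevalences[{ch!r}] must be in (0, 1), got {p}"
                )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")


@dataclass
class SyntheticSubject:
    """One simulated subject with its hidden ground truth."""

    subject_id: str
    image: ImageTensor
    tabular: SubjectRecord
    labels: LabelSet
    stage_group: str
    latent_risk: float
    lesion_mask: np.ndarray  # bool, same spatial size as the image


def _crest_rows(h: int) -> tuple[int, int]:
    """Row range of the alveolar-crest band (just below the tooth row)."""
    return int(0.62 * h), int(0.76 * h)


def _base_texture(h: int, w: int) -> np.ndarray:
    """Schematic tooth-row texture shared by all subjects."""
    img = np.full((h, w), 0.15)
    # tooth row: bright repeating blocks
    t0, t1 = int(0.30 * h), int(0.62 * h)
    period = max(w // 8, 2)
    cols = np.arange(w)
    tooth = (cols % period) < max(int(0.7 * period), 1)
    img[t0:t1, tooth] = 0.9
    # alveolar crest band
    c0, c1 = _crest_rows(h)
    img[c0:c1, :] = 0.75
    return img


def chapter_intercept(prevalence: float, eta_sd: float) -> float:
    """Solve alpha so E[sigmoid(alpha + eta)] = prevalence, eta ~ N(0, sd^2)."""
    if eta_sd == 0.0:
        return float(np.log(prevalence / (1.0 - prevalence)))
    x, w = np.polynomial.hermite_e.hermegauss(80)
    wn = w / math.sqrt(2.0 * math.pi)

    def marginal(alpha: float) -> float:
        return float(wn @ (1.0 / (1.0 + np.exp(-(alpha + eta_sd * x))))) - prevalence

    return float(brentq(marginal, -30.0, 30.0))


def generate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Draw a full synthetic cohort; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    h, w = spec.image_size
    a_img = math.sqrt(spec.image_signal_weight)
    a_tab = math.sqrt(spec.tabular_signal_weight)
    a_res = math.sqrt(max(1.0 - spec.image_signal_weight - spec.tabular_signal_weight, 0.0))
    tau = severity_threshold(SEVERE_FRACTION)

    z_img = rng.standard_normal(n)
    z_tab = rng.standard_normal(n)
    z_res = rng.standard_normal(n)
    s = a_img * z_img + a_tab * z_tab + a_res * z_res
    severity = (s > tau).astype(int)

    # stage group from the latent score via fixed population quantile cuts
    cuts = [norm.ppf(frac) for _, frac in _STAGE_LADDER[:-1]]
    stage_idx = np.searchsorted(cuts, s, side="right")
    stage_names = [_STAGE_LADDER[i][0] for i in stage_idx]

    # chapter labels: logistic on the modality-borne risk components
    s_img = a_img * z_img
    s_tab = a_tab * z_tab
    eta = BETA_IMG * s_img + BETA_TAB * s_tab
    eta_sd = math.sqrt(
        BETA_IMG**2 * spec.image_signal_weight + BETA_TAB**2 * spec.tabular_signal_weight
    )
    chapters = sorted(spec.chapter_prevalences)
    alphas = {
        ch: chapter_intercept(spec.chapter_prevalences[ch], eta_sd) for ch in chapters
    }
    chapter_labels = {
        ch: (rng.random(n) < 1.0 / (1.0 + np.exp(-(alphas[ch] + eta)))).astype(int)
        for ch in chapters
    }

    base = _base_texture(h, w)
    c0, c1 = _crest_rows(h)
    female = (rng.random(n) < _FEMALE_RATE).astype(float)
    pad = len(str(n))

    subjects: list[SyntheticSubject] = []
    for i in range(n):
        sid = f"S{i + 1:0{pad}d}"
        img = base.copy()
        mask = np.zeros((h, w), dtype=bool)
        # the mask marks exactly the pixels whose expected intensity differs
        # between labels, so it stays empty when no lesion is planted
        if severity[i] == 1 and spec.lesion_effect > 0:
            depth = spec.lesion_effect * (0.5 + 0.5 * norm.cdf(z_img[i]))
            img[c0:c1, :] -= depth
            mask[c0:c1, :] = True
        img += rng.normal(0.0, spec.noise_sd, size=(h, w))
        np.clip(img, 0.0, 1.0, out=img)

        vals: dict[str, float | None] = {"gender": female[i]}
        for col, (lam, mu, scale) in _TABULAR_LOADINGS.items():
            noise = rng.standard_normal()
            v = mu + scale * (lam * z_tab[i] + math.sqrt(1.0 - lam**2) * noise)
            if col == "age":
                v = float(np.clip(v, 35.0, 97.0))
            elif col == "income":
                v = float(max(v, 2000.0))
            elif col == "n_teeth":
                v = float(int(np.clip(round(v), 0, 32)))
            vals[col] = float(v)
        # missingness only on bone-level columns
        if spec.missing_rate > 0.0:
            for col in MASKABLE_COLUMNS:
                if rng.random() < spec.missing_rate:
                    vals[col] = None

        record = SubjectRecord(subject_id=sid, **{c: vals[c] for c in FEATURE_COLUMNS})
        labels = LabelSet(
            severity=int(severity[i]),
            chapters={ch: int(chapter_labels[ch][i]) for ch in chapters},
        )
        subjects.append(
            SyntheticSubject(
                subject_id=sid,
                image=ImageTensor(pixels=img, subject_id=sid),
                tabular=record,
                labels=labels,
                stage_group=stage_names[i],
                latent_risk=float(s[i]),
                lesion_mask=mask,
            )
        )
    return subjects


def _format_cell(v: float | None) -> str:
    if v is None:
        return ""
    return repr(float(v))


def write_cohort(subjects: list[SyntheticSubject], out_dir: str | Path) -> Path:
    """Write PNGs, subjects.csv and manifest.csv; returns the manifest path.

    The tabular CSV round-trips bit-exactly (floats written with repr);
    images round-trip to 8-bit quantization.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    chapters = sorted(subjects[0].labels.chapters) if subjects else []

    rows = []
    manifest_rows = []
    for sub in subjects:
        rel = f"images/{sub.subject_id}.png"
        write_png(sub.image, out_dir / rel)
        manifest_rows.append({"subject_id": sub.subject_id, "image_path": rel})
        row = {"subject_id": sub.subject_id}
        for col in FEATURE_COLUMNS:
            row[col] = _format_cell(getattr(sub.tabular, col))
        row["stage_group"] = sub.stage_group
        for ch in chapters:
            row[f"ch_{ch}"] = str(sub.labels.chapters[ch])
        rows.append(row)

    pd.DataFrame(rows).to_csv(out_dir / "subjects.csv", index=False)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(cohort_dir: str | Path) -> tuple[SubjectTable, list[ImageTensor]]:
    """Read a written cohort back: subject table plus images in table order."""
    from .tabular import read_subject_table

    cohort_dir = Path(cohort_dir)
    table = read_subject_table(cohort_dir / "subjects.csv")
    manifest = pd.read_csv(cohort_dir / "manifest.csv", dtype=str)
    path_by_id = dict(zip(manifest["subject_id"], manifest["image_path"]))
    images = []
    for sid in table.ids:
        if sid not in path_by_id:
            raise FileNotFoundError(f"no image listed in manifest for subject {sid}")
        p = cohort_dir / path_by_id[sid]
        if not p.exists():
            raise FileNotFoundError(f"image file missing for subject {sid}: {p}")
        images.append(read_image(p, subject_id=sid))
    return table, images
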