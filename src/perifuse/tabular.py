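"""Subject-table ingestion, imputation, label binarisation and splitting.

The subject table is a UTF-8 CSV with one row per subject carrying the
eight demographic/clinical features (age, gender, income, number of teeth,
periodontal stage code, extent of bone loss, maximum bone loss,
age-adjusted bone loss), the categorical periodontal stage group used for
severity binarisation, and one 0/1 column per ICD-10 chapter
(``ch_<roman>``).  Empty cells in numeric columns mean "missing".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "FEATURE_COLUMNS",
    "SEVERE_GROUPS",
    "NON_SEVERE_GROUPS",
    "SubjectRecord",
    "LabelSet",
    "SplitPlan",
    "SubjectTable",
    "read_subject_table",
    "mean_impute",
    "binarize_severity",
    "downsample_balance",
    "make_split",
    "zscore_fit",
    "zscore_apply",
]

#: The eight model features, in canonical column order.
FEATURE_COLUMNS = (
    "age",
    "gender",
    "income",
    "n_teeth",
    "perio_stage",
    "extent_bone_loss",
    "bone_loss_max",
    "age_adj_bone_loss",
)

#: Stage groups mapped to the severe label (generalised Stage III and Stage IV).
SEVERE_GROUPS = frozenset({"Stage III generalized", "Stage IV"})
#: Everything milder, down to periodontal health.
NON_SEVERE_GROUPS = frozenset(
    {"health", "gingivitis", "Stage I", "Stage II", "Stage III localized"}
)


@dataclass
class SubjectRecord:
    """One subject's eight features; ``None`` marks a missing value."""

    subject_id: str
    age: float | None
    gender: float | None
    income: float | None
    n_teeth: float | None
    perio_stage: float | None
    extent_bone_loss: float | None
    bone_loss_max: float | None
    age_adj_bone_loss: float | None

    def missing_fields(self) -> list[str]:
        return [c for c in FEATURE_COLUMNS if getattr(self, c) is None]

    def as_vector(self) -> np.ndarray:
        vals = [getattr(self, c) for c in FEATURE_COLUMNS]
        if any(v is None for v in vals):
            raise ValueError(
                f"subject {self.subject_id} still has missing fields: "
                f"{self.missing_fields()}"
            )
        return np.asarray(vals, dtype=float)


@dataclass
class LabelSet:
    """Severity label plus per-chapter binary membership."""

    severity: int
    chapters: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.severity not in (0, 1):
            raise ValueError(f"severity must be 0/1, got {self.severity}")
        for ch, v in self.chapters.items():
            if v not in (0, 1):
                raise ValueError(f"chapter {ch} label must be 0/1, got {v}")


@dataclass
class SubjectTable:
    """Parsed subject table: parallel record/label lists."""

    records: list[SubjectRecord]
    labels: list[LabelSet]

    @property
    def ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    @property
    def chapter_ids(self) -> list[str]:
        return sorted(self.labels[0].chapters) if self.labels else []

    def feature_matrix(self) -> np.ndarray:
        return np.stack([r.as_vector() for r in self.records])

    def severity(self) -> np.ndarray:
        return np.array([l.severity for l in self.labels], dtype=int)

    def chapter(self, chapter_id: str) -> np.ndarray:
        return np.array([l.chapters[chapter_id] for l in self.labels], dtype=int)


def read_subject_table(path: str | Path) -> SubjectTable:
    """Parse the subject CSV; missing numeric cells become ``None`` flags.

    Raises ``ValueError`` on unknown columns, non-numeric values in numeric
    columns, or duplicated subject ids.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["subject_id", *FEATURE_COLUMNS, "stage_group"]
    chapter_cols = [c for c in df.columns if c.startswith("ch_")]
    known = set(required) | set(chapter_cols)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(f"unknown column(s) in subject table: {unknown}")
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"subject table lacks required column(s): {missing_cols}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id: {sorted(set(dup))}")

    records: list[SubjectRecord] = []
    labels: list[LabelSet] = []
    for _, row in df.iterrows():
        vals: dict[str, float | None] = {}
        for col in FEATURE_COLUMNS:
            cell = row[col].strip()
            if cell == "":
                vals[col] = None
                continue
            try:
                vals[col] = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric value {cell!r} in column {col} "
                    f"(subject {row['subject_id']})"
                ) from exc
        records.append(SubjectRecord(subject_id=row["subject_id"], **vals))
        chapters = {}
        for col in chapter_cols:
            cell = row[col].strip()
            if cell not in ("0", "1"):
                raise ValueError(
                    f"chapter column {col} must be 0/1, got {cell!r} "
                    f"(subject {row['subject_id']})"
                )
            chapters[col[3:]] = int(cell)
        labels.append(
            LabelSet(severity=binarize_severity(row["stage_group"]), chapters=chapters)
        )
    return SubjectTable(records=records, labels=labels)


def mean_impute(records: list[SubjectRecord]) -> list[SubjectRecord]:
    """Replace each missing cell by the column mean of the observed cells.

    Observed values are untouched, so every column mean is preserved
    exactly.  A column with no observed value at all is an error.
    """
    out = [SubjectRecord(**vars(r)) for r in records]
    for col in FEATURE_COLUMNS:
        observed = [getattr(r, col) for r in records if getattr(r, col) is not None]
        holes = [r for r in out if getattr(r, col) is None]
        if holes and not observed:
            raise ValueError(f"column {col} has no observed values to impute from")
        if holes:
            m = float(np.mean(observed))
            for r in holes:
                setattr(r, col, m)
    return out


def binarize_severity(stage_group: str) -> int:
    """Map a periodontal stage group to the binary severe label.

    Severe (1) is generalised Stage III or Stage IV periodontitis; health,
    gingivitis, Stages I-II and localised Stage III map to 0.
    """
    g = stage_group.strip()
    if g in SEVERE_GROUPS:
        return 1
    if g in NON_SEVERE_GROUPS:
        return 0
    raise ValueError(
        f"unrecognized stage group {stage_group!r}; expected one of "
        f"{sorted(SEVERE_GROUPS | NON_SEVERE_GROUPS)}"
    )


def downsample_balance(ids, labels, seed: int) -> list:
    """Downsample the majority class when the imbalance is extreme.

    If the majority count exceeds twice the minority count, majority ids
    are sampled without replacement down to the minority count; otherwise
    the ids are returned unchanged.  Minority ids are always all retained.
    """
    ids = list(ids)
    labels = np.asarray(labels, dtype=int)
    if len(ids) != len(labels):
        raise ValueError("ids and labels length mismatch")
    pos = [i for i, y in zip(ids, labels) if y == 1]
    neg = [i for i, y in zip(ids, labels) if y == 0]
    if not pos or not neg:
        raise ValueError("both classes must be present to balance")
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    if len(majority) <= 2 * len(minority):
        return ids
    rng = np.random.default_rng(seed)
    kept = set(rng.choice(len(majority), size=len(minority), replace=False))
    kept_majority = {m for j, m in enumerate(majority) if j in kept}
    keep = set(minority) | kept_majority
    return [i for i in ids if i in keep]


@dataclass
class SplitPlan:
    """70/30 stratified holdout plus stratified k folds over the train ids."""

    train_ids: list[str]
    test_ids: list[str]
    fold_assignments: dict[str, int]
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.fold_assignments.items() if f == fold]

    @property
    def n_folds(self) -> int:
        return len(set(self.fold_assignments.values()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train_ids": self.train_ids,
                    "test_ids": self.test_ids,
                    "fold_assignments": self.fold_assignments,
                    "seed": self.seed,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            train_ids=d["train_ids"],
            test_ids=d["test_ids"],
            fold_assignments={k: int(v) for k, v in d["fold_assignments"].items()},
            seed=int(d["seed"]),
        )


def make_split(ids, labels, train_frac: float = 0.70, k: int = 10, seed: int = 0) -> SplitPlan:
    """Stratified 70/30 split plus stratified k-fold plan on the train ids."""
    ids = list(ids)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    n_train_pos = int(round(n_pos * train_frac))
    n_train_neg = int(round(n_neg * train_frac))
    if min(n_train_pos, n_train_neg) < k:
        raise ValueError(
            f"need at least {k} training subjects per class, have "
            f"{n_train_pos} positive / {n_train_neg} negative"
        )
    train_idx, test_idx = train_test_split(
        np.arange(len(ids)),
        train_size=train_frac,
        stratify=labels,
        random_state=seed % (2**32),
    )
    train_ids = [ids[i] for i in sorted(train_idx)]
    test_ids = [ids[i] for i in sorted(test_idx)]
    y_train = labels[sorted(train_idx)]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    fold_assignments: dict[str, int] = {}
    for fold, (_, val) in enumerate(skf.split(np.zeros(len(train_ids)), y_train)):
        for j in val:
            fold_assignments[train_ids[j]] = fold
    return SplitPlan(
        train_ids=train_ids,
        test_ids=test_ids,
        fold_assignments=fold_assignments,
        seed=seed,
    )


def zscore_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and stds (std floor 1e-12) from training data."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return mu, sd


def zscore_apply(x: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (x - mu) / sd
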