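"""End-to-end orchestration: cohort -> phase 1 -> phase 2 -> reports.

A single YAML run configuration drives everything; every source of
randomness is derived from one master seed, and each output directory
receives a copy of the resolved configuration plus the package version so
a run is fully reconstructable from its artifacts.

To keep the unseen test set genuinely unseen, one severity-stratified
70/30 split is drawn up front and reused everywhere: the phase-1
autoencoder trains only on training subjects, and each per-chapter
classifier is balanced, cross-validated and refit on training subjects
only before scoring the held-out 30%.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, autoencoder, evaluation, fusion, synthetic, tabular
from .images import resize_square

__all__ = ["RunConfig", "run_simulate", "run_phase1", "run_phase2", "run_demo"]

log = logging.getLogger("perifuse")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    cohort_dir: str
    out_dir: str
    cohort: synthetic.CohortSpec | None = None
    ae: autoencoder.AEConfig = field(default_factory=autoencoder.AEConfig)
    fusion: fusion.FusionConfig = field(default_factory=fusion.FusionConfig)
    image_size: int = 32
    train_frac: float = 0.70
    n_folds: int = 10
    chapters: tuple[str, ...] = ("III", "VI", "IX")
    n_refits: int = 3
    threshold: float = 0.5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if Path(self.cohort_dir).resolve() == Path(self.out_dir).resolve():
            raise ValueError("out_dir must differ from cohort_dir")
        # route every nested seed through the master seed
        self.ae = dataclasses.replace(self.ae, seed=self.master_seed + 101)
        self.fusion = dataclasses.replace(self.fusion, seed=self.master_seed + 202)
        if self.cohort is not None:
            self.cohort = dataclasses.replace(self.cohort, seed=self.master_seed)

    @property
    def split_seed(self) -> int:
        return self.master_seed + 303

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        cohort = raw.pop("cohort", None)
        if cohort is not None:
            if "image_size" in cohort:
                cohort["image_size"] = tuple(cohort["image_size"])
            if "chapter_prevalences" not in cohort:
                cohort["chapter_prevalences"] = synthetic.default_chapter_prevalences()
            cohort = synthetic.CohortSpec(**cohort)
        ae = autoencoder.AEConfig(**raw.pop("ae", {}))
        fus = fusion.FusionConfig(**{
            k: tuple(v) if k == "n3_hidden" else v
            for k, v in raw.pop("fusion", {}).items()
        })
        if "chapters" in raw:
            raw["chapters"] = tuple(raw["chapters"])
        return cls(cohort=cohort, ae=ae, fusion=fus, **raw)

    def resolved_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort is not None:
            d["cohort"]["image_size"] = list(self.cohort.image_size)
        d["chapters"] = list(self.chapters)
        d["fusion"]["n3_hidden"] = list(self.fusion.n3_hidden)
        d["version"] = __version__
        return d

    def write_resolved(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "resolved_config.yaml").write_text(
            yaml.safe_dump(self.resolved_dict(), sort_keys=True)
        )


def run_simulate(config: RunConfig) -> Path:
    """Generate the synthetic cohort and write it to ``cohort_dir``."""
    if config.cohort is None:
        raise ValueError("config has no cohort section; nothing to simulate")
    subjects = synthetic.generate_cohort(config.cohort)
    manifest = synthetic.write_cohort(subjects, config.cohort_dir)
    log.info("wrote %d-subject cohort to %s", len(subjects), config.cohort_dir)
    return manifest


def _load_cohort(config: RunConfig):
    table, images = synthetic.read_cohort(config.cohort_dir)
    images = [resize_square(im, config.image_size) for im in images]
    return table, np.stack([im.pixels for im in images])


def run_phase1(config: RunConfig):
    """Train the dual-loss autoencoder and cache latent features.

    Returns ``(trained_ae, latents_frame, split_plan)``; writes the
    checkpoint, the latent CSV, the loss trajectory and the split plan.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.write_resolved(out)
    table, x = _load_cohort(config)
    records = tabular.mean_impute(table.records)
    severity = table.severity()
    plan = tabular.make_split(
        table.ids, severity, train_frac=config.train_frac,
        k=config.n_folds, seed=config.split_seed,
    )
    train_idx = [table.ids.index(i) for i in plan.train_ids]
    trained = autoencoder.train_ae(x[train_idx], severity[train_idx], config.ae)
    latents = autoencoder.encode(trained, x)
    frame = pd.DataFrame(latents, columns=[f"z{i}" for i in range(latents.shape[1])])
    frame.insert(0, "subject_id", table.ids)
    frame.to_csv(out / "latents.csv", index=False)
    autoencoder.history_to_csv(trained, out / "loss_curve.csv")
    autoencoder.save_ae(trained, out / "ae_checkpoint.npz")
    plan.to_json(out / "split.json")
    # cache imputed tabular features alongside
    feats = np.stack([r.as_vector() for r in records])
    tf = pd.DataFrame(feats, columns=list(tabular.FEATURE_COLUMNS))
    tf.insert(0, "subject_id", table.ids)
    tf.to_csv(out / "tabular_features.csv", index=False)
    log.info("phase 1 done: latent dim %d, %d subjects", latents.shape[1], len(table.ids))
    return trained, frame, plan


def _fusion_trainer(config: RunConfig, mode: str, seed: int):
    cfg = dataclasses.replace(config.fusion, seed=seed)

    def trainer(features, labels):
        f_img, f_tab = features
        model = fusion.train_fusion(
            f_img if mode != "tabular-only" else None,
            f_tab if mode != "image-only" else None,
            labels,
            cfg,
            mode=mode,
        )

        def predict_fn(feats):
            fi, ft = feats
            return fusion.predict(model, fi, ft)

        return predict_fn

    return trainer


def run_phase2(config: RunConfig) -> dict[str, dict]:
    """Train/evaluate per-chapter fusion models from the phase-1 cache."""
    out = Path(config.out_dir)
    latents = pd.read_csv(out / "latents.csv")
    tabs = pd.read_csv(out / "tabular_features.csv")
    plan = tabular.SplitPlan.from_json(out / "split.json")
    table, _ = synthetic.read_cohort(config.cohort_dir)
    ids = list(latents["subject_id"])
    z = latents.drop(columns="subject_id").to_numpy(float)
    t = tabs.drop(columns="subject_id").to_numpy(float)
    row = {sid: i for i, sid in enumerate(ids)}

    reports: dict[str, dict] = {}
    for ci, chapter in enumerate(config.chapters):
        y_all = {sid: lab for sid, lab in zip(table.ids, table.chapter(chapter))}
        train_ids = plan.train_ids
        y_train = np.array([y_all[s] for s in train_ids])
        balanced = tabular.downsample_balance(
            train_ids, y_train, seed=config.master_seed + 404 + ci
        )
        leak = set(balanced) & set(plan.test_ids)
        if leak:
            raise ValueError(f"test ids leaked into chapter {chapter} training: {leak}")
        bal_idx = np.array([row[s] for s in balanced])
        test_idx = np.array([row[s] for s in plan.test_ids])
        y_bal = np.array([y_all[s] for s in balanced])
        y_test = np.array([y_all[s] for s in plan.test_ids])

        # standardize both branches with training-set statistics so neither
        # feature set dominates the shared learning rate
        mu, sd = tabular.zscore_fit(t[bal_idx])
        zmu, zsd = tabular.zscore_fit(z[bal_idx])
        f_img_bal = tabular.zscore_apply(z[bal_idx], zmu, zsd)
        f_tab_bal = tabular.zscore_apply(t[bal_idx], mu, sd)
        f_img_test = tabular.zscore_apply(z[test_idx], zmu, zsd)
        f_tab_test = tabular.zscore_apply(t[test_idx], mu, sd)

        # ten-fold CV on the balanced training subjects
        bal_labels = y_bal
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True,
            random_state=(config.split_seed + 17) % 2**32,
        )
        fold_assignments = {}
        for fold, (_, val) in enumerate(skf.split(np.zeros(len(balanced)), bal_labels)):
            for j in val:
                fold_assignments[balanced[j]] = fold
        cv_split = tabular.SplitPlan(
            train_ids=list(balanced), test_ids=[],
            fold_assignments=fold_assignments, seed=config.split_seed + 17,
        )
        cv = evaluation.cross_validate(
            (f_img_bal, f_tab_bal), y_bal, cv_split,
            _fusion_trainer(config, "fused", config.master_seed + 202),
        )

        def fit_predict(seed, mode="fused"):
            trainer = _fusion_trainer(config, mode, seed)
            predict_fn = trainer((f_img_bal, f_tab_bal), y_bal)
            return predict_fn((f_img_test, f_tab_test))

        refit_seeds = [config.master_seed + 505 + 1000 * ci + i for i in range(config.n_refits)]
        report = evaluation.evaluate_chapter(
            chapter,
            fit_predict,
            y_test,
            n_refits=config.n_refits,
            seeds=refit_seeds,
            train_ids=balanced,
            test_ids=plan.test_ids,
            cv=cv,
            threshold=config.threshold,
        )

        # unimodal ablations + paired DeLong comparisons on the test set
        scores_fused = fit_predict(refit_seeds[0])
        scores_img = fit_predict(refit_seeds[0], mode="image-only")
        scores_tab = fit_predict(refit_seeds[0], mode="tabular-only")
        d_img = evaluation.delong_test(y_test, scores_fused, scores_img)
        d_tab = evaluation.delong_test(y_test, scores_fused, scores_tab)
        rep = report.as_dict()
        rep["unimodal"] = {
            "image_only_auc": evaluation.mann_whitney_auc(y_test, scores_img),
            "tabular_only_auc": evaluation.mann_whitney_auc(y_test, scores_tab),
            "delong_fused_vs_image": dataclasses.asdict(d_img),
            "delong_fused_vs_tabular": dataclasses.asdict(d_tab),
        }
        reports[chapter] = rep
        (out / f"report_{chapter}.json").write_text(json.dumps(rep, indent=1))
        _write_figures(out, chapter, report)
        log.info(
            "chapter %s: test AUC %.3f (image %.3f, tabular %.3f)",
            chapter, report.test_auc_mean, d_img.auc_b, d_tab.auc_b,
        )
    return reports


def _write_figures(out: Path, chapter: str, report: evaluation.ChapterModelReport) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(report.roc.fpr, report.roc.tpr, label=f"AUC = {report.roc.auc:.2f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(f"Chapter {chapter}")
    ax.legend()
    fig.savefig(figdir / f"roc_{chapter}.png", dpi=100, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(3.5, 3))
    im = ax.imshow(report.confusion_mean, cmap="Blues", vmin=0, vmax=1)
    for i in range(2):
        for j in range(2):
            ax.text(j, i, f"{report.confusion_mean[i, j]:.2f}", ha="center", va="center")
    ax.set_xticks([0, 1], ["pred 0", "pred 1"])
    ax.set_yticks([0, 1], ["true 0", "true 1"])
    ax.set_title(f"Chapter {chapter} (normalized)")
    fig.colorbar(im, fraction=0.046)
    fig.savefig(figdir / f"confusion_{chapter}.png", dpi=100, bbox_inches="tight")
    plt.close(fig)


def _check_report_invariants(reports: dict[str, dict]) -> list[str]:
    failures = []
    for ch, rep in reports.items():
        for refit in rep["refits"]:
            p, s, f1 = refit["precision"], refit["sensitivity"], refit["f1"]
            if p is not None and f1 is not None:
                expect = evaluation.f1_score(p, s)
                if abs(expect - f1) > 1e-9:
                    failures.append(f"chapter {ch}: F1 inconsistent with precision/recall")
            rows = np.asarray(refit["confusion"]).sum(axis=1)
            if not np.allclose(rows, 1.0):
                failures.append(f"chapter {ch}: confusion rows do not sum to 1")
        for key in ("test_auc_mean", "cv_auc_mean"):
            v = rep.get(key)
            if v is not None and not 0.0 <= v <= 1.0:
                failures.append(f"chapter {ch}: {key} outside [0, 1]")
    return failures


def run_demo(
    seed: int = 0,
    out_dir: str | Path = "demo_out",
    n_subjects: int = 120,
    chapters: tuple[str, ...] = ("III", "VI", "IX"),
    zero_signal: bool = False,
    n_folds: int = 10,
    n_refits: int = 3,
) -> dict:
    """Full synthetic end-to-end run; raises if an invariant check fails."""
    out_dir = Path(out_dir)
    spec = synthetic.CohortSpec(
        n_subjects=n_subjects,
        seed=seed,
        lesion_effect=0.0 if zero_signal else 0.35,
        image_signal_weight=0.5,
        tabular_signal_weight=0.5,
    )
    if zero_signal:
        # tabular features carry no risk loading either: shuffle-free null is
        # achieved by zeroing both modality weights
        spec = dataclasses.replace(
            spec, image_signal_weight=0.0, tabular_signal_weight=0.0
        )
    config = RunConfig(
        cohort_dir=str(out_dir / "cohort"),
        out_dir=str(out_dir / "run"),
        cohort=spec,
        image_size=32,
        chapters=tuple(chapters),
        n_folds=n_folds,
        n_refits=n_refits,
        master_seed=seed,
    )
    run_simulate(config)
    run_phase1(config)
    reports = run_phase2(config)
    failures = _check_report_invariants(reports)
    if failures:
        raise RuntimeError("demo invariant checks failed: " + "; ".join(failures))
    (Path(config.out_dir) / "demo_summary.json").write_text(
        json.dumps(
            {
                ch: {
                    "test_auc": rep["test_auc_mean"],
                    "cv_auc": rep["cv_auc_mean"],
                    "accuracy": rep["metric_mean"]["accuracy"],
                }
                for ch, rep in reports.items()
            },
            indent=1,
        )
    )
    return reports
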