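"""Cohort generator: calibration, determinism, round trips and oracles."""

import numpy as np
import pytest
from scipy.stats import norm

from perifuse import synthetic, theory
from perifuse.synthetic import CohortSpec, generate_cohort, read_cohort, write_cohort


@pytest.mark.parametrize(
    "kwargs, field",
    [
        ({"n_subjects": 5}, "n_subjects"),
        ({"lesion_effect": -0.1}, "lesion_effect"),
        ({"image_signal_weight": 0.7, "tabular_signal_weight": 0.7}, "image_signal_weight"),
        ({"chapter_prevalences": {"IX": 1.5}}, "chapter_prevalences"),
        ({"missing_rate": 1.0}, "missing_rate"),
        ({"noise_sd": -1.0}, "noise_sd"),
    ],
)
def test_invalid_spec_raises_naming_the_field(kwargs, field):
    with pytest.raises(ValueError, match=field):
        CohortSpec(**kwargs)


def test_severe_fraction_calibrated_to_458_over_seeds():
    """Severity prevalence concentrates at 45.8% within binomial error."""
    fracs = []
    for seed in range(8):
        subs = generate_cohort(CohortSpec(n_subjects=300, seed=seed))
        fracs.append(np.mean([s.labels.severity for s in subs]))
    pooled_n = 8 * 300
    se = np.sqrt(0.458 * 0.542 / pooled_n)
    assert abs(np.mean(fracs) - 0.458) < 4 * se


def test_expected_severe_count_at_reference_cohort_size():
    """At n = 1188 (the reference cohort size) about 544 subjects (45.8%) are severe."""
    subs = generate_cohort(CohortSpec(n_subjects=1188, seed=5, image_size=(16, 16)))
    count = sum(s.labels.severity for s in subs)
    se = np.sqrt(1188 * 0.458 * 0.542)
    assert abs(count - 544) < 3 * se
    # the split implied by the group sizes themselves
    assert 544 / 1188 == pytest.approx(0.458, abs=5e-4)


def test_lesion_mask_iff_severe_and_marks_expected_intensity_difference(small_cohort):
    _, subs = small_cohort
    for s in subs:
        assert s.lesion_mask.any() == (s.labels.severity == 1)
        assert s.lesion_mask.shape == s.image.pixels.shape
    # expected intensity differs between labels exactly on mask pixels
    sev = np.stack([s.image.pixels for s in subs if s.labels.severity == 1])
    non = np.stack([s.image.pixels for s in subs if s.labels.severity == 0])
    mask = next(s.lesion_mask for s in subs if s.labels.severity == 1)
    diff = np.abs(sev.mean(axis=0) - non.mean(axis=0))
    noise_floor = 4 * 0.05 / np.sqrt(min(len(sev), len(non)))
    assert diff[mask].min() > noise_floor
    assert np.median(diff[~mask]) < noise_floor


def test_zero_lesion_effect_images_carry_no_class_signal():
    """With lesion_effect 0 severe and non-severe images are exchangeable."""
    subs = generate_cohort(CohortSpec(n_subjects=400, seed=9, lesion_effect=0.0))
    y = np.array([s.labels.severity for s in subs])
    assert not any(s.lesion_mask.any() for s in subs)
    # crest-band mean intensity is the sufficient statistic of the planted
    # lesion; with no lesion its class-conditional means coincide
    c0, c1 = synthetic._crest_rows(32)
    means = np.array([s.image.pixels[c0:c1, :].mean() for s in subs])
    gap = means[y == 1].mean() - means[y == 0].mean()
    assert abs(gap) < 4 * 0.05 / np.sqrt(len(subs) / 4)


def test_generation_deterministic_and_csv_byte_identical(tmp_path):
    spec = CohortSpec(n_subjects=30, seed=123, missing_rate=0.1)
    a = tmp_path / "a"
    b = tmp_path / "b"
    write_cohort(generate_cohort(spec), a)
    write_cohort(generate_cohort(spec), b)
    assert (a / "subjects.csv").read_bytes() == (b / "subjects.csv").read_bytes()
    assert (a / "manifest.csv").read_bytes() == (b / "manifest.csv").read_bytes()


def test_write_read_round_trip(tmp_path, small_cohort):
    _, subs = small_cohort
    out = tmp_path / "cohort"
    manifest = write_cohort(subs, out)
    assert manifest.exists()
    table, images = read_cohort(out)
    assert len(table.records) == len(subs) == len(images)
    # tabular values round-trip bit-exactly
    for rec, sub in zip(table.records, subs):
        for col in ("age", "income", "perio_stage"):
            assert getattr(rec, col) == getattr(sub.tabular, col)
        assert table.ids == [s.subject_id for s in subs]
    # images round-trip to 8-bit quantization
    for img, sub in zip(images, subs):
        assert np.abs(img.pixels - np.clip(sub.image.pixels, 0, 1)).max() <= 1 / 255 + 1e-9


def test_missingness_rate_and_location(tmp_path):
    """About missing_rate of the maskable cells are written empty."""
    n_missing = 0
    n_cells = 0
    for seed in range(6):
        subs = generate_cohort(CohortSpec(n_subjects=100, seed=seed, missing_rate=0.1))
        for s in subs:
            for col in synthetic.MASKABLE_COLUMNS:
                n_cells += 1
                if getattr(s.tabular, col) is None:
                    n_missing += 1
            # only bone-level columns are ever masked
            for col in ("age", "gender", "income", "n_teeth", "perio_stage"):
                assert getattr(s.tabular, col) is not None
    rate = n_missing / n_cells
    se = np.sqrt(0.1 * 0.9 / n_cells)
    assert abs(rate - 0.1) < 4 * se


def test_chapter_prevalences_match_request():
    prev = {"III": 0.3, "IX": 0.4}
    counts = {"III": 0, "IX": 0}
    n_total = 0
    for seed in range(5):
        subs = generate_cohort(
            CohortSpec(n_subjects=300, seed=seed, chapter_prevalences=prev)
        )
        n_total += len(subs)
        for ch in prev:
            counts[ch] += sum(s.labels.chapters[ch] for s in subs)
    for ch, p in prev.items():
        se = np.sqrt(p * (1 - p) / n_total)
        assert abs(counts[ch] / n_total - p) < 4 * se


def test_unimodal_bayes_auc_matches_quadrature_oracle():
    """Ranking the severe label by one latent factor reproduces the
    deterministic quadrature value of the thresholded-normal model."""
    oracle = theory.unimodal_severity_auc(0.5)
    assert oracle == pytest.approx(0.8267, abs=5e-4)  # frozen quadrature value
    rng = np.random.default_rng(77)
    n = 200_000
    z_img = rng.standard_normal(n)
    z_tab = rng.standard_normal(n)
    s = np.sqrt(0.5) * z_img + np.sqrt(0.5) * z_tab
    y = (s > theory.severity_threshold()).astype(int)
    # Monte-Carlo AUC of the single-factor ranking
    from perifuse.evaluation import mann_whitney_auc

    sub = rng.choice(n, 4000, replace=False)
    mc = mann_whitney_auc(y[sub], z_img[sub])
    assert mc == pytest.approx(oracle, abs=0.02)


def test_fused_bayes_auc_exceeds_each_unimodal():
    """The full latent score separates the thresholded label perfectly,
    strictly beating each single-modality Bayes AUC."""
    uni = theory.unimodal_severity_auc(0.5)
    assert theory.fused_severity_auc() == 1.0 > uni
    # quadrature cross-check on the unconditional Gaussian-shift model
    assert theory.gaussian_shift_auc(0.0) == pytest.approx(0.5)
    assert theory.gaussian_shift_auc(2.0) == pytest.approx(norm.cdf(np.sqrt(2.0)))
    # more informative factor -> higher unimodal AUC, up to 1 at weight 1
    assert uni < theory.unimodal_severity_auc(0.8) < theory.unimodal_severity_auc(1.0) + 1e-12
    assert theory.unimodal_severity_auc(1.0) == pytest.approx(1.0, abs=1e-9)
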