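"""Subject-table parsing, imputation, balancing and split plans."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perifuse import tabular
from perifuse.tabular import (
    SubjectRecord,
    binarize_severity,
    downsample_balance,
    make_split,
    mean_impute,
    read_subject_table,
)

_HEADER = (
    "subject_id,age,gender,income,n_teeth,perio_stage,extent_bone_loss,"
    "bone_loss_max,age_adj_bone_loss,stage_group,ch_III,ch_IX"
)


def _write(tmp_path, rows):
    p = tmp_path / "subjects.csv"
    p.write_text("\n".join([_HEADER, *rows]) + "\n")
    return p


def _row(sid, stage="Stage I", bone="3.5", ch=("0", "1")):
    return f"{sid},50,1,30000,28,2,20,{bone},0.5,{stage},{ch[0]},{ch[1]}"


def test_well_formed_table_parses_with_flags(tmp_path):
    rows = [_row(f"S{i}") for i in range(5)]
    rows[2] = _row("S2", bone="")  # missing bone_loss_max
    table = read_subject_table(_write(tmp_path, rows))
    assert len(table.records) == 5
    assert table.records[2].missing_fields() == ["bone_loss_max"]
    assert table.records[0].missing_fields() == []
    assert table.labels[0].chapters == {"III": 0, "IX": 1}


@pytest.mark.parametrize(
    "rows, message",
    [
        ([_row("S1"), _row("S1")], "S1"),  # duplicate id
        ([_row("S1", bone="abc")], "bone_loss_max"),  # non-numeric
        ([_row("S1", stage="Stage V")], "Stage V"),  # unknown category
    ],
)
def test_malformed_table_raises_descriptive_error(tmp_path, rows, message):
    with pytest.raises(ValueError, match=message):
        read_subject_table(_write(tmp_path, rows))


def test_unknown_column_rejected(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text(_HEADER + ",extra\n" + _row("S1") + ",1\n")
    with pytest.raises(ValueError, match="extra"):
        read_subject_table(p)


def _rec(sid, **kw):
    base = dict(
        age=50.0, gender=1.0, income=3e4, n_teeth=28.0, perio_stage=2.0,
        extent_bone_loss=20.0, bone_loss_max=3.5, age_adj_bone_loss=0.5,
    )
    base.update(kw)
    return SubjectRecord(subject_id=sid, **base)


def test_mean_impute_fills_with_observed_mean():
    recs = [_rec("a", bone_loss_max=2.0), _rec("b", bone_loss_max=None), _rec("c", bone_loss_max=4.0)]
    out = mean_impute(recs)
    assert out[1].bone_loss_max == pytest.approx(3.0)
    assert out[0].bone_loss_max == 2.0  # observed untouched
    assert recs[1].bone_loss_max is None  # input not mutated


def test_mean_impute_identity_without_missing_and_errors_on_empty_column():
    recs = [_rec("a"), _rec("b")]
    assert [vars(r) for r in mean_impute(recs)] == [vars(r) for r in recs]
    holes = [_rec("a", bone_loss_max=None), _rec("b", bone_loss_max=None)]
    with pytest.raises(ValueError, match="bone_loss_max"):
        mean_impute(holes)


@settings(deadline=None, max_examples=30)
@given(
    values=st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=30),
    missing=st.sets(st.integers(0, 29)),
)
def test_imputation_preserves_column_mean(values, missing):
    """Replacing holes with the observed mean leaves the column mean fixed."""
    observed = [v for i, v in enumerate(values) if i not in missing]
    if not observed:
        return
    recs = [
        _rec(str(i), age=(None if i in missing else v)) for i, v in enumerate(values)
    ]
    out = mean_impute(recs)
    assert np.mean([r.age for r in out]) == pytest.approx(np.mean(observed), abs=1e-9)


@pytest.mark.parametrize(
    "group, expected",
    [
        ("Stage IV", 1),
        ("Stage III generalized", 1),
        ("Stage III localized", 0),
        ("gingivitis", 0),
        ("health", 0),
        ("Stage I", 0),
        ("Stage II", 0),
    ],
)
def test_severity_binarization(group, expected):
    assert binarize_severity(group) == expected


def test_downsample_triggers_only_when_extremely_unbalanced():
    ids = [f"i{k}" for k in range(130)]
    labels = [1] * 30 + [0] * 100
    out = downsample_balance(ids, labels, seed=0)
    kept = [l for i, l in zip(ids, labels) if i in set(out)]
    assert sum(kept) == 30 and len(kept) == 60  # 100/30 -> 30/30
    assert set(ids[:30]) <= set(out)  # minority fully retained
    # 50 vs 30: majority not more than double -> unchanged
    ids2, labels2 = ids[:80], [1] * 30 + [0] * 50
    assert downsample_balance(ids2, labels2, seed=0) == ids2
    # already balanced -> unchanged
    assert downsample_balance(ids[:60], [1] * 30 + [0] * 30, seed=0) == ids[:60]
    # deterministic given seed
    assert downsample_balance(ids, labels, seed=5) == downsample_balance(ids, labels, seed=5)
    with pytest.raises(ValueError, match="class"):
        downsample_balance(ids[:10], [1] * 10, seed=0)


def test_make_split_stratified_disjoint_deterministic():
    rng = np.random.default_rng(0)
    ids = [f"s{k}" for k in range(100)]
    labels = np.array([1] * 50 + [0] * 50)
    plan = make_split(ids, labels, seed=4)
    assert len(plan.train_ids) == 70 and len(plan.test_ids) == 30
    assert set(plan.train_ids) | set(plan.test_ids) == set(ids)
    assert not set(plan.train_ids) & set(plan.test_ids)
    lab = dict(zip(ids, labels))
    train_pos = sum(lab[i] for i in plan.train_ids)
    assert abs(train_pos - 35) <= 1  # stratified within one subject
    sizes = [len(plan.fold_ids(f)) for f in range(10)]
    assert max(sizes) - min(sizes) <= 1
    assert sorted(sum([plan.fold_ids(f) for f in range(10)], [])) == sorted(plan.train_ids)
    plan2 = make_split(ids, labels, seed=4)
    assert plan.train_ids == plan2.train_ids
    assert plan.fold_assignments == plan2.fold_assignments
    with pytest.raises(ValueError, match="class"):
        make_split(ids, [1] * 95 + [0] * 5, seed=0)


def test_split_plan_json_round_trip(tmp_path):
    ids = [f"s{k}" for k in range(60)]
    labels = [1] * 30 + [0] * 30
    plan = make_split(ids, labels, k=5, seed=9)
    path = tmp_path / "split.json"
    plan.to_json(path)
    loaded = tabular.SplitPlan.from_json(path)
    assert loaded == plan
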