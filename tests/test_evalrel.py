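"""Unit tests for metrics, pairing designs, aggregation, and statistics."""

import numpy as np
import pandas as pd
import pytest

from motionseg.core_io import LabelMask, default_scheme
from motionseg.evalrel import (
    StatResult,
    aggregate,
    bh_adjust,
    bh_adjust_pvalues,
    build_pairs,
    compare_methods,
    dsc,
    evaluate_pairs,
    hausdorff,
    iou,
    per_region_metrics,
    volumetric_difference,
)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def test_dsc_iou_basic_and_nan():
    a = np.zeros((4, 4, 4), bool); a[:2] = True
    b = np.zeros((4, 4, 4), bool); b[1:3] = True
    assert dsc(a, b) == pytest.approx(2 * 16 / (32 + 32))
    assert iou(a, b) == pytest.approx(16 / 48)
    assert dsc(a, a) == 1.0
    empty = np.zeros((4, 4, 4), bool)
    assert np.isnan(dsc(empty, empty))
    assert np.isnan(iou(empty, empty))
    assert dsc(a, empty) == 0.0
    assert iou(a, empty) == 0.0
    with pytest.raises(ValueError, match="shapes"):
        dsc(a, np.zeros((3, 3, 3), bool))


def test_hausdorff_hand_example():
    a = np.zeros((8, 8, 8), bool); a[1, 1, 1] = True
    b = np.zeros((8, 8, 8), bool); b[1, 1, 4] = True
    assert hausdorff(a, b) == pytest.approx(3.0)
    # anisotropic spacing scales the distance
    assert hausdorff(a, b, spacing=(1, 1, 0.5)) == pytest.approx(1.5)
    assert np.isnan(hausdorff(a, np.zeros((8, 8, 8), bool)))
    assert hausdorff(a, a) == 0.0


def test_hausdorff_percentile_robust_to_outlier():
    a = np.zeros((20, 8, 8), bool); a[1, 1, 1:5] = True
    b = a.copy(); b[18, 1, 1] = True  # one far outlier voxel in b
    assert hausdorff(a, b) == pytest.approx(17.0)
    assert hausdorff(a, b, percentile=50) < 17.0


def test_volumetric_difference():
    assert volumetric_difference(100.0, 80.0) == pytest.approx(0.2)
    assert volumetric_difference(100.0, 120.0) == pytest.approx(0.2)
    assert np.isnan(volumetric_difference(0.0, 5.0))
    with pytest.raises(ValueError):
        volumetric_difference(-1.0, 5.0)


def test_per_region_metrics_rows():
    s = default_scheme()
    ref = np.zeros((6, 6, 6), np.int32); ref[0:3] = 5
    cmp_ = np.zeros((6, 6, 6), np.int32); cmp_[1:4] = 5; cmp_[5, 5, 5] = 7
    rows = per_region_metrics(
        LabelMask(labels=ref, scheme=s), LabelMask(labels=cmp_, scheme=s)
    )
    # regions present in either mask, never Unknown
    assert sorted(rows["region_id"]) == [5, 7]
    r5 = rows[rows["region_id"] == 5].iloc[0]
    assert r5["dsc"] == pytest.approx(2 * 72 / (108 + 108))
    assert r5["iou"] == pytest.approx(r5["dsc"] / (2 - r5["dsc"]))
    r7 = rows[rows["region_id"] == 7].iloc[0]
    assert r7["dsc"] == 0.0
    assert np.isnan(r7["vd"])  # region absent from the reference


def test_per_region_metrics_scheme_mismatch():
    s = default_scheme()
    other = s.merged({i: (0 if i > 5 else i) for i in s.ids})
    m1 = LabelMask(labels=np.zeros((4, 4, 4), np.int32) + 1, scheme=s)
    m2 = LabelMask(labels=np.zeros((4, 4, 4), np.int32) + 1, scheme=other)
    with pytest.raises(ValueError, match="scheme"):
        per_region_metrics(m1, m2)


# ---------------------------------------------------------------------------
# Pairing designs
# ---------------------------------------------------------------------------

def _roster():
    rows = []
    for subj, conv_tier in (("sub-000", "HM1"), ("sub-001", "HM2")):
        rows.append(dict(subject=subj, method="m", record_id=f"{subj}_CONV",
                         condition="CONV", session=0, tier=conv_tier))
        rows.append(dict(subject=subj, method="m", record_id=f"{subj}_MOVE1",
                         condition="MOVE1", session=1, tier="HM2"))
        rows.append(dict(subject=subj, method="m", record_id=f"{subj}_MOVE2",
                         condition="MOVE2", session=2, tier="HM3"))
    return pd.DataFrame(rows)


def test_build_pairs_head_motion_excludes_bad_reference():
    pairs = build_pairs(_roster(), "head_motion")
    # sub-001's rest scan is HM2, so the subject is excluded entirely
    assert set(pairs["subject"]) == {"sub-000"}
    assert sorted(pairs["pairing_type"]) == ["HM1-HM2", "HM1-HM3"]
    assert (pairs["ref_record"] == "sub-000_CONV").all()
    excl = pairs.attrs["excluded"]
    assert len(excl) == 1 and excl[0]["subject"] == "sub-001"


def test_build_pairs_test_retest():
    roster = _roster()
    pairs = build_pairs(roster, "test_retest")
    # every within-subject combination: C(3,2) = 3 per subject
    assert len(pairs) == 6
    assert (pairs["pairing_type"] == "TR").all()
    # earlier record (by session) is always the reference
    first = pairs.iloc[0]
    assert first["ref_record"].endswith("CONV")
    with pytest.raises(ValueError, match="design"):
        build_pairs(roster, "nope")
    with pytest.raises(ValueError, match="lacks columns"):
        build_pairs(roster.drop(columns=["tier"]), "head_motion")


def test_evaluate_pairs_lookup():
    s = default_scheme()
    labels = np.zeros((5, 5, 5), np.int32); labels[1:4] = 5
    m = LabelMask(labels=labels, scheme=s)
    roster = _roster().iloc[:3]
    pairs = build_pairs(roster, "head_motion")
    rows = evaluate_pairs(pairs, {r: m for r in roster["record_id"]})
    assert (rows["dsc"] == 1.0).all()
    # method-scoped lookup takes precedence
    rows2 = evaluate_pairs(
        pairs, {("m", r): m for r in roster["record_id"]}
    )
    assert len(rows2) == len(rows)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def test_aggregate_skips_nan_and_counts():
    rows = pd.DataFrame(
        {
            "subject": ["s"] * 3, "method": ["m"] * 3,
            "macro_region": ["cortical"] * 3, "pairing_type": ["HM1-HM2"] * 3,
            "region_id": [1, 2, 3],
            "dsc": [0.8, np.nan, 0.6], "iou": [0.7, 0.5, 0.6],
            "hd_mm": [1.0, 2.0, np.nan], "vd": [0.1, 0.2, 0.3],
        }
    )
    out = aggregate(rows)
    assert len(out) == 1
    r = out.iloc[0]
    assert r["dsc"] == pytest.approx(0.7)
    assert r["n_excluded_dsc"] == 1
    assert r["n_excluded_hd_mm"] == 1
    assert r["n_excluded_iou"] == 0
    assert r["n_rows"] == 3


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _summary_two_methods(n=6, delta=0.05):
    rows = []
    rng = np.random.default_rng(0)
    for i in range(n):
        base = 0.8 + 0.01 * rng.random()
        # distinct per-subject shifts (no rank ties) of the same sign
        shift = delta * (1 + 0.1 * i) if delta else 0.0
        for method, v in (("a", base + shift), ("b", base)):
            rows.append(dict(subject=f"s{i}", method=method,
                             macro_region="cortical", pairing_type="HM1-HM2",
                             dsc=v, iou=v, hd_mm=1.0, vd=0.1))
    return pd.DataFrame(rows)


def test_wilcoxon_exact_small_n():
    """n = 6 all-positive paired shifts: exact two-sided p = 2/64 = 0.03125."""
    res = compare_methods(_summary_two_methods(), "a", "b", "dsc",
                          "cortical", "HM1-HM2")
    assert res.test_name == "wilcoxon"
    assert res.p_raw == pytest.approx(0.03125)


def test_mannwhitney_when_subjects_differ():
    df = _summary_two_methods(n=6)
    df.loc[df["method"] == "b", "subject"] = [f"t{i}" for i in range(6)]
    res = compare_methods(df, "a", "b", "dsc", "cortical", "HM1-HM2")
    assert res.test_name == "mannwhitney"
    assert 0 <= res.p_raw <= 1


def test_degenerate_all_zero_differences():
    res = compare_methods(_summary_two_methods(delta=0.0), "a", "b", "dsc",
                          "cortical", "HM1-HM2")
    assert res.degenerate
    assert res.test_name == "degenerate"


def test_compare_requires_three_observations():
    with pytest.raises(ValueError, match=">= 3"):
        compare_methods(_summary_two_methods(n=2), "a", "b", "dsc",
                        "cortical", "HM1-HM2")


def test_bh_worked_example():
    adj = bh_adjust_pvalues([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
    with pytest.raises(ValueError):
        bh_adjust_pvalues([0.5, 1.2])


def test_bh_adjust_per_metric_families():
    def res(metric, p):
        return StatResult(method_a="a", method_b="b", metric=metric,
                          macro_region="c", pairing_type="t",
                          test_name="wilcoxon", statistic=0.0, p_raw=p,
                          n_a=6, n_b=6)

    results = [res("dsc", 0.01), res("dsc", 0.4), res("vd", 0.01)]
    bh_adjust(results)
    # families are per metric: the lone vd p-value is unchanged
    assert results[2].p_adjusted == pytest.approx(0.01)
    assert results[0].p_adjusted == pytest.approx(0.02)
    assert results[1].p_adjusted == pytest.approx(0.4)
    assert results[0].significant and not results[1].significant
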