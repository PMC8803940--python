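"""Per-region segmentation-similarity metrics and reliability statistics.

Metrics (per region, region binarized): Dice similarity coefficient (DSC),
intersection over union (IoU, Jaccard), symmetric Hausdorff distance between
boundary voxels in mm (95th-percentile variant available), and the relative
volumetric difference VD = |V_g - V_p| / V_g with the reference mask as
ground truth.  Undefined values (empty regions, V_g = 0) are flagged as NaN,
excluded from averages, and counted.

Pairing designs: ``head_motion`` pairs each subject's no-motion reference
mask (only subjects whose rest acquisition is tier HM1) with every motion
acquisition's mask (pairing type HM1-<tier>); ``test_retest`` pairs every
within-subject mask pair, the earlier record serving as ground truth.

Method comparison: Wilcoxon signed-rank on per-subject aggregated values
when both methods cover identical subject sets, Mann-Whitney U otherwise;
all tests two-sided; Benjamini-Hochberg correction applied within each
evaluation metric's family; significance at adjusted p < 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .core_io import LabelMask, LabelScheme

METRICS = ("dsc", "iou", "hd_mm", "vd")


# ---------------------------------------------------------------------------
# Mask-pair metrics
# ---------------------------------------------------------------------------

def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); NaN when both masks are empty."""
    _check_shapes(a, b)
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return float("nan")
    return 2.0 * int((a & b).sum()) / (sa + sb)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index |A∩B| / |A∪B|; NaN when both masks are empty."""
    _check_shapes(a, b)
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = int((a | b).sum())
    if union == 0:
        return float("nan")
    return int((a & b).sum()) / union


def _boundary_coords(mask: np.ndarray, spacing) -> np.ndarray:
    """Boundary voxels (eroded-interior removed) as physical coordinates."""
    m = np.asarray(mask, bool)
    interior = ndimage.binary_erosion(m)
    boundary = m & ~interior
    coords = np.argwhere(boundary)
    return coords * np.asarray(spacing, dtype=np.float64)


def hausdorff(
    a: np.ndarray,
    b: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    percentile: float | None = None,
) -> float:
    """Symmetric Hausdorff distance between boundary-voxel sets in mm.

    ``percentile`` switches to the percentile variant (e.g. 95); default is
    the classical maximum.  NaN when either mask is empty.
    """
    _check_shapes(a, b)
    if not np.asarray(a, bool).any() or not np.asarray(b, bool).any():
        return float("nan")
    pa = _boundary_coords(a, spacing)
    pb = _boundary_coords(b, spacing)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    if percentile is None:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))


def volumetric_difference(v_g: float, v_p: float) -> float:
    """Relative absolute volume error |V_g - V_p| / V_g; NaN when V_g = 0."""
    if v_g < 0 or v_p < 0:
        raise ValueError("volumes must be nonnegative")
    if v_g == 0:
        return float("nan")
    return abs(v_g - v_p) / v_g


# ---------------------------------------------------------------------------
# Per-region rows
# ---------------------------------------------------------------------------

def per_region_metrics(
    ref: LabelMask,
    cmp: LabelMask,
    spacing=(1.0, 1.0, 1.0),
    hd_percentile: float | None = None,
) -> pd.DataFrame:
    """All four metrics per non-Unknown region present in either mask.

    ``ref`` is the ground truth for VD.  The Unknown label is never a
    region.  Returns one row per region with columns region_id, region_name,
    macro_region, dsc, iou, hd_mm, vd.
    """
    if ref.shape != cmp.shape:
        raise ValueError(f"mask shapes differ: {ref.shape} vs {cmp.shape}")
    if ref.scheme.entries != cmp.scheme.entries:
        raise ValueError("label schemes differ between the two masks")
    scheme = ref.scheme
    regions = sorted(
        (set(ref.present_labels()) | set(cmp.present_labels())) - {scheme.unknown_id}
    )
    rows = []
    for rid in regions:
        ra = ref.labels == rid
        rb = cmp.labels == rid
        rows.append(
            {
                "region_id": rid,
                "region_name": scheme.name(rid),
                "macro_region": scheme.macro_region(rid),
                "dsc": dsc(ra, rb),
                "iou": iou(ra, rb),
                "hd_mm": hausdorff(ra, rb, spacing, percentile=hd_percentile),
                "vd": volumetric_difference(float(ra.sum()), float(rb.sum())),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pairing designs
# ---------------------------------------------------------------------------

def build_pairs(roster: pd.DataFrame, design: str) -> pd.DataFrame:
    """Build the evaluation pair list from a roster table.

    The roster must carry columns subject, method, record_id, condition,
    session, tier (head_motion) or session order (test_retest), and a mask
    reference column (any of mask_path / pred_path / record_id is carried
    through).  Returns rows (pair_id, subject, method, pairing_type,
    ref_record, cmp_record); excluded subjects are reported in the attrs.
    """
    required = {"subject", "method", "record_id", "condition", "session", "tier"}
    missing = required - set(roster.columns)
    if missing:
        raise ValueError(f"roster lacks columns {sorted(missing)}")
    pairs = []
    excluded = []
    if design == "head_motion":
        for (subject, method), grp in roster.groupby(["subject", "method"], sort=True):
            conv = grp[grp["condition"] == "CONV"]
            if len(conv) != 1 or conv.iloc[0]["tier"] != "HM1":
                excluded.append(
                    {"subject": subject, "method": method,
                     "reason": "no usable HM1 rest reference"}
                )
                continue
            ref = conv.iloc[0]
            moves = grp[grp["condition"].str.startswith("MOVE")].sort_values("record_id")
            for _, row in moves.iterrows():
                pairs.append(
                    {
                        "subject": subject, "method": method,
                        "pairing_type": f"HM1-{row['tier']}",
                        "ref_record": ref["record_id"],
                        "cmp_record": row["record_id"],
                    }
                )
    elif design == "test_retest":
        for (subject, method), grp in roster.groupby(["subject", "method"], sort=True):
            grp = grp.sort_values(["session", "record_id"])
            for a, b in itertools.combinations(range(len(grp)), 2):
                pairs.append(
                    {
                        "subject": subject, "method": method, "pairing_type": "TR",
                        "ref_record": grp.iloc[a]["record_id"],
                        "cmp_record": grp.iloc[b]["record_id"],
                    }
                )
    else:
        raise ValueError(f"unknown design {design!r}")
    df = pd.DataFrame(pairs).drop_duplicates().reset_index(drop=True)
    if len(df):
        df.insert(0, "pair_id", [f"pair-{i:04d}" for i in range(len(df))])
    else:
        df = pd.DataFrame(
            columns=["pair_id", "subject", "method", "pairing_type",
                     "ref_record", "cmp_record"]
        )
    df.attrs["excluded"] = excluded
    return df


def evaluate_pairs(
    pairs: pd.DataFrame,
    masks: dict[str, LabelMask],
    spacing=(1.0, 1.0, 1.0),
    hd_percentile: float | None = None,
) -> pd.DataFrame:
    """Per-region metric rows for every pair.

    ``masks`` maps ``record_id`` — or ``(method, record_id)`` when the same
    acquisition is segmented by several methods — to its segmentation mask.
    """

    def lookup(method: str, record_id: str) -> LabelMask:
        if (method, record_id) in masks:
            return masks[(method, record_id)]
        return masks[record_id]

    out = []
    for _, p in pairs.iterrows():
        rows = per_region_metrics(
            lookup(p["method"], p["ref_record"]),
            lookup(p["method"], p["cmp_record"]),
            spacing=spacing, hd_percentile=hd_percentile,
        )
        for col in ("pair_id", "subject", "method", "pairing_type"):
            rows[col] = p[col]
        out.append(rows)
    if not out:
        return pd.DataFrame()
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate(rows: pd.DataFrame, scheme: LabelScheme | None = None) -> pd.DataFrame:
    """Average metrics across regions (and pairs) within each
    (subject, method, macro_region, pairing_type) cell.

    NaN (undefined) metric values are excluded from the means and counted in
    ``n_excluded_<metric>`` columns.
    """
    if "macro_region" not in rows.columns:
        if scheme is None:
            raise ValueError("rows lack macro_region and no scheme was given")
        rows = rows.assign(
            macro_region=[scheme.macro_region(r) for r in rows["region_id"]]
        )
    keys = ["subject", "method", "macro_region", "pairing_type"]
    agg = {m: "mean" for m in METRICS}  # pandas mean skips NaN
    out = rows.groupby(keys, sort=True).agg(agg)
    for m in METRICS:
        out[f"n_excluded_{m}"] = rows.groupby(keys, sort=True)[m].apply(
            lambda s: int(s.isna().sum())
        )
    out["n_rows"] = rows.groupby(keys, sort=True).size()
    return out.reset_index()


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass
class StatResult:
    """One method-vs-method comparison within a macro-region / pairing type."""

    method_a: str
    method_b: str
    metric: str
    macro_region: str
    pairing_type: str
    test_name: str  # "wilcoxon" | "mannwhitney" | "degenerate"
    statistic: float
    p_raw: float
    n_a: int
    n_b: int
    p_adjusted: float = float("nan")
    significant: bool = False
    degenerate: bool = False


def compare_methods(
    summary: pd.DataFrame,
    method_a: str,
    method_b: str,
    metric: str,
    macro_region: str,
    pairing_type: str,
) -> StatResult:
    """Two-sided nonparametric comparison of two methods.

    Uses an exact Wilcoxon signed-rank test on per-subject paired values
    when both methods cover identical subject sets, a Mann-Whitney U test
    otherwise.  All-zero paired differences are flagged as degenerate
    instead of tested.
    """
    sel = (summary["macro_region"] == macro_region) & (
        summary["pairing_type"] == pairing_type
    )
    a = summary[sel & (summary["method"] == method_a)].set_index("subject")[metric]
    b = summary[sel & (summary["method"] == method_b)].set_index("subject")[metric]
    a, b = a.dropna(), b.dropna()
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 observations per method")
    base = dict(
        method_a=method_a, method_b=method_b, metric=metric,
        macro_region=macro_region, pairing_type=pairing_type,
        n_a=len(a), n_b=len(b),
    )
    if set(a.index) == set(b.index):
        av = a.sort_index().to_numpy()
        bv = b.sort_index().to_numpy()
        diffs = av - bv
        if np.all(diffs == 0):
            return StatResult(
                test_name="degenerate", statistic=float("nan"),
                p_raw=float("nan"), degenerate=True, **base,
            )
        res = stats.wilcoxon(av, bv, alternative="two-sided", method="exact")
        return StatResult(
            test_name="wilcoxon", statistic=float(res.statistic),
            p_raw=float(res.pvalue), **base,
        )
    res = stats.mannwhitneyu(a.to_numpy(), b.to_numpy(), alternative="two-sided")
    return StatResult(
        test_name="mannwhitney", statistic=float(res.statistic),
        p_raw=float(res.pvalue), **base,
    )


def bh_adjust(results: list[StatResult], alpha: float = 0.05) -> list[StatResult]:
    """Benjamini-Hochberg step-up correction, applied within each metric's
    family of comparisons; sets p_adjusted and significant in place."""
    by_metric: dict[str, list[StatResult]] = {}
    for r in results:
        if not r.degenerate:
            by_metric.setdefault(r.metric, []).append(r)
    for group in by_metric.values():
        ps = [r.p_raw for r in group]
        _, adj, _, _ = multipletests(ps, alpha=alpha, method="fdr_bh")
        for r, p in zip(group, adj):
            r.p_adjusted = float(p)
            r.significant = bool(p < alpha)
    return results


def bh_adjust_pvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for one family."""
    p = np.asarray(p_values, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def stat_results_frame(results: list[StatResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclass_asdict(r) for r in results])


def dataclass_asdict(r: StatResult) -> dict:
    import dataclasses

    return dataclasses.asdict(r)
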