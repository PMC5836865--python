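"""Threshold-based three-class maps and quantitative method agreement.

The threshold-based method (TBM) reduces each voxel to binary
enhancing/non-enhancing calls for DCE and OE and forms three classes:

1. non-enhancing in DCE (necrosis-like; OE status ignored),
2. DCE-enhancing but OE-refractory ("perfused Oxy-R", putatively hypoxic),
3. enhancing in both.

The enhancement call used here is a one-sided Welch t-test of the mean
post-event delta R1 against the pre-event frames, thresholded at a
configurable significance level — a documented stand-in for the original
(unpublished in detail) threshold; statistic and level are configurable.

Agreement between a clustering-derived map (concatenated to three classes)
and TBM is quantified by the proportion of identically classified voxels
(phi), Cohen's kappa, and Bland-Altman statistics on per-tumor class voxel
counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DeltaR1Matrix, RegionMap

__all__ = [
    "tbm_classify",
    "enhancement_call",
    "concatenate_odd",
    "proportional_agreement",
    "cohens_kappa",
    "confusion_matrix",
    "AgreementStats",
    "agreement_stats",
    "bland_altman",
    "bias_as_percent",
    "composition_ratio",
    "DEFAULT_GROUPING",
]

#: six habitat clusters -> three classes: 1 | {2,3} | {4,5,6}
DEFAULT_GROUPING = {1: 1, 2: 2, 3: 2, 4: 3, 5: 3, 6: 3}


def enhancement_call(matrix: DeltaR1Matrix, alpha_level: float = 0.05) -> np.ndarray:
    """Per-voxel one-sided enhancement test: mean post-event delta R1 > 0.

    Welch t-statistic of post-event versus pre-event frames with
    Welch-Satterthwaite degrees of freedom; a voxel is called enhancing when
    the one-sided p-value falls below ``alpha_level``.  NaN frames are
    ignored.  Requires at least 3 pre-event frames.
    """
    ev = matrix.event_frame
    if ev < 3:
        raise ValueError("too few pre-event frames for the enhancement test")
    pre = matrix.values[:, :ev]
    post = matrix.values[:, ev:]

    def mvn(x):
        n = np.sum(np.isfinite(x), axis=1).astype(float)
        m = np.nanmean(x, axis=1)
        v = np.nanvar(x, axis=1, ddof=1)
        return m, v, n

    m1, v1, n1 = mvn(post)
    m0, v0, n0 = mvn(pre)
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = v1 / n1 + v0 / n0
        t = (m1 - m0) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
    p = stats.t.sf(t, df)
    return np.where(np.isfinite(p), p < alpha_level, False)


def tbm_classify(
    dce: DeltaR1Matrix,
    oe: DeltaR1Matrix,
    grid_shape,
    tumor_id=None,
    alpha_level: float = 0.05,
) -> RegionMap:
    """Three-class threshold-based map from enhancement calls.

    Classes: (DCE-, any OE) -> 1; (DCE+, OE-) -> 2; (DCE+, OE+) -> 3.
    """
    if not np.array_equal(dce.coords, oe.coords):
        raise ValueError("DCE and OE matrices must cover the same voxels")
    dce_enh = enhancement_call(dce, alpha_level)
    oe_enh = enhancement_call(oe, alpha_level)
    classes = np.where(~dce_enh, 1, np.where(oe_enh, 3, 2))
    from .cluster import build_region_map

    legend = {1: "non-enhancing", 2: "perfused Oxy-R", 3: "perfused oxygenated"}
    rmap = build_region_map(classes, dce.coords, grid_shape, tumor_id=tumor_id, legend=legend)
    return rmap


def concatenate_odd(region_map: RegionMap, grouping: dict | None = None) -> RegionMap:
    """Collapse habitat clusters into the three comparison classes."""
    grouping = DEFAULT_GROUPING if grouping is None else grouping
    labels = region_map.labels
    present = set(np.unique(labels)) - {0}
    unknown = present - set(grouping)
    if unknown:
        raise ValueError(f"labels outside grouping domain: {sorted(unknown)}")
    out = np.zeros_like(labels)
    for old, new in grouping.items():
        out[labels == old] = new
    return RegionMap(labels=out, legend={}, tumor_id=region_map.tumor_id)


def _aligned_labels(a, b):
    """In-mask label vectors from two RegionMaps (same mask) or two 1-D arrays."""
    if isinstance(a, RegionMap) and isinstance(b, RegionMap):
        if a.labels.shape != b.labels.shape or not np.array_equal(a.mask, b.mask):
            raise ValueError("maps must share the same mask")
        return a.in_mask_labels(), b.in_mask_labels()
    la, lb = np.asarray(a).ravel(), np.asarray(b).ravel()
    if la.shape != lb.shape:
        raise ValueError("label vectors must be paired")
    return la, lb


def proportional_agreement(a: RegionMap, b: RegionMap) -> float:
    """Fraction of in-mask voxels assigned the same class (phi)."""
    la, lb = _aligned_labels(a, b)
    return float(np.mean(la == lb))


def confusion_matrix(a: RegionMap, b: RegionMap, n_classes: int = 3) -> np.ndarray:
    la, lb = _aligned_labels(a, b)
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for i, j in zip(la, lb):
        cm[i - 1, j - 1] += 1
    return cm


def cohens_kappa(a: RegionMap, b: RegionMap) -> float:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e).

    When both maps are constant (p_e = 1) kappa is defined as 1 if the maps
    are identical and 0 otherwise, with a warning — the chance correction is
    meaningless in that degenerate case.
    """
    la, lb = _aligned_labels(a, b)
    p_o = float(np.mean(la == lb))
    classes = np.union1d(la, lb)
    n = la.size
    p_e = float(
        sum((np.sum(la == c) / n) * (np.sum(lb == c) / n) for c in classes)
    )
    if p_e >= 1.0 - 1e-15:
        warnings.warn("both maps constant; kappa degenerate", stacklevel=2)
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class AgreementStats:
    confusion: np.ndarray
    phi: float
    kappa: float
    n_voxels: int


def agreement_stats(a: RegionMap, b: RegionMap) -> AgreementStats:
    la, _ = _aligned_labels(a, b)
    return AgreementStats(
        confusion=confusion_matrix(a, b),
        phi=proportional_agreement(a, b),
        kappa=cohens_kappa(a, b),
        n_voxels=int(la.size),
    )


def bias_as_percent(bias: float, mean_tumor_size: float) -> float:
    """A Bland-Altman bias (voxels) expressed as % of the mean tumor size."""
    if mean_tumor_size <= 0:
        raise ValueError("mean tumor size must be positive")
    return 100.0 * bias / mean_tumor_size


def bland_altman(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    tumor_sizes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-class Bland-Altman statistics on paired per-tumor voxel counts.

    ``counts_a``/``counts_b`` are (n_tumors, n_classes) arrays (method A
    minus method B defines the differences).  Returns per class the bias
    (mean difference), the 95% limits of agreement (bias +/- 1.96 SD), and
    the bias as a percentage of the mean tumor size.  With a single pair the
    limits are undefined (NaN).
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    if counts_a.shape != counts_b.shape:
        raise ValueError("count arrays must be paired")
    if tumor_sizes is None:
        tumor_sizes = counts_a.sum(axis=1)
    mean_size = float(np.mean(tumor_sizes))
    diffs = counts_a - counts_b
    rows = []
    for c in range(counts_a.shape[1]):
        d = diffs[:, c]
        bias = float(np.mean(d))
        if d.size >= 2:
            sd = float(np.std(d, ddof=1))
            lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
        else:
            lo = hi = np.nan
        rows.append(
            {
                "class": c + 1,
                "bias_voxels": bias,
                "loa_low": lo,
                "loa_high": hi,
                "bias_pct_mean_size": bias_as_percent(bias, mean_size),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["mean_tumor_size"] = mean_size
    return out


def composition_ratio(counts: dict) -> tuple[float, str, str]:
    """Ratio of the larger to the smaller count in a two-group composition.

    Returns ``(ratio, majority_group, minority_group)``; used to express
    cluster compositions such as voxel counts per tumor line.
    """
    if len(counts) != 2:
        raise ValueError("composition ratio is defined for exactly two groups")
    (g1, n1), (g2, n2) = counts.items()
    if n1 <= 0 or n2 <= 0:
        raise ValueError("counts must be positive")
    if n1 >= n2:
        return n1 / n2, g1, g2
    return n2 / n1, g2, g1
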