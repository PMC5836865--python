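"""Exclusion of erratically enhancing voxels before feature extraction.

Erratic voxels (boundary motion, large vessels) would dominate feature
calculation.  For each modality the area under the modulus of the delta
R1(t) curve is computed over the full series; the voxels with the highest
1% from each modality (union) are removed from the tumor ROI.

Interpretation choices (documented because they are not uniquely
determined): per-modality top ``ceil(fraction * N)`` with union removal,
ceiling rounding, and stable tie-break by (z, y, x) coordinate order.
Re-running the exclusion removes further voxels — it is intentionally not
idempotent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DeltaR1Matrix

__all__ = ["modulus_auc", "exclude_erratic_voxels"]


def modulus_auc(matrix: DeltaR1Matrix) -> np.ndarray:
    """Trapezoidal AUC of |delta R1(t)| over the full series, per voxel.

    Non-finite frames are filled by linear interpolation over time (edge
    frames by nearest finite value) before integration; all-NaN voxels get
    +inf so that they rank first for removal.
    """
    vals = matrix.values.copy()
    t = matrix.frame_times
    out = np.empty(matrix.n_voxels)
    for i in range(matrix.n_voxels):
        row = vals[i]
        finite = np.isfinite(row)
        if not finite.any():
            out[i] = np.inf
            continue
        if not finite.all():
            row = np.interp(t, t[finite], row[finite])
        out[i] = np.trapezoid(np.abs(row), t)
    return out


def _rank_order(auc: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Indices sorted by descending AUC, ties broken by (z, y, x) order."""
    # lexsort: last key is primary
    return np.lexsort((coords[:, 0], coords[:, 1], coords[:, 2], -auc))


def exclude_erratic_voxels(
    dce: DeltaR1Matrix,
    oe: DeltaR1Matrix,
    fraction: float = 0.01,
):
    """Remove the top-``fraction`` modulus-AUC voxels per modality (union).

    Voxels already flagged erratic upstream (failed signal inversion) are
    always removed.  Returns the reduced (dce, oe) pair plus a report
    listing every removed voxel and which modality (or upstream flag)
    triggered it.

    Raises if the voxel sets differ, ``fraction`` is outside [0, 0.5), or
    the result would be empty.
    """
    if not np.array_equal(dce.coords, oe.coords):
        raise ValueError("DCE and OE matrices must cover the same voxels")
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    n = dce.n_voxels
    n_remove = int(np.ceil(fraction * n)) if fraction > 0 else 0

    auc_dce = modulus_auc(dce)
    auc_oe = modulus_auc(oe)
    top_dce = _rank_order(auc_dce, dce.coords)[:n_remove]
    top_oe = _rank_order(auc_oe, oe.coords)[:n_remove]
    flagged = np.nonzero(dce.erratic | oe.erratic)[0]

    removed = np.union1d(np.union1d(top_dce, top_oe), flagged)
    keep = np.setdiff1d(np.arange(n), removed)
    if keep.size == 0:
        raise ValueError("exclusion would remove every voxel")

    rows = []
    top_dce_set, top_oe_set, flagged_set = set(top_dce), set(top_oe), set(flagged)
    for idx in removed:
        reasons = []
        if idx in top_dce_set:
            reasons.append("dce_auc")
        if idx in top_oe_set:
            reasons.append("oe_auc")
        if idx in flagged_set:
            reasons.append("erratic_flag")
        x, y, z = dce.coords[idx]
        rows.append(
            {
                "x": x, "y": y, "z": z,
                "auc_dce_mod": auc_dce[idx],
                "auc_oe_mod": auc_oe[idx],
                "reason": "+".join(reasons),
            }
        )
    report = pd.DataFrame(rows, columns=["x", "y", "z", "auc_dce_mod", "auc_oe_mod", "reason"])
    return dce.subset(keep), oe.subset(keep), report
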