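"""Feature extraction: the 2-D AUC set and the 4-D PCA set.

AUC features are *signed* trapezoidal areas (the modulus AUC is used only
for erratic-voxel exclusion): the area under the first 90 s post-injection
of the DCE delta R1(t) curve, and under all post-gas-switch frames of the OE
curve.  Sign preservation keeps non-enhancement and negative OE responses
representable.

PCA features are the per-voxel weightings on the leading principal
components of composite curves built by concatenating each voxel's DCE curve
with its OE curve, after scaling the OE block so that the mean per-voxel
temporal standard deviation matches that of the DCE block.  The
decomposition is computed once over the pooled cohort of voxels.  Component
signs are fixed so that each component's largest-magnitude loading is
positive, making outputs deterministic.
"""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA

from .containers import DeltaR1Matrix, FeatureSet

__all__ = ["auc_features", "scale_and_concatenate", "pca_features"]


def _window_auc(values: np.ndarray, times: np.ndarray, sel: np.ndarray) -> np.ndarray:
    if sel.sum() < 2:
        raise ValueError("fewer than 2 frames in the integration window")
    return np.trapezoid(values[:, sel], times[sel], axis=1)


def auc_features(
    dce: DeltaR1Matrix,
    oe: DeltaR1Matrix,
    tumor_ids: np.ndarray | None = None,
    window_dce_s: float = 90.0,
) -> FeatureSet:
    """Signed AUC features (units s^-1 * s = dimensionless R1-time area).

    AUC_DCE integrates frames with ``0 <= t - t_inj <= window_dce_s`` (no
    partial-frame interpolation at the endpoint: integration stops at the
    last frame inside the window).  AUC_OE integrates all frames with
    ``t >= t_switch``.
    """
    if not np.array_equal(dce.coords, oe.coords):
        raise ValueError("DCE and OE matrices must cover the same voxels")
    tp_dce = dce.frame_times - dce.event_time
    tp_oe = oe.frame_times - oe.event_time
    auc_dce = _window_auc(dce.values, dce.frame_times, (tp_dce >= 0) & (tp_dce <= window_dce_s))
    auc_oe = _window_auc(oe.values, oe.frame_times, tp_oe >= 0)
    if tumor_ids is None:
        tumor_ids = np.zeros(dce.n_voxels, dtype=int)
    matrix = np.column_stack([auc_dce, auc_oe])
    if not np.all(np.isfinite(matrix)):
        raise ValueError("non-finite AUC features; exclude erratic voxels first")
    return FeatureSet(
        matrix=matrix,
        names=["AUC_DCE", "AUC_OE"],
        coords=dce.coords,
        tumor_ids=np.asarray(tumor_ids),
        kind="auc",
        meta={"window_dce_s": window_dce_s},
    )


def scale_and_concatenate(dce: DeltaR1Matrix, oe: DeltaR1Matrix):
    """Composite per-voxel curves: [DCE curve, s * OE curve].

    The scale factor ``s`` equates the mean (over voxels) per-voxel temporal
    standard deviation of the two modalities: ``s = mean(SD_dce) /
    mean(SD_oe)``.  Sample SDs (ddof=1) are used.  Returns ``(composite,
    s)``.
    """
    if not np.array_equal(dce.coords, oe.coords):
        raise ValueError("DCE and OE matrices must cover the same voxels")
    sd_dce = np.std(dce.values, axis=1, ddof=1)
    sd_oe = np.std(oe.values, axis=1, ddof=1)
    mean_sd_oe = float(np.mean(sd_oe))
    if mean_sd_oe == 0:
        raise ValueError("OE curves have zero temporal variability")
    s = float(np.mean(sd_dce)) / mean_sd_oe
    composite = np.hstack([dce.values, s * oe.values])
    if not np.all(np.isfinite(composite)):
        raise ValueError("non-finite curves; exclude erratic voxels first")
    return composite, s


def pca_features(
    composite: np.ndarray,
    coords: np.ndarray,
    tumor_ids: np.ndarray | None = None,
    n_components: int = 4,
    oe_scale: float | None = None,
) -> FeatureSet:
    """Per-voxel weightings on the first ``n_components`` principal components.

    Mean-centered PCA over the pooled voxel population.  The returned
    FeatureSet carries the component vectors, the mean curve, and the
    explained-variance fractions (so the cumulative-variance curve can be
    reconstructed).  Raises if the centered data rank is below
    ``n_components``.
    """
    composite = np.asarray(composite, dtype=float)
    n, p = composite.shape
    if n < n_components:
        raise ValueError("need at least n_components voxels")
    pca = PCA(n_components=min(n - 1, p))
    scores = pca.fit_transform(composite)
    sv = pca.singular_values_
    tol = sv[0] * max(n, p) * np.finfo(float).eps if sv.size else 0.0
    if np.sum(sv > tol) < n_components:
        raise ValueError("data rank is below the requested number of components")

    components = pca.components_[:n_components].copy()
    scores = scores[:, :n_components].copy()
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(n_components):
        k = np.argmax(np.abs(components[j]))
        if components[j, k] < 0:
            components[j] *= -1
            scores[:, j] *= -1

    if tumor_ids is None:
        tumor_ids = np.zeros(n, dtype=int)
    return FeatureSet(
        matrix=scores,
        names=[f"PC_{j + 1}" for j in range(n_components)],
        coords=np.asarray(coords),
        tumor_ids=np.asarray(tumor_ids),
        kind="pca",
        meta={
            "components": components,
            "mean_curve": pca.mean_,
            "explained_variance_ratio": pca.explained_variance_ratio_.copy(),
            "oe_scale": oe_scale,
        },
    )
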