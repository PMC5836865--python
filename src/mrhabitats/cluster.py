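"""Gaussian-mixture habitat clustering.

:class:`HabitatMixture` is the model object: it is built from a
:class:`~mrhabitats.containers.FeatureSet` (pooled over the cohort) and its
:meth:`~HabitatMixture.fit` runs full-covariance EM from several random
initializations, keeping the restart with the highest log-likelihood.
:class:`HabitatMixtureResults` carries the estimates (means, covariances,
weights), per-voxel hard labels and responsibilities, the log-likelihood and
AIC, and methods to build per-tumor region maps and mean within-cluster
enhancement curves.

Cluster labels are canonicalized so that clusters 1..N_C are ordered by
increasing within-cluster mean DCE AUC, making labels comparable across
fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .containers import DeltaR1Matrix, FeatureSet, RegionMap

__all__ = [
    "HabitatMixture",
    "HabitatMixtureResults",
    "relabel_by_dce_auc",
    "build_region_map",
    "mean_cluster_curves",
]


class HabitatMixture:
    """Gaussian mixture model over a voxel feature set.

    Parameters
    ----------
    features : FeatureSet
        Pooled voxel-by-feature matrix (AUC or PCA flavour).
    auc_dce : ndarray, optional
        Per-voxel DCE AUC used for canonical cluster ordering.  Defaults to
        the ``AUC_DCE`` column when the feature set contains one; PCA
        feature sets must supply it explicitly for relabeling to happen.
    covariance_type : str
        sklearn covariance structure; full per-cluster covariances by
        default.
    """

    def __init__(
        self,
        features: FeatureSet,
        auc_dce: np.ndarray | None = None,
        covariance_type: str = "full",
    ):
        self.features = features
        if auc_dce is None and "AUC_DCE" in list(features.names):
            auc_dce = features.matrix[:, list(features.names).index("AUC_DCE")]
        self.auc_dce = None if auc_dce is None else np.asarray(auc_dce, dtype=float)
        if self.auc_dce is not None and self.auc_dce.shape != (features.n_voxels,):
            raise ValueError("auc_dce must be one value per voxel")
        self.covariance_type = covariance_type

    def fit(
        self,
        n_clusters: int,
        n_restarts: int = 10,
        random_state: int | None = None,
        max_iter: int = 500,
        tol: float = 1e-4,
        reg_scale: float = 1e-6,
    ) -> "HabitatMixtureResults":
        """Best-of-``n_restarts`` EM fit with ``n_clusters`` components.

        Initial means are drawn from random data points; covariances are
        regularized by ``reg_scale`` times the mean feature variance on the
        diagonal.  Deterministic given ``random_state``.  ``tol`` is the EM
        stopping threshold on the change in mean per-sample log-likelihood;
        the default trades a negligible likelihood plateau for a large
        iteration saving (past it, EM only creeps along near-degenerate
        directions without moving assignments).
        """
        X = self.features.matrix
        if not 1 <= n_clusters <= 25:
            raise ValueError("n_clusters must be in [1, 25]")
        if X.shape[0] <= n_clusters:
            raise ValueError("need more voxels than clusters")
        reg_covar = reg_scale * float(np.mean(np.var(X, axis=0)))
        gmm = GaussianMixture(
            n_components=n_clusters,
            covariance_type=self.covariance_type,
            n_init=n_restarts,
            init_params="random_from_data",
            max_iter=max_iter,
            tol=tol,
            reg_covar=max(reg_covar, 1e-12),
            random_state=random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gmm.fit(X)
        resp = gmm.predict_proba(X)
        llf = float(gmm.score(X) * X.shape[0])
        res = HabitatMixtureResults(
            model=self,
            n_clusters=n_clusters,
            means=gmm.means_.copy(),
            covariances=_full_covariances(gmm),
            weights=gmm.weights_.copy(),
            llf=llf,
            labels=np.argmax(resp, axis=1) + 1,
            responsibilities=resp,
            n_restarts=n_restarts,
            random_state=random_state,
            converged=bool(gmm.converged_),
            permutation=np.arange(n_clusters),
        )
        if self.auc_dce is not None:
            res = relabel_by_dce_auc(res, self.auc_dce)
        return res


def _full_covariances(gmm: GaussianMixture) -> np.ndarray:
    """Covariances as (n_components, d, d) regardless of covariance_type."""
    k, d = gmm.means_.shape
    c = gmm.covariances_
    if gmm.covariance_type == "full":
        return c.copy()
    if gmm.covariance_type == "tied":
        return np.repeat(c[None], k, axis=0)
    if gmm.covariance_type == "diag":
        return np.stack([np.diag(row) for row in c])
    return np.stack([np.eye(d) * v for v in c])  # spherical


@dataclass
class HabitatMixtureResults:
    """Fitted mixture: estimates, per-voxel assignments, and diagnostics."""

    model: HabitatMixture
    n_clusters: int
    means: np.ndarray  # (N_C, d)
    covariances: np.ndarray  # (N_C, d, d)
    weights: np.ndarray  # (N_C,)
    llf: float
    labels: np.ndarray  # (n_voxels,), 1-based
    responsibilities: np.ndarray  # (n_voxels, N_C)
    n_restarts: int
    random_state: int | None
    converged: bool
    permutation: np.ndarray  # old (0-based) -> new (0-based) applied so far

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    @property
    def n_free_parameters(self) -> int:
        """Free parameters of a full-covariance mixture: means + covariances
        + weights (one weight constrained by the simplex)."""
        k, d = self.n_clusters, self.n_features
        return k * d + k * d * (d + 1) // 2 + (k - 1)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free_parameters - 2.0 * self.llf

    def region_map(
        self, grid_shape, tumor_id=None, voxel_filter: np.ndarray | None = None
    ) -> RegionMap:
        coords = self.model.features.coords
        labels = self.labels
        if voxel_filter is not None:
            coords = coords[voxel_filter]
            labels = labels[voxel_filter]
        return build_region_map(labels, coords, grid_shape, tumor_id=tumor_id)

    def summary(self) -> str:
        lines = [
            "Gaussian mixture habitat model",
            "=" * 46,
            f"feature set:     {self.model.features.kind} (d={self.n_features})",
            f"voxels:          {self.model.features.n_voxels}",
            f"clusters (N_C):  {self.n_clusters}",
            f"restarts:        {self.n_restarts}",
            f"log-likelihood:  {self.llf:.3f}",
            f"AIC:             {self.aic:.3f}   (k={self.n_free_parameters})",
            f"converged:       {self.converged}",
            "-" * 46,
            "cluster   weight   n_voxels   mean",
        ]
        for j in range(self.n_clusters):
            n_j = int(np.sum(self.labels == j + 1))
            mean_str = np.array2string(self.means[j], precision=3, separator=", ")
            lines.append(f"{j + 1:7d}   {self.weights[j]:.4f}   {n_j:8d}   {mean_str}")
        return "\n".join(lines)


def relabel_by_dce_auc(
    result: HabitatMixtureResults, auc_dce: np.ndarray
) -> HabitatMixtureResults:
    """Reorder clusters 1..N_C by increasing within-cluster mean DCE AUC.

    All fields (means, covariances, weights, labels, responsibilities) are
    permuted consistently; empty clusters and exact ties keep their original
    relative order.  Idempotent.
    """
    auc_dce = np.asarray(auc_dce, dtype=float)
    k = result.n_clusters
    cluster_means = np.full(k, np.inf)
    for j in range(k):
        member = result.labels == j + 1
        if member.any():
            cluster_means[j] = float(np.mean(auc_dce[member]))
    order = np.argsort(cluster_means, kind="stable")  # old indices, new order
    perm = np.empty(k, dtype=int)  # old -> new
    perm[order] = np.arange(k)
    new_labels = perm[result.labels - 1] + 1
    return replace(
        result,
        means=result.means[order],
        covariances=result.covariances[order],
        weights=result.weights[order],
        labels=new_labels,
        responsibilities=result.responsibilities[:, order],
        permutation=perm[result.permutation],
    )


def build_region_map(
    labels: np.ndarray,
    coords: np.ndarray,
    grid_shape,
    tumor_id=None,
    legend: dict | None = None,
) -> RegionMap:
    """Transfer per-voxel cluster labels into image space (0 off-mask)."""
    coords = np.asarray(coords, dtype=int)
    labels = np.asarray(labels)
    if coords.shape != (labels.size, 3):
        raise ValueError("coords must be (n_voxels, 3)")
    if len({tuple(c) for c in coords}) != coords.shape[0]:
        raise ValueError("duplicate voxel coordinates")
    if np.any(coords < 0) or np.any(coords >= np.asarray(grid_shape)):
        raise ValueError("coordinates outside the grid")
    vol = np.zeros(tuple(grid_shape), dtype=np.int32)
    vol[coords[:, 0], coords[:, 1], coords[:, 2]] = labels
    return RegionMap(labels=vol, legend=legend or {}, tumor_id=tumor_id)


def mean_cluster_curves(
    result: HabitatMixtureResults,
    dce: DeltaR1Matrix,
    oe: DeltaR1Matrix,
) -> pd.DataFrame:
    """Mean +/- SEM delta R1(t) per cluster for both modalities.

    SEM is SD/sqrt(n) with sample SD; single-member clusters get SEM 0 by
    convention.  Clusters with no members are listed in the frame's
    ``attrs['absent_clusters']``.
    """
    rows = []
    absent = []
    for modality, mat in (("DCE", dce), ("OE", oe)):
        for j in range(1, result.n_clusters + 1):
            member = result.labels == j
            n = int(member.sum())
            if n == 0:
                absent.append((modality, j))
                continue
            curves = mat.values[member]
            mean = np.nanmean(curves, axis=0)
            if n > 1:
                sem = np.nanstd(curves, axis=0, ddof=1) / np.sqrt(n)
            else:
                sem = np.zeros(mat.n_frames)
            for f in range(mat.n_frames):
                rows.append(
                    {
                        "modality": modality,
                        "cluster": j,
                        "frame": f,
                        "time_s": mat.frame_times[f],
                        "mean_dr1": mean[f],
                        "sem_dr1": sem[f],
                        "n_voxels": n,
                    }
                )
    out = pd.DataFrame(rows)
    out.attrs["absent_clusters"] = absent
    return out
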