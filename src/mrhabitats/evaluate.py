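"""Model selection for habitat clustering: AIC, spatial contiguity z-scores,
and bootstrap cluster-stability scores, plus the optimum-selection rule.

* **AIC** — 2k - 2 lnL with k the free-parameter count of a full-covariance
  Gaussian mixture.
* **Contiguity z-score** — the number of 26-connected regions summed over
  labels is compared against a null built by redrawing in-mask labels (with
  replacement from the observed label multiset) at fixed spatial positions;
  positive z means more spatially contiguous than chance.
* **Stability score** — the feature set is bootstrap-resampled over voxels,
  the mixture refitted, each realization's centers matched to the reference
  centers with the Hungarian algorithm, and silhouette values computed on
  the pooled matched centers.  Values near +1 indicate that refits land
  their centers in the same places: a reproducible clustering.

The selection rule codifies the by-eye criterion these metrics support:
among configurations whose median stability silhouette and per-tumor median
contiguity z clear their thresholds, keep the largest number of clusters,
breaking feature-set ties toward lower AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .cluster import HabitatMixture, HabitatMixtureResults, build_region_map
from .containers import FeatureSet, RegionMap

__all__ = [
    "aic",
    "count_connected_regions",
    "contiguity_zscore",
    "hungarian_match",
    "silhouette_values",
    "stability_analysis",
    "ClusterSweep",
    "EvaluationReport",
    "select_optimum",
]

_KERNEL_26 = np.ones((3, 3, 3), dtype=int)


def aic(result: HabitatMixtureResults) -> float:
    """Akaike information criterion, 2k - 2 lnL.

    k counts means (N_C * d), full covariances (N_C * d(d+1)/2) and mixing
    weights (N_C - 1).
    """
    return result.aic


def count_connected_regions(region_map: RegionMap | np.ndarray) -> int:
    """Total number of 26-connected components over all non-zero labels."""
    labels = region_map.labels if isinstance(region_map, RegionMap) else np.asarray(region_map)
    total = 0
    for lab in np.unique(labels):
        if lab == 0:
            continue
        _, n = ndimage.label(labels == lab, structure=_KERNEL_26)
        total += n
    return total


def contiguity_zscore(
    region_map: RegionMap,
    n_boot: int = 100,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Contiguity z-score of a region map against a label-shuffle null.

    Null realizations redraw the in-mask voxel labels with replacement from
    the observed label multiset, keeping spatial positions fixed, and
    recount connected regions.  ``z = (mean_null - observed) / sd_null``, so
    maps more contiguous than chance score positive.  Returns +inf with a
    warning when the null has zero spread.
    """
    labels_obs = region_map.in_mask_labels()
    if np.unique(labels_obs).size < 2:
        raise ValueError("contiguity z-score requires at least 2 labels")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    observed = count_connected_regions(region_map)
    mask_idx = np.nonzero(region_map.mask)
    null_counts = np.empty(n_boot)
    vol = np.zeros_like(region_map.labels)
    for b in range(n_boot):
        vol[...] = 0
        vol[mask_idx] = rng.choice(labels_obs, size=labels_obs.size, replace=True)
        null_counts[b] = count_connected_regions(vol)
    sd = float(np.std(null_counts, ddof=1))
    if sd == 0:
        warnings.warn("degenerate contiguity null (zero spread); z undefined", stacklevel=2)
        return np.inf
    return float((np.mean(null_counts) - observed) / sd)


def hungarian_match(centers_a: np.ndarray, centers_b: np.ndarray):
    """Optimal assignment of rows of ``centers_b`` to rows of ``centers_a``.

    Returns ``(perm, cost)`` where ``perm[i]`` is the row of ``centers_b``
    matched to ``centers_a[i]`` and ``cost`` is the total Euclidean
    distance, minimized over all assignments.
    """
    a = np.atleast_2d(np.asarray(centers_a, dtype=float))
    b = np.atleast_2d(np.asarray(centers_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("center sets must have equal shape")
    dist = cdist(a, b)
    row, col = linear_sum_assignment(dist)
    return col, float(dist[row, col].sum())


def silhouette_values(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point silhouette values with Euclidean distances.

    ``s_i = (b_i - a_i) / max(a_i, b_i)`` with ``a_i`` the mean distance to
    other points of the same label and ``b_i`` the smallest mean distance to
    another label.  Points in singleton labels (and points where both means
    vanish) get 0.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouettes require at least 2 labels")
    dist = cdist(points, points)
    n = points.shape[0]
    s = np.zeros(n)
    member = {lab: labels == lab for lab in uniq}
    sizes = {lab: int(m.sum()) for lab, m in member.items()}
    for i in range(n):
        lab = labels[i]
        if sizes[lab] == 1:
            continue
        a_i = dist[i, member[lab]].sum() / (sizes[lab] - 1)
        b_i = min(
            dist[i, member[other]].mean() for other in uniq if other != lab
        )
        denom = max(a_i, b_i)
        s[i] = 0.0 if denom == 0 else (b_i - a_i) / denom
    return s


def stability_analysis(
    features: FeatureSet,
    nc_values,
    n_boot: int = 100,
    n_restarts: int = 10,
    seed: int | None = None,
    reference: dict | None = None,
    auc_dce: np.ndarray | None = None,
    index_sampler=None,
):
    """Bootstrap cluster-stability scores for each candidate N_C.

    For every bootstrap realization the voxels are resampled with
    replacement, the mixture refitted (same restart policy, fresh seed),
    and the refit centers Hungarian-matched to the reference centers.  The
    pooled ``n_boot * N_C`` matched centers, grouped by matched reference
    index, are scored with silhouettes.  Returns ``(scores, reference)``:
    ``scores[nc]`` is the pooled silhouette array, ``reference[nc]`` the
    reference fit.  Failed refits are skipped; more than 20% failures for an
    N_C triggers a warning.  ``index_sampler(rng, n)`` overrides the
    with-replacement resampling (used e.g. to reproduce the degenerate
    identity bootstrap).
    """
    if index_sampler is None:
        index_sampler = lambda rng, n: rng.integers(0, n, size=n)
    ss = np.random.SeedSequence(seed)
    model = HabitatMixture(features, auc_dce=auc_dce)
    n = features.n_voxels
    scores: dict[int, np.ndarray] = {}
    reference = dict(reference) if reference else {}

    for nc in nc_values:
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(int(nc),))
        seeds = child.generate_state(n_boot + 2) % (2**31)
        rng = np.random.default_rng(child.spawn(1)[0])
        if nc not in reference:
            reference[nc] = model.fit(
                nc, n_restarts=n_restarts, random_state=int(seeds[0])
            )
        ref_centers = reference[nc].means
        pooled_centers, pooled_labels = [], []
        failures = 0
        for b in range(n_boot):
            idx = index_sampler(rng, n)
            boot_features = FeatureSet(
                matrix=features.matrix[idx],
                names=list(features.names),
                coords=np.column_stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)]),
                tumor_ids=features.tumor_ids[idx],
                kind=features.kind,
            )
            try:
                boot_fit = HabitatMixture(boot_features).fit(
                    nc, n_restarts=n_restarts, random_state=int(seeds[b + 1])
                )
            except Exception:
                failures += 1
                continue
            perm, _ = hungarian_match(ref_centers, boot_fit.means)
            # boot center matched to reference center j is boot_fit.means[perm[j]]
            pooled_centers.append(boot_fit.means[perm])
            pooled_labels.append(np.arange(nc))
        if failures > 0.2 * n_boot:
            warnings.warn(
                f"{failures}/{n_boot} bootstrap refits failed at N_C={nc}", stacklevel=2
            )
        centers = np.vstack(pooled_centers)
        labels = np.concatenate(pooled_labels)
        scores[nc] = silhouette_values(centers, labels)
    return scores, reference


@dataclass
class EvaluationReport:
    """Metrics per (feature set, N_C) plus the data behind them."""

    table: pd.DataFrame  # feature_set, n_clusters, aic, median_stability, median_contiguity_z
    stability: dict = field(default_factory=dict)  # (fs, nc) -> silhouette array
    contiguity: dict = field(default_factory=dict)  # (fs, nc) -> {tumor_id: z}
    fits: dict = field(default_factory=dict)  # (fs, nc) -> HabitatMixtureResults
    selection: tuple | None = None
    trace: list = field(default_factory=list)

    def stability_long(self) -> pd.DataFrame:
        """Long-format silhouette table, box-plot ready."""
        rows = []
        for (fs, nc), vals in self.stability.items():
            for v in vals:
                rows.append({"feature_set": fs, "n_clusters": nc, "silhouette": v})
        return pd.DataFrame(rows)


class ClusterSweep:
    """Sweep (feature set, N_C) and compute the three evaluation metrics.

    Parameters
    ----------
    feature_sets : dict
        Mapping name -> FeatureSet, e.g. ``{"auc": ..., "pca": ...}``.  All
        feature sets must cover the same voxels.
    grids : dict
        Mapping tumor id -> grid shape, for per-tumor region maps.
    auc_dce : ndarray
        Per-voxel DCE AUC for canonical cluster ordering.
    """

    def __init__(self, feature_sets: dict, grids: dict, auc_dce: np.ndarray):
        self.feature_sets = feature_sets
        self.grids = grids
        self.auc_dce = np.asarray(auc_dce, dtype=float)

    def run(
        self,
        nc_values,
        n_boot: int = 100,
        n_restarts: int = 10,
        contiguity_boot: int = 100,
        seed: int | None = None,
    ) -> EvaluationReport:
        nc_values = list(nc_values)
        ss = np.random.SeedSequence(seed)
        rows = []
        report = EvaluationReport(table=pd.DataFrame())
        for f_i, (fs_name, fs) in enumerate(sorted(self.feature_sets.items())):
            fs_seed = int(ss.generate_state(2 + f_i)[-1] % (2**31))
            scores, fits = stability_analysis(
                fs,
                nc_values,
                n_boot=n_boot,
                n_restarts=n_restarts,
                seed=fs_seed,
                auc_dce=self.auc_dce,
            )
            for nc in nc_values:
                fit = fits[nc]
                zs = {}
                rng = np.random.default_rng([fs_seed, nc])
                for tumor in self.grids:
                    sel = fs.tumor_ids == tumor
                    rmap = build_region_map(
                        fit.labels[sel], fs.coords[sel], self.grids[tumor], tumor_id=tumor
                    )
                    try:
                        zs[tumor] = contiguity_zscore(rmap, n_boot=contiguity_boot, seed=rng)
                    except ValueError:
                        zs[tumor] = np.nan
                key = (fs_name, nc)
                report.stability[key] = scores[nc]
                report.contiguity[key] = zs
                report.fits[key] = fit
                rows.append(
                    {
                        "feature_set": fs_name,
                        "n_clusters": nc,
                        "aic": fit.aic,
                        "median_stability": float(np.median(scores[nc])),
                        "median_contiguity_z": float(np.nanmedian(list(zs.values()))),
                    }
                )
        report.table = pd.DataFrame(rows)
        return report


def select_optimum(
    report: EvaluationReport,
    s_min: float = 0.8,
    z_min: float = 3.0,
) -> tuple:
    """Pick the optimized (feature set, N_C) from an evaluation report.

    Candidates must have median stability silhouette >= ``s_min`` and
    per-tumor median contiguity z >= ``z_min``; among them the largest N_C
    wins, ties broken toward the feature set with lower AIC.  If no
    configuration qualifies, the largest N_C meeting the stability threshold
    alone is returned with a warning.  The decision path is appended to
    ``report.trace`` and the choice stored in ``report.selection``.
    """
    t = report.table
    trace = report.trace
    cand = t[(t.median_stability >= s_min) & (t.median_contiguity_z >= z_min)]
    trace.append(
        f"{len(cand)}/{len(t)} configurations pass stability >= {s_min} "
        f"and contiguity z >= {z_min}"
    )
    if cand.empty:
        warnings.warn("no configuration passed both thresholds; using stability only")
        cand = t[t.median_stability >= s_min]
        trace.append("fallback: stability threshold only")
        if cand.empty:
            cand = t.loc[[t.median_stability.idxmax()]]
            trace.append("fallback: most stable configuration")
    nc_best = int(cand.n_clusters.max())
    at_best = cand[cand.n_clusters == nc_best].sort_values("aic")
    row = at_best.iloc[0]
    if len(at_best) > 1:
        trace.append(
            f"N_C={nc_best} reached by {list(at_best.feature_set)}; "
            f"tie broken toward lower AIC ({row.feature_set})"
        )
    trace.append(f"selected feature set '{row.feature_set}' with N_C={nc_best}")
    report.selection = (str(row.feature_set), nc_best)
    return report.selection
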