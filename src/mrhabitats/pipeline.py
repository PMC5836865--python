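"""End-to-end pipeline driver.

Stages run in acquisition order: phantom generation (or loading series from
disk), VFA T1 fitting, OE drift correction, signal-to-delta-R1 conversion,
erratic-voxel exclusion, feature extraction (AUC and PCA sets), the
(feature set, N_C) evaluation sweep, optimum selection, region maps and mean
cluster curves at the optimum, and the comparison against the three-class
threshold-based method.

A single global seed is expanded deterministically into per-stage child
seeds; reruns with the same configuration and seed are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare, features as feat, io as mio, preprocess
from .cluster import HabitatMixture, mean_cluster_curves
from .containers import DeltaR1Matrix, FeatureSet, RegionMap
from .evaluate import ClusterSweep, EvaluationReport, select_optimum
from .phantom import PhantomConfig, render_phantom, three_habitat_config
from .relaxometry import fit_drift_baseline, fit_vfa_t1, signal_to_delta_r1

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "auto_grouping"]


@dataclass
class PipelineConfig:
    """All stage parameters plus the global seed and stage toggles."""

    # phantom cohort (the built-in data source)
    n_tumors: int = 4
    phantom_grid: tuple = (20, 20, 10)
    phantom_radii: tuple = (7.0, 6.0, 3.0)
    phantom_noise_sd: float = 2.0
    # stage parameters
    drift_correct: bool = True
    exclusion_fraction: float = 0.01
    window_dce_s: float = 90.0
    n_components: int = 4
    nc_values: tuple = (2, 3, 4, 5)
    n_restarts: int = 10
    n_boot: int = 50
    contiguity_boot: int = 100
    s_min: float = 0.8
    z_min: float = 3.0
    tbm_alpha: float = 0.05
    grouping: dict | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for key in ("phantom_grid", "phantom_radii", "nc_values"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


@dataclass
class PipelineResult:
    dce: DeltaR1Matrix
    oe: DeltaR1Matrix
    tumor_ids: np.ndarray
    feature_sets: dict
    report: EvaluationReport
    selection: tuple
    region_maps: dict  # tumor id -> RegionMap at the optimum
    truth_maps: dict | None
    curves: pd.DataFrame
    tbm_maps: dict
    odd3_maps: dict
    agreement: pd.DataFrame
    pooled_agreement: compare.AgreementStats
    bland_altman: pd.DataFrame
    drift_models: dict
    exclusion_reports: dict


def auto_grouping(n_clusters: int) -> dict:
    """Collapse N_C ordered clusters into three classes.

    Cluster 1 (lowest DCE AUC) stays class 1; the remaining clusters are
    split so the lower-enhancing half maps to class 2 and the rest to class
    3.  For six clusters this gives 1 | {2,3} | {4,5,6}; for three it is the
    identity.
    """
    if n_clusters < 3:
        raise ValueError("grouping needs at least 3 clusters")
    rest = list(range(2, n_clusters + 1))
    n2 = len(rest) // 2
    grouping = {1: 1}
    grouping.update({c: 2 for c in rest[:n2]})
    grouping.update({c: 3 for c in rest[n2:]})
    return grouping


def _process_tumor(out, cfg: PipelineConfig):
    """VFA fit, drift fit, delta-R1 conversion and exclusion for one phantom."""
    t1_dce = fit_vfa_t1(out.dce_vfa, out.mask)
    t1_oe = fit_vfa_t1(out.oe_vfa, out.mask)

    drift = None
    if cfg.drift_correct:
        mean_sig = out.oe.data[out.mask].mean(axis=0)
        drift = fit_drift_baseline(
            mean_sig,
            out.oe.frame_times,
            n_pre_event=out.oe.event_frame,
            t10_s=float(np.nanmean(t1_oe.t10[out.mask])),
            alpha0_deg=out.oe.flip_angle_deg,
            tr_ms=out.oe.tr_ms,
        )
    dce_m = signal_to_delta_r1(out.dce, t1_dce.s0, t1_dce.t10, out.mask)
    oe_m = signal_to_delta_r1(out.oe, t1_oe.s0, t1_oe.t10, out.mask, drift=drift)
    dce_m, oe_m, report = preprocess.exclude_erratic_voxels(
        dce_m, oe_m, fraction=cfg.exclusion_fraction
    )
    return dce_m, oe_m, report, drift


def _pool(matrices: list[DeltaR1Matrix], ids: list) -> tuple[DeltaR1Matrix, np.ndarray]:
    """Concatenate per-tumor matrices; coords stay per-tumor (tumor id keys rows)."""
    tumor_ids = np.concatenate(
        [np.full(m.n_voxels, i) for m, i in zip(matrices, ids)]
    )
    # offset x by tumor index to keep pooled coordinates unique
    offset = max(m.coords[:, 0].max() for m in matrices) + 1
    coords = np.vstack(
        [m.coords + np.array([k * offset, 0, 0]) for k, m in enumerate(matrices)]
    )
    pooled = DeltaR1Matrix(
        values=np.vstack([m.values for m in matrices]),
        frame_times=matrices[0].frame_times,
        event_frame=matrices[0].event_frame,
        coords=coords,
        modality=matrices[0].modality,
        erratic=np.concatenate([m.erratic for m in matrices]),
    )
    return pooled, tumor_ids


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> PipelineResult:
    """Run the full analysis on a synthetic phantom cohort.

    Returns a :class:`PipelineResult`; when ``out_dir`` is given, region
    maps (NIfTI), tables (CSV) and a hashed manifest are written there.
    """
    ss = np.random.SeedSequence(cfg.seed)
    phantom_seeds, sweep_seed = ss.spawn(cfg.n_tumors), ss.spawn(1)[0]
    sweep_seed = int(sweep_seed.generate_state(1)[0] % (2**31))

    # --- data generation + per-tumor relaxometry/preprocessing
    phantoms, dce_list, oe_list, excl_reports, drifts = {}, [], [], {}, {}
    coords_by_tumor = {}
    for k in range(cfg.n_tumors):
        pcfg = three_habitat_config(
            grid_shape=cfg.phantom_grid,
            radii=cfg.phantom_radii,
            noise_sd=cfg.phantom_noise_sd,
        )
        out = render_phantom(pcfg, seed=int(phantom_seeds[k].generate_state(1)[0] % (2**31)))
        phantoms[k] = out
        dce_m, oe_m, report, drift = _process_tumor(out, cfg)
        coords_by_tumor[k] = dce_m.coords
        dce_list.append(dce_m)
        oe_list.append(oe_m)
        excl_reports[k] = report
        drifts[k] = drift

    dce_pool, tumor_ids = _pool(dce_list, list(range(cfg.n_tumors)))
    oe_pool, _ = _pool(oe_list, list(range(cfg.n_tumors)))

    # --- features (pooled over the cohort)
    auc = feat.auc_features(dce_pool, oe_pool, tumor_ids, window_dce_s=cfg.window_dce_s)
    composite, scale = feat.scale_and_concatenate(dce_pool, oe_pool)
    pca = feat.pca_features(
        composite, dce_pool.coords, tumor_ids, n_components=cfg.n_components, oe_scale=scale
    )

    # pooled coords are offset to stay unique; region maps need the per-tumor
    # (local-grid) coordinates, so swap them in on the feature sets
    local_coords = np.vstack([coords_by_tumor[k] for k in range(cfg.n_tumors)])
    auc.coords = local_coords
    pca.coords = local_coords

    # --- evaluation sweep and optimum selection
    grids = {k: cfg.phantom_grid for k in range(cfg.n_tumors)}
    sweep = ClusterSweep({"auc": auc, "pca": pca}, grids, auc_dce=auc.matrix[:, 0])
    report = sweep.run(
        cfg.nc_values,
        n_boot=cfg.n_boot,
        n_restarts=cfg.n_restarts,
        contiguity_boot=cfg.contiguity_boot,
        seed=sweep_seed,
    )
    selection = select_optimum(report, s_min=cfg.s_min, z_min=cfg.z_min)
    fs_name, nc_opt = selection
    best = report.fits[(fs_name, nc_opt)]

    # --- outputs at the optimum
    region_maps, truth_maps = {}, {}
    for k in range(cfg.n_tumors):
        sel = tumor_ids == k
        from .cluster import build_region_map

        region_maps[k] = build_region_map(
            best.labels[sel], coords_by_tumor[k], cfg.phantom_grid, tumor_id=k
        )
        truth_maps[k] = phantoms[k].truth
    curves = mean_cluster_curves(best, dce_pool, oe_pool)

    # --- comparison with the threshold-based method
    grouping = cfg.grouping or (auto_grouping(nc_opt) if nc_opt >= 3 else None)
    tbm_maps, odd3_maps, agree_rows = {}, {}, []
    counts_odd, counts_tbm, sizes = [], [], []
    pooled_odd, pooled_tbm = [], []
    for k in range(cfg.n_tumors):
        sel = tumor_ids == k
        tbm_maps[k] = compare.tbm_classify(
            dce_list[k], oe_list[k], cfg.phantom_grid, tumor_id=k, alpha_level=cfg.tbm_alpha
        )
        odd3_maps[k] = (
            compare.concatenate_odd(region_maps[k], grouping)
            if grouping is not None
            else region_maps[k]
        )
        st = compare.agreement_stats(odd3_maps[k], tbm_maps[k])
        agree_rows.append(
            {"tumor": k, "phi": st.phi, "kappa": st.kappa, "n_voxels": st.n_voxels}
        )
        lo, lt = odd3_maps[k].in_mask_labels(), tbm_maps[k].in_mask_labels()
        pooled_odd.append(lo)
        pooled_tbm.append(lt)
        counts_odd.append([np.sum(lo == c) for c in (1, 2, 3)])
        counts_tbm.append([np.sum(lt == c) for c in (1, 2, 3)])
        sizes.append(lo.size)
    pooled = compare.agreement_stats(
        np.concatenate(pooled_odd), np.concatenate(pooled_tbm)
    )
    ba = compare.bland_altman(
        np.asarray(counts_odd), np.asarray(counts_tbm), np.asarray(sizes)
    )

    result = PipelineResult(
        dce=dce_pool,
        oe=oe_pool,
        tumor_ids=tumor_ids,
        feature_sets={"auc": auc, "pca": pca},
        report=report,
        selection=selection,
        region_maps=region_maps,
        truth_maps=truth_maps,
        curves=curves,
        tbm_maps=tbm_maps,
        odd3_maps=odd3_maps,
        agreement=pd.DataFrame(agree_rows),
        pooled_agreement=pooled,
        bland_altman=ba,
        drift_models=drifts,
        exclusion_reports=excl_reports,
    )
    if out_dir is not None:
        _write_outputs(result, cfg, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, cfg: PipelineConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = mio.Manifest(out_dir, seed=cfg.seed)
    for k, rmap in result.region_maps.items():
        p = mio.save_volume(out_dir / f"tumor{k}_regions.nii.gz", rmap.labels)
        manifest.record(p)
        p = mio.save_volume(out_dir / f"tumor{k}_tbm.nii.gz", result.tbm_maps[k].labels)
        manifest.record(p)
    tables = {
        "evaluation_report.csv": result.report.table,
        "stability_scores.csv": result.report.stability_long(),
        "mean_cluster_curves.csv": result.curves,
        "agreement.csv": result.agreement,
        "bland_altman.csv": result.bland_altman,
    }
    for name, df in tables.items():
        p = out_dir / name
        df.to_csv(p, index=False)
        manifest.record(p)
    summary = {
        "selection": {"feature_set": result.selection[0], "n_clusters": result.selection[1]},
        "trace": result.report.trace,
        "pooled_phi": result.pooled_agreement.phi,
        "pooled_kappa": result.pooled_agreement.kappa,
    }
    import json

    p = out_dir / "summary.json"
    p.write_text(json.dumps(summary, indent=1))
    manifest.record(p)
    manifest.write()
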