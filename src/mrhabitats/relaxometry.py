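"""SPGR relaxometry: the signal model, VFA T1 fitting, OE baseline-drift
correction, and conversion of dynamic signals to delta R1.

The spoiled gradient-recalled echo (SPGR) steady-state signal is

    S = S0 * sin(alpha) * (1 - E1) / (1 - E1 * cos(alpha)),   E1 = exp(-TR/T1)

All conversions in this module are exact algebraic manipulations of that
equation; the only fitted quantities are (T10, S0) per voxel from the
variable-flip-angle data and the baseline-drift parameters on the OE series.

Drift is modelled as an exponentially time-varying effective flip angle

    alpha(t) = alpha0 * (1 + A_drift * (1 - exp(-t / tau_drift)))

fitted to the pre-gas-switch ROI-mean signal and extrapolated over the whole
series.  The functional form is a package choice: monotone, bounded, and
two-parameter.  It is fitted on the ROI mean (per-voxel drift fits are
unstable at realistic SNR) and then applied voxel-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .containers import DeltaR1Matrix, DynamicSeries, VfaSet

__all__ = [
    "spgr_signal",
    "fit_vfa_t1",
    "fit_drift_baseline",
    "signal_to_delta_r1",
    "extract_voxel_matrix",
    "T1FitResult",
    "DriftModel",
]

T1_BOUNDS_S = (0.05, 10.0)


def spgr_signal(s0, t1_s, alpha_deg, tr_ms):
    """SPGR steady-state signal.

    Parameters are broadcast together; ``t1_s`` in seconds, ``tr_ms`` in
    milliseconds, ``alpha_deg`` in degrees.  ``alpha_deg`` must lie in
    [0, 180); T1 and TR must be positive.
    """
    s0 = np.asarray(s0, dtype=float)
    t1_s = np.asarray(t1_s, dtype=float)
    alpha_deg = np.asarray(alpha_deg, dtype=float)
    if np.any(t1_s <= 0):
        raise ValueError("T1 must be positive")
    if tr_ms <= 0:
        raise ValueError("TR must be positive")
    if np.any(alpha_deg < 0) or np.any(alpha_deg >= 180):
        raise ValueError("flip angle must be in [0, 180) degrees")
    a = np.deg2rad(alpha_deg)
    e1 = np.exp(-(tr_ms / 1000.0) / t1_s)
    return s0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


@dataclass
class T1FitResult:
    """Per-voxel native T1 (T10) and equilibrium signal (S0) estimates."""

    t10: np.ndarray  # (x, y, z), seconds; NaN where the fit failed
    s0: np.ndarray  # (x, y, z), signal units
    residual_norm: np.ndarray  # (x, y, z)
    success: np.ndarray  # (x, y, z) bool


def _despot1_init(signals: np.ndarray, angles_rad: np.ndarray, tr_s: float):
    """Linearized DESPOT1 regression: S/sin(a) = E1 * S/tan(a) + S0*(1-E1)."""
    y = signals / np.sin(angles_rad)
    x = signals / np.tan(angles_rad)
    xm, ym = x.mean(), y.mean()
    denom = np.sum((x - xm) ** 2)
    if denom <= 0:
        return 1.0, max(float(signals.max()), 1.0)
    slope = float(np.sum((x - xm) * (y - ym)) / denom)
    e1 = np.clip(slope, 1e-6, 1.0 - 1e-9)
    t1 = float(np.clip(-tr_s / np.log(e1), *T1_BOUNDS_S))
    s0 = max(float((ym - e1 * xm) / (1.0 - e1)), 1e-6)
    return t1, s0


def fit_vfa_t1(vfa: VfaSet, mask: np.ndarray | None = None) -> T1FitResult:
    """Fit (T10, S0) per voxel by nonlinear least squares on the SPGR model.

    The fit is seeded by the linearized DESPOT1 regression and bounded to
    T10 in [0.05, 10] s.  Voxels with all-zero or non-finite signals are
    flagged failed (NaN maps) and excluded downstream.
    """
    grid = vfa.grid_shape
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid:
        raise ValueError("mask shape must match VFA grid")

    angles = np.deg2rad(vfa.angles_deg)
    tr_s = vfa.tr_ms / 1000.0

    t10 = np.full(grid, np.nan)
    s0 = np.full(grid, np.nan)
    resid = np.full(grid, np.nan)
    success = np.zeros(grid, dtype=bool)

    def residuals(params, sig):
        t1, s0v = params
        e1 = np.exp(-tr_s / t1)
        model = s0v * np.sin(angles) * (1.0 - e1) / (1.0 - e1 * np.cos(angles))
        return model - sig

    for ix, iy, iz in zip(*np.nonzero(mask)):
        sig = vfa.signals[ix, iy, iz]
        if not np.all(np.isfinite(sig)) or np.all(sig == 0):
            continue
        t1_init, s0_init = _despot1_init(sig, angles, tr_s)
        try:
            sol = least_squares(
                residuals,
                x0=[t1_init, s0_init],
                args=(sig,),
                bounds=([T1_BOUNDS_S[0], 1e-9], [T1_BOUNDS_S[1], np.inf]),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except ValueError:
            continue
        t10[ix, iy, iz] = sol.x[0]
        s0[ix, iy, iz] = sol.x[1]
        resid[ix, iy, iz] = np.linalg.norm(sol.fun)
        success[ix, iy, iz] = True

    return T1FitResult(t10=t10, s0=s0, residual_norm=resid, success=success)


@dataclass
class DriftModel:
    """Exponentially time-varying effective flip angle for the OE baseline."""

    s0: float  # baseline equilibrium signal (signal units)
    a_drift: float  # fractional drift amplitude (unitless)
    tau_drift_s: float  # drift time constant (s)
    alpha0_deg: float  # nominal flip angle (deg)

    def __post_init__(self) -> None:
        if self.tau_drift_s <= 0:
            raise ValueError("tau_drift must be positive")
        a_end = self.alpha0_deg * (1.0 + self.a_drift)
        if not 0 < a_end < 90:
            raise ValueError("effective flip angle must stay in (0, 90) deg")

    def alpha_of_t(self, t_s) -> np.ndarray:
        """Effective flip angle (deg) at times ``t_s`` (seconds)."""
        t_s = np.asarray(t_s, dtype=float)
        return self.alpha0_deg * (
            1.0 + self.a_drift * (1.0 - np.exp(-t_s / self.tau_drift_s))
        )


def fit_drift_baseline(
    oe_signal_mean: np.ndarray,
    frame_times: np.ndarray,
    n_pre_event: int,
    t10_s: float,
    alpha0_deg: float,
    tr_ms: float,
) -> DriftModel:
    """Fit the baseline-drift model to the pre-gas-switch ROI-mean signal.

    Only the ``n_pre_event`` frames before the event enter the residuals;
    the returned model extrapolates alpha(t) over the whole series.  A
    degenerate fit (tau pinned at a bound) falls back to no drift with a
    warning.
    """
    oe_signal_mean = np.asarray(oe_signal_mean, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    if n_pre_event < 5:
        raise ValueError("at least 5 pre-event frames are required")
    t_pre = frame_times[:n_pre_event]
    s_pre = oe_signal_mean[:n_pre_event]

    tau_bounds = (1.0, 1e5)
    a_bounds = (-0.5, 0.5)

    def residuals(params):
        s0v, a, tau = params
        alpha_t = alpha0_deg * (1.0 + a * (1.0 - np.exp(-t_pre / tau)))
        return spgr_signal(s0v, t10_s, alpha_t, tr_ms) - s_pre

    s0_init = float(s_pre[0] / spgr_signal(1.0, t10_s, alpha0_deg, tr_ms))
    sol = least_squares(
        residuals,
        x0=[s0_init, 0.0, 200.0],
        bounds=([1e-9, a_bounds[0], tau_bounds[0]], [np.inf, a_bounds[1], tau_bounds[1]]),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    s0_fit, a_fit, tau_fit = sol.x
    at_bound = (
        tau_fit <= tau_bounds[0] * 1.01
        or tau_fit >= tau_bounds[1] * 0.99
        or abs(a_fit) >= a_bounds[1] * 0.999
    )
    # a ~ 0 with tau at a bound is the unidentifiable no-drift case, not a
    # degenerate fit worth warning about
    if at_bound and abs(a_fit) > 1e-3:
        warnings.warn(
            "drift fit degenerate (parameter at bound); falling back to no drift",
            stacklevel=2,
        )
        return DriftModel(s0=s0_fit, a_drift=0.0, tau_drift_s=200.0, alpha0_deg=alpha0_deg)
    if at_bound:
        a_fit = 0.0
        tau_fit = 200.0
    return DriftModel(
        s0=float(s0_fit),
        a_drift=float(a_fit),
        tau_drift_s=float(tau_fit),
        alpha0_deg=float(alpha0_deg),
    )


def extract_voxel_matrix(series: DynamicSeries, mask: np.ndarray):
    """Masked (n_voxels, n_frames) signal matrix plus (x, y, z) coordinates.

    Voxels are ordered by (z, y, x) lexicographic coordinate order, the
    package's canonical stable voxel order.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.grid_shape:
        raise ValueError("mask shape must match series grid")
    xs, ys, zs = np.nonzero(mask)
    order = np.lexsort((xs, ys, zs))
    xs, ys, zs = xs[order], ys[order], zs[order]
    coords = np.stack([xs, ys, zs], axis=1)
    return series.data[xs, ys, zs, :], coords


def signal_to_delta_r1(
    series: DynamicSeries,
    s0: np.ndarray,
    t10: np.ndarray,
    mask: np.ndarray,
    drift: DriftModel | None = None,
    erratic_fraction: float = 0.5,
) -> DeltaR1Matrix:
    """Invert the SPGR equation frame-by-frame to obtain delta R1(t).

    For each voxel and frame, solve the SPGR equation for E1, giving
    T1(t) = -TR/ln(E1) and delta R1(t) = 1/T1(t) - 1/T10.  For OE data a
    fitted :class:`DriftModel` supplies the time-varying effective flip
    angle; for DCE the nominal (constant) angle is used.

    Frames with an unphysical inversion (E1 outside (0, 1)) are NaN; voxels
    with more than ``erratic_fraction`` of frames unphysical are flagged
    erratic.
    """
    signals, coords = extract_voxel_matrix(series, mask)
    s0_vox = np.asarray(s0, dtype=float)[coords[:, 0], coords[:, 1], coords[:, 2]]
    t10_vox = np.asarray(t10, dtype=float)[coords[:, 0], coords[:, 1], coords[:, 2]]

    if drift is not None:
        alpha_t = drift.alpha_of_t(series.frame_times)  # (n_frames,)
    else:
        alpha_t = np.full(series.n_frames, series.flip_angle_deg)
    a = np.deg2rad(alpha_t)[None, :]
    tr_s = series.tr_ms / 1000.0

    sin_a, cos_a = np.sin(a), np.cos(a)
    s0sin = s0_vox[:, None] * sin_a
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (s0sin - signals) / (s0sin - signals * cos_a)
        valid = np.isfinite(e1) & (e1 > 0) & (e1 < 1)
        r1 = np.where(valid, -np.log(np.where(valid, e1, 0.5)) / tr_s, np.nan)
        dr1 = r1 - 1.0 / t10_vox[:, None]
    bad_voxel = ~np.isfinite(t10_vox) | ~np.isfinite(s0_vox)
    dr1[bad_voxel, :] = np.nan
    erratic = np.mean(~np.isfinite(dr1), axis=1) > erratic_fraction
    return DeltaR1Matrix(
        values=dr1,
        frame_times=series.frame_times,
        event_frame=series.event_frame,
        coords=coords,
        modality=series.modality,
        erratic=erratic,
    )
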