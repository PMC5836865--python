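"""Digital phantoms: synthetic DCE/OE/VFA acquisitions with known habitats.

A phantom is an ellipsoidal "tumor" partitioned into habitats by simple
spatial rules (concentric shells and azimuthal wedges).  Each habitat has its
own enhancement kinetics:

* DCE:  delta R1(t') = A_dce * (1 - exp(-k_in * t')) * exp(-k_out * t')
  with t' the time since injection in minutes (zero before injection) —
  a gamma-variate-like uptake/washout shape;
* OE:   delta R1(t') = sign * A_oe * (1 - exp(-t' / tau_oe))
  with t' the time since the gas switch in seconds — a saturating
  exponential that can be positive, negative, or absent.

Raw signals are produced through the SPGR forward model at the configured
flip angle and TR, with the OE series additionally rendered through an
exponentially time-varying effective flip angle (baseline drift) and
additive Gaussian noise on all series.  Default acquisition timing follows a
preclinical protocol: OE 42 frames every 28.80 s with the gas switch at the
beginning of the 19th acquisition; DCE 96 frames every 5.78 s with injection
at the beginning of the 25th; 64 x 64 in-plane, 16 slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import DynamicSeries, RegionMap, VfaSet
from .relaxometry import spgr_signal

__all__ = [
    "HabitatSpec",
    "AcquisitionTiming",
    "PhantomConfig",
    "PhantomOutput",
    "make_ground_truth_curves",
    "render_phantom",
    "three_habitat_config",
]


@dataclass
class HabitatSpec:
    """One habitat: a spatial rule plus DCE/OE kinetics and native T1.

    The spatial rule selects tumor voxels by normalized ellipsoidal radius
    ``rho`` in ``[rho_min, rho_max)`` and, optionally, azimuth (degrees, in
    ``[theta_min, theta_max)`` measured in the xy plane) for wedge regions.
    """

    name: str
    rho_min: float = 0.0
    rho_max: float = 1.0
    theta_min: float | None = None
    theta_max: float | None = None
    # DCE kinetics
    a_dce: float = 0.0  # s^-1
    k_in: float = 5.0  # min^-1
    k_out: float = 0.2  # min^-1
    # OE kinetics
    a_oe: float = 0.0  # s^-1
    tau_oe: float = 60.0  # s
    oe_sign: int = 0  # +1, -1 or 0
    t10: float = 1.5  # s
    # within-habitat amplitude variability, so habitats are continua rather
    # than point masses in feature space (as in real tumors):
    # - gradient: deterministic radial modulation, +/-gradient from the
    #   habitat's inner to outer edge (structured substructure)
    # - jitter: per-voxel fractional amplitude SD, spatially unstructured
    gradient: float = 0.0
    jitter: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.a_dce, self.k_in, self.k_out, self.a_oe, self.tau_oe, self.t10):
            if not np.isfinite(v):
                raise ValueError("habitat kinetic parameters must be finite")
        if self.t10 <= 0 or self.tau_oe <= 0:
            raise ValueError("t10 and tau_oe must be positive")
        if self.oe_sign not in (-1, 0, 1):
            raise ValueError("oe_sign must be -1, 0 or +1")
        if not 0 <= self.gradient < 1:
            raise ValueError("gradient must be in [0, 1)")
        if not 0 <= self.jitter < 1:
            raise ValueError("jitter must be in [0, 1)")


@dataclass
class AcquisitionTiming:
    """Frame counts, intervals, event frames and readout parameters."""

    dce_n_frames: int = 96
    dce_frame_interval_s: float = 5.78
    dce_event_frame: int = 24  # injection at the beginning of the 25th frame
    dce_flip_deg: float = 10.0
    dce_tr_ms: float = 6.02
    dce_vfa_angles_deg: tuple = (2.0, 5.0, 10.0)

    oe_n_frames: int = 42
    oe_frame_interval_s: float = 28.80
    oe_event_frame: int = 18  # gas switch at the beginning of the 19th frame
    oe_flip_deg: float = 20.0
    oe_tr_ms: float = 30.0
    oe_vfa_angles_deg: tuple = (5.0, 10.0, 20.0)

    def __post_init__(self) -> None:
        if self.dce_frame_interval_s <= 0 or self.oe_frame_interval_s <= 0:
            raise ValueError("frame intervals must be positive")
        if not 0 <= self.dce_event_frame < self.dce_n_frames:
            raise ValueError("DCE event frame outside series")
        if not 0 <= self.oe_event_frame < self.oe_n_frames:
            raise ValueError("OE event frame outside series")

    @property
    def dce_times(self) -> np.ndarray:
        return np.arange(self.dce_n_frames) * self.dce_frame_interval_s

    @property
    def oe_times(self) -> np.ndarray:
        return np.arange(self.oe_n_frames) * self.oe_frame_interval_s


@dataclass
class PhantomConfig:
    grid_shape: tuple = (64, 64, 16)
    center: tuple = (32.0, 32.0, 8.0)
    radii: tuple = (14.0, 12.0, 6.0)  # voxels
    habitats: list = field(default_factory=list)
    timing: AcquisitionTiming = field(default_factory=AcquisitionTiming)
    s0: float = 1000.0
    noise_sd: float = 2.0  # signal units
    vfa_noise_sd: float | None = None  # None -> same as noise_sd
    drift_a: float = 0.05  # unitless
    drift_tau_s: float = 300.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError("ellipsoid radii must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.drift_tau_s <= 0:
            raise ValueError("drift tau must be positive")
        if not self.habitats:
            raise ValueError("at least one habitat is required")


@dataclass
class PhantomOutput:
    dce: DynamicSeries
    oe: DynamicSeries
    dce_vfa: VfaSet
    oe_vfa: VfaSet
    mask: np.ndarray
    truth: RegionMap
    truth_curves: dict  # habitat name -> {"dce": ndarray, "oe": ndarray}
    config: PhantomConfig
    # per-voxel amplitude modulation; the injected delta R1 curve of a voxel
    # is amp_scale * its habitat's template
    amp_scale: np.ndarray | None = None


def three_habitat_config(
    grid_shape=(24, 24, 12),
    center=None,
    radii=(8.0, 7.0, 4.0),
    noise_sd: float = 2.0,
    gradient: float = 0.0,
    jitter: float = 0.1,
    seed: int | None = None,
) -> PhantomConfig:
    """Default three-habitat phantom: necrotic core, hypoxic shell, perfused rim.

    The habitats emulate the three canonical enhancement classes seen in
    xenograft DCE/OE data: non-enhancing (core), DCE-enhancing but
    oxygen-refractory (mid shell, mildly negative OE response), and
    enhancing in both (rim).  ``jitter`` sets the spatially unstructured
    per-voxel amplitude variability (default 10% SD) so habitats are smooth
    continua in feature space, as in real tumors, without introducing
    clusterable substructure; ``gradient`` adds a deterministic radial
    modulation instead (off by default).
    """
    if center is None:
        center = tuple((s - 1) / 2.0 for s in grid_shape)
    habitats = [
        HabitatSpec(
            name="necrotic_core", rho_min=0.0, rho_max=0.45,
            a_dce=0.0, a_oe=0.0, oe_sign=0, t10=1.8, gradient=gradient, jitter=jitter,
        ),
        HabitatSpec(
            name="hypoxic_shell", rho_min=0.45, rho_max=0.75,
            a_dce=0.8, k_in=5.0, k_out=0.15,
            a_oe=0.01, tau_oe=90.0, oe_sign=-1, t10=1.5, gradient=gradient, jitter=jitter,
        ),
        HabitatSpec(
            name="perfused_rim", rho_min=0.75, rho_max=1.0,
            a_dce=1.8, k_in=8.0, k_out=0.3,
            a_oe=0.04, tau_oe=60.0, oe_sign=1, t10=1.2, gradient=gradient, jitter=jitter,
        ),
    ]
    return PhantomConfig(
        grid_shape=grid_shape, center=center, radii=radii,
        habitats=habitats, noise_sd=noise_sd, seed=seed,
    )


def _dce_template(h: HabitatSpec, times: np.ndarray, event_frame: int) -> np.ndarray:
    t_event = times[event_frame]
    tp_min = np.maximum(times - t_event, 0.0) / 60.0  # minutes since injection
    curve = h.a_dce * (1.0 - np.exp(-h.k_in * tp_min)) * np.exp(-h.k_out * tp_min)
    curve[times < t_event] = 0.0
    return curve


def _oe_template(h: HabitatSpec, times: np.ndarray, event_frame: int) -> np.ndarray:
    t_event = times[event_frame]
    tp = np.maximum(times - t_event, 0.0)  # seconds since gas switch
    curve = h.oe_sign * h.a_oe * (1.0 - np.exp(-tp / h.tau_oe))
    curve[times < t_event] = 0.0
    return curve


def make_ground_truth_curves(config: PhantomConfig) -> dict:
    """Per-habitat ground-truth delta R1(t) templates for DCE and OE."""
    t = config.timing
    return {
        h.name: {
            "dce": _dce_template(h, t.dce_times, t.dce_event_frame),
            "oe": _oe_template(h, t.oe_times, t.oe_event_frame),
        }
        for h in config.habitats
    }


def _assign_habitats(config: PhantomConfig):
    """Label volume (0 outside tumor, 1..N habitats) from spatial rules."""
    nx, ny, nz = config.grid_shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = config.center
    rx, ry, rz = config.radii
    rho = np.sqrt(((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2)
    mask = rho <= 1.0
    if not mask.any():
        raise ValueError("tumor ellipsoid contains no voxels")
    theta = np.rad2deg(np.arctan2(y - cy, x - cx)) % 360.0

    labels = np.zeros(config.grid_shape, dtype=np.int32)
    for i, h in enumerate(config.habitats, start=1):
        sel = mask & (rho >= h.rho_min) & (rho < h.rho_max + (1e-9 if h.rho_max >= 1.0 else 0.0))
        if h.theta_min is not None:
            sel &= (theta >= h.theta_min) & (theta < h.theta_max)
        if np.any(labels[sel] != 0):
            raise ValueError(f"habitat rules overlap at habitat '{h.name}'")
        labels[sel] = i
    if np.any(mask & (labels == 0)):
        raise ValueError("habitat rules leave tumor voxels unlabeled")

    # per-voxel amplitude modulation: linear in rho across each habitat's
    # radial extent, spanning 1 - gradient (inner edge) to 1 + gradient
    amp_scale = np.ones(config.grid_shape)
    for i, h in enumerate(config.habitats, start=1):
        if h.gradient == 0:
            continue
        sel = labels == i
        half = (h.rho_max - h.rho_min) / 2.0
        mid = (h.rho_min + h.rho_max) / 2.0
        amp_scale[sel] = 1.0 + h.gradient * (rho[sel] - mid) / half
    return labels, mask, amp_scale


def render_phantom(config: PhantomConfig, seed: int | None = None) -> PhantomOutput:
    """Render raw DCE/OE dynamic series and VFA sets with ground truth.

    Deterministic given the seed (``seed`` argument overrides
    ``config.seed``).  With ``noise_sd == 0`` and ``drift_a == 0`` the
    signal-to-delta-R1 conversion recovers the ground-truth curves exactly.
    """
    labels, mask, amp_scale = _assign_habitats(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    # spatially unstructured within-habitat amplitude variability (drawn
    # before the series noise so renders stay bit-reproducible per seed)
    for i, h in enumerate(config.habitats, start=1):
        if h.jitter > 0:
            sel = labels == i
            amp_scale[sel] *= 1.0 + h.jitter * rng.normal(size=int(sel.sum()))
    t = config.timing
    curves = make_ground_truth_curves(config)

    # per-voxel T10
    t10_vol = np.full(config.grid_shape, np.nan)
    for i, h in enumerate(config.habitats, start=1):
        t10_vol[labels == i] = h.t10

    def render_series(times, event_frame, flip_deg, tr_ms, templates, drifted):
        vol = np.zeros(config.grid_shape + (times.size,))
        if drifted and config.drift_a != 0.0:
            alpha_t = flip_deg * (
                1.0 + config.drift_a * (1.0 - np.exp(-times / config.drift_tau_s))
            )
        else:
            alpha_t = np.full(times.size, float(flip_deg))
        for i, h in enumerate(config.habitats, start=1):
            sel = labels == i
            r1 = 1.0 / h.t10 + amp_scale[sel][:, None] * templates[h.name][None, :]
            vol[sel, :] = spgr_signal(config.s0, 1.0 / r1, alpha_t[None, :], tr_ms)
        if config.noise_sd > 0:
            vol += rng.normal(0.0, config.noise_sd, size=vol.shape)
        return vol

    dce_templates = {name: c["dce"] for name, c in curves.items()}
    oe_templates = {name: c["oe"] for name, c in curves.items()}

    dce_vol = render_series(
        t.dce_times, t.dce_event_frame, t.dce_flip_deg, t.dce_tr_ms,
        dce_templates, drifted=False,
    )
    oe_vol = render_series(
        t.oe_times, t.oe_event_frame, t.oe_flip_deg, t.oe_tr_ms,
        oe_templates, drifted=True,
    )

    def render_vfa(angles, tr_ms):
        vfa = np.zeros(config.grid_shape + (len(angles),))
        for i, h in enumerate(config.habitats, start=1):
            sig = spgr_signal(config.s0, h.t10, np.asarray(angles), tr_ms)
            vfa[labels == i, :] = sig
        sd = config.noise_sd if config.vfa_noise_sd is None else config.vfa_noise_sd
        if sd > 0:
            vfa += rng.normal(0.0, sd, size=vfa.shape)
        return vfa

    dce_vfa = VfaSet(
        signals=render_vfa(t.dce_vfa_angles_deg, t.dce_tr_ms),
        angles_deg=np.asarray(t.dce_vfa_angles_deg),
        tr_ms=t.dce_tr_ms,
    )
    oe_vfa = VfaSet(
        signals=render_vfa(t.oe_vfa_angles_deg, t.oe_tr_ms),
        angles_deg=np.asarray(t.oe_vfa_angles_deg),
        tr_ms=t.oe_tr_ms,
    )

    legend = {i: h.name for i, h in enumerate(config.habitats, start=1)}
    return PhantomOutput(
        dce=DynamicSeries(
            data=dce_vol, frame_times=t.dce_times, event_frame=t.dce_event_frame,
            modality="DCE", flip_angle_deg=t.dce_flip_deg, tr_ms=t.dce_tr_ms,
        ),
        oe=DynamicSeries(
            data=oe_vol, frame_times=t.oe_times, event_frame=t.oe_event_frame,
            modality="OE", flip_angle_deg=t.oe_flip_deg, tr_ms=t.oe_tr_ms,
        ),
        dce_vfa=dce_vfa,
        oe_vfa=oe_vfa,
        mask=mask,
        truth=RegionMap(labels=labels, legend=legend),
        truth_curves=curves,
        config=config,
        amp_scale=amp_scale,
    )
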