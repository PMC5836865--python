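"""Core data containers shared across the pipeline stages.

Conventions used throughout the package:

* volumes are ``(x, y, z)`` numpy arrays; dynamic series are ``(x, y, z, t)``
* voxel coordinates are 0-based ``(x, y, z)`` integer triples
* times are seconds from the start of the dynamic series
* the *event frame* is the 0-based index of the first acquisition after the
  physiological event (gadolinium injection for DCE, gas switch for OE);
  "beginning of the 19th acquisition" therefore maps to event frame 18
* T1 is carried in seconds, TR in milliseconds (converted internally), and
  relaxation-rate changes ``delta R1`` in s^-1
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DynamicSeries",
    "VfaSet",
    "DeltaR1Matrix",
    "FeatureSet",
    "RegionMap",
]


@dataclass
class DynamicSeries:
    """A 4D dynamic acquisition with frame timing and the event frame.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Raw signal volumes, one per frame.
    frame_times : ndarray, shape (t,)
        Acquisition time of each frame in seconds from series start.
    event_frame : int
        0-based index of the first frame acquired after the event
        (contrast injection or gas switch).
    modality : str
        ``"DCE"`` or ``"OE"``.
    flip_angle_deg : float
        Nominal flip angle of the dynamic acquisition.
    tr_ms : float
        Repetition time in milliseconds.
    """

    data: np.ndarray
    frame_times: np.ndarray
    event_frame: int
    modality: str
    flip_angle_deg: float
    tr_ms: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("dynamic series data must be 4D (x, y, z, t)")
        if self.frame_times.shape != (self.data.shape[3],):
            raise ValueError("frame_times length must match the time axis")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not 0 <= self.event_frame < self.n_frames:
            raise ValueError("event frame outside the series")
        if self.tr_ms <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def event_time(self) -> float:
        return float(self.frame_times[self.event_frame])


@dataclass
class VfaSet:
    """Multi-flip-angle baseline volumes for variable flip angle T1 fitting.

    ``signals`` stacks one volume per flip angle on the last axis.
    """

    signals: np.ndarray  # (x, y, z, n_angles)
    angles_deg: np.ndarray
    tr_ms: float
    te_ms: float | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.signals.ndim != 4:
            raise ValueError("VFA signals must be 4D (x, y, z, n_angles)")
        if self.signals.shape[3] != self.angles_deg.size:
            raise ValueError("number of volumes must match number of angles")
        if np.unique(self.angles_deg).size < 2:
            raise ValueError("at least two distinct flip angles are required")
        if self.tr_ms <= 0:
            raise ValueError("TR must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signals.shape[:3]


@dataclass
class DeltaR1Matrix:
    """Masked voxel-by-time delta R1 values with voxel coordinates retained.

    ``values`` holds delta R1 in s^-1; frames where the signal-to-R1
    inversion was unphysical are NaN.  ``erratic`` flags voxels where the
    inversion failed on more than half of the frames.
    """

    values: np.ndarray  # (n_voxels, n_frames), s^-1
    frame_times: np.ndarray
    event_frame: int
    coords: np.ndarray  # (n_voxels, 3) int, 0-based (x, y, z)
    modality: str
    erratic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (voxels x time)")
        if self.coords.shape != (self.values.shape[0], 3):
            raise ValueError("coords must be (n_voxels, 3)")
        if self.frame_times.shape != (self.values.shape[1],):
            raise ValueError("frame_times length must match time axis")
        if not 0 <= self.event_frame < self.values.shape[1]:
            raise ValueError("event frame outside the series")
        if len({tuple(c) for c in self.coords}) != self.coords.shape[0]:
            raise ValueError("voxel coordinates must be unique")
        if self.erratic is None:
            self.erratic = np.zeros(self.values.shape[0], dtype=bool)
        else:
            self.erratic = np.asarray(self.erratic, dtype=bool)
            if self.erratic.shape != (self.values.shape[0],):
                raise ValueError("erratic flags must be per voxel")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def event_time(self) -> float:
        return float(self.frame_times[self.event_frame])

    def subset(self, index: np.ndarray) -> "DeltaR1Matrix":
        """Row subset preserving alignment of values, coords and flags."""
        return DeltaR1Matrix(
            values=self.values[index],
            frame_times=self.frame_times,
            event_frame=self.event_frame,
            coords=self.coords[index],
            modality=self.modality,
            erratic=self.erratic[index],
        )


@dataclass
class FeatureSet:
    """Voxel-by-feature matrix with provenance metadata.

    The two built-in flavours are the 2-D AUC set (signed areas under the
    DCE and OE enhancement curves) and the PCA set (voxel weightings on the
    leading principal components of scaled, concatenated curves).
    """

    matrix: np.ndarray  # (n_voxels, d)
    names: Sequence[str]
    coords: np.ndarray  # (n_voxels, 3)
    tumor_ids: np.ndarray  # (n_voxels,)
    kind: str = "auc"  # "auc" | "pca"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        self.tumor_ids = np.asarray(self.tumor_ids)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2D")
        if len(self.names) != self.matrix.shape[1]:
            raise ValueError("one name per feature column required")
        if self.coords.shape != (self.matrix.shape[0], 3):
            raise ValueError("coords must align with feature rows")
        if self.tumor_ids.shape != (self.matrix.shape[0],):
            raise ValueError("tumor_ids must align with feature rows")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix must be finite")

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass
class RegionMap:
    """3D integer label volume: 0 outside the mask, 1..N inside."""

    labels: np.ndarray  # (x, y, z) int
    legend: dict = field(default_factory=dict)
    tumor_id: str | int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("region map must be a 3D volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("region map labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def present_labels(self) -> np.ndarray:
        vals = np.unique(self.labels)
        return vals[vals > 0]

    def in_mask_labels(self) -> np.ndarray:
        """Flat vector of labels at in-mask voxels (C order)."""
        return self.labels[self.mask]
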