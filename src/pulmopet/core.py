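"""Core domain types: grids, volumes, frame schedules, masks, plasma curves.

All spatial quantities are in millimetres; voxel indices are 0-based and a
voxel's physical coordinate is its centre. Frame times are float seconds
(minutes appear only at the Patlak API boundary). Activity is carried in an
arbitrary-but-consistent unit: every quantity the analysis reports (Q_rel,
sV, Ki, Fgas) is a ratio or a rate, so the absolute calibration cancels.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "VolumeGrid",
    "ScalarVolume",
    "FrameSchedule",
    "DynamicScan",
    "LobeMaskVolume",
    "PlasmaCurve",
    "CellCountRecord",
    "VOLUME_KINDS",
    "LOBE_ROLES",
]

VOLUME_KINDS = ("hu", "activity", "fgas", "q_rel", "sv", "ki")

#: Experimental lobe roles: baseline (unexposed LUL), diluent-challenged RUL,
#: allergen-challenged RML.
LOBE_ROLES = ("baseline", "diluent", "allergen")


@dataclass(frozen=True)
class VolumeGrid:
    """Regular 3-D voxel grid.

    Parameters
    ----------
    dims : tuple of int
        Number of voxels along each axis.
    spacing : tuple of float
        Voxel size in mm along each axis.
    gravity_axis : int
        Index of the axis aligned with gravity (supine subject).
    dependent_positive : bool
        True if the dependent (dorsal, gravitationally lowest) end of the
        lung lies at the high-index end of ``gravity_axis``.
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    gravity_axis: int = 2
    dependent_positive: bool = False

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) <= 0 for d in self.dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths (mm), got {self.spacing}")
        if self.gravity_axis not in (0, 1, 2):
            raise ValueError(f"gravity_axis must be 0, 1 or 2, got {self.gravity_axis}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def height_coordinate(self) -> np.ndarray:
        """Per-voxel coordinate (mm) increasing away from the dependent end.

        The origin is the dependent face of the grid; subtract the minimum
        over lung voxels to measure height from the most dependent lung
        voxel, as the gravity-profile analysis does.
        """
        ax = self.gravity_axis
        n = self.dims[ax]
        centers = (np.arange(n) + 0.5) * self.spacing[ax]
        if self.dependent_positive:
            centers = centers[::-1].copy()
        shape = [1, 1, 1]
        shape[ax] = n
        return np.broadcast_to(centers.reshape(shape), self.dims).astype(float)


@dataclass
class ScalarVolume:
    """A scalar field on a :class:`VolumeGrid` with a kind tag."""

    grid: VolumeGrid
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid dims {self.grid.dims}"
            )
        if self.kind not in VOLUME_KINDS:
            raise ValueError(f"unknown volume kind {self.kind!r}; expected one of {VOLUME_KINDS}")
        if self.kind == "fgas":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
                raise ValueError("fgas values must lie in [0, 1]")

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "ScalarVolume":
        return ScalarVolume(self.grid, values, kind if kind is not None else self.kind)


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, contiguous, non-overlapping acquisition frames (seconds)."""

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        frames = tuple((float(s), float(d)) for s, d in self.frames)
        if not frames:
            raise ValueError("schedule must contain at least one frame")
        for start, dur in frames:
            if dur <= 0:
                raise ValueError(f"frame durations must be > 0, got {dur}")
        for (s0, d0), (s1, _) in zip(frames, frames[1:]):
            if not np.isclose(s0 + d0, s1):
                raise ValueError(
                    f"frames must be contiguous: frame ending at {s0 + d0} s "
                    f"followed by frame starting at {s1} s"
                )
        object.__setattr__(self, "frames", frames)

    @classmethod
    def from_durations(cls, durations: Sequence[float], start: float = 0.0) -> "FrameSchedule":
        starts = start + np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(tuple(zip(starts.tolist(), [float(d) for d in durations])))

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def starts(self) -> np.ndarray:
        return np.array([s for s, _ in self.frames])

    @property
    def durations(self) -> np.ndarray:
        return np.array([d for _, d in self.frames])

    @property
    def mid_times(self) -> np.ndarray:
        return self.starts + self.durations / 2.0

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())


def nn13_default_schedule() -> FrameSchedule:
    """The 16-frame dynamic ¹³NN-saline schedule: 8×5 s, 3×10 s, 5×30 s."""
    return FrameSchedule.from_durations([5.0] * 8 + [10.0] * 3 + [30.0] * 5)


def fdg_default_schedule() -> FrameSchedule:
    """The 36-frame dynamic ¹⁸F-FDG schedule:
    9×10 s, 3×15 s, 1×30 s, 7×60 s, 14×120 s, 1×300 s, 1×600 s."""
    return FrameSchedule.from_durations(
        [10.0] * 9 + [15.0] * 3 + [30.0] + [60.0] * 7 + [120.0] * 14 + [300.0] + [600.0]
    )


#: Venous plasma sampling times during the FDG scan (minutes).
FDG_PLASMA_SAMPLE_TIMES_MIN = (5.5, 9.5, 25.0, 37.0, 42.5)


@dataclass
class DynamicScan:
    """4-D activity scan: one frame-averaged activity volume per frame."""

    grid: VolumeGrid
    schedule: FrameSchedule
    frames: np.ndarray  # shape (n_frames, *grid.dims)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError("frames must be a 4-D array (n_frames, nx, ny, nz)")
        if self.frames.shape[0] != len(self.schedule):
            raise ValueError(
                f"scan has {self.frames.shape[0]} frames but schedule has "
                f"{len(self.schedule)} entries"
            )
        if self.frames.shape[1:] != self.grid.dims:
            raise ValueError(
                f"frame shape {self.frames.shape[1:]} does not match grid dims {self.grid.dims}"
            )

    def frame_volume(self, i: int) -> ScalarVolume:
        return ScalarVolume(self.grid, self.frames[i], "activity")

    def mean_tac(self, mask: np.ndarray) -> np.ndarray:
        """Mean time-activity curve over a boolean voxel mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.grid.dims:
            raise ValueError("mask shape does not match scan grid")
        if not mask.any():
            raise ValueError("mask selects no voxels")
        return self.frames[:, mask].mean(axis=1)


@dataclass
class LobeMaskVolume:
    """Integer lobe labels (0 = outside lung) with experimental role map."""

    grid: VolumeGrid
    labels: np.ndarray
    role_labels: Mapping[str, int]
    label_names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("lobe labels must be integers")
        if self.labels.shape != self.grid.dims:
            raise ValueError("label shape does not match grid dims")
        missing = [r for r in LOBE_ROLES if r not in self.role_labels]
        if missing:
            raise ValueError(f"role map missing roles: {missing}")
        for role, lab in self.role_labels.items():
            if not (self.labels == lab).any():
                raise ValueError(f"role {role!r} maps to label {lab} with no voxels")

    @property
    def lung_mask(self) -> np.ndarray:
        return self.labels > 0

    def role_mask(self, role: str) -> np.ndarray:
        if role not in self.role_labels:
            raise KeyError(f"unknown lobe role {role!r}")
        return self.labels == self.role_labels[role]

    def lung_voxel_count(self) -> int:
        return int(self.lung_mask.sum())


@dataclass
class PlasmaCurve:
    """Venous plasma activity samples (times in minutes).

    ``dense`` marks simulator-provided curves sampled finely enough to act
    as the true input function (bypassing sparse-sample interpolation).
    """

    times_min: np.ndarray
    activities: np.ndarray
    dense: bool = False

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if self.times_min.shape != self.activities.shape or self.times_min.ndim != 1:
            raise ValueError("times and activities must be matching 1-D arrays")
        if self.times_min.size and np.any(np.diff(self.times_min) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.activities < 0):
            raise ValueError("plasma activities must be >= 0")


@dataclass
class CellCountRecord:
    """BAL cell counts for one lobe with returned-fluid volume."""

    lobe_role: str
    returned_volume_ml: float
    total_cells: float
    eosinophils: float
    neutrophils: float
    mononuclear: float

    def __post_init__(self) -> None:
        if self.returned_volume_ml <= 0:
            raise ValueError("returned BAL volume must be > 0")
        counts = (self.total_cells, self.eosinophils, self.neutrophils, self.mononuclear)
        if any(c < 0 for c in counts):
            raise ValueError("cell counts must be >= 0")
        differential = self.eosinophils + self.neutrophils + self.mononuclear
        if differential > self.total_cells * (1 + 1e-9):
            raise ValueError(
                f"differential counts ({differential:g}) exceed total ({self.total_cells:g})"
            )
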