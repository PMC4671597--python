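"""Relative perfusion and specific ventilation from dynamic ¹³NN-saline PET.

Because nitrogen is nearly insoluble in tissue (water/air partition
coefficient ~0.0015 at 37 °C), an intravenous ¹³NN-saline bolus delivered
during a breath-hold diffuses almost completely into alveolar gas on first
pass. Accumulated activity at the end of the apnea is therefore
proportional to regional perfusion (Q), and once breathing resumes the
tracer is cleared by ventilation, so the washout rate of each voxel's
activity estimates its specific ventilation (sV, min⁻¹):

    A(t) = A_plateau · exp(−sV · (t − t_washout)),   A_plateau ∝ Q.

`WashoutModel` bundles the full voxelwise analysis (optional moving-average
smoothing, plateau perfusion proxy, log-linear washout fit, low-signal
flagging, mean-normalization); the module-level functions expose each stage
separately.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import DynamicScan, LobeMaskVolume, ScalarVolume

__all__ = [
    "WashoutModel",
    "WashoutResults",
    "WashoutFitResult",
    "estimate_perfusion",
    "estimate_specific_ventilation",
    "smooth_moving_average",
    "mean_normalize",
    "low_signal_flags",
    "box_kernel_sizes",
]


def box_kernel_sizes(spacing: tuple[float, float, float], target_mm: float) -> tuple[int, int, int]:
    """Per-axis odd box-kernel sizes whose physical extent best matches the target.

    With 5.3456 mm in-plane voxels and a 10.125 mm target this selects 1
    voxel in-plane; with 2.025 mm axial voxels it selects 5 (5 × 2.025 =
    10.125 mm exactly).
    """
    sizes = []
    for s in spacing:
        if target_mm < s:
            raise ValueError(
                f"target resolution {target_mm} mm is below the voxel spacing {s} mm"
            )
        candidates = np.arange(1, 2 * int(np.ceil(target_mm / s)) + 2, 2)
        sizes.append(int(candidates[np.argmin(np.abs(candidates * s - target_mm))]))
    return tuple(sizes)


def smooth_moving_average(
    vol: ScalarVolume,
    target_resolution_mm: float = 10.125,
    mask: np.ndarray | None = None,
) -> ScalarVolume:
    """3-D moving-average (box) filter to an effective resolution.

    With a mask, voxels outside it carry zero weight and the kernel weights
    are renormalized inside the mask, so lung values are never diluted by
    surrounding air; the output is zero outside the mask.
    """
    sizes = box_kernel_sizes(vol.grid.spacing, target_resolution_mm)
    if mask is None:
        out = ndimage.uniform_filter(vol.values, size=sizes, mode="constant", cval=0.0)
        return vol.with_values(out)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.grid.dims:
        raise ValueError("mask shape does not match volume grid")
    m = mask.astype(float)
    num = ndimage.uniform_filter(vol.values * m, size=sizes, mode="constant", cval=0.0)
    den = ndimage.uniform_filter(m, size=sizes, mode="constant", cval=0.0)
    out = np.zeros_like(vol.values)
    np.divide(num, den, out=out, where=den > 0)
    out[~mask] = 0.0
    return vol.with_values(out)


def mean_normalize(vol: ScalarVolume, mask: LobeMaskVolume | np.ndarray) -> ScalarVolume:
    """Divide by the mean over lung voxels so the lung mean becomes 1."""
    lung = mask.lung_mask if isinstance(mask, LobeMaskVolume) else np.asarray(mask, dtype=bool)
    if lung.shape != vol.grid.dims:
        raise ValueError("mask shape does not match volume grid")
    if not lung.any():
        raise ValueError("mask selects no lung voxels")
    mean = float(vol.values[lung].mean())
    if mean == 0:
        raise ValueError("cannot mean-normalize: lung mean is zero")
    out = vol.values / mean
    return vol.with_values(out)


def _resolve_window(
    scan: DynamicScan, window: tuple[float, float], in_seconds: bool
) -> np.ndarray:
    """Frame indices selected by a window of frame indices or of seconds.

    A seconds window (t0, t1) selects frames fully contained in [t0, t1].
    """
    if in_seconds:
        t0, t1 = window
        sched = scan.schedule
        idx = np.where((sched.starts >= t0 - 1e-9) & (sched.ends <= t1 + 1e-9))[0]
    else:
        i0, i1 = window
        if i0 < 0 or i1 > len(scan.schedule) or i0 >= i1:
            raise ValueError(f"frame window {window} outside schedule of {len(scan.schedule)} frames")
        idx = np.arange(int(i0), int(i1))
    if idx.size == 0:
        raise ValueError(f"window {window} selects no frames")
    return idx


def low_signal_flags(
    plateau: np.ndarray,
    lung_mask: np.ndarray | None = None,
    threshold_frac: float = 0.05,
) -> np.ndarray:
    """Flag voxels whose plateau is below a fraction of the lung-median plateau."""
    plateau = np.asarray(plateau, dtype=float)
    ref = plateau if lung_mask is None else plateau[np.asarray(lung_mask, dtype=bool)]
    median = float(np.median(ref)) if ref.size else 0.0
    threshold = threshold_frac * median
    return plateau <= max(threshold, 0.0)


def estimate_perfusion(
    scan: DynamicScan,
    apnea_window: tuple[float, float] = (0.0, 30.0),
    window_in_seconds: bool = True,
    plateau_fraction: float = 0.5,
) -> ScalarVolume:
    """Relative-perfusion proxy: mean activity over the apnea plateau frames.

    Tracer accumulated in alveolar gas by the end of the breath-hold is
    proportional to regional blood flow. Only the final ``plateau_fraction``
    of the apnea frames is averaged, to exclude the bolus-arrival ramp.
    The result is unnormalized; apply :func:`mean_normalize` for values
    relative to the imaged-lung mean.
    """
    idx = _resolve_window(scan, apnea_window, window_in_seconds)
    n_plateau = max(1, int(np.ceil(len(idx) * plateau_fraction)))
    plateau_idx = idx[-n_plateau:]
    plateau = scan.frames[plateau_idx].mean(axis=0)
    return ScalarVolume(scan.grid, plateau, "q_rel")


@dataclass
class WashoutFitResult:
    """Voxelwise log-linear washout fit."""

    sv: ScalarVolume  # min^-1; 0 where flagged
    plateau: np.ndarray
    r_squared: np.ndarray
    low_signal: np.ndarray  # bool; flagged voxels carry no sV estimate

    def sv_values(self) -> np.ndarray:
        """sV with flagged voxels masked to NaN."""
        out = self.sv.values.copy()
        out[self.low_signal] = np.nan
        return out


def estimate_specific_ventilation(
    scan: DynamicScan,
    washout_window: tuple[float, float] = (30.0, 220.0),
    window_in_seconds: bool = True,
    plateau: np.ndarray | None = None,
    lung_mask: np.ndarray | None = None,
    signal_threshold_frac: float = 0.05,
) -> WashoutFitResult:
    """Voxelwise sV from the washout: weighted log-linear fit of ln A vs t.

    For each voxel, ln A(t_mid) = ln A0 − sV·(t_mid − t0) is fitted by
    weighted least squares over the washout frame mid-times with weights
    duration × activity (down-weighting long low-count tail frames), which
    is exact on noise-free exponential data. sV is reported in min⁻¹ and
    clamped at 0. Voxels with fewer than 3 positive washout frames, or with
    plateau activity below ``signal_threshold_frac`` of the lung-median
    plateau, are flagged low-signal and excluded from downstream summaries.
    """
    idx = _resolve_window(scan, washout_window, window_in_seconds)
    if idx.size < 3:
        raise ValueError(f"washout window selects {idx.size} frames; need at least 3")
    t = scan.schedule.mid_times[idx]
    d = scan.schedule.durations[idx]
    A = scan.frames[idx].reshape(idx.size, -1)  # (nf, nvox)

    pos = A > 0
    usable = pos.sum(axis=0) >= 3
    if not usable.any():
        # no voxel has enough positive frames: everything flagged
        if plateau is None:
            plateau = scan.frames[idx[0]]
        shape = scan.grid.dims
        zeros = np.zeros(shape)
        return WashoutFitResult(
            ScalarVolume(scan.grid, zeros, "sv"),
            np.asarray(plateau, dtype=float),
            zeros.copy(),
            np.ones(shape, dtype=bool),
        )

    logA = np.zeros_like(A)
    np.log(A, out=logA, where=pos)
    w = np.where(pos, d[:, None] * A, 0.0)
    sw = w.sum(axis=0)
    sw[sw == 0] = 1.0  # flagged anyway
    tbar = (w * t[:, None]).sum(axis=0) / sw
    ybar = (w * logA).sum(axis=0) / sw
    dt = t[:, None] - tbar
    dy = logA - ybar
    sxx = (w * dt * dt).sum(axis=0)
    sxy = (w * dt * dy).sum(axis=0)
    syy = (w * dy * dy).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / sxx, 0.0)
        r2 = np.where((sxx > 0) & (syy > 0), (sxy * sxy) / (sxx * syy), 0.0)
    sv_per_min = np.clip(-slope * 60.0, 0.0, None)
    sv_per_min[~usable] = 0.0
    r2[~usable] = 0.0

    if plateau is None:
        plateau = scan.frames[idx[0]]
    plateau = np.asarray(plateau, dtype=float)
    flags = low_signal_flags(plateau, lung_mask, signal_threshold_frac)
    flags |= ~usable.reshape(scan.grid.dims)
    sv_vol = sv_per_min.reshape(scan.grid.dims)
    sv_vol = np.where(flags, 0.0, sv_vol)
    return WashoutFitResult(
        ScalarVolume(scan.grid, sv_vol, "sv"),
        plateau,
        r2.reshape(scan.grid.dims),
        flags,
    )


@dataclass
class WashoutResults:
    """Fitted ¹³NN washout analysis: maps, diagnostics, lobe summaries."""

    model: "WashoutModel"
    perfusion: ScalarVolume  # mean-normalized Q_rel
    perfusion_raw: ScalarVolume
    specific_ventilation: ScalarVolume  # absolute sV, min^-1
    specific_ventilation_norm: ScalarVolume  # mean-normalized sV
    r_squared: np.ndarray
    low_signal: np.ndarray
    flagged_count: int = field(init=False)

    def __post_init__(self) -> None:
        mask = self.model.mask
        lung = mask.lung_mask if mask is not None else np.ones(self.perfusion.grid.dims, bool)
        self.flagged_count = int((self.low_signal & lung).sum())

    def lobe_means(self) -> pd.DataFrame:
        """Per-lobe means of mean-normalized Q and sV, excluding flagged voxels."""
        mask = self.model.mask
        if mask is None:
            raise ValueError("lobe summaries require a lobe mask")
        rows = []
        for role in mask.role_labels:
            m = mask.role_mask(role) & ~self.low_signal
            if not m.any():
                raise ValueError(f"lobe {role!r} has no unflagged voxels")
            rows.append(
                {
                    "lobe": role,
                    "q_rel": float(self.perfusion.values[m].mean()),
                    "sv_norm": float(self.specific_ventilation_norm.values[m].mean()),
                    "sv_per_min": float(self.specific_ventilation.values[m].mean()),
                    "n_voxels": int(m.sum()),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "13NN washout analysis",
            f"  apnea window:    {self.model.apnea_window} s",
            f"  washout window:  {self.model.washout_window} s",
            f"  smoothing:       {self.model.smoothing_mm} mm box"
            if self.model.smoothing_mm
            else "  smoothing:       none",
            f"  low-signal voxels flagged: {self.flagged_count}",
        ]
        if self.model.mask is not None:
            lines.append(self.lobe_means().to_string(index=False))
        return "\n".join(lines)


class WashoutModel:
    """Full ¹³NN-saline perfusion/ventilation analysis of a dynamic scan.

    Parameters
    ----------
    scan : DynamicScan
        Dynamic ¹³NN scan covering apnea and washout.
    mask : LobeMaskVolume, optional
        Lung/lobe labels; required for mean-normalization over the lung and
        for lobe summaries. Without it, normalization runs over all voxels.
    apnea_window, washout_window : (float, float)
        Time windows in seconds (breath-hold, washout).
    smoothing_mm : float or None
        Target effective resolution for the moving-average prefilter
        applied to every frame (None disables).
    """

    def __init__(
        self,
        scan: DynamicScan,
        mask: LobeMaskVolume | None = None,
        apnea_window: tuple[float, float] = (0.0, 30.0),
        washout_window: tuple[float, float] | None = None,
        plateau_fraction: float = 0.5,
        smoothing_mm: float | None = None,
        signal_threshold_frac: float = 0.05,
    ) -> None:
        self.scan = scan
        self.mask = mask
        self.apnea_window = apnea_window
        if washout_window is None:
            washout_window = (apnea_window[1], scan.schedule.total_duration)
        self.washout_window = washout_window
        self.plateau_fraction = plateau_fraction
        self.smoothing_mm = smoothing_mm
        self.signal_threshold_frac = signal_threshold_frac

    def fit(self) -> WashoutResults:
        scan = self.scan
        lung = self.mask.lung_mask if self.mask is not None else None
        if self.smoothing_mm is not None:
            frames = np.stack(
                [
                    smooth_moving_average(
                        ScalarVolume(scan.grid, f, "activity"), self.smoothing_mm, lung
                    ).values
                    for f in scan.frames
                ]
            )
            scan = DynamicScan(scan.grid, scan.schedule, frames)
        q_raw = estimate_perfusion(
            scan, self.apnea_window, plateau_fraction=self.plateau_fraction
        )
        fit = estimate_specific_ventilation(
            scan,
            self.washout_window,
            plateau=q_raw.values,
            lung_mask=lung,
            signal_threshold_frac=self.signal_threshold_frac,
        )
        norm_mask = lung if lung is not None else np.ones(scan.grid.dims, bool)
        q_norm = mean_normalize(q_raw, norm_mask)
        sv_norm = mean_normalize(fit.sv, norm_mask)
        return WashoutResults(
            model=self,
            perfusion=q_norm,
            perfusion_raw=q_raw,
            specific_ventilation=fit.sv,
            specific_ventilation_norm=sv_norm,
            r_squared=fit.r_squared,
            low_signal=fit.low_signal,
        )
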