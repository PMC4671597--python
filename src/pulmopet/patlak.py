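"""Patlak graphical analysis of ¹⁸F-FDG net uptake rate (Ki).

FDG enters cells like glucose but is trapped after phosphorylation, so for
an irreversibly trapping tracer the tissue curve obeys, once exchange with
the reversible compartment has equilibrated,

    C_t(t) / Cp(t)  ≈  Ki · (∫₀ᵗ Cp dτ) / Cp(t)  +  V0,

i.e. normalized tissue activity plotted against normalized integrated
plasma activity ("Patlak time") becomes linear after a settling time t*
(about 8–10 min for lung). The slope of that linear segment, estimated by
ordinary least squares, is the net uptake rate Ki (min⁻¹), proportional to
cellular glucose metabolic rate; the intercept is the initial distribution
volume.

The plasma input function is reconstructed from sparse venous samples:
piecewise-linear between samples, a linear rise from zero at injection
before the first sample, and a mono-exponential tail fitted to the final
two samples.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DynamicScan, LobeMaskVolume, PlasmaCurve, ScalarVolume

__all__ = [
    "InputFunction",
    "build_input_function",
    "patlak_transform",
    "fit_patlak",
    "PatlakModel",
    "PatlakResult",
    "lobe_ki",
    "lobe_ki_table",
    "voxelwise_ki",
]


class InputFunction:
    """Continuous plasma curve Cp(t) with exact running integral.

    Piecewise-linear between the sample knots (with a knot at t = 0,
    Cp = 0, unless the first sample is at 0); mono-exponential beyond the
    last sample, with decay rate fitted to the final two samples (clamped
    at 0, i.e. constant extrapolation, if the samples do not decay).
    Times in minutes.
    """

    def __init__(self, times_min: np.ndarray, activities: np.ndarray) -> None:
        t = np.asarray(times_min, dtype=float)
        c = np.asarray(activities, dtype=float)
        if t.size < 2:
            raise ValueError("input function requires at least 2 plasma samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if t[0] > 0:
            t = np.concatenate([[0.0], t])
            c = np.concatenate([[0.0], c])
        self.knot_t = t
        self.knot_c = c
        if c[-1] <= 0 or c[-2] <= 0:
            raise ValueError("nonpositive late samples: exponential extrapolation undefined")
        b = np.log(c[-2] / c[-1]) / (t[-1] - t[-2])
        self.tail_rate = max(b, 0.0)
        # cumulative trapezoid integral at the knots (exact for linear pieces)
        seg = 0.5 * (c[1:] + c[:-1]) * np.diff(t)
        self.knot_int = np.concatenate([[0.0], np.cumsum(seg)])

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.interp(t, self.knot_t, self.knot_c)
        late = t > self.knot_t[-1]
        if np.any(late):
            out = np.where(
                late,
                self.knot_c[-1] * np.exp(-self.tail_rate * (t - self.knot_t[-1])),
                out,
            )
        return out

    def integral(self, t: np.ndarray | float) -> np.ndarray:
        """∫₀ᵗ Cp dτ, exact on the piecewise model."""
        scalar = np.ndim(t) == 0
        t = np.atleast_1d(np.asarray(t, dtype=float))
        kt, kc, ki = self.knot_t, self.knot_c, self.knot_int
        idx = np.clip(np.searchsorted(kt, t, side="right") - 1, 0, len(kt) - 2)
        t0 = kt[idx]
        dt = np.clip(t, kt[0], kt[-1]) - t0
        c0 = kc[idx]
        slope = (kc[idx + 1] - kc[idx]) / (kt[idx + 1] - kt[idx])
        out = ki[idx] + c0 * dt + 0.5 * slope * dt * dt
        late = t > kt[-1]
        if np.any(late):
            te = t - kt[-1]
            if self.tail_rate > 0:
                tail = self.knot_c[-1] / self.tail_rate * (1.0 - np.exp(-self.tail_rate * te))
            else:
                tail = self.knot_c[-1] * te
            out = np.where(late, ki[-1] + tail, out)
        return float(out[0]) if scalar else out


def build_input_function(plasma: PlasmaCurve, method: str = "linear") -> InputFunction:
    """Build a continuous, integrable input function from plasma samples."""
    if method != "linear":
        raise ValueError(f"unknown input-function method {method!r}")
    return InputFunction(plasma.times_min, plasma.activities)


def patlak_transform(
    times_min: np.ndarray, tissue: np.ndarray, input_fn: InputFunction
) -> tuple[np.ndarray, np.ndarray]:
    """Patlak coordinates: x = ∫₀ᵗCp/Cp(t), y = C_tissue(t)/Cp(t)."""
    t = np.asarray(times_min, dtype=float)
    tissue = np.asarray(tissue, dtype=float)
    cp = input_fn(t)
    if np.any(cp <= 0):
        bad = t[cp <= 0]
        raise ValueError(f"plasma activity is zero at frame time(s) {bad} min")
    x = np.asarray(input_fn.integral(t)) / cp
    y = tissue / cp
    return x, y


@dataclass
class PatlakResult:
    """Ki and diagnostics from the linear Patlak segment."""

    ki: float  # min^-1
    intercept: float  # initial distribution volume, dimensionless
    r_squared: float
    t_star: float  # min
    n_points: int
    x: np.ndarray | None = None
    y: np.ndarray | None = None

    def summary(self) -> str:
        return (
            f"Patlak fit: Ki = {self.ki:.6g} /min, intercept = {self.intercept:.4g}, "
            f"R^2 = {self.r_squared:.4f} (t* = {self.t_star:g} min, "
            f"{self.n_points} frames)"
        )

    def plot(self, ax=None):
        """Patlak plot with the fitted linear segment."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.x is not None:
            ax.plot(self.x, self.y, "o", label="frames")
            xs = np.linspace(self.x.min(), self.x.max(), 2)
            ax.plot(xs, self.intercept + self.ki * xs, "-", label=f"Ki={self.ki:.4g}/min")
        ax.set_xlabel("integrated plasma / plasma (min)")
        ax.set_ylabel("tissue / plasma")
        ax.legend()
        return ax


def fit_patlak(
    x: np.ndarray,
    y: np.ndarray,
    times_min: np.ndarray | None = None,
    t_star: float = 10.0,
) -> PatlakResult:
    """OLS fit of the Patlak points with mid-time >= t* (min).

    If ``times_min`` is omitted, all points are used (they are assumed
    pre-selected).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if times_min is not None:
        sel = np.asarray(times_min, dtype=float) >= t_star
        x, y = x[sel], y[sel]
    if x.size < 3:
        raise ValueError(f"only {x.size} Patlak points at t >= {t_star} min; need >= 3")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 0:
        raise ValueError("degenerate Patlak abscissa: no spread in normalized time")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    syy = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / syy if syy > 0 else 1.0
    return PatlakResult(slope, intercept, r2, t_star, int(x.size), x=x, y=y)


class PatlakModel:
    """Patlak graphical model for one tissue time-activity curve.

    Parameters
    ----------
    times_min : array
        Frame mid-times in minutes.
    tissue : array
        Frame-averaged tissue activity.
    plasma : PlasmaCurve or InputFunction
        Venous plasma samples (an input function is built from them) or a
        prebuilt continuous input function.
    t_star : float
        Linearization time (min); frames before t* are excluded from the
        fit. Default 10 min.
    """

    def __init__(
        self,
        times_min: np.ndarray,
        tissue: np.ndarray,
        plasma: PlasmaCurve | InputFunction,
        t_star: float = 10.0,
    ) -> None:
        self.times_min = np.asarray(times_min, dtype=float)
        self.tissue = np.asarray(tissue, dtype=float)
        self.input_fn = plasma if isinstance(plasma, InputFunction) else build_input_function(plasma)
        self.t_star = float(t_star)

    def fit(self) -> PatlakResult:
        x, y = patlak_transform(self.times_min, self.tissue, self.input_fn)
        return fit_patlak(x, y, self.times_min, self.t_star)


def lobe_ki(
    scan: DynamicScan,
    mask: LobeMaskVolume,
    plasma: PlasmaCurve | InputFunction,
    t_star: float = 10.0,
) -> dict[str, PatlakResult]:
    """Per-lobe Ki from the lobe-mean time-activity curve.

    Aggregating the TAC before fitting (rather than averaging voxelwise Ki)
    is the default: the lobe-mean TAC has far better counting statistics
    under sparse venous sampling. Use :func:`voxelwise_ki` for maps.
    """
    if scan.grid.dims != mask.grid.dims:
        raise ValueError("scan and mask are on different grids")
    input_fn = plasma if isinstance(plasma, InputFunction) else build_input_function(plasma)
    t_mid_min = scan.schedule.mid_times / 60.0
    out: dict[str, PatlakResult] = {}
    for role in mask.role_labels:
        m = mask.role_mask(role)
        if not m.any():
            raise ValueError(f"lobe {role!r} is empty")
        tac = scan.mean_tac(m)
        out[role] = PatlakModel(t_mid_min, tac, input_fn, t_star).fit()
    return out


def voxelwise_ki(
    scan: DynamicScan,
    mask: LobeMaskVolume,
    plasma: PlasmaCurve | InputFunction,
    t_star: float = 10.0,
) -> ScalarVolume:
    """Voxelwise Patlak slope map over the lung (vectorized OLS)."""
    input_fn = plasma if isinstance(plasma, InputFunction) else build_input_function(plasma)
    t_mid_min = scan.schedule.mid_times / 60.0
    sel = t_mid_min >= t_star
    if sel.sum() < 3:
        raise ValueError("fewer than 3 frames after t*")
    t = t_mid_min[sel]
    cp = input_fn(t)
    x = np.asarray(input_fn.integral(t)) / cp
    lung = mask.lung_mask
    tissue = scan.frames[sel][:, lung]  # (nf, nvox)
    y = tissue / cp[:, None]
    xc = x - x.mean()
    slope = (xc[:, None] * (y - y.mean(axis=0))).sum(axis=0) / np.sum(xc**2)
    ki = np.zeros(scan.grid.dims)
    ki[lung] = slope
    return ScalarVolume(scan.grid, ki, "ki")


def lobe_ki_table(results: dict[str, PatlakResult]) -> pd.DataFrame:
    rows = [
        {
            "lobe": role,
            "ki_per_min": r.ki,
            "intercept": r.intercept,
            "r_squared": r.r_squared,
            "t_star_min": r.t_star,
            "n_points": r.n_points,
        }
        for role, r in results.items()
    ]
    return pd.DataFrame(rows)
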