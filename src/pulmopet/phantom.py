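"""Digital lung phantom and dynamic tracer simulators.

The phantom emulates the study conditions of a segmental allergen
challenge imaged supine: a lung partitioned into five lobes with the left
upper lobe (LUL) as the unexposed baseline, the right upper lobe (RUL)
receiving diluent and the right middle lobe (RML) receiving allergen;
gravitational gradients in aeration (Fgas increasing away from the
dependent, dorsal lung) and perfusion (decreasing with height); and an
allergen lobe with perfusion and specific ventilation reduced by
configurable multipliers (defaults 0.6 and 0.65, sized to mimic the
reported ~0.9 vs ~0.6 mean-normalized contrast between control and
allergen lobes).

Lobe geometry is deliberately simple (axis-aligned blocks inside a box
lung): the analysis mathematics is insensitive to anatomical shape, and
simple shapes make ground-truth bookkeeping exact.

Both tracer simulators integrate their continuous voxel model over each
acquisition frame (PET frames integrate counts), so frame values are frame
means, not instantaneous samples. ¹³NN recirculation is neglected
entirely, justified by the tracer's water/air partition coefficient of
0.0015 at 37 °C: virtually all tracer leaves the blood on first pass.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aeration import AerationConstants, fgas_to_hu
from .core import (
    FDG_PLASMA_SAMPLE_TIMES_MIN,
    DynamicScan,
    FrameSchedule,
    LobeMaskVolume,
    PlasmaCurve,
    ScalarVolume,
    VolumeGrid,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "TracerSimConfig",
    "FdgInputParams",
    "generate_phantom",
    "simulate_nn13",
    "simulate_fdg",
    "dense_plasma_curve",
    "subject_table_fixture",
    "LOBE_LABELS",
]

#: Lobe label conventions used by the phantom.
LOBE_LABELS = {"LUL": 1, "RUL": 2, "RML": 3, "LLL": 4, "RLL": 5}
ROLE_LABELS = {"baseline": 1, "diluent": 2, "allergen": 3}

#: Water/air partition coefficient of nitrogen at 37 °C; its smallness is
#: why ¹³NN recirculation is neglected in the simulator.
NN13_PARTITION_COEFFICIENT = 0.0015


@dataclass(frozen=True)
class FdgInputParams:
    """Analytic FDG plasma input function: linear rise then a sum of
    decaying exponentials (times in minutes).

    Cp(t) = c0·t/t_rise for t < t_rise, then c0·Σ aᵢ·exp(−bᵢ·(t−t_rise)).
    The default amplitudes/rates describe a fast distribution phase
    (half-life ≈ 10 s), an intermediate exchange phase (≈ 42 s) and a slow
    clearance tail (≈ 69 min), a realistic venous profile after a short
    infusion: by the Patlak settling time (~8–10 min) only the slow phase
    survives, which is what makes the Patlak plot linearize on that
    timescale as observed in lung studies.
    """

    c0: float = 1.0
    t_rise_min: float = 1.0
    amplitudes: tuple[float, ...] = (0.75, 0.15, 0.1)
    rates_per_min: tuple[float, ...] = (4.0, 1.0, 0.01)

    def __post_init__(self) -> None:
        if self.c0 < 0 or self.t_rise_min <= 0:
            raise ValueError("c0 must be >= 0 and t_rise_min > 0")
        if len(self.amplitudes) != len(self.rates_per_min):
            raise ValueError("amplitudes and rates must have equal length")
        if any(a < 0 for a in self.amplitudes) or any(b < 0 for b in self.rates_per_min):
            raise ValueError("amplitudes and rates must be >= 0")

    def cp(self, t_min: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        a = np.array(self.amplitudes)
        b = np.array(self.rates_per_min)
        tau = np.maximum(t - self.t_rise_min, 0.0)
        decay = (a[:, None] * np.exp(-b[:, None] * np.ravel(tau))).sum(axis=0).reshape(tau.shape)
        rise = np.clip(t / self.t_rise_min, 0.0, 1.0) * a.sum()
        out = self.c0 * np.where(t < self.t_rise_min, rise, decay)
        return np.where(t < 0, 0.0, out)

    def cp_integral(self, t_min: np.ndarray | float) -> np.ndarray:
        """Closed-form ∫₀ᵗ Cp dτ (min units)."""
        t = np.asarray(t_min, dtype=float)
        a = np.array(self.amplitudes)
        b = np.array(self.rates_per_min)
        asum = a.sum()
        tr = self.t_rise_min
        rise_part = asum * np.clip(t, 0, tr) ** 2 / (2 * tr)
        tau = np.maximum(t - tr, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            per = np.where(
                b[:, None] > 0,
                a[:, None] / np.where(b[:, None] > 0, b[:, None], 1.0)
                * (1.0 - np.exp(-b[:, None] * np.ravel(tau))),
                a[:, None] * np.ravel(tau),
            )
        decay_part = per.sum(axis=0).reshape(tau.shape)
        return self.c0 * (rise_part + decay_part)


@dataclass(frozen=True)
class TracerSimConfig:
    """Timing and noise configuration for the tracer simulators.

    The ¹³NN bolus arrives ``bolus_arrival_s`` after scan start, ramps up
    linearly for ``rise_s``, and the breath-hold ends (washout begins) at
    ``apnea_end_s`` (default 30 s, the upper end of the 20–30 s
    breath-hold, which with the 16-frame schedule leaves 3 min 10 s of
    washout imaging).
    """

    bolus_arrival_s: float = 5.0
    rise_s: float = 10.0
    apnea_end_s: float = 30.0
    washout_start_s: float | None = None  # defaults to apnea_end_s
    fdg_input: FdgInputParams = field(default_factory=FdgInputParams)
    noise: str = "none"  # none | gaussian | poisson
    noise_level: float = 2.0
    dense_plasma: bool = False
    activity_scale: float = 100.0  # plateau activity for Q_rel = 1

    def __post_init__(self) -> None:
        ws = self.apnea_end_s if self.washout_start_s is None else self.washout_start_s
        if not (self.bolus_arrival_s < self.apnea_end_s <= ws):
            raise ValueError("require bolus arrival < apnea end <= washout start")
        if self.noise not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise kind {self.noise!r}")
        if self.noise_level < 0:
            raise ValueError("noise magnitude must be >= 0")

    @property
    def washout_start(self) -> float:
        return self.apnea_end_s if self.washout_start_s is None else self.washout_start_s


@dataclass
class PhantomSpec:
    """Geometry, physiology and effect sizes of the digital lung phantom."""

    dims: tuple[int, int, int] = (32, 32, 24)
    spacing: tuple[float, float, float] = (5.3456, 5.3456, 2.025)
    gravity_axis: int = 1  # anterior-posterior, in-plane
    dependent_positive: bool = True  # dorsal (dependent) end at high index
    lung_margin: int = 2  # air voxels around the lung box
    fgas_base: float = 0.75
    q_base: float = 1.0
    sv_base_per_min: float = 0.7
    ki_base_per_min: float = 0.003
    fgas_slope_per_mm: float = 0.0008  # Fgas increase per mm of height
    q_slope_per_mm: float = -0.004  # relative Q change per mm of height
    allergen_q_multiplier: float = 0.6
    allergen_sv_multiplier: float = 0.65
    k1_per_min: float = 0.1
    k2_per_min: float = 0.7
    vb: float = 0.15
    hu_noise_sd: float = 0.0
    lobe_overrides: dict = field(default_factory=dict)  # lobe -> {field: value}

    def __post_init__(self) -> None:
        for m in (self.allergen_q_multiplier, self.allergen_sv_multiplier):
            if not (0 < m <= 1):
                raise ValueError("allergen multipliers must lie in (0, 1]")
        if not (0 <= self.fgas_base <= 1):
            raise ValueError("fgas_base must lie in [0, 1]")
        if self.sv_base_per_min < 0 or self.ki_base_per_min < 0:
            raise ValueError("sv and Ki must be >= 0")
        if not (0 <= self.ki_base_per_min < self.k1_per_min):
            raise ValueError("ki_base must be in [0, K1) for an irreversible 2TC parameterization")

    def grid(self) -> VolumeGrid:
        return VolumeGrid(self.dims, self.spacing, self.gravity_axis, self.dependent_positive)


@dataclass
class PhantomTruth:
    """Voxelwise ground truth used by the simulators and recovery tests."""

    grid: VolumeGrid
    lung_mask: np.ndarray
    q_rel: np.ndarray  # unnormalized relative perfusion
    sv_per_min: np.ndarray
    fgas: np.ndarray
    ki_per_min: np.ndarray
    k1: np.ndarray
    k2: np.ndarray
    k3: np.ndarray
    vb: np.ndarray
    fdg_input: FdgInputParams = field(default_factory=FdgInputParams)
    partition_coefficient: float = NN13_PARTITION_COEFFICIENT

    def __post_init__(self) -> None:
        macro = np.zeros_like(self.k1)
        denom = self.k2 + self.k3
        np.divide(self.k1 * self.k3, denom, out=macro, where=denom > 0)
        if not np.allclose(macro, self.ki_per_min, atol=1e-12):
            raise ValueError("Ki must equal K1*k3/(k2+k3) wherever kinetics are set")

    def q_rel_normalized(self) -> np.ndarray:
        """True Q_rel mean-normalized over the lung (the analysis target)."""
        out = np.zeros_like(self.q_rel)
        out[self.lung_mask] = self.q_rel[self.lung_mask] / self.q_rel[self.lung_mask].mean()
        return out

    def sv_normalized(self) -> np.ndarray:
        out = np.zeros_like(self.sv_per_min)
        out[self.lung_mask] = (
            self.sv_per_min[self.lung_mask] / self.sv_per_min[self.lung_mask].mean()
        )
        return out


def _lobe_labels(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.dims
    m = spec.lung_margin
    if nx - 2 * m < 2 or ny - 2 * m < 2 or nz - 2 * m < 3:
        raise ValueError(f"grid {spec.dims} too small for a {m}-voxel margin and 5 lobes")
    labels = np.zeros(spec.dims, dtype=np.int32)
    x0, x1 = m, nx - m
    y0, y1 = m, ny - m
    z0, z1 = m, nz - m
    xmid = (x0 + x1) // 2
    zmid_l = (z0 + z1) // 2
    z_r1 = z0 + (z1 - z0) // 3
    z_r2 = z0 + 2 * (z1 - z0) // 3
    # left lung: LUL cranial, LLL caudal (cranio-caudal along z, cranial = high z)
    labels[x0:xmid, y0:y1, zmid_l:z1] = LOBE_LABELS["LUL"]
    labels[x0:xmid, y0:y1, z0:zmid_l] = LOBE_LABELS["LLL"]
    # right lung: RUL cranial, RML middle, RLL caudal
    labels[xmid:x1, y0:y1, z_r2:z1] = LOBE_LABELS["RUL"]
    labels[xmid:x1, y0:y1, z_r1:z_r2] = LOBE_LABELS["RML"]
    labels[xmid:x1, y0:y1, z0:z_r1] = LOBE_LABELS["RLL"]
    for name, lab in LOBE_LABELS.items():
        if not (labels == lab).any():
            raise ValueError(f"lobe {name} is empty on grid {spec.dims}")
    return labels


def generate_phantom(
    spec: PhantomSpec, seed: int | None = None
) -> tuple[ScalarVolume, LobeMaskVolume, PhantomTruth]:
    """Build the HU volume, lobe mask and ground truth for one subject.

    HU is derived from the true Fgas field by inverting the gas-fraction
    formula (HU = 65 − Fgas·1065 with the default density constants), so
    CT analysis of the phantom recovers the constructed aeration exactly.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    grid = spec.grid()
    labels = _lobe_labels(spec)
    lung = labels > 0
    height = grid.height_coordinate()
    h = height - height[lung].min()
    h_centered = h - h[lung].mean()

    fgas = np.zeros(spec.dims)
    q = np.zeros(spec.dims)
    sv = np.zeros(spec.dims)
    ki = np.zeros(spec.dims)
    per_lobe = {
        name: {
            "fgas": spec.fgas_base,
            "q": spec.q_base,
            "sv": spec.sv_base_per_min,
            "ki": spec.ki_base_per_min,
            **spec.lobe_overrides.get(name, {}),
        }
        for name in LOBE_LABELS
    }
    for name, lab in LOBE_LABELS.items():
        m = labels == lab
        p = per_lobe[name]
        fgas[m] = np.clip(p["fgas"] + spec.fgas_slope_per_mm * h_centered[m], 0.02, 0.98)
        q[m] = np.clip(p["q"] * (1.0 + spec.q_slope_per_mm * h_centered[m]), 0.05, None)
        sv[m] = p["sv"]
        ki[m] = p["ki"]
    allergen = labels == ROLE_LABELS["allergen"]
    q[allergen] *= spec.allergen_q_multiplier
    sv[allergen] *= spec.allergen_sv_multiplier

    k1 = np.where(lung, spec.k1_per_min, 0.0)
    k2 = np.where(lung, spec.k2_per_min, 0.0)
    k3 = np.zeros(spec.dims)
    np.divide(k2 * ki, k1 - ki, out=k3, where=lung)
    vb = np.where(lung, spec.vb, 0.0)

    fgas_vol = ScalarVolume(grid, fgas, "fgas")
    hu = fgas_to_hu(fgas_vol, AerationConstants())
    if spec.hu_noise_sd > 0:
        hu = hu.with_values(hu.values + rng.normal(0, spec.hu_noise_sd, spec.dims))
    mask = LobeMaskVolume(grid, labels, dict(ROLE_LABELS), {v: k for k, v in LOBE_LABELS.items()})
    truth = PhantomTruth(
        grid=grid,
        lung_mask=lung,
        q_rel=q,
        sv_per_min=sv,
        fgas=fgas,
        ki_per_min=ki,
        k1=k1,
        k2=k2,
        k3=k3,
        vb=vb,
    )
    return hu, mask, truth


# ---------------------------------------------------------------------------
# 13NN-saline simulation


def _nn13_frame_means(
    schedule: FrameSchedule,
    plateau: np.ndarray,
    k_per_s: np.ndarray,
    t_arrival: float,
    t_rise: float,
    t_washout: float,
) -> np.ndarray:
    """Exact frame means of the ramp–plateau–exponential voxel model.

    A(t) = 0 (t < t_a); A_p·(t−t_a)/t_r (ramp); A_p (plateau);
    A_p·exp(−k·(t−t_w)) (washout). Each frame value is the time average of
    A over the frame, integrated in closed form piecewise.
    """
    plateau = np.ravel(plateau)
    k = np.ravel(k_per_s)
    starts, ends = schedule.starts, schedule.ends
    nf, nv = len(starts), plateau.size
    out = np.zeros((nf, nv))
    t_pl = t_arrival + t_rise
    for i, (a, b) in enumerate(zip(starts, ends)):
        integral = np.zeros(nv)
        # ramp segment [t_a, t_a + t_r]
        lo, hi = max(a, t_arrival), min(b, t_pl)
        if hi > lo and t_rise > 0:
            integral += ((hi - t_arrival) ** 2 - (lo - t_arrival) ** 2) / (2 * t_rise) * plateau
        # plateau segment [t_a + t_r, t_w]
        lo, hi = max(a, t_pl), min(b, t_washout)
        if hi > lo:
            integral += (hi - lo) * plateau
        # washout segment [t_w, inf)
        lo, hi = max(a, t_washout), b
        if hi > lo:
            with np.errstate(divide="ignore", invalid="ignore"):
                decayed = np.where(
                    k > 0,
                    (np.exp(-k * (lo - t_washout)) - np.exp(-k * (hi - t_washout)))
                    / np.where(k > 0, k, 1.0),
                    hi - lo,
                )
            integral += plateau * decayed
        out[i] = integral / (b - a)
    return out


def _apply_noise(
    frames: np.ndarray, durations: np.ndarray, config: TracerSimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Frame noise after integration: Gaussian with sd ∝ sqrt(signal/duration)
    (a desk-scale proxy for count statistics), or Poisson on scaled counts."""
    if config.noise == "none" or config.noise_level == 0:
        return frames
    d = durations.reshape((-1,) + (1,) * (frames.ndim - 1))
    if config.noise == "gaussian":
        sd = config.noise_level * np.sqrt(np.clip(frames, 0, None) / d)
        return frames + rng.normal(0.0, 1.0, frames.shape) * sd
    counts = rng.poisson(np.clip(frames, 0, None) * d * config.noise_level)
    return counts / (d * config.noise_level)


def simulate_nn13(
    truth: PhantomTruth,
    config: TracerSimConfig | None = None,
    schedule: FrameSchedule | None = None,
    seed: int | None = None,
) -> DynamicScan:
    """Simulate the dynamic ¹³NN-saline scan from ground truth.

    During the breath-hold the tracer accumulates to a plateau
    proportional to true relative perfusion; once breathing resumes each
    voxel washes out as exp(−sV·t). Frames are exact time averages of that
    model; noise (if configured) is applied per frame per voxel after
    integration.
    """
    from .core import nn13_default_schedule

    config = config or TracerSimConfig()
    schedule = schedule or nn13_default_schedule()
    if schedule.total_duration <= config.apnea_end_s:
        raise ValueError(
            f"schedule ({schedule.total_duration} s) does not extend past the "
            f"apnea ({config.apnea_end_s} s)"
        )
    rng = np.random.default_rng(seed)
    plateau = config.activity_scale * truth.q_rel
    k_per_s = truth.sv_per_min / 60.0
    frames = _nn13_frame_means(
        schedule,
        plateau,
        k_per_s,
        config.bolus_arrival_s,
        config.rise_s,
        config.washout_start,
    ).reshape((len(schedule),) + truth.grid.dims)
    frames = _apply_noise(frames, schedule.durations, config, rng)
    return DynamicScan(truth.grid, schedule, frames)


# ---------------------------------------------------------------------------
# FDG simulation


def _fdg_tissue_curves(
    params: FdgInputParams,
    k1: np.ndarray,
    k2: np.ndarray,
    k3: np.ndarray,
    vb: np.ndarray,
    schedule: FrameSchedule,
    dt_s: float = 0.5,
) -> np.ndarray:
    """Frame-averaged irreversible two-tissue curves for parameter vectors.

    C_t(t) = Ki·∫₀ᵗCp + [K1·k2/(k2+k3)]·(e^{−(k2+k3)t} ⊛ Cp)(t) + vb·Cp(t)
    with Ki = K1·k3/(k2+k3). The convolution uses an exact exponential-step
    recursion on a fine grid whose step divides every frame boundary; the
    ∫Cp term is closed-form.
    """
    if np.any(k1 < 0) or np.any(k2 < 0) or np.any(k3 < 0) or np.any(vb < 0):
        raise ValueError("kinetic constants must be >= 0")
    n_steps = int(round(schedule.total_duration / dt_s))
    if not np.allclose(n_steps * dt_s, schedule.total_duration):
        raise ValueError("dt must divide the total scan duration")
    t_s = np.arange(n_steps + 1) * dt_s
    t_min = t_s / 60.0
    cp = params.cp(t_min)
    icp = params.cp_integral(t_min)

    params_arr = np.stack([np.ravel(k1), np.ravel(k2), np.ravel(k3), np.ravel(vb)], axis=1)
    uniq, inverse = np.unique(params_arr, axis=0, return_inverse=True)
    dt_min = dt_s / 60.0
    curves = np.zeros((len(uniq), len(t_s)))
    for j, (K1, K2, K3, VB) in enumerate(uniq):
        beta = K2 + K3
        ki = K1 * K3 / beta if beta > 0 else 0.0
        amp = K1 * K2 / beta if beta > 0 else K1  # k2+k3=0: pure integrator handled via ki=0
        conv = np.zeros_like(cp)
        if amp != 0.0 or (beta == 0 and K1 > 0):
            decay = np.exp(-beta * dt_min)
            for i in range(1, len(t_s)):
                conv[i] = conv[i - 1] * decay + dt_min * 0.5 * (cp[i] + cp[i - 1] * decay)
        if beta == 0 and K1 > 0:
            # degenerate: no efflux, tracer integrates K1*Cp
            curves[j] = K1 * icp + VB * cp
        else:
            curves[j] = ki * icp + amp * conv + VB * cp

    # frame averages by trapezoid within each frame
    starts_idx = np.rint(schedule.starts / dt_s).astype(int)
    ends_idx = np.rint(schedule.ends / dt_s).astype(int)
    frame_means = np.zeros((len(schedule), len(uniq)))
    for i, (i0, i1) in enumerate(zip(starts_idx, ends_idx)):
        seg = curves[:, i0 : i1 + 1]
        frame_means[i] = np.trapezoid(seg, dx=dt_s, axis=1) / (schedule.ends[i] - schedule.starts[i])
    return frame_means[:, inverse]


def simulate_fdg(
    truth: PhantomTruth,
    config: TracerSimConfig | None = None,
    schedule: FrameSchedule | None = None,
    seed: int | None = None,
) -> tuple[DynamicScan, PlasmaCurve]:
    """Simulate the dynamic FDG scan and its venous plasma samples.

    Returns the frame-integrated scan and the plasma curve sampled at the
    five venous draw times (5 min 30 s, 9 min 30 s, 25 min, 37 min,
    42 min 30 s), or a dense curve when ``config.dense_plasma`` is set.
    """
    from .core import fdg_default_schedule

    config = config or TracerSimConfig()
    schedule = schedule or fdg_default_schedule()
    rng = np.random.default_rng(seed)
    frames = _fdg_tissue_curves(
        config.fdg_input, truth.k1, truth.k2, truth.k3, truth.vb, schedule
    ).reshape((len(schedule),) + truth.grid.dims)
    frames = _apply_noise(frames, schedule.durations, config, rng)
    scan = DynamicScan(truth.grid, schedule, frames)
    if config.dense_plasma:
        plasma = dense_plasma_curve(config.fdg_input, schedule.total_duration / 60.0)
    else:
        times = np.array(FDG_PLASMA_SAMPLE_TIMES_MIN)
        plasma = PlasmaCurve(times, config.fdg_input.cp(times), dense=False)
    return scan, plasma


def dense_plasma_curve(
    params: FdgInputParams, t_max_min: float, dt_min: float = 0.25
) -> PlasmaCurve:
    """Finely sampled simulator input function (for oracle-grade analyses)."""
    times = np.arange(dt_min, t_max_min + dt_min / 2, dt_min)
    return PlasmaCurve(times, params.cp(times), dense=True)


# ---------------------------------------------------------------------------
# Printed subject table (worked examples for the statistics module)

_SUBJECTS = [
    # subject, gender, age, height_cm, bmi, fev1_l, fev1_pct, fvc_l, fvc_pct,
    # fev1_fvc, pc20_mg_ml, allergen, dose
    (1, "F", 20, 160.0, 22.1, 4.03, 126, 4.37, 123, 0.92, "19.96", "DP", 370),
    (2, "M", 28, 185.4, 25.1, 4.76, 98, 5.76, 99, 0.83, "20.64", "DP", 1111),
    (3, "F", 33, 165.1, 28.5, 3.64, 120, 4.51, 126, 0.81, ">25", "DP", 41),
    (4, "M", 49, 180.3, 34.7, 3.42, 85, 4.31, 87, 0.79, ">25", "DP", 370),
    (5, "F", 24, 177.8, 21.5, 3.65, 101, 4.49, 104, 0.81, ">25", "Cat", 370),
    (6, "F", 31, 162.6, 24.3, 3.85, 128, 5.10, 145, 0.75, ">25", "DP", 123),
]


def subject_table_fixture() -> pd.DataFrame:
    """The six study subjects' demographics, lung function and allergen dose.

    Used as worked-example input for the summary-statistics conventions
    (median [IQR] reporting).
    """
    return pd.DataFrame(
        _SUBJECTS,
        columns=[
            "subject",
            "gender",
            "age_yr",
            "height_cm",
            "bmi_kg_m2",
            "fev1_l",
            "fev1_pct_pred",
            "fvc_l",
            "fvc_pct_pred",
            "fev1_fvc",
            "pc20_mg_ml",
            "allergen",
            "dose",
        ],
    )
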