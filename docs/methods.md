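# Methods

This note records the models implemented by `pulmopet`, the conventions
and defaults that matter, what the synthetic phantom does and does not
emulate, and the numerical choices made where the design was open.

## ¹³NN-saline perfusion and specific ventilation

The tracer model rests on the near-insolubility of nitrogen in tissue
(water/air partition coefficient 0.0015 at 37 °C): an intravenous
¹³NN-saline bolus delivered at the start of a breath-hold leaves the
blood essentially completely on first pass through the pulmonary
capillaries. Recirculation is therefore neglected entirely. Per voxel the
continuous model is

    A(t) = 0                          t < t_arrival
           A_p (t − t_arrival)/t_rise ramp during bolus arrival
           A_p                        plateau until washout starts
           A_p exp(−sV (t − t_w))     washout after breathing resumes

with A_p proportional to regional perfusion. The default timing (bolus
arrival 5 s, rise 10 s, apnea end / washout start 30 s) places the end of
the breath-hold at the upper end of the scanned 20–30 s range, leaving
3 min 10 s of washout imaging on the 16-frame schedule (8×5 s, 3×10 s,
5×30 s; 220 s total).

**Estimation.** The perfusion proxy is the mean activity over the final
half of the apnea frames — the plateau — rather than the whole apnea, to
exclude the arrival ramp (`plateau_fraction` configurable). Specific
ventilation is fitted per voxel as a weighted least-squares line through
ln A at the washout frame mid-times, weights = frame duration × activity;
this is exact on the model class, convex and fast, and down-weights the
long low-count tail frames. sV is reported in min⁻¹ and clamped at zero.
Voxels with fewer than three positive washout frames or plateau below 5%
of the lung-median plateau are flagged low-signal, carry no sV estimate,
and are excluded from lobe means (flag counts are reported).

Because frames are time-integrals, evaluating them at frame mid-times
incurs a second-order bias of relative size ≈ (sV·Δ/2)²/6 per frame; with
the mixed 5/10/30 s durations of the printed schedule this leaves a
voxelwise error below 1% for physiologic sV (≈0.3% at 0.7 min⁻¹),
verified by recovery tests. A nonlinear fit of the exact frame-integral
model is not implemented; the log-linear fit is the estimator the package
commits to.

**Smoothing and normalization.** A 3-D moving-average (box) filter with
per-axis odd kernel sizes chosen to best approximate a target effective
resolution (default 10.125 mm: 1×1×5 voxels at the scanner's
5.3456×5.3456×2.025 mm grid) can be applied to every frame, with kernel
weights renormalized inside the lung mask. Both Q̂ and sV maps are
mean-normalized over the imaged lung (lung mean = 1). Note that smoothing
mixes voxels across lobe boundaries: on the phantom it visibly dilutes
the allergen lobe's deficit toward its neighbours (the analogous boundary
blur exists in the real data). Parameter-recovery tests therefore run the
unsmoothed estimator; the pipeline default mirrors the acquisition
(10.125 mm).

## CT gas fraction

F_gas = (ρ_blood − HU)/(ρ_blood − ρ_air) with ρ_blood = 65 HU and
ρ_air = −1000 HU — affine, 0 at blood, 1 at air. Values outside [0, 1]
(bone, calibration outliers) are clamped and counted rather than
rejected. Lobe aeration is reported relative to the mean F_gas of the
whole lung, where "whole lung" includes every labelled lung voxel, not
only the three study lobes. Lobe means are computed on the native CT
grid.

## FDG kinetics and Patlak analysis

The simulator solves the irreversible two-tissue model

    C_t(t) = Ki ∫₀ᵗ Cp dτ + [K₁k₂/(k₂+k₃)] (e^{−(k₂+k₃)t} ⊛ Cp)(t) + v_b Cp(t),
    Ki = K₁k₃/(k₂+k₃)

with ∫Cp in closed form and the convolution by an exact exponential-step
recursion on a 0.5 s grid; frame values are within-frame trapezoid means.
The synthetic plasma input is a linear rise over 1 min followed by three
decaying exponentials with default amplitudes (0.75, 0.15, 0.10) and
rates (4.0, 1.0, 0.01) min⁻¹ — fast distribution (half-life ≈ 10 s),
intermediate exchange (≈ 42 s), slow clearance (≈ 69 min). These rates
were chosen, once, so that the synthetic data reproduce the empirical
property of real lung FDG studies that the Patlak plot linearizes by
about 8–10 min: all plasma components except the slow tail, and the
tissue equilibration transient e^{−(k₂+k₃)t}, must be over by t*. The
phantom's lung kinetics default to K₁ = 0.1, k₂ = 0.7 min⁻¹,
v_b = 0.15, with k₃ set per lobe from the target Ki (default
0.003 min⁻¹, a normal-lung magnitude).

**Input function from venous samples.** Five venous draws (5 min 30 s,
9 min 30 s, 25 min, 37 min, 42 min 30 s) are interpolated
piecewise-linearly (monotone, no overshoot, exact integral); before the
first sample the curve rises linearly from zero at injection, and beyond
the last sample it decays mono-exponentially at the rate fitted to the
final two samples. The onset model necessarily misses the first-pass
peak, so ∫Cp is underestimated by a constant that maps into the Patlak
intercept and, through the residual 1/Cp variation, tilts the slope by
up to ~10% on the default simulation. This is an inherent limitation of
sparse late venous sampling, and the interpolation error over the fit
window is measured in the tests. Recovery benchmarks therefore evaluate
the Patlak machinery against the simulator's dense plasma curve (the
`dense_plasma` flag), while the end-to-end pipeline uses the five-sample
route exactly as a real study would — its small common-mode Ki bias is
identical across lobes and cancels from the between-lobe comparison.

**Fitting.** Patlak coordinates are x = ∫₀ᵗCp/Cp(t), y = C_t/Cp(t) at
frame mid-times; ordinary least squares over frames with mid-time ≥ t*
(default 10 min, the conservative end of the 8–10 min linearization
window; ≥3 points required) gives Ki (slope), the distribution volume
(intercept) and R². The default lobe estimator fits the lobe-mean
time-activity curve rather than averaging voxelwise slopes — far better
conditioned under sparse venous sampling; a voxelwise map is available
separately. Venous samples are used at face value with no
venous-to-arterial correction.

## Regional summaries and statistics

**Gravity profiles.** Height is measured along the declared gravity axis
(supine subject; dependent = dorsal, stated in metadata, never inferred
from image content) from the most dependent voxel of the whole lung.
Each lobe's voxels are sorted by height and split into 8 contiguous
equal-count bins (equal count = equal volume on a uniform grid); a
remainder of r voxels is absorbed one-per-bin by the r most dependent
bins. Per bin, the mean height and mean normalized perfusion are
reported.

**Median [IQR].** Quantiles use linear interpolation at position
1 + (n−1)p computed in IEEE double precision; the even-n median is the
exact decimal midpoint of the two central values. Rounding is half-up on
the full-precision value. This combination was selected because it
reproduces the published subject-table summary row cell-for-cell at the
printed precision (several cells sit exactly on decimal rounding ties,
where the double-precision representation of the interpolated quantile
determines the printed digit); the worked-example tests pin every cell.

**Three-condition comparison.** Kruskal–Wallis H with tie correction,
H = [12/(N(N+1)) Σ nᵢR̄ᵢ² − 3(N+1)] / (1 − Σ(t³−t)/(N³−N)), p from the
χ² approximation with k−1 df; all-tied data returns H = 0, p = 1. The
pairwise follow-up for the three condition pairs is a Tukey-type
studentized-range test on pooled mean ranks,
q = |R̄ᵢ−R̄ⱼ| / sqrt(V(1/nᵢ+1/nⱼ)/2) with V the tie-corrected rank
variance N(N+1)/12, referred to the studentized-range distribution with
infinite error df — the convention of rank-based post-hoc testing in the
common commercial statistics packages. An exact two-group permutation
test on the mean-rank difference is available as an alternative
(`method="permutation"`); with n = 6 per group it is noticeably more
powerful than the studentized-range test under complete separation,
because it conditions on the pair rather than the pooled three-group
ranking. No multiplicity correction is applied beyond the procedure
itself. At α = 0.05, the null pair necessarily fires in about 5% of
replicates; no test configuration can make the full
"two pairs significant and the third not" pattern hold more often than
~95% × the detection power.

**BAL.** Cell concentrations are counts divided by the returned lavage
volume; differential counts are validated against the total.

## The phantom: what it emulates, what it does not

The phantom provides a five-lobe lung (baseline LUL, diluent RUL,
allergen RML, plus two "other" lobes) as axis-aligned blocks inside a
box, on a 32×32×24 grid at the scanner voxel size by default, gravity
along an in-plane axis (~170 mm of lung height). It carries gravitational
gradients — F_gas increasing away from the dependent lung
(+0.0008 mm⁻¹), perfusion decreasing (−0.004 mm⁻¹ relative) — and an
allergen lobe with perfusion and ventilation multiplied by 0.6 and 0.65,
sized to produce the ~0.9 vs ~0.6 mean-normalized contrast between
control and allergen lobes. HU is derived by inverting the gas-fraction
formula, so CT analysis recovers the constructed aeration exactly.
Aeration and FDG uptake are, by default, not differentiated in the
allergen lobe (both are configurable via `lobe_overrides`). The pipeline
simulates a six-subject cohort with mild inter-subject jitter of the sV
baseline (10%) and of the allergen multipliers (±0.05).

Noise is zero-mean Gaussian per frame per voxel with
sd = level·sqrt(signal/duration) (default level 2.0, ≈9% at the apnea
plateau) — a desk-scale proxy for count statistics; a Poisson-count mode
exists. The phantom does **not** emulate sinogram physics (scatter,
attenuation, reconstruction correlations), respiratory or cardiac
motion, airway trees, anatomical lobe shapes, CT-PET misregistration, or
edge artifacts. Passing recovery tests therefore demonstrates the
correctness of the estimators on the stated forward models, not
robustness to those real-data effects.

## Numerical conventions

- Voxel indices 0-based; physical coordinates are voxel centres in mm.
- Frame times are float seconds; minutes appear only at the Patlak API.
- Activity units are arbitrary-but-consistent; every reported quantity is
  a ratio or a per-minute rate, so calibration cancels.
- Frame values are time-averages of the continuous model over the frame
  (PET frames integrate counts), making the frame-mean oracles exact.
- Fixed seeds make phantom generation and both simulators
  bit-reproducible; different seeds change only the noise realization.
- Degenerate inputs fail loudly: empty lobes, all-flagged lobes,
  non-contiguous schedules, frame-count mismatches, zero plasma at a fit
  time, fewer than three fit points.

## Problem sizes

Tests and the acceptance script run on the default 32×32×24 phantom
(≈16k lung voxels), 16-frame ¹³NN and 36-frame FDG schedules, six
simulated subjects, and 200-replicate statistical simulations; the whole
suite completes in well under a minute.
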