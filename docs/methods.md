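# Methods

## Scope and data model

The package analyses a simultaneous two-arm GFR measurement in small
animals: a dynamic contrast-enhanced MRI renography series (4D NIfTI,
nominally 0.9 s per volume for ~7 minutes, bolus administered after 15
pre-contrast volumes) with hand-drawn label masks on the same grid, and a
transcutaneous FITC-sinistrin fluorescence recording (CSV, 1 Hz, 90
minutes, first minute pre-injection). Masks are taken as given on the
dynamic grid — no registration, resampling or segmentation is performed,
and no motion correction is applied. Time is carried in seconds
internally; flows are stored in the renal reporting unit ml/100 ml/min and
converted to fractional per-second rates only where the differential
equations are evaluated.

## Two-compartment filtration model

Each tissue voxel follows the serial plasma → tubular system

    dC_P/dt = f_p c_a(t − δ) − C_P/T_P,   T_P = v_p/(f_p + f_t)
    dC_T/dt = (f_t/v_p) C_P − C_T/T_T,    C = C_P + C_T

with f_p, f_t the fractional plasma and tubular flows, v_p the fractional
plasma volume, δ a bolus-arrival delay and T_T the tubular mean transit
time. Because the system is linear and time-invariant, C is a sum of
convolutions of the AIF with one- and two-exponential kernels. The AIF is
only known at the frame times, so the model's input convention is fixed as
*the piecewise-linear interpolant of the sampled, delay-shifted AIF on the
evaluation grid*. Under that convention the convolutions are evaluated
**exactly** by a per-interval recursion (run as an IIR filter): at the
coarse 0.9 s frame spacing, rectangle- or FFT-based quadrature introduces
bias comparable to plausible plasma transit times (a few seconds), which
the exact recursion avoids. Numerical safeguards:

* `expm1` is used for `1 − exp(−dt/T)` and a series expansion for
  `dt − T(1 − exp(−dt/T))` when `dt/T < 1e-4`, so very long time constants
  do not lose precision to cancellation;
* when T_P and T_T coincide within 1e-9 relative, the two-exponential
  difference kernel degenerates to `t·exp(−t/T)`, which has its own exact
  recursion (no division by a vanishing rate difference);
* `T_T = inf` (the no-outflow variant) uses the exact closed form
  `∫C_P = f_p T_P (∫c_a − c_a ⊛ e^{−t/T_P})`, with the running integral of
  the piecewise-linear AIF computed as the exact trapezoid sum;
* `F_P = 0` short-circuits to the zero curve (no tracer enters).

A reference implementation integrating the same ODEs with `solve_ivp`
(RK45, rtol 1e-9, step bounded by the frame interval) under the identical
input convention provides the independent cross-check; the closed form
agrees with it to better than 1e-6 of the curve maximum across random
parameter sweeps, while being orders of magnitude faster.

## Voxel-wise fitting

The inverse problem is bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) over
(F_P, V_P, F_T, T_T) with default physiologic envelopes
F_P ∈ [0, 500], F_T ∈ [0, 300] ml/100 ml/min, V_P ∈ [0.1, 100] ml/100 ml,
T_T ∈ [1, 600] s — all configurable. Voxel curves are noisy and the cost
surface has local minima in T_T, so each fit is restarted from three
deterministic initial points spanning low/medium/high flow. The
bolus-arrival delay is selected by grid search over a configurable set of
candidates (default 0–10 s in 2.5 s steps, consistent with an arterial ROI
placed close to the kidneys); continuous optimisation of δ is deliberately
avoided because the residual is nearly flat in δ between frames. An
early-stopping shortcut skips remaining starts once a fit reaches the
exact-interpolation floor (RSS < 1e-12·‖curve‖²), which makes noise-free
phantom fits cheap. The goodness-of-fit map χ² is the plain residual sum
of squares in signal units (RSS/d.o.f. is available by division; the RSS
convention is the package's documented choice since common usage varies).
Voxels where the optimiser fails are excluded from the fitted mask and
carry NaN — a sentinel deliberately distinct from 0, which is a legitimate
flow value. A flat (all-zero) curve drives F_P to its lower bound with
χ² ≈ 0; F_T is then unidentifiable (no tracer enters the voxel), so only
F_P and the model curve, not F_T, are meaningful in that degenerate case.

The two estimators follow scikit-learn conventions: construction stores
hyper-parameters only, `fit` consumes a curve matrix (n_curves × n_times)
or a time/signal pair, fitted quantities appear as trailing-underscore
attributes, and `get_params`/`set_params`/`clone` work for composition with
sklearn model selection.

## Clearance fitting

Skin background is the mean signal over the pre-injection window (default:
first 60 s). The elimination phase is fitted as A·2^(−t/(60·t½)) to the
background-subtracted signal from (smoothed) peak + lag to the end of the
trace; the default lag of 5 minutes excludes the distribution phase, whose
kinetics the one-compartment model does not describe. The fit is
log-linear initialised and refined by bounded least squares in (A, λ).
Degenerate inputs — a tail that is not positive or does not decay (e.g. a
constant trace) — raise a dedicated error rather than returning a
meaningless half-life. With a realistic ~3-minute distribution phase the
single-exponential tail fit carries a model-misfit bias of a few tenths of
a percent in t½; it vanishes when the trace satisfies the one-compartment
model exactly.

## Absolute GFR

MRI: GFR per kidney = mean F_T over that kidney's fitted cortex voxels ×
cortex volume / 100, summed over kidneys. The /100 is stated explicitly:
"flow × volume" is only dimensionally consistent when the flow is per
100 ml of tissue. Cortex volume is voxel count × voxel volume from the
mask. Optical: GFR = (factor / t½) × BW/100. The conversion factor
(ml/100 g b.w.) is a mandatory configuration value — the default 31.26 is
the published rat calibration constant, and it is recorded in the result
provenance on every run, never hard-coded into outputs.

## Comparison statistics

Group summaries use the arithmetic mean and sample (n−1) SD. The
percentage reduction between groups is 100·(1 − mean_test/mean_ref).
Between-method agreement uses Bland-Altman differences (optical − MRI)
with limits of agreement bias ± 2·SD — the ±2 convention, not 1.96 — and
the sample-SD convention; on the bundled 12-rat table these choices
reproduce the published bias and SD at 1 d.p. (the n-denominator SD would
not). The paired t-test is two-sided with df = n−1; zero-variance
differences are flagged degenerate instead of raising. A note on the
bundled table: the healthy group's published mean (4.34 ml/min) is not the
mean of its rounded per-animal entries (4.15), presumably because the
original summary used unrounded raw values; both per-animal values and
published group means are therefore shipped, and percentage reductions are
computed from the published means, which is how the published reduction
figures arise. The published p-values are consistent with within-group
between-method paired tests, which is what the package computes; the
between-group reading of the same sentence is not supported by the printed
numbers.

## Synthetic data

The phantom emulates the acquisition's statistical structure, not anatomy:
an aorta cylinder plus two kidney boxes (cortex shell around a medulla
core) on a configurable grid (default 48×32×12 voxels at 0.6×0.6×1.2 mm,
470 frames at 0.9 s; smallest supported grid 16×12×6). The AIF is a
gamma-variate bolus (peak 60 a.u. at ~18 s) with an exponential
recirculation tail; its time integral has a closed form used as a
quadrature oracle. Tissue voxels carry exact 2CFM forward curves for
per-role truth parameters (cortex F_T 61/68, medulla 25 ml/100 ml/min —
magnitudes of healthy rat cortex); aorta voxels carry the AIF itself. The
signal response is linear by default; a saturating spoiled-gradient-echo
response (R1 linear in concentration, scale solved so the departure from
linearity is exactly 5% at the configured knee) reproduces the
low-dose-linear/high-dose-compressive behaviour seen in gadolinium phantom
measurements. Noise is additive Gaussian on the magnitude signal — in-vivo
SNR is not reported for this protocol, so the default levels are chosen
for test power, not realism. Fluorescence traces are background +
distribution-phase rise × monoexponential decay, 1 Hz for 90 minutes, with
seeded Gaussian noise; a warning is emitted when the duration covers fewer
than two elimination half-lives (the point at which the tail fit becomes
poorly conditioned — the 90-minute protocol itself covers only ~2–4
half-lives at rat-typical t½ of 25–50 min, so a stricter threshold would
flag every realistic trace). All generators are bit-reproducible under a
fixed integer seed.

What passing tests on these phantoms show: that the inverse machinery
recovers the generating model's parameters under the analysis assumptions
(linear signal response, no motion, mask-perfect ROIs, Gaussian noise).
What they do not show: robustness to breathing motion, partial-volume AIF
contamination, susceptibility or inflow artefacts, or signal
non-linearity — all present in vivo and all outside the generator.

## Virtual agreement experiment

Twelve virtual animals are simulated with per-animal flow scales
s ~ U(0.6, 1.4) applied to the phantom truth (coarse 2.5×2.5×5 mm voxels so
each cortex is ~1.4 ml and GFR lands at rat scale). The MRI arm fits the
phantom and converts to GFR; the optical arm simulates and refits a trace
whose half-life implies GFR = 2 × MRI truth + N(0, 0.15) ml/min. Because
the injected offset is known exactly, the recovered Bland-Altman bias can
be checked against it; it agrees within the cohort standard error, showing
the pipeline transports a factor-of-two inter-method offset through both
arms without distortion.

## Problem sizes and defaults

Test and acceptance runs use the small phantom (16×12×6, 200–300 frames),
200-curve noisy recovery sets, 200-point forward-model sweeps, 1000
clearance replicates and 12-animal cohorts — sizes at which every check
runs in seconds to a couple of minutes on one CPU while keeping Monte-Carlo
standard errors well below the tolerances being asserted. The full-size
default phantom (48×32×12 × 470) is intended for interactive use via
`renogfr simulate`.

## Known limitations

* The delay grid search quantises δ; sub-frame arrival differences fold
  into T_P.
* F_T and T_T become jointly weakly identifiable when the acquisition is
  short relative to T_T; bounds keep the fit proper but posterior-style
  uncertainty is not reported.
* χ² is unnormalised; comparing across acquisitions with different noise
  levels requires RSS/d.o.f. or an external noise estimate.
* The optical conversion factor is a literature constant; no per-animal
  calibration is attempted.
* The saturating signal model is a qualitative stand-in parameterised by
  its knee, not a scanner-calibrated signal equation.
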