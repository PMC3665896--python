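# Methods

This document records the quantitative model behind each module, the
default parameters and their rationale, what the synthetic generators do
and do not emulate, and the open design decisions.

## Data model and units

An assay is an `AnnotatedTrace`: a shared time axis (s), an oxygen
channel (nmol O₂ · mL⁻¹), optional fluorescence channels (`fluo_*`,
arbitrary units), a stream of titration event marks drawn from a fixed
vocabulary, and metadata (assay temperature °C, fibre wet mass mg,
chamber volume mL, subject, group). Traces and events are plain CSV;
metadata is a YAML sidecar. Validation reports machine-readable issue
codes (`LOW_OXYGEN`, `NON_MONOTONE_TIME`, …); only structural violations
(non-monotone time, events outside the record, missing oxygen values)
are fatal on read.

## Oxygen flux (`flux`)

Respiration is the negative derivative of chamber oxygen, scaled to a
mass-specific flux:

    J(t) = −dC/dt · V · 1000 / m    [pmol O₂ · s⁻¹ · mg⁻¹]

- The derivative is `np.gradient` on a moving-average-smoothed signal
  (window 10 s). Smoothing suppresses sensor noise at the cost of a
  ~window-wide taper at record edges and titration steps; both lie
  outside the plateau windows used downstream.
- One steady-state flux per titration interval: the **median** over the
  final 60 s of the interval (`plateau_s`) after discarding the first
  120 s (`settle_s`). With the generator's first-order mixing constant
  τ = 20 s, 120 s ≈ 6τ leaves a relative transient residual < 0.3%.
  Intervals too short for settle + plateau are skipped with a
  `SKIPPED_INTERVAL` issue rather than failing the assay.
- CCO flux is corrected by subtracting a per-temperature
  TMPD/ascorbate autoxidation background measured in blank chambers,
  floored at zero.

## SUIT states and ratios (`suit`)

The canonical titration order is Mal, Pyr (Leak-I) → ADP → Glu (OXP-I) →
Cyt c → Succ (OXP-I,II) → NADH → Atr (Leak-I,II) → FCCP × n (ETS = max
across uncoupler steps) → Rot, Malo, Ant → TMPD+Asc (CCO). Leak-I is the
interval opened by the later of malate/pyruvate; missing events produce
`MISSING_STATE:<name>` issues, out-of-order canonical events a
`PROTOCOL_ORDER` issue.

Ratios: RCR = OXP-I/Leak-I, UCR = ETS/OXP-I,II, RCR2 =
OXP-I,II/Leak-I,II, FCR = Leak-I,II/ETS, CCO/OXP-I,II, CCO/ETS, and the
integrity fractions Cyt c/OXP-I − 1 and NADH/OXP-I,II − 1. All ratios
are invariant to rescaling of the state table (mass or calibration
errors cancel). Thermal sensitivity of a single state is summarised by
the two-parameter exponential J = a·e^{bT}; a poor R² flags a plateau
or depression at the warm end.

**Open decision — FCR orientation.** The source conventions disagree on
whether FCR is Leak/ETS or ETS/Leak; this package uses
FCR = Leak-I,II/ETS (the flux-control-ratio convention, bounded by 1),
treating the opposite wording elsewhere as a typo. The reciprocal is
trivially available.

## Fluorometry (`fluoro`)

**ROS.** Resorufin fluorescence rises 1:1 with cumulative H₂O₂. A known
resorufin spike (400 pmol) calibrates sensitivity = step height /
amount, with the pre-spike drift slope subtracted from the step. Rates:
(dF/dt − blank slope) / sensitivity / mass, reported in
fmol H₂O₂ · (mg·s)⁻¹, floored at zero with a `NEGATIVE_RATE` flag.
Slopes are least-squares over the same settle/plateau windows as flux.

**ATP.** Magnesium Green quench: separate ADP and ATP titrations give
linear quench slopes (require R² ≥ 0.98); their ratio converts the ADP
calibration to an ATP scale per assay temperature. ATP rate =
|dF/dt| / (adp_slope · ratio) · V · 1000 / m, in pmol ATP · s⁻¹ · mg⁻¹.
Using quench *magnitudes* everywhere avoids sign ambiguity. A
calibration taken at a different temperature than the trace raises an
error. ATP/O is reported per mole O₂ (`per_o_atom=True` doubles it).

## Kinetics (`kinetics`)

v(c) = Vmax·c/(Km+c) by unweighted nonlinear least squares, initialised
by the Hanes–Woolf linearisation (c/v vs c), SEs from the fit
covariance. Efficiency = Vmax/Km. If the highest concentration is below
the fitted Km the fit is flagged `NON_SATURATED` (the 32.5 °C condition
needs a wider titration range — the generator presets encode that).

## Cardiac function (`cardiac`)

**Beat detection.** Sliding RMS envelope (50 ms window, reflect-padded
so a single edge sample cannot fabricate a beat), threshold at 50% of
the envelope maximum, contiguous supra-threshold regions closer than
100 ms merged (< 300 bpm implies ≥ 200 ms spacing), one beat per region
at its envelope peak. The threshold is relative, so detection is
amplitude-invariant. A 50 ms RMS window resolves the ~10 ms Doppler
bursts while averaging the 200 Hz carrier.

**ABT.** Per-fish continuous two-segment regression of rate on ramp
temperature (below); fish without a significant break are flagged and
excluded from the mean. The summary reports per-fish breakpoints, mean ±
SEM, pooled R².

**Haemoglobin saturation.** Per-group OLS of the 940:600 absorbance
ratio (controls on time, ramped fish on temperature) with pointwise 95%
bands and a band-overlap verdict on the shared abscissa.

## Breakpoint statistics (`stats`)

**Segmented regression.** y = a + b·x + d·(x−c)₊, continuous at c. The
breakpoint is found by an exhaustive SSE scan on a grid (default 0.1 in
x units; solved by vectorised 3×3 normal equations on centred data with
a tiny ridge) followed by bounded scalar refinement between the
neighbouring grid points. Existence of a break: F-test of the 2-extra-
parameter model against a single line at α = 0.05. Breakpoint SE: seeded
nonparametric pair-resampling bootstrap, B = 1000 (SE estimates
stabilise well below B = 1000 for these n; the cost is ~0.3 s per
8-fish data set).

**4PL dose-response.** y = bottom + (top−bottom)/(1 + 10^((c−x)·h)) with
assay temperature as the dose. `direction` constrains the hill sign
(inhibition h < 0, stimulation h > 0); initial values come from
per-dose means; SEs from the fit covariance. Flat responses return a
`DEGENERATE` fit instead of an arbitrary inflection.

**Open decision — dose axis.** Classical 4PL fits use log-dose; here the
dose is temperature in °C, which is already a narrow linear range, so
the default fits **untransformed** temperature. `log_dose=True` switches
to log₁₀ with a delta-method back-transform of the inflection SE for
genuine concentration axes.

Group statistics: one-sample t (with exact handling of zero-variance
inputs), one-way ANOVA + Tukey HSD with an insert-and-absorb compact
letter display, crossed two-factor ANOVA, and internal-standard-
normalised fold-change tables (Welch t).

## Synthetic generators (`synth`)

Every generator is a pure function of (parameters, seed) using
`numpy.random.default_rng`. The chamber model: after each titration the
true rate relaxes to the new interval level as a first-order exponential
(τ = 20 s); oxygen and fluorescence are trapezoidal integrals of those
rates. Noise enters at two levels: a multiplicative lognormal
per-interval factor (fish-to-fish and titration variability, default 4%)
and additive white noise on the flux or fluorescence samples. FCCP is
titrated in three steps reaching (0.85, 0.95, 1.0) of true ETS, so the
max-across-steps rule is actually exercised. Doppler audio is
Gaussian-windowed 200 Hz tone bursts at known beat times plus white
noise.

What is **not** emulated: oxygen back-diffusion and sensor drift,
instrument re-oxygenation events, temperature equilibration transients,
photobleaching, fibre-bundle heterogeneity within an assay, and beat-to-
beat heart-rate variability. Tolerances in the tests reflect the modeled
noise only.

The five presets (`fig3`, `exp2_suit`, `fig8_ros`, `fig9_kinetics`,
`fig10_atp`) are YAML fixtures whose *true* parameters encode the
headline statistics of the emulated study (mean ABT 27.81 °C; RCR/UCR
inflections 19.97/16.68 °C; Leak-I ROS inflection 29.96 °C; Leak-I +74%
at 25 °C; RCR2 declining from 2.22; Km 81 µM → 1.52 mM with ~19-fold
loss; ATP/O 1.8 falling 3.5-fold). They were fixed at design time from
those published numbers; noise levels were chosen a priori as realistic
for permeabilized-fibre assays. Each preset carries a `truth:` block so
round-trip tests compare against the generating values, not against
re-tuned targets.

## Numerical choices

- Plateau statistic is the median (robust to single-sample spikes); its
  dispersion is reported as the plateau SD.
- The segmented-fit scan centres x and y before solving the normal
  equations to avoid catastrophic cancellation in SSE at large offsets,
  and adds a 1e-12-scaled ridge so degenerate bootstrap resamples stay
  solvable.
- Seeds derived inside pipelines are drawn below 2³¹ so they remain
  valid C `int` seeds everywhere.
- CSV round trips use `%.12g`, lossless to ~1e-12 relative.

## Limitations

- The 4PL inflection SE is a local (covariance) estimate; with only 7
  dose levels it can be optimistic when the plateau ends are weakly
  identified (visible as the larger UCR uncertainty).
- `steady_state_flux` assumes monotone chamber depletion between
  events; re-oxygenation mid-assay would need interval splitting.
- The MgG model treats the quench as linear over the working range;
  strong Mg²⁺ depletion would bend it.
- `detect_beats` assumes a roughly stationary beat amplitude within a
  record; a slow 10× amplitude fade within one record would drop the
  quiet beats (per-bin analysis via `rate_per_bin` mitigates this).
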