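# Methods

## Scope and conventions

The package covers four connected pieces: (i) stirred-tank mixing and
oxygen-transfer characterisation, (ii) the chemostat rate/yield/carbon
calculus, (iii) steady-state group statistics, and (iv) a synthetic
three-phase cultivation that supplies ground truth for everything upstream.

Fixed unit conventions (no general unit algebra): time in hours, volume in
litres, gas flow in normalised L/h (molar volume 22.414 L/mol), masses in
grams, concentrations in g/L, power in W (displayed per volume as kW/m³,
numerically identical to W/L). All correlations are evaluated in SI and
converted only for display.

Sign conventions: substrate uptake is consumption-positive
(ΔS_reactor = S_prev − S_curr), product formation production-positive, OUR
is inlet-minus-outlet (positive for consumption). These choices make every
yield and the respiratory quotient positive, which is the only orientation
in which the C-mol balance Y_X/S + Y_CO2/S + Y_Tre/S ≈ 1 is meaningful.

## Compositions

The shipped compound table uses anhydrous monosodium glutamate
(169.11 g/mol, 5 C): the conventional 1.15 factor that converts an assayed
glutamic-acid concentration to an MSG basis equals the molar-mass ratio
169.11/147.13 = 1.149 for exactly this form. Biomass defaults to the
standard microbial elemental composition CH₁.₈O₀.₅N₀.₂ (0.4878 g C/g DCW).
No measured elemental analysis for *S. acidocaldarius* was available to us;
the default is overridable wherever a `BiomassComposition` is accepted, and
the carbon balance shifts proportionally if the true carbon fraction
differs.

## kLa estimation and scale translation

The gassing-out estimator log-linearises C(t) = C\*(1 − e^(−kLa·t)) and
regresses ln(1 − C/C\*) on time. Defaults and why:

* **Fit window 10–90 %DO.** Near saturation the log transform amplifies
  probe noise without bound; below ~10 % the vessel may still be purging
  nitrogen. Points at or above the calibrated C\* are always excluded.
* **Probe lag off by default** (`probe_lag = 0`). The synthetic trace
  generator can convolve a first-order probe response (two-exponential
  cascade) for sensitivity studies, but the estimator itself assumes a
  calibrated, fast probe.
* At 1 %DO additive noise and ~1000 trace points the estimator's relative
  SD across replicates is well under 1 %; the additive noise does introduce
  a small (~1 %) downward bias through the log transform, visible in the
  acceptance output's noisy mean estimate.

Ungassed power uses constant turbulent power numbers (warning below
Re = 10⁴). The aerated draw uses the Michel–Miller form
P_g = 0.72·(P²·n·d³/Q^0.56)^0.45 with SI inputs; because the expression
diverges as Q → 0 it is capped at the ungassed power, which also enforces
the correct zero-aeration limit. The correlation choice is a configurable
coefficient, not a law; published aerated-power data for a specific vessel
should always take precedence.

Scale translation fits log kLa = log α + a·log(P_g/V_L) + b·log v_s by least
squares (≥ 3 operating points spanning both regressors; the design matrix is
rank-checked) and root-solves the stirrer speed for a target kLa at fixed
gas flow over an admissible 50–1500 rpm range (configurable), using Brent's
method; predicted kLa is strictly increasing in stirrer speed, so the root
is unique when bracketed.

The scale presets (2 L/20 L/200 L) carry the study's stirrer speeds, gas
flows, overpressures and geometry ratios; impeller power numbers are generic
Rushton-class values (Nₚ = 5, two stages), so computed kW/m³ values are
magnitude-class estimates, not reproductions of measured power inputs.

## Chemostat calculus

All rates are interval-wise between consecutive sampling points, computed on
total amounts (concentration × volume) with bleed correction. Choices made
where the calculus is genuinely open:

* Bleed discharge terms use the arithmetic mean of the two bounding broth
  concentrations; with ~24 h between samples no finer trace exists, and at
  steady state the approximation is exact.
* Acid addition counts toward the dilution rate but carries no substrate.
  Consequently the textbook steady-state closed form
  q_S = D·(S_feed − S_res)/x̄ holds only for zero acid flow; with an acid
  share a of the total inflow the exact limit is
  q_S = D·(S_feed/(1+a) − S_res)/x̄. The simulator defaults to a = 2 %, so
  validation uses the corrected form.
* Off-gas signals are linearly interpolated to interval midpoints.
* Irregular sampling gaps (weekends) need no resampling: every balance is
  written over the actual Δt.
* Y_X/S in g/g divides µ by the gram-sum q_Glc + q_MSG; all C-mol yields
  divide by the C-mol-sum of the two uptake rates. (Grams of different
  substrates add; converting a C-mol sum "back to grams" would need an
  arbitrary reference molar mass and carries no extra information.)
* Steady state begins four dwell times (4/D) after the chemostat start;
  summaries report mean and STD% = 100·SD(sample)/mean per parameter, with
  STD% undefined (None) for zero means.

The group-comparison module uses classical one-way ANOVA and
pooled-variance two-sample t-tests with a Bonferroni threshold α/k over the
k pairs — the standard post-hoc after ANOVA; the original analysis tool's
exact pairwise variant is not documented, and pooled variance is the
conventional default for small, similar-sized steady-state series.

## The synthetic cultivation

The generator emulates the study conditions end to end: batch on 2 g/L MSG
+ 1 g/L glucose in 75 % of the working volume, exponential feed ramp
(14.8 g/h start at benchtop scale, ×10 per scale step) at µ_set = 0.035 h⁻¹
until the working volume is reached, then a chemostat at D = 0.03 h⁻¹ on
9.5 g/L MSG + 4.5 g/L glucose, sampled every 24 h (optionally with 72 h
weekend gaps), with constant volume held by a bleed.

Growth is dual-substrate Monod with the specific growth rate allocated to
the two substrates by their carbon share in the feed (φ_glc = 0.35,
φ_msg = 0.65), each share saturating by its own Monod term. Kinetic
defaults: µ_max = 0.05 h⁻¹ (comfortably above both the 0.035 h⁻¹ ramp and
D = 0.03 h⁻¹, as a slow-growing thermoacidophile), K_S = 0.05/0.10 g/L
(glucose/MSG), yields 0.30 g/g on both substrates (giving a steady-state
DCW near 4 g/L on this feed, the observed scale), a constant trehalose
formation rate of 0.001 g/g/h (the organism secretes trehalose at low,
roughly growth-independent levels; a kinetic law for it is not established),
and a true RQ of 1.0 (fully oxidative carbon metabolism). Trehalose carbon
is drawn from the glucose pool in glucose-equivalent mass.

CO₂ production is computed as consumed substrate carbon minus biomass and
trehalose carbon — carbon conservation is therefore structural, and the
cumulative audit (`carbon_closure`) verifies the integrator keeps it to
≤ 0.1 %. O₂ consumption is CO₂/RQ_true; a separate per-biomass O₂
coefficient would over-determine the gas phase. Dissolved oxygen follows
dc/dt = kLa(c\* − c) − OUR with an effective saturation c\* = 0.28 mmol/L —
a lumped process constant (temperature, pressure, medium effects folded
in), not a tabulated solubility; at the default operating point it puts the
steady-state DO near 30 % of air saturation.

Integration uses LSODA (rtol 1e-8, atol 1e-10) over three phases separated
by events (batch substrate exhaustion below 0.02 g/L; volume reaching the
chemostat working volume). The deterministic trajectory is cached per
parameter set, so seed sweeps re-sample noise without re-integrating.
Measurement noise is multiplicative Gaussian (CV = `noise_cv`) on the
measured quantities — DCW, OD, concentrations, viability, off-gas
mole-fraction differences — while volumes and cumulative flows are balance
readings and stay exact. A dilution rate above the achievable growth rate
produces a washed-out but still valid output, flagged in the truth record.

One deliberate fidelity note: with the study's own ramp start (14.8 g/h)
and the batch-end biomass implied by the batch carbon load at Y = 0.3, the
feed initially oversupplies by ~30 %, so µ runs near 0.040 h⁻¹ during the
short fed-batch and relaxes toward the 0.035 h⁻¹ set-point on a ~1/µ_set
timescale. The simulator reproduces this start-up transient rather than
forcing µ = µ_set; exact set-point tracking is verified separately under a
biomass-matched ramp.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: pH/DO control dynamics and sensor drift,
oxygen-toxicity effects on viability (viability is a constant tagged level,
91 % by default, plus noise), NZ-amine consumption in the batch medium
(excluded from carbon bookkeeping), gas-phase holdup/headspace mixing
dynamics, gradients in large vessels, and any systematic (non-multiplicative
or correlated) assay errors. Real cultivations will close their carbon
balance less perfectly than the simulator's structural 1.00.

## Problem sizes

Default validation runs use the benchtop-scale scenario: ~430 h simulated
(≈ 8 steady-state samples at 24 h spacing), 100-replicate seed sweeps for
the kLa estimator, and 50-seed sweeps for noisy parameter recovery. These
sizes keep the full suite and the acceptance script in the seconds range
while leaving the statistical checks well-powered.

## Known limitations

* The kLa correlation form and Michel–Miller constants are engineering
  correlations; extrapolating them far outside the fitted operating window
  (or to non-coalescing media) is unreliable.
* The gassed-power cap at the ungassed draw is a pragmatic limit, not a
  physical model of the low-aeration transition.
* Interval rates inherit the quasi-steady assumption between samples;
  strongly dynamic phases (early fed-batch) are only approximately captured
  by 24 h sampling.
* The elemental biomass composition is a default, not a measurement; the
  C-mol yields and carbon balance scale with it.
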