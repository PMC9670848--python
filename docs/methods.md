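# Methods

## Relative-rate determination of gas-phase rate constants

All chamber loss processes are modeled as first order, so for a compound X
with second-order oxidant rate constant k_X and wall-loss constant k_WL,X,

    ln([X]0/[X]t) = k_X ∫0t [OH](t') dt' + k_WL,X (t − t0).

Subtracting the wall-loss term leaves a quantity proportional to the shared
OH exposure integral; regressing the corrected target curve on the corrected
reference curve therefore estimates the ratio k_T/k_ref as the slope, for
*any* OH history. This exposure-profile invariance is asserted as a property
test (constant vs strongly ramped OH, identical slope to 1e-10 relative).

Numerical and statistical choices:

* **Free intercept.** All regressions (first-order loss and relative-rate)
  use OLS with a free intercept. A forced origin is only correct if t0 and
  C0 are exact; a free intercept is robust to t0 mis-specification, and on
  clean data the tests assert the intercept vanishes. C0 is the first
  sample, not a fitted parameter, matching the ln(C0/Ct) construction.
* **Common time grid by exact intersection.** Target and reference series
  are restricted to exactly shared timestamps; no interpolation is applied,
  to avoid introducing smoothing the data never had. Fewer than three
  shared points is an error, as is a reference that shows no decay after
  correction (degenerate regression).
* **Uncertainties are 1σ throughout.** Regression slopes carry the 1σ
  standard error from the fit. The stored wall-loss constant
  (3.1 ± 0.2)×10⁻⁴ s⁻¹ is 1σ; display conventions that double it to 2σ are
  a formatting concern, handled at the reporting layer.
* **Ratio → rate constant.** value = slope × k_ref with
  σ = value·sqrt((σ_slope/slope)² + rel_unc²); the reference's relative
  uncertainty (default 0.10) is an irreducible floor on the result's
  relative uncertainty (property-tested).
* **Weighted average.** Inverse-variance weights w_i = 1/σ_i²,
  σ = (Σw)^(−1/2). The mean is clamped into the convex hull of the inputs
  to keep the betweenness invariant exact against last-ulp rounding. A zero
  input σ is an error (it cannot be weighted), as are mixed units.
* **Unit conversions** between s⁻¹ and day⁻¹ use exactly 86 400 s day⁻¹;
  second-order units are deliberately non-convertible.

## OH source and atmospheric descriptors

The NOx-free OH source is dark TME ozonolysis. OH production
Y·k(TME+O₃)·[O₃]·[TME] balanced against loss dominated by TME itself gives

    [OH]ss = Y·k(TME+O₃)·[O₃] / ( k(TME+OH)·(1 + s) ),

where s is the pseudo-first-order OH sink from everything other than TME,
expressed as a fraction of the TME sink (default 0). With the recommended
constants (Y = 1, k(TME+O₃) = 1.1×10⁻¹⁵, k(TME+OH) = 1.1×10⁻¹⁰ cm³
molecule⁻¹ s⁻¹) and the top of the chamber ozone range (4.92×10¹³ cm⁻³),
the simple form gives 4.9×10⁸ cm⁻³; a modest extra sink (s ≈ 0.2) brings
this to ~4×10⁸, which is why s is exposed as a parameter rather than fixed.

Pseudo-first-order rate and lifetime are k_g = k₂[OH] and τ = 1/(k₂[OH]);
their product is exactly 1 in consistent units (property-tested). A zero OH
concentration raises an error from the lifetime rather than returning inf.

## The two-media fate model

The three-species network (parent in water, product in water, product in
gas) is linear, with rates in day⁻¹:

    dP/dt = −k_d P,   dA/dt = k_f P − K A,   dG/dt = k_vol A − k_g G,

K = k_vol + k_d′, P(0) = 1, A(0) = G(0) = 0. Concentrations are fractions
of the initial aqueous parent; absolute units are a display-time
multiplier. The gas reservoir is an infinite sink with first-order loss
only — no re-deposition and no Henry's-law equilibrium (the kinetic
treatment is the appropriate one when volatilization and aqueous
degradation have comparable rates, as here).

Closed forms: P is a single exponential; A is the classic intermediate
k_f/(K−k_d)·(e^(−k_d t) − e^(−K t)); G is k_f·k_vol times the second
divided difference of x ↦ e^(−xt) on the cascade nodes {k_d, K, k_g}.

Numerical handling of near-equal rates:

* A(t) is evaluated as e^(−k_d t)·t·E(u) with u = (K−k_d)t and
  E(u) = −expm1(−u)/u, ordering the two nodes so u ≥ 0. This is accurate
  for every gap, including the confluent limit k_f·t·e^(−k_d t), with no
  branch threshold.
* G(t) uses the explicit three-term sum when the smallest pairwise node gap
  exceeds 10⁻⁷ × max(rates, 1); below that, where the sum would cancel
  catastrophically, it switches to evaluating the matrix exponential of the
  3×3 rate matrix, which is exact for any degeneracy. The ~eps cancellation
  residue of the explicit sum near t = 0 is clipped at zero, since the
  divided difference of the convex function e^(−xt) is provably
  non-negative.
* The independent oracle in the tests is stiff-safe `solve_ivp` (LSODA,
  rtol 10⁻¹², atol 10⁻¹⁸). Agreement is asserted at 10⁻⁶ relative with an
  absolute floor of 10⁻¹² × trajectory peak, because below that floor the
  oracle itself cannot certify relative accuracy. One hundred random
  parameter sets drawn log-uniformly in [10⁻³, 10] day⁻¹ are checked, with
  near-degenerate (gap 10⁻¹⁰) and exactly-degenerate node pairs injected.

Summary fractions are pure rate-constant algebra: f = k_f/k_d,
v = k_vol/(k_vol + k_d′), F_j = k_j/(k_vol + k_d′). Their flux meaning —
∫k_f P dt = f and (∫k_vol A dt)/(∫k_f P dt) = v over [0, ∞), independent of
k_g — is verified by quadrature. Pathway fractions are renormalized to sum
to exactly 1; a pathway with zero rate gets fraction 0.

Built-in scenarios (day⁻¹): `fast` k_d = 0.3, k_f = 0.05, k_d′ = 0.4
(shallow, low-DOC, high-nitrate water, where aqueous photochemistry is
quick) and `slow` k_d = 0.02, k_f = 0.005, k_d′ = 0.03 (deep, DOC-rich
water). Both use k_vol = 0.052 day⁻¹ (a structure-activity estimate for
calm-wind volatilization) and k_g = 0.46 day⁻¹. The k_g default follows
the arithmetic 4.7×10⁻¹² cm³ molecule⁻¹ s⁻¹ × 1.13×10⁶ cm⁻³ × 86 400
= 0.459 day⁻¹; published figures for this constant vary slightly
(0.46–0.62 day⁻¹ depending on the k₂ rounding adopted), so it is a plain
config field, never hardcoded in the model. Note v and f do not depend on
k_g at all.

The conversion fraction f is also checked against the 0.18–0.26 range
produced by full aqueous photochemical modeling across realistic water
columns: the slow scenario gives f = 0.25 (inside), the fast scenario
f ≈ 0.167 (slightly below; the flag is informational).

## Synthetic data: what it emulates and what it does not

`generate_chamber_pair` integrates d ln C = −(k_OH[OH](t) + k_WL) dt
exactly for a piecewise-constant OH profile, then applies i.i.d.
multiplicative lognormal noise (mean one, coefficient of variation
`noise_cv`) to every concentration. Lognormal noise was chosen because
spectroscopically retrieved concentrations are positive and analyzed in log
space; no instrument noise model is published for such retrievals, and
`noise_cv = 0.02` is a free default. Defaults emulate a NOx-free run: 30
min duration sampled every 60 s (31 spectra), constant [OH] = 2×10⁸ cm⁻³
(inside the TME-source estimate of up to ~4.9×10⁸), target wall loss
3.1×10⁻⁴ s⁻¹, no reference wall loss. The 30-min/2×10⁸ combination gives a
reference log-depletion range of order 1, which keeps the errors-in-
variables attenuation of the relative-rate slope (noise is present in the
regressor too) small against the regression standard error; with much
shorter exposures the 2σ intervals would undercover.

What the generator does *not* emulate: spectral line shapes and retrieval
cross-talk between co-monitored compounds, drifts in the OH source,
dilution/leak losses, or temperature excursions. Passing recovery tests
therefore demonstrate correctness of the estimators under the assumed
first-order + multiplicative-noise data-generating process, not robustness
to instrument systematics.

`generate_fate_observations` multiplies the analytic trajectories by the
same noise model, supporting end-to-end re-fit tests (e.g. k_d recovered
within 10% from a 50-point parent trace at 5% noise).

## Problem sizes

Stochastic assertions use 200 replicates (2σ coverage ≥ 90%, mean fitted
ratio within 1%), 100 random parameter sets for oracle agreement, and
40–3000-point time grids; the full suite runs in a few seconds on one core.

## Known limitations

* The chamber module assumes the oxidant field is identical for target and
  reference (well-mixed reactor) and that wall loss is constant in time.
* The fate model has no spatial resolution, no re-deposition from air to
  water, and treats all rate constants as time-invariant (24 h averages);
  diel cycles are outside its scope.
* Aqueous pathway splits (for F_j) must be supplied by the caller — the
  package stores the photoreactivity parameter table but deliberately does
  not reimplement full aqueous photochemical modeling to derive k_d, k_f,
  k_d′ from water chemistry.
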