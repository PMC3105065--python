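# Methods

This note documents the models, assumptions, parameter choices and
numerical details behind `crustgas`, and what the synthetic-data tests do
and do not establish about real measurements.

## Gas kinetics

Headspace mixing ratios are converted to absolute amounts with the ideal
gas law, `n = x·10⁻⁶ · PV/(RT)`, and normalised by soil dry weight.
Production rates are ordinary-least-squares slopes of amount versus time
with a free intercept, so a detection lag in the first days biases the
intercept, not the slope. Two windows matter: the full incubation
(0–42 d, the default) and the post-lag window (14–42 d) used for the
treatment-effect statistics; both are exposed because neither is uniquely
implied for every reported figure. Defaults when the input omits them:
25 °C (298.15 K) and 101325 Pa. Gas withdrawn by the sampling syringe is
neglected — sample volumes are small against the ~100 mL headspace — and
rates may be negative (O₂ consumption); nothing is clamped.

## Isotope calculus

All δ values are ‰ vs V-PDB, with a physical floor at −1000‰. Four
operations, in order of application:

1. **Newly formed methane.** With `fₙ = (m₂ − m₁)/m₂` the fraction of the
   time-2 pool formed during the interval, two-pool mass balance gives
   `δₙ = (δ₂ − (1 − fₙ)δ₁)/fₙ`. Intervals without net production carry no
   new-methane signal and are skipped (logged), not errored through.
2. **Apparent fractionation** `α_app = (δ_CO₂ + 10³)/(δ_CH₄ + 10³)`.
   Treatment-level values average per-time-point α rather than computing
   α of averaged deltas; the difference is second order but the pairwise
   form propagates naturally to time series.
3. **Per-mil form** `ε = (α − 1)·10³` (not `10³·ln α`; at these
   magnitudes the two differ in the third decimal of ε and the linear
   form matches how isoline plots are labelled).
4. **Partition.** `f_mc = (δ_CH₄ − δ_ma)/(δ_mc − δ_ma)` splits methane
   between hydrogenotrophic (`δ_mc`, best calibrated by a CH₃F-inhibited
   incubation in which only CO₂ reduction operates) and acetoclastic
   production (`δ_ma` = soil organic carbon plus an assumed
   acetate-to-methane fractionation; scenarios of 0 and −25.6‰ bracket
   published values, the organic-C-to-acetate step being nearly
   unfractionating). Raw coordinates outside [0, 1] mean the measurement
   lies beyond an end-member scenario; they are clamped with a flag and
   the raw value retained, because a scenario that overshoots simply
   saturates at a pure pathway. A first-order delta-method standard error
   on `f_mc` is available from the three input SEs.

CO₂ sources are partitioned the same way between organic carbon and
carbonate end members; in oxic/oxygenic microcosms CO₂ is essentially
organic-derived, while anaerobic acid production mobilises carbonate.

## Oxygen microprofiles

Steady state, one dimension, constant porosity φ and sediment diffusivity
D_s: `d/dz(φD_s dC/dz) + P(z) = 0` with P piecewise constant over a small
number of zones. The solution is piecewise quadratic and C¹; with a fixed
surface concentration and a zero-flux bottom (closed microcosm; a fixed
bottom concentration is available) the flux profile is
`J(z) = J₀ + ∫₀ᶻP`, so the surface flux obeys the conservation identity
`J₀ = −∫P dz` exactly. Units: depth µm (positive down), concentration
µmol L⁻¹ (≡ nmol cm⁻³), rates nmol cm⁻³ s⁻¹, flux nmol cm⁻² s⁻¹
(positive into the soil).

The inversion exploits that for fixed boundaries the forward map is
affine in the rates: each zone contributes one basis profile, the top
concentration is a free column, and the rates come from a single linear
least-squares solve. Boundaries are restricted to measurement depths and
searched exhaustively for k ≤ 3 zones (greedy extension above). The zone
count is the smallest k for which adding a zone no longer reduces the SSE
significantly by a nested F-test at α = 0.05, with parameter counts
p_k = 2k (k rates, k−1 interior boundaries, free top concentration); an
essentially exact fit (SSE below a relative tolerance of 10⁻⁸ of the
concentration scale, squared) stops the search early. A constant profile
short-circuits to one zone of rate zero. Fitted profiles that go negative
where measurements are non-negative are flagged (`nonphysical`), not
rejected — the linear algebra remains valid and the flag is the
diagnostic.

Defaults φ = 0.6 and D_s = 1.2·10⁻⁹ m² s⁻¹ describe a water-saturated
silty loam at 25 °C; neither is measured by the pipeline and both are
config. The anoxic boundary is the shallowest depth below which the
concentration stays under 1% of air saturation (default 253 µmol L⁻¹ at
25 °C; both the reference and the fraction are config), linearly
interpolated between bracketing measurements; transient dips that recover
do not count.

A note on flux magnitudes: with millimetre-scale penetration at air
saturation, molecular-diffusion fluxes at these parameters are of order
10⁻² nmol cm⁻² s⁻¹. The model is linear in the rates, so fits and the
conservation identity hold at any magnitude; profiles whose integrated
consumption is large relative to φD_s·C_top/L simply produce (flagged)
negative modelled concentrations. The synthetic presets use physically
consistent rates — a single consumption zone with O₂ penetrating to
~2.5 mm for dark-oxic treatments, and a production zone over a
respiration zone with anoxia below ~1.5 mm for light treatments.

## qPCR

Absolute quantification inverts the standard curve
`Ct = intercept + slope·log₁₀(copies)` (slope < 0; −3.32 cycles per
decade at perfect efficiency), scaled by dilution and extraction dry
weight. Relative expression uses 2^(−ΔΔCT) with the amplification base
fixed at 2: per replicate, ΔCt = Ct(transcript, cDNA) − Ct(gene, DNA);
replicates are paired by index between matched treatments (n = 3
microcosms per treatment) and the fold change is the arithmetic mean of
per-pair 2^(−ΔΔCt) with the SE across pairs — this is why reported SEs
can exceed the mean. A pooled-ΔCt variant and geometric averaging (under
which the A→B and B→A folds are exact reciprocals) are options.
Taxon-to-total copy ratios above 1 are flagged rather than rejected,
since assays differ in target copies per cell.

## Factorial statistics

The design is a balanced 2×2×2 with n = 3, so the fixed-effects
decomposition is orthogonal and each of the seven terms has
`SS = (±1-contrast of cell totals)²/N`, `F = MS/MS_resid` on
(1, 8(n−1)) df — with triplicates, residual df = 16. Sequential and
marginal (type-I/type-III) sums of squares coincide; the implementation
requires balance and refuses anything else. Tests cross-check every
statistic against an independent general-linear-model fit. Rates are
log-transformed (natural log) and copy numbers log₁₀-transformed before
analysis; the t-test is Welch's (the unequal-variance form is the safe
default when the variant is unspecified), with degenerate zero-variance
groups resolved by their means.

## Upscaling

`areal = rate · (wet_weeks·7 d) · crust areal density · M(CH₄) · 10⁻⁶`
in mg m⁻² yr⁻¹, and `global = areal · desert area · 10⁻⁹` in Tg yr⁻¹.
The crust areal density default, 5300 g m⁻², is a 3–4 mm crust at
silty-loam bulk density (~1.5 g cm⁻³); it is an inferred, overridable
quantity, not a measurement. The rate entering the default scenario is
the mean of the six oxic/oxygenic treatments — the field-relevant
condition, since natural crusts sit under air — over 2–7 wet weeks per
year and 44·10⁶ km² of desert.

## Synthetic data: what it emulates, and what it does not

Generators are deterministic under a fixed seed and return ground truth
alongside the data. Noise models are the simplest forms consistent with
replicate-level spread: multiplicative Gaussian (sd 0.1) on cumulative
gas amounts, additive Gaussian (0.5‰) on reported deltas, additive
Gaussian (1% of the surface concentration) on O₂ profiles, additive
Gaussian (0.15 cycles) on Ct values. Treatment presets sit at the
experiment's reported scales: CH₄ rates 3800/1500 (strictly anoxic,
flooded/drained), 41.6/9.2 (dark oxic) and 21.7 (light) nmol gdw⁻¹ d⁻¹;
pathway mix 0.27 hydrogenotrophic in strictly anoxic treatments and 1.0
elsewhere; end members −20.5‰ (organic), −4.09‰ (carbonate), −75‰
(hydrogenotrophic), CH₃F-calibration α 1.066; gene copies 10⁸–10⁹ gdw⁻¹
anoxic versus 10⁵–10⁷ oxic/oxygenic; katE fold-change presets per
matched treatment pair. Isotope series are built by exact incremental
mass balance, so recovery failures indicate estimator problems, not
generator drift.

Passing recovery tests on these data shows the estimators are correct
and calibrated under the stated noise models. It does not validate the
models against real crusts: the generators assume strictly linear
accumulation (no lag, no substrate depletion), time-constant pathway
fractions and δ_CO₂, steady-state O₂ profiles, and independent Gaussian
errors — all idealisations a field dataset will violate to some degree.

## Numerical choices and test design

- Recovery assertions on stochastic quantities use the study's own
  replication (n = 3): the surface-flux and rate checks compare the
  triplicate mean against truth, and the fold-change check uses a 95%
  Student-t band (df = 2), the correct coverage for an SE estimated from
  three pairs.
- Problem sizes in tests and the acceptance script are the experiment's
  own: 7 sampling days, triplicates, 26–31-point profiles at 100 µm
  resolution; simulation-based calibration tests use 200–1000
  replications, which keeps the whole suite in the tens of seconds.
- Golden pipeline outputs are pinned at 6 significant digits to absorb
  platform float noise; CSV writers use fixed formats so identical
  configs produce byte-identical files.
- Degenerate inputs have defined behaviour throughout: flat profiles fit
  one zero-rate zone, zero-variance t-tests resolve by means, empty
  isotope intervals are skipped, and every guard raises a typed error
  from `crustgas.errors`.

## Known limitations

- The partition is a two-end-member model; methylotrophic methanogenesis
  and closed-system Rayleigh distillation are out of scope.
- The O₂ model is single-phase and steady-state; unsaturated (gas/water)
  crusts and photosynthesis transients are not represented.
- The ANOVA handles only the complete balanced design by construction.
- Efficiency-corrected qPCR fold changes (base ≠ 2) are available but
  off by default, matching the classical estimator.
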