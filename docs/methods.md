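# Methods

## Scope and model

`beachrisk` estimates incremental lifetime cancer risk to young children
from recreational exposure to a carcinogenic oil-spill chemical
(benzo[b]fluoranthene in the bundled scenarios) in beach sediment, weathered
oil, and tarballs. Three routes are modelled and combined additively:

* **oral** — incidental ingestion of sand,
  `dose = C·IRs·RBA·EF·CF / BW`;
* **dermal** — uptake through sand adhering to skin, one loading event per
  exposure day, `dose = C·SA·AF·ABS·EF·CF / BW`;
* **inhalation** — suspended solid-phase particulates only (no gas phase),
  `dose = C·(1/PEF)·IRa·ET·EF / BW`.

Risk per route is `dose × SF` with route-specific slope factors; the linear
low-dose model is used throughout. Slope factors, RBA and ABS are inputs,
not fitted: dose–response modelling is out of scope, as are non-cancer
hazard quotients, multiple sequential skin-loading events, and gas-phase
inhalation.

### Assumptions inherited from the published parameterisation

The engine reproduces a published spreadsheet workflow, including two
quirks that are kept **deliberately** (correcting them silently would make
published results irreproducible):

* **ET as a bare multiplier.** The inhalation dose multiplies by exposure
  time in hours/day with no /24 normalisation, so the equation is not
  dimensionally clean. The bundled point estimates are only reproducible
  with ET applied as written.
* **Exposure-factor override.** EF is normally computed as `F·ED/AT`
  (3·8/28489 = 8.424e-4 for the `beaches` scenario, matching the published
  0.000842). The `literature-default` scenario instead carries the
  published EF = 0.002948 verbatim, although 12·8/28489 = 0.00337; profiles
  therefore accept an `exposure_factor_override` that wins over the
  formula. Even with the override, the comparison study's oral risk cells
  are only matched to ~1–2 % — their printed cells imply mutually
  inconsistent exposure factors (2.92–3.01 × 10⁻³), i.e. independent
  rounding that cannot be recovered. The acceptance test asserting that
  total at display precision is left failing by design.
* **Concentration-to-medium mapping.** The published summary gives only the
  concentration triple 0.62/1.46/4.40 mg/kg. The per-medium assignment
  (sediment 1.46, weathered oil 4.40, tar 0.62) is fixed by back-calculation
  from the published per-medium risks together with the statement that
  weathered oil is the upper limit; the derivation is noted in the fixture.
* **CF semantics.** CF is the dimensionless 10⁻⁶ mg→kg conversion, applied
  exactly once in the oral and dermal doses and never in inhalation (PEF
  already carries the mass unit).

### Numerical choices

* Risks are never clamped to [0, 1]; above 0.01 a warning is emitted because
  the linear model is not credible there. Zero frequency, concentration, or
  exposure time are valid (zero risk); zero body weight, averaging time, or
  PEF are domain errors.
* Table margins are `math.fsum` sums of cells, so additivity holds to well
  within 1 part in 10⁹.
* Reports render at 3 significant figures (`{:.2e}`), the display precision
  of the published tables; `--raw` gives full doubles. One published cell
  (weathered-oil inhalation) sits on a rounding boundary: the exact value
  is 7.68499...e-13, printed as 7.69e-13 — the test suite therefore accepts
  one unit in the last printed digit when comparing to published values.

## Monte Carlo uncertainty propagation

Body weight, skin surface area, visit frequency, and concentration are
treated as independent triangular(min, likeliest, max) variables; the
likeliest value is the observed cohort *median* standing in for the mode.
Sampling is plain independent Monte Carlo (no Latin hypercube), by inverse
CDF: for `u < (c−a)/(b−a)`, `x = a + √(u(b−a)(c−a))`, else
`x = b − √((1−u)(b−a)(b−c))`, with `u ~ U(0,1)` from a seeded numpy PCG64
generator. Parameters are drawn in fixed alphabetical order, so identical
spec + seed is bit-reproducible. Defaults: 1000 iterations (overridable).

Per iteration the profile is rebuilt with the draws and all three route
risks are evaluated for the sampled *single* concentration — the
concentration triple spans all media, so an iteration's risk is a
single-medium risk, not a three-media sum. When frequency is sampled, EF is
recomputed from `F·ED/AT` with fixed ED and AT (any EF override is
discarded for those iterations). Summaries are per-route means and
empirical 2.5 %/97.5 % quantiles using linear interpolation between order
statistics (numpy's `linear` convention; the original spreadsheet tool's
convention is unknown, so ours is stated explicitly).

The published Monte Carlo summary table is **not** a reproduction target at
any scale: its printed oral 97.5 % value exceeds the analytic maximum risk
attainable under the stated model (all parameters at their risk-maximising
corner give ≈1.17 × 10⁻⁶), and its inhalation mean is ~6 orders of magnitude
below the deterministic point estimate. The test suite instead verifies the
simulation against independent oracles: Kolmogorov–Smirnov and moment
agreement of the sampler with closed forms, corner-bound envelopes on every
risk sample, the structural route ordering dermal > oral > inhalation, the
seed contract, and convergence to the deterministic table under
near-point-mass distributions.

## Synthetic cohorts

`generate_cohort` emulates the per-child field records behind the
triangular assumptions: BW, SA, and visit frequency drawn independently
from their triples, frequency rounded to a whole number of visits with a
floor of 1 (an observed child visited at least once). `summarize_cohort`
takes exact min/median/max/mean per parameter (even-length median = mean of
the central pair), and `fit_triangular` applies the plug-in rule
(min, median, max) — not a maximum-likelihood fit. Defaults are the bundled
field-study triples, making the synthetic cohort statistically
exchangeable with what the original summarisation step consumed.

What the generator does **not** emulate: the physical correlation between
body weight and skin surface area (both the generator and the downstream
analysis assume independence); age/gender structure; micro-activity
patterns; and the height/weight formulas behind per-child skin surface area
(SA is sampled directly from its triple). Frequency integerisation is
one-way: downstream analysis treats frequency as continuous. A green
round-trip test therefore establishes parameter recovery under the model's
own independence assumptions, not fidelity to a real cohort's joint
distribution. Note that refitting recovers (min, median, max): the fitted
"likeliest" converges to the generating distribution's median (≈43.6 kg for
the body-weight triple), which differs from the generating mode (34.8 kg) —
an intentional property of the plug-in rule, not an estimation error.

## Scenarios and interface

Scenarios are TOML files with `[chemical]`, `[concentrations]`,
`[exposure]`, and optional `[distributions]` tables, validated at load time
with field-naming errors. Two are bundled: `beaches` and
`literature-default`, so the published two-column comparison is a
two-invocation workflow. The CLI (`beachrisk point | simulate |
synth-cohort | fit`) is a thin layer over the library; reports go to stdout
or `--out`, logs to stderr, and usage errors exit with status 2.

## Known limitations

* Single-chemical engine; multi-chemical aggregation would be additive but
  is not exercised by any bundled scenario.
* Constant concentration across the whole beach environment and all routes;
  no spatial variation (intertidal zone, dunes) or wet/dry sand effects on
  adherence.
* Uncertainty, not variability, is what the Monte Carlo band represents:
  parameters are resampled per iteration around one child population, with
  no between-child correlation structure.
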