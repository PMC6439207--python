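# Methods

## Scope and model structure

`pahrisk` implements a deterministic, closed-form exposure-screening
procedure for inhaled particle-bound PAHs. There is no fitting and no
stochastic simulation in the assessment itself; every output is a product
or ratio of measured inputs and fixed constants. The package therefore
separates cleanly into:

1. a **data-reduction** step turning desorption measurements into
   bioaccessible fractions (`bioaccessibility`),
2. two **assessment** models sharing one constants registry (`intake`,
   `teq`, `registry`),
3. bundled **reference tables** and a synthetic desorption generator
   (`fixtures`), and
4. CSV/CLI plumbing (`io`, `cli`).

## Bioaccessible fraction

F_bioa is defined operationally as the *total extent of desorption*: the
maximal cumulative mass released into simulated lung fluid divided by the
total particle load. It is deliberately **not** a fitted kinetic asymptote
— the estimate is the series maximum, which for a valid (monotone
non-decreasing) series is its final point. Series that momentarily decrease
violate the cumulative-release invariant and are rejected rather than
monotonized: a decrease signals a measurement problem that silent
correction would hide. A released mass exceeding the load is likewise an
error, never a fraction above 1.

All internal values are fractions of 1; percent appears only in CSV files
and rendered tables.

## Exposure and toxicity parameters

| symbol | meaning | unit | default | note |
|---|---|---|---|---|
| TR | tracheobronchial retention | fraction | 0.75 | retained fraction of inhaled particles |
| V_resp | inhalation rate | m³/day | 20 | adult |
| BW | body weight | kg | 60 | adult |
| C_particle | particle concentration in air | g/m³ | 5.6 × 10⁻³ | extreme biochar-pollution scenario; a screening bound, not a typical level |
| q_PAH | PAH mass fraction in particle | ng/g | input | loadings accepted in μg/g at the CSV boundary (×1000) |
| C_PAH | ambient PAH concentration | ng/m³ | input | |
| CR | target lifetime cancer risk | — | 10⁻⁶ | acceptable range [10⁻⁶, 10⁻⁴] configurable |
| IPF_BaP | BaP inhalation potency factor | (ng/kg/day)⁻¹ | 3.9 × 10⁻³ | |
| UR | unit risk per BaP-eq concentration | (ng/m³)⁻¹ | 8.7 × 10⁻⁵ | lifetime-70-year assumption is metadata; no time-integration is performed |
| TEF | toxic equivalency factor | — | per analyte | BaP = 1 |

The defaults give the unit intake factor TR · V_resp / BW = 0.25
m³/(kg·day) exactly, a maximum ADI of CR/(IPF_BaP · 0.001) = 0.2564
ng/kg/day, and ATEQ = CR/UR = 0.0115 ng/m³.

The registry models benzo[b]- and benzo[k]fluoranthene as **one combined
analyte** with TEF 0.2, because the bundled measurements report the pair
jointly; no attempt is made to split it. Naphthalene has a TEF but no
bioaccessibility measurement: the registry stores the constant and the
missing measurement separately, and every assessment reports the
bioaccessible side of naphthalene as *not assessed* — a missing F_bioa is
never imputed and never silently treated as zero, and not-assessed rows are
excluded from min/max summaries.

## Classification conventions

Risk is flagged when the exposure metric strictly exceeds its threshold
(DI > ADI; TC or BC > AC). A value exactly equal to the threshold is
acceptable; the reading "below the threshold is acceptable, otherwise not"
is ambiguous at the boundary, equality is a measure-zero event for
continuous inputs, and the convention is configurable
(`tie_acceptable=False` for the strict reading).

Comparing a concentration with its per-analyte AC is algebraically the same
decision as comparing its BaP-equivalent TEQ with ATEQ
(TC > ATEQ/TEF ⟺ TC·TEF > ATEQ for TEF > 0); the TEQ report presents both
views and the identity is enforced property-wise in the tests.

## Numerical choices

- All arithmetic runs at full double precision. Rounding happens only at
  presentation boundaries, half-up (`rounding.round_half_up` /
  `round_sig`), matching how the reference tables were printed.
- Regression tests against printed tables use a tolerance of one unit in
  the last printed digit. This absorbs two artefacts of the source tables:
  their own rounding of the F_bioa inputs before computing DI, and a few
  truncated (rather than half-up-rounded) entries.
- The PM2.5 fixture stores bioaccessible fractions at two precisions. The
  higher-precision values (e.g. 21.28%, 19.58%) are canonical and feed all
  computation; the 3-significant-figure values (21.3, 19.6) are display
  only. The printed daily intakes are reproducible only from the canonical
  precision, which is how the two were distinguished.
- Acceptable concentrations are always recomputed from CR/UR/TEF, never
  read back from a table; printed AC columns serve purely as oracles.

## Synthetic desorption generator

The generator emulates first-order single-compartment release,

    m(t) = M_total · p · (1 − e^{−k t}),

with plateau fraction p ∈ (0, 1], rate k (default 0.35 h⁻¹) and a 24-point,
24-hour sampling grid, so the horizon is ≈ 8.4/k and the final point sits at
the plateau to within 0.03%. Multiplicative Gaussian noise (default σ = 0,
tests use 2%) is applied per release *increment*, with negative increments
clipped to zero; the cumulative series is therefore monotone by
construction, satisfies the desorption invariants, and the plateau estimate
averages the noise across increments instead of taking a running maximum of
noisy levels (which would bias it upward). Identical configs, including the
seed, yield identical series.

What the generator emulates is only the one feature the assessment
consumes: a monotone approach to a release plateau. It does not emulate
biphasic desorption, fluid chemistry, particle-property covariates
(pyrolysis temperature, black-carbon content) or inter-replicate
variability, so passing the round-trip tests shows the reduction pipeline
is correct, not that real desorption curves are first-order.

## Problem sizes

Everything is desk-scale: the full regression suite (every cell of the four
bundled tables plus the quoted summary figures, ~130 tests including
property-based checks) runs in a couple of seconds; the parameter-recovery
study uses 200 synthetic series of 24 points.

## Known limitations

- TEF additivity is assumed; no mixture interactions, and no alternative
  TEF schemes are bundled (users may supply their own registry file).
- Inhalation only: no dermal or ingestion routes, no age-stratified
  exposure factors, no probabilistic (Monte-Carlo) exposure assessment.
- The in-vitro bioaccessible fraction stands in for absorbed dose; in-vivo
  validation is outside the package's scope.
- The 5.6 mg/m³ particle concentration is an extreme screening scenario,
  not a validated ambient level.
- K_d is computed by the standard sorbed/aqueous ratio (L/kg); no in-package
  reference values exist for it, so it carries no regression oracle.
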