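# Methods

## Model

The hydrotime (population-threshold) model treats germination as the
accumulation of suprathreshold water potential over time. Seed *i*
germinates at time t satisfying θ_H = (Ψ − Ψ_b,i)·t whenever the ambient
water potential Ψ exceeds the seed's base water potential Ψ_b,i; a seed with
Ψ_b,i ≥ Ψ accumulates nothing and never germinates. With Ψ_b normally
distributed across the lot — median Ψ_b(50), standard deviation σ_φb — the
cumulative germinated fraction is

    g(t; Ψ) = Φ((Ψ − θ_H/t − Ψ_b(50)) / σ_φb).

Assumptions worth stating explicitly:

- θ_H is a single constant for the whole lot; all between-seed variation is
  carried by the Ψ_b distribution.
- The fraction basis is germinated / *sown* seeds. Sub-maximal final
  germination (dead or dormant seeds) is absorbed by the upper tail of the
  Ψ_b distribution rather than modeled with a separate viability parameter.
- No dormancy release or threshold drift over the assay; temperature is
  constant (no thermal-time component).
- The Ψ_b distribution is normal. Alternative distributions (Weibull,
  lognormal) are out of scope.

## Estimation: repeated probit analysis

For a trial θ_H, each replicate-pooled observation (Ψ, t, g) with
0 < g < 1 yields a point (x, probit g), x = Ψ − θ_H/t, and the model makes
these points collinear: probit g = (x − Ψ_b(50))/σ_φb. The fit is classical
unweighted least squares on this line — not binomial maximum likelihood —
matching the procedure long used with this model. Details and numerical
choices:

- **Pooling.** Replicates are pooled by summing counts before fractions are
  formed; for equal per-dish n this equals fitting the replicate-mean time
  course.
- **Boundary fractions.** g = 0 and g = 1 are excluded (the probit is
  undefined); an optional (k+0.5)/(n+1) continuity correction retains them,
  off by default so that default results are exactly reproducible from the
  stated formulas.
- **θ_H profile.** The probit-regression r² is maximized over θ_H on a
  200-point log-spaced grid spanning 0.5–200 MPa·h (hydrotime constants for
  small-seeded legumes are order 10 MPa·h), then refined by golden-section
  search to 10⁻³ MPa·h around the grid winner. The global grid pass guards
  against flat or multi-modal profiles; ties break toward smaller θ_H.
  Candidate θ_H values whose probit slope would be non-positive are
  inadmissible (the model requires germination to increase with x).
- **Parameter extraction.** σ_φb = 1/slope, Ψ_b(50) = −intercept/slope from
  the winning regression.
- **Reported r².** The r² attached to a fit is the *fraction-scale* goodness
  of fit — the squared Pearson correlation between observed and predicted
  cumulative fractions over all (Ψ, t) cells, boundary fractions included —
  the scale on which fitted time courses are conventionally judged. The
  probit-scale r² is only the internal profiling criterion.
- **Identifiability guards.** At least 3 usable probit points and at least 2
  distinct water potentials among them are required; violations raise typed
  errors rather than returning garbage.
- **No interpolation.** Each scheduled observation contributes its cumulative
  fraction at its exact time; germination times are never interpolated
  between observations.

Inversion utilities follow directly from the model: t_g = θ_H/(Ψ − Ψ_b(g))
with Ψ_b(g) = Ψ_b(50) + σ_φb·Φ⁻¹(g); when Ψ ≤ Ψ_b(g) the fraction never
germinates and the package returns an infinite-time sentinel (`NEVER`)
rather than raising, since "never" is a legitimate model answer.

## Germination and vigor statistics

- Final germination percentage: 100 × final cumulative count / sown.
- Germination rate (GR) and germination index (GI): both are
  Σ (seeds newly germinated on day d) / d. The two names circulate with
  identical printed formulas, so one kernel serves both; GR additionally
  offers fractional day indices (t/24) to honor sub-daily counting, with
  integer daily bins as the default. Day d covers (24(d−1), 24d] hours, so
  an observation at exactly 24 h belongs to day 1.
- Soil water content: 100 × (wet − dry)/wet, dry reference mass 950 g per
  pot by default (overridable).
- Simplified vigor index: SVI = emergence % × mean seedling dry weight
  (mg/plant). When replicate data exist SVI is computed per replicate and
  then averaged (mean of products); published SVI columns are not exactly
  the product of the published mean columns, so fixture-based analyses use
  the SVI column as printed and never recompute it from rounded factors.

## Correlation screening

Each hydrotime parameter is paired with each lot-level variable across
lots: Pearson r with the two-sided p from t = r√((n−2)/(1−r²)) on n−2
degrees of freedom, plus the OLS line where regression is requested.
Percentage variables enter untransformed — the arcsine transform customary
for ANOVA of proportions is not part of correlation input — and the
per-lot germination percentage is the unweighted mean over the assay's five
water potentials (equal to the grand replicate mean under the balanced
design). This choice is validated by exact reproduction of the published
cells (48/48 within ±0.005 in r; printed p-values within ±0.001). Raw
p-values are reported; a Holm adjustment is available but off by default,
matching standard practice for this kind of screening table.

Missing lots are dropped pairwise with the remaining n recorded.
Zero-variance variables yield flagged (NaN) entries instead of failing the
whole matrix.

## Synthetic-data generator

The generator emulates the standard assay design: 12 lots × 5 water
potentials {0.0, −0.2, −0.4, −0.6, −0.8} MPa × 3 replicates of 30 seeds,
observed every 8 h to 96 h then every 24 h to a 504-h censoring horizon
(29 observation times). Default per-lot truths are the fitted parameters
shipped in the `table2` fixture, giving realistic spreads (θ_H 8.8–14.8
MPa·h, Ψ_b(50) −0.52 to −0.28 MPa, σ_φb 0.27–0.33 MPa).

- **Noiseless mode** records round(n·g(t)) per scheduled time (round half
  up); a fractional variant records n·g(t) exactly and is the oracle used in
  tests, avoiding rounding artifacts.
- **Binomial mode** draws one Ψ_b per seed from Normal(Ψ_b(50), σ_φb²);
  a seed germinates at θ_H/(Ψ − Ψ_b) if Ψ_b < Ψ, never otherwise, and counts
  accumulate on the schedule. This is exact sampling from the model, so the
  count at each scheduled time is Binomial(n, g(t)).
- **Censoring caveat.** The final observed fraction estimates g(504 h), not
  the asymptote Φ((Ψ−Ψ_b(50))/σ_φb): seeds with thresholds just below Ψ
  germinate after the horizon. At the default design the gap can reach
  ~0.006 in fraction, so asymptote checks in the tests use an extended
  horizon where censoring is negligible, while per-time checks compare
  against g(t) exactly.
- **RNG splitting.** Each (lot, Ψ, replicate) cell derives its seed as the
  CRC-32 of "root|lot|Ψ(4 d.p.)|replicate", making streams independent of
  iteration order and bit-reproducible for a given root seed.
- **Emergence tables.** Lot-level emergence % and seedling dry weight are
  generated as linear functions of Ψ_b(50) plus Gaussian noise, clamped to
  valid ranges; the default slopes/intercepts (−118, 21.5 for emergence %;
  −65, 21.6 mg for SDW; noise SD 5 and 3) interpolate the control-condition
  extremes of the vigor fixture, so default panels carry the strongly
  negative Ψ_b(50)–vigor association the screening is designed to detect.

What the generator does *not* emulate: between-replicate overdispersion
beyond binomial, hard-seededness, dormancy release, temperature or moisture
dynamics of pot/field environments, and spatial effects. Passing tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to field realities.

## Problem sizes

Deterministic checks use replicate-pooled noiseless panels (5 water
potentials × 29 times, 90 seeds pooled). The stochastic recovery check uses
200 binomial panels of 3 × 30 seeds per water potential at one truth
(median |ΔΨ_b(50)| ≈ 0.016 MPa observed, bound 0.03); large-sample simulator
checks use n = 10⁵ seeds. The whole suite runs in a few seconds on one CPU.

## Known limitations

- Unweighted probit least squares is statistically less efficient than
  binomial ML and treats all usable fractions equally; it is retained as
  the field's canonical procedure for this model.
- Published per-lot r² values cannot be reproduced without the raw time
  courses (only lot-level means are printed), so goodness-of-fit is
  validated by construction on synthetic data instead.
- Correlations at n = 12 lots have wide sampling variability; the screening
  table reports raw p-values and leaves family-wise control to the optional
  Holm column.
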