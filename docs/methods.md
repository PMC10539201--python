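# Methods

This note documents the models, the numerical choices and the limits of what
the synthetic-data tests demonstrate.

## Survival model and lethal temperatures

Survival after a fixed exposure duration is a descending logistic of test
temperature, `S(T) = c / (1 + exp(a(T − b)))`, with plateau `c ∈ (0, 1]`
(maximum survival at benign temperatures), midpoint `b` (°C) and slope
`a > 0` (°C⁻¹). Some published variants of this sigmoid omit the slope from
the exponent while still describing a slope parameter; we use the
three-parameter form throughout, since without `a` the transition width is
fixed at ~1 °C and cannot be fitted.

Lethal temperatures are defined **relative to the fitted plateau**, not to
100% survival: LT(m) solves `S = (1 − m)c`, giving
`LT(m) = b + ln(m/(1−m))/a`, hence LT50 = b and LT90 − LT50 = ln(9)/a. This
matters when chronic exposure lowers the plateau (e.g. c ≈ 0.85 after 7 d):
LT50 then marks a 50% loss of the survivable maximum.

The fit is ordinary least squares on per-bottle alive fractions (the curve
is fitted to the replicate-level proportions, matching how such curves are
usually fitted to mean survival; a binomial likelihood would weight the
transition region differently, and OLS keeps estimates comparable with the
common practice). Multi-start initialisation: `b₀` at the temperature of
the steepest observed drop in mean fraction, `c₀` = maximum observed mean
fraction, `a₀ ∈ {0.5, 2, 5}`; bounds `a ∈ (0, 50]`, `c ∈ (0, 1]`,
`b ∈ [min T − 5, max T + 5]`. Data with no observed transition (all alive or
all dead) are rejected as degenerate rather than returning an unidentified
plateau-only fit.

## Thermal performance curve

Egg-production rate follows the cardinal-temperature model with inflexion
(Lobry–Rosso–Flandrois family):

    R(T) = Rmax (T − Tmax)(T − Tmin)² /
           [(Topt − Tmin)((Topt − Tmin)(T − Topt) − (Topt − Tmax)(Topt + Tmin − 2T))]

on `[Tmin, Tmax]`, zero outside, clamped at ≥ 0. The three cardinal
identities — R(Tmin) = R(Tmax) = 0, R(Topt) = Rmax — hold exactly; a variant
with the square on the whole product `(T − Tmax)(T − Tmin)` circulates in
print but violates R(Topt) = Rmax, so the standard form with the square on
`(T − Tmin)` only is implemented. CTmax is identified with the fitted Tmax
(the temperature where the modelled rate reaches zero at the upper limit).

The fitter works in the internal parametrisation
`(Rmax, Topt, Δlow = Topt − Tmin, Δhigh = Tmax − Topt)` with positive bounds
on the two Δ, which enforces the cardinal ordering smoothly instead of
through a discontinuous penalty. Starts: `Rmax₀` = maximum observed mean
rate, `Topt₀` its temperature, `Tmin₀ = min T − 2`, `Tmax₀` = highest
positive-rate temperature + 1, plus two perturbed variants. Δhigh is capped
at 30 °C and Δlow at the design span + 40 °C, wide enough that the cap never
binds on realistic data.

**Derived metrics.** Thermal breadth at level ℓ (default 0.8) solves
`R(T) = ℓ·Rmax` by bracketed root-finding (Brent, xtol 1e-9 °C) on
(Tmin, Topt) and (Topt, Tmax); the interval always contains Topt. Thermal
safety margin = Topt − rearing temperature (negative when reared above the
optimum). Both are validated in tests against a 1e-4 °C brute-force grid
scan.

**Model selection.** Candidate families compete on the same per-bottle data
by `AIC = n ln(RSS/n) + 2k`; ties break toward fewer parameters, then
lexicographic name for determinism. Cardinal (k=4), Gaussian (k=3) and
quadratic (k=3) ship by default; the registry accepts any
`(T, y) → RSS` fitter. A family that fails to converge is reported with a
`failed` status, never silently dropped.

## Bootstrap confidence intervals

All CIs are 95% percentile intervals from case-resampling bootstrap with the
replicate bottle as resampling unit. Resampling is **stratified by test
temperature**: bottles are drawn with replacement within each temperature
cell, so every replicate retains the design's full temperature coverage (an
unstratified draw of 50-odd rows regularly loses the 2–3 temperatures that
carry the mortality transition and produces degenerate refits). Refits start
from the full-data point estimate; failed refits are dropped and counted,
and the failure fraction is reported. Default 1999 resamples; interval
endpoints are widened, if necessary, to contain the point estimate so every
reported CI brackets the value it qualifies.

Simulation tests show percentile coverage for Topt of roughly 93–96% at
nominal 95% under the default design (4 bottles, rate noise sd 8), checked
at 499 resamples per fit to keep the study tractable.

## Q10 coefficients

Q10 = exp(10·slope) where the slope comes from regressing ln(predicted rate)
on temperature over a phase window: *global* — lowest tested temperature to
Topt; *cooling* — lowest tested temperature to the rearing temperature;
*warming* — rearing temperature to Topt. Evaluation points are the
experimental test temperatures inside the window plus the window endpoints
themselves (so the maximum rate at Topt anchors the warming phase even
though Topt is not a tested temperature). Predictions ≤ 0 are excluded from
the ln-regression rather than floored — flooring would drag the slope toward
an arbitrary constant — and exclusions are counted in the result. Because
the cardinal curve is log-concave below Topt, the cooling-phase Q10 always
exceeds the warming-phase Q10 when rearing is below the optimum, which the
property suite asserts.

## Recruitment profile

Potential recruitment per line is S(T)·R(T) with S from the 7-day survival
fit, on a regular grid (default 0.1 °C) over the overlap of the two lines'
TPC domains. The warm/control fold-change is reported only where control
recruitment exceeds a floor (default 1e-3 eggs ind⁻¹ d⁻¹); cells below the
floor are explicit missing values, never 0 or infinity, because the ratio of
two near-zero curve tails is numerically meaningless. The fold is invariant
to rescaling both lines' rates by a common factor.

## Egg diameters

Egg diameter decays exponentially with test temperature,
`D(T) = D0·exp(−kT)`; the per-line fit is OLS of ln D on T. The two lines
are compared ANCOVA-style through one pooled model
`ln D ~ T + line + T:line`: the interaction F-test checks for unequal
slopes, and, under a common slope, the line indicator tests an intercept
offset. Non-positive diameters are rejected at ingestion.

## Synthetic experiment generator

The generator emulates the bottle-incubation design: two rearing lines
(19 °C control, 25 °C warm), 13 test temperatures (11–34 °C), by default 4
replicate bottles of 20 females per cell, survival checks at 24 h and 7 d.
Mortality is binomial per bottle with success probability S(T); egg rates
are the TPC prediction plus additive Gaussian noise truncated at zero
(default sd 8 eggs ind⁻¹ d⁻¹, comparable to the standard errors typical of
such incubations); egg diameters are `D0·exp(−kT)` plus Gaussian noise
(defaults D0 = 80 μm, k = 0.004 °C⁻¹, sd = 1.5 μm), floored at a small
positive value. The 24-h and 7-d survival truths are independent parameter
sets — the two exposures are fitted separately, so the generator does not
model within-week death dynamics.

Default truth parameters place the survival midpoints and slopes at the
study's reported lethal temperatures (b = LT50; a = ln 9 / (LT90 − LT50)),
with plateaus 0.98 (24 h) and 0.85 (7 d), and the TPC at the reported
cardinal estimates (control: Rmax 98.2, Topt 26.4, Tmax 32.1; warm: 83.5,
26.9, 32.4). The lower thermal limit of reproduction is not reported
anywhere; Tmin = 6 °C is used for both lines, consistent with the species'
laboratory viable range (~5.7–32 °C). Because thermal breadth and the
cooling/global Q10 depend strongly on Tmin, those derived values are
internally consistent with this choice but are not expected to coincide with
breadth or Q10 values computed from any other Tmin.

The random stream is split per (line, duration, temperature, bottle) via
seed-sequence spawn keys, so enlarging the design never perturbs the draws
of existing cells.

**What passing tests do and do not show.** The generator draws independent
binomial deaths and homoscedastic Gaussian rate noise. Real bottle data can
be overdispersed (shared bottle effects), heteroscedastic (noise scaling
with the mean), and temperature cells can lose bottles asymmetrically.
Parameter-recovery and coverage results under the generator therefore
demonstrate correctness of the estimators under the stated noise model, not
robustness to overdispersion; with strong within-bottle correlation the
bootstrap CIs (which do resample bottles, the right unit) remain valid in
structure but the binomial-based recovery rates would degrade.

## Pipeline and reproducibility

`run_full_analysis` is deterministic given (inputs, seed): generators and
bootstrap streams derive from the config seed, tables are written with fixed
float formatting, and the manifest records the seed, a SHA-256 config hash,
package and library versions, convergence flags, bootstrap failure fractions
and all excluded rows, so every number in the output tables is regenerable
from the manifest alone. Input CSVs are validated row-by-row (counts within
bottle bounds, non-negative rates, positive diameters) with per-row
diagnostics; invalid rows are excluded and logged, empty or mis-schema'd
files are hard errors.

`scripts/acceptance.py` reports across-replicate summaries (mean; median for
fold-changes, which are heavy-tailed ratios) over 20 independently seeded
simulated experiments, fitting every curve with point estimates only. The
replicate average is the standard way to report a simulation-derived
estimate: it reduces Monte-Carlo error of the summary without touching the
per-experiment design (4 bottles × 20 females × 13 temperatures).

## Known limitations

- No time-to-death modelling; the two exposure durations are independent.
- No within-bottle overdispersion in the mortality model (binomial assumed).
- Egg rates are unweighted by surviving female counts per bottle.
- The candidate family registry ships with three families, not an exhaustive
  screen; AIC uses the least-squares form, appropriate only for comparing
  fits on identical data.
- Q10, thermal breadth and the recruitment tail are sensitive to the fitted
  Tmin, which the experimental grid (11 °C minimum) constrains only weakly.
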