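# Methods

## Model

Two treatments, α (new) and β (comparator), are compared for a binary
event *e* in a population split by a dichotomous pharmacogenomic marker
into marker-positive (A, prevalence *p*) and marker-negative (A′)
subgroups. Within each arm, the law of total probability ties the
marginal event risk to the subgroup risks:

    P[e | arm] = p · P[e | arm, A] + (1 − p) · P[e | arm, A′]

and the within-arm association risk ratio RR<sup>assoc</sup> =
P[e | arm, A] / P[e | arm, A′] fixes their ratio. Solving both per arm and
dividing gives the closed forms implemented in `estimand.py`:

    P[e | arm, A′] = P[e | arm] / (p · RR_assoc + 1 − p)
    RR_neg = RR_overall · (p · RR_assoc_β + 1 − p) / (p · RR_assoc_α + 1 − p)
    RR_pos = RR_neg · RR_assoc_α / RR_assoc_β

These are the unique subgroup treatment effects consistent with the
inputs, as the `oracle` module verifies by brute force: any fully
specified 2 × 2 × 2 population whose marginal summaries equal the inputs
has exactly these cell ratios (tested over 1,000 random populations to
1e−9, and independently via a root-finding solver in the test suite that
uses none of the closed forms).

Consequences worth knowing: RR_pos / RR_neg always equals
RR_assoc_α / RR_assoc_β, so the interaction is determined entirely by the
two association RRs; equal association RRs (a purely prognostic marker)
make both subgroup RRs collapse to RR_overall; and as *p* → 0 or 1 the
populated subgroup's RR tends to RR_overall while the other becomes an
extrapolation over an empty subgroup (returned, but flagged with
`ExtrapolationWarning`).

## Assumptions

- **Exchangeability** of the contributing studies: they must not differ on
  any modifier of the marker's prognostic or predictive effect. This is
  the method's dominant risk of bias; it is a narrative judgement, not a
  computation, so the package only attaches the reminder to every result
  bundle. The test suite demonstrates the closed-form bias that a
  non-exchangeable association RR induces.
- **Rare events** when hazard or odds ratios stand in for risk ratios.
  `check_rare_event_assumption` warns when a supplied marginal risk
  exceeds 10% (the conventional point at which the approximation degrades);
  the substitution is accepted with a warning rather than converted,
  because a principled conversion needs baseline-risk detail the inputs
  do not carry.
- Marker prevalence balanced between arms of the (hypothetical) trial —
  guaranteed in expectation by randomization.
- Jointly impossible inputs (a decomposition implying a subgroup risk
  ≥ 1) raise `InputInconsistencyError` rather than being clamped, since
  clamping would mask exactly the violations the warnings exist for.

## Uncertainty propagation

Ratio estimates are given lognormal distributions fitted from their
95% CIs: μ = ln(point), σ = (ln hi − ln lo) / (2z) with z = 1.959964 (six
decimals, so fit → CI round-trips are exact to float precision; the
difference from 1.96 is far below reporting precision). A degenerate CI
means σ = 0 and the parameter is held fixed. CIs that are asymmetric on
the log scale are fitted by the same symmetric formula — the fitting
recipe presumes log-symmetry, and published intervals rarely deviate
beyond rounding.

Probabilities take beta distributions: from an effective sample size
(a = pn, b = (1−p)n) or by method of moments from a CI (mean = point,
variance = ((hi − lo)/2z)²). The prevalence is **not** sampled unless it
opts in (`sample_uncertainty` or `effective_n`): the canonical use quotes
a prevalence without uncertainty, and silently inventing one would widen
the credible intervals untraceably.

`run_psa` draws all non-fixed inputs (default n_sims = 10,000; the
acceptance script uses 200,000) in a fixed order from a seeded numpy
Generator and applies the estimator vectorized, so a seed fully determines
the output. Credible intervals are equal-tailed percentile intervals with
linear interpolation between order statistics (numpy's default); the
convention is fixed because bounds reported at two decimals can straddle a
rounding boundary under other definitions. For the packaged case study the
marker-negative lower bound is such a case: the Monte Carlo/delta-method
value is ≈ 0.804, which prints as 0.80 at two decimals against the
published 0.88 (0.81–0.97) interval — agreement to within 0.01, at the
limit of what unstated simulation settings (percentile convention, n_sims)
can explain.

The interaction test exploits the identity above: because the indirect
construction makes RR_pos / RR_neg deterministic given the association
RRs, the test is a z-test on ln(RR_assoc_α / RR_assoc_β) with variance
σ_α² + σ_β² — pretending the subgroup draws carried extra information
would be wrong. The Monte Carlo direction probability
P(RR_pos < RR_neg) is reported alongside, and every report carries the
caution that indirect estimation's bias risk is not in the p-value.

## Sensitivity analysis

`run_sweep` re-evaluates the estimator over a grid of one (or two) inputs
with everything else pinned at point estimates — the deterministic
analysis a reader uses to translate "what if the association RR is really
1.4?" into subgroup treatment effects. Grids must be strictly increasing
and valid for the parameter before any evaluation runs. The packaged
default grid for the case study is RR_assoc_β from 1.0 to 2.0 in steps of
0.05, spanning the heterogeneity reported across association
meta-analyses (≈ 1.10–1.60) with margin. `crossover_threshold` locates
where a subgroup RR crosses 1 (Brent's method, tolerance 1e−8) after
checking monotonicity on a dense grid; a non-monotone response is reported
as ambiguous rather than returning an arbitrary root. Preferred-treatment
labels use strict RR < 1; exact ties are "indifferent".

## Trial simulator

`population_from_effects` parameterizes a stratified population by
(prevalence, comparator/marker-negative baseline risk, RR_assoc_β, RR_pos,
RR_neg) — deliberately the estimator's own coordinates, so round-trips
through `direct_subgroup_rr` are exact and the simulator cannot hide a
formula error. `simulate_trial` assigns marker status independently per
subject (balanced across arms in expectation; exact allocation available
for variance reduction) and draws events binomially per cell.
`estimate_from_counts` returns every RR the estimator consumes or
predicts, with log-normal CIs (SE = √(1/e₁ − 1/n₁ + 1/e₂ − 1/n₂)) and a
0.5 continuity correction for zero-event cells (flagged). The simulator
emulates a clean two-arm binomial trial: no censoring, no time-to-event
structure, no covariate confounding, no differential dropout — so
agreement between direct and indirect estimates here validates the
algebra and the finite-sample behaviour, not robustness to the
exchangeability violations real evidence bases suffer.

Problem sizes used by the shipped validation: 1,000 random populations for
exact inversion; 100 seeded replicates of 10⁶-subject-per-arm trials for
direct-vs-indirect coverage (≥ 93/100 of direct 95% CIs must cover the
indirect estimate recomputed from the same trial's marginal summaries);
10⁶ Monte Carlo replicates for the delta-method cross-check (log-scale
agreement within 0.005).

## Interface

Runs are described in YAML (see `pgxindirect example-config`), validated
strictly — unknown keys are rejected with their field path, and a fixed
parameter is written `fixed: 1.0`. Result bundles echo the inputs, carry
every warning, and record seed, n_sims and fitted distribution parameters
(μ, σ, a, b) so any published number is auditable and reproducible from
the bundle alone. Reports print full precision and two decimals; two
decimals is the comparison surface against published values.

## Known limitations

Dichotomous markers and outcomes only; risk-ratio scale only (no risk
differences or NNT); no meta-analytic handling of heterogeneous
association studies — the case-study literature itself reports unexplained
heterogeneity (association RRs ≈ 1.10–1.60), which is precisely what the
sensitivity sweep is for; no cost-effectiveness or value-of-information
layer, though the subgroup estimates are designed to feed one.
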