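"""Uncertainty parameterization and Monte Carlo propagation.

Published 95% confidence intervals are turned into sampling distributions —
lognormal for ratio-scale estimates, beta for probabilities — and propagated
through the indirect subgroup estimator by probabilistic sensitivity
analysis (PSA).  Equal-tailed percentile intervals of the resulting draws
are reported as credible intervals, and a test of interaction on the ratio
of the two association risk ratios quantifies whether the marker modifies
the treatment effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimand import EffectEstimate, Prevalence, Scenario, indirect_subgroup_rr

__all__ = [
    "LogNormalParams",
    "BetaParams",
    "PosteriorDraws",
    "InteractionTest",
    "fit_lognormal",
    "fit_beta",
    "run_psa",
    "credible_interval",
    "interaction_test",
]

# Two-sided standard-normal quantile for a 95% interval, kept at six
# decimals so that fit -> refit round-trips are reproducible to float
# precision rather than depending on an ad-hoc 1.96.
Z_95 = 1.959964


def _z_for_level(level: float) -> float:
    if level == 0.95:
        return Z_95
    return float(stats.norm.ppf(0.5 + level / 2.0))


@dataclass(frozen=True)
class LogNormalParams:
    """Log-scale location/spread of a fitted ratio estimate.

    ``sigma == 0`` marks a parameter held fixed at its point value.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = _z_for_level(level)
        return math.exp(self.mu - z * self.sigma), math.exp(self.mu + z * self.sigma)


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of a beta distribution fitted to a probability."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"beta shapes must be positive, got a={self.a}, b={self.b}")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)


@dataclass(frozen=True)
class PosteriorDraws:
    """Monte Carlo draws of the two subgroup treatment-effect RRs."""

    rr_marker_pos: np.ndarray
    rr_marker_neg: np.ndarray
    seed: int
    n_sims: int

    def __post_init__(self) -> None:
        if len(self.rr_marker_pos) != self.n_sims or len(self.rr_marker_neg) != self.n_sims:
            raise ValueError("draw vectors must have length n_sims")


def fit_lognormal(estimate: EffectEstimate) -> LogNormalParams:
    """Fit a lognormal to a ratio estimate from its symmetric-on-log CI.

    mu = ln(point); sigma = (ln(ci_high) - ln(ci_low)) / (2 z), with z the
    two-sided normal quantile for the CI level.  A degenerate CI
    (low = point = high) yields sigma = 0, i.e. a fixed parameter.

    Printed CIs that are asymmetric on the log scale are still fitted by
    this symmetric formula; the implied asymmetry ln(high/point) -
    ln(point/low) is not corrected (it is below reporting precision for
    typical published intervals).
    """
    z = _z_for_level(estimate.ci_level)
    mu = math.log(estimate.point)
    sigma = (math.log(estimate.ci_high) - math.log(estimate.ci_low)) / (2.0 * z)
    return LogNormalParams(mu=mu, sigma=sigma)


def fit_beta(prevalence: Prevalence, effective_n: float | None = None) -> BetaParams | None:
    """Fit a beta distribution to a prevalence.

    With ``effective_n``, the fit is the binomial-style a = p·n,
    b = (1-p)·n.  Otherwise, if the prevalence carries a CI, the beta is
    matched by method of moments to the point estimate (mean) and the
    CI-implied normal variance ((ci_high - ci_low) / 2z)².  With neither,
    the prevalence is treated as fixed and ``None`` is returned (no
    sampling).
    """
    p = prevalence.point
    if effective_n is not None:
        if effective_n <= 0:
            raise ValueError(f"effective_n must be positive, got {effective_n}")
        if not 0.0 < p < 1.0:
            raise ValueError("prevalence at 0 or 1 cannot be sampled; treat as fixed")
        return BetaParams(a=p * effective_n, b=(1.0 - p) * effective_n)
    if prevalence.has_ci:
        if not 0.0 < p < 1.0:
            raise ValueError("prevalence at 0 or 1 cannot be sampled; treat as fixed")
        sd = (prevalence.ci_high - prevalence.ci_low) / (2.0 * Z_95)
        var = sd * sd
        if var >= p * (1.0 - p):
            raise ValueError(
                f"CI-implied variance {var:.4g} is incompatible with a beta "
                f"distribution of mean {p}"
            )
        nu = p * (1.0 - p) / var - 1.0  # a + b
        return BetaParams(a=p * nu, b=(1.0 - p) * nu)
    return None


def run_psa(
    scenario: Scenario,
    n_sims: int = 10_000,
    seed: int | None = None,
    prevalence_effective_n: float | None = None,
) -> PosteriorDraws:
    """Propagate input uncertainty by Monte Carlo simulation.

    Each replicate draws every non-fixed input from its fitted distribution
    (lognormal for the three risk ratios; beta for the prevalence only when
    it opts into sampling) and applies the indirect subgroup estimator.
    Fixed inputs (sigma = 0, or prevalence without uncertainty) are held at
    their point values.  Identical ``seed`` and ``n_sims`` give bit-identical
    draws.

    Parameters
    ----------
    scenario
        Validated input bundle.
    n_sims
        Number of Monte Carlo replicates (default 10,000).
    seed
        Seed for the random generator; required for reproducibility and
        recorded in the output.
    prevalence_effective_n
        Optional effective sample size to sample the prevalence from a
        beta distribution even without a CI.
    """
    if n_sims < 1:
        raise ValueError(f"n_sims must be >= 1, got {n_sims}")
    if seed is None:
        raise ValueError("a seed is required for every stochastic operation")
    rng = np.random.default_rng(seed)

    def draw_rr(estimate: EffectEstimate) -> np.ndarray:
        params = fit_lognormal(estimate)
        if params.sigma == 0.0:
            return np.full(n_sims, estimate.point)
        return rng.lognormal(mean=params.mu, sigma=params.sigma, size=n_sims)

    # Draw order is fixed: rr_overall, rr_assoc_alpha, rr_assoc_beta,
    # prevalence — part of the reproducibility contract.
    rr_overall = draw_rr(scenario.rr_overall)
    rr_assoc_alpha = draw_rr(scenario.rr_assoc_alpha)
    rr_assoc_beta = draw_rr(scenario.rr_assoc_beta)

    sample_prev = scenario.prevalence.sample_uncertainty or prevalence_effective_n is not None
    if sample_prev:
        beta = fit_beta(scenario.prevalence, effective_n=prevalence_effective_n)
        prev = rng.beta(beta.a, beta.b, size=n_sims)
    else:
        prev = np.full(n_sims, scenario.prevalence.point)

    # Vectorized form of indirect_subgroup_rr.
    rr_neg = rr_overall * (prev * rr_assoc_beta + 1.0 - prev) / (
        prev * rr_assoc_alpha + 1.0 - prev
    )
    rr_pos = rr_neg * rr_assoc_alpha / rr_assoc_beta

    # Defensive: cannot trigger for positive lognormal/beta draws, but any
    # inconsistent replicate is reported by index rather than silently kept.
    bad = ~(np.isfinite(rr_pos) & np.isfinite(rr_neg) & (rr_pos > 0) & (rr_neg > 0))
    if bad.any():
        idx = np.flatnonzero(bad)
        raise RuntimeError(
            f"{len(idx)} of {n_sims} PSA replicates produced invalid outputs "
            f"(first failing replicate index: {idx[0]})"
        )
    return PosteriorDraws(
        rr_marker_pos=rr_pos, rr_marker_neg=rr_neg, seed=seed, n_sims=n_sims
    )


def credible_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval of Monte Carlo draws.

    Percentiles use linear interpolation between order statistics (numpy's
    default definition); the choice is fixed because interval bounds
    reported at two decimals can depend on it.
    """
    draws = np.asarray(draws)
    if draws.size == 0:
        raise ValueError("cannot compute a credible interval from empty draws")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0,1), got {level}")
    tail = 100.0 * (1.0 - level) / 2.0
    low, high = np.percentile(draws, [tail, 100.0 - tail])
    return float(low), float(high)


#: Caution attached to every interaction-test report: the indirect
#: construction inherits the biases of the contributing studies, so a small
#: p-value must not be read with the confidence a stratified RCT would earn.
INTERACTION_CAVEAT = (
    "Caution: this interaction test is computed from indirectly estimated "
    "subgroup effects; the risk of bias inherent in indirect estimation "
    "(non-exchangeable studies, biased inputs) is not reflected in the "
    "p-value, so statistical significance must be interpreted carefully."
)


@dataclass(frozen=True)
class InteractionTest:
    """Test of interaction on the ratio of subgroup treatment effects."""

    z: float
    p: float
    mc_prob: float
    report: str


def interaction_test(scenario: Scenario, draws: PosteriorDraws) -> InteractionTest:
    """Test whether the marker modifies the treatment effect.

    Because the indirect construction makes the ratio of the subgroup RRs
    algebraically equal to the ratio of the two association RRs
    (RR_pos / RR_neg = RR_assoc_alpha / RR_assoc_beta), the interaction test
    reduces to a z-test on that ratio on the log scale:

        z = (mu_alpha - mu_beta) / sqrt(sigma_alpha² + sigma_beta²)

    with a two-sided normal p-value.  ``mc_prob`` is the Monte Carlo
    probability that the marker-positive subgroup has the smaller RR
    (fraction of PSA replicates with RR_pos < RR_neg), a direction-of-effect
    summary consistent with the z-test.
    """
    pa = fit_lognormal(scenario.rr_assoc_alpha)
    pb = fit_lognormal(scenario.rr_assoc_beta)
    var = pa.sigma**2 + pb.sigma**2
    if var == 0.0:
        raise ValueError(
            "interaction test undefined: both association RRs are fixed "
            "(zero sampling variance)"
        )
    z = (pa.mu - pb.mu) / math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    mc_prob = float(np.mean(draws.rr_marker_pos < draws.rr_marker_neg))
    report = (
        f"Interaction (ratio of subgroup RRs, log scale): z = {z:.3f}, "
        f"two-sided p = {p:.3g}; Monte Carlo P(RR_pos < RR_neg) = {mc_prob:.4f} "
        f"({draws.n_sims} replicates, seed {draws.seed}). {INTERACTION_CAVEAT}"
    )
    return InteractionTest(z=z, p=p, mc_prob=mc_prob, report=report)
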