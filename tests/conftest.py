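import numpy as np
import pytest
from scipy import optimize

from pgxindirect import Scenario, case_study_scenario
from pgxindirect.oracle import StratifiedPopulation


@pytest.fixture
def case_study() -> Scenario:
    return case_study_scenario()


def brute_force_subgroup_rr(
    rr_overall: float,
    rr_assoc_alpha: float,
    rr_assoc_beta: float,
    prevalence: float,
    baseline_risk: float = 0.05,
) -> tuple[float, float]:
    """Independent oracle: solve for the subgroup RRs numerically.

    Constructs the comparator arm from the baseline risk and its
    association RR, then root-finds the treatment arm's marker-negative
    risk so that (a) the within-arm association RR is rr_assoc_alpha and
    (b) the ratio of prevalence-weighted marginal risks equals rr_overall.
    Uses no formula from the estimand module.
    """
    p = prevalence
    risk_beta_neg = baseline_risk
    risk_beta_pos = rr_assoc_beta * baseline_risk
    marginal_beta = p * risk_beta_pos + (1.0 - p) * risk_beta_neg

    def mismatch(risk_alpha_neg: float) -> float:
        risk_alpha_pos = rr_assoc_alpha * risk_alpha_neg
        marginal_alpha = p * risk_alpha_pos + (1.0 - p) * risk_alpha_neg
        return marginal_alpha / marginal_beta - rr_overall

    risk_alpha_neg = optimize.brentq(mismatch, 1e-12, 1.0 - 1e-12, xtol=1e-15)
    risk_alpha_pos = rr_assoc_alpha * risk_alpha_neg
    return risk_alpha_pos / risk_beta_pos, risk_alpha_neg / risk_beta_neg


@pytest.fixture
def brute_force_oracle():
    return brute_force_subgroup_rr


def random_population(rng: np.random.Generator) -> StratifiedPopulation:
    """A random valid stratified population (all four cell risks in (0,1))."""
    prevalence = rng.uniform(0.02, 0.98)
    risk = {
        (arm, marker): rng.uniform(0.005, 0.6)
        for arm in ("alpha", "beta")
        for marker in ("pos", "neg")
    }
    return StratifiedPopulation(prevalence=prevalence, risk=risk)
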