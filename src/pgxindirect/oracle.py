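"""Stratified-population oracle and finite-trial simulator.

A fully specified 2 (arm) x 2 (marker) x 2 (event) population makes every
quantity of the indirect estimator — subgroup treatment effects,
within-arm association RRs, marginal risks, the overall treatment effect —
exactly computable by brute force.  It therefore serves as the independent
oracle against which the closed-form indirect reconstruction is checked,
and as the generative model for simulating finite stratified RCTs (the
hypothetical trial embodying the known treatment and marker
characteristics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimand import EffectEstimate, InputInconsistencyError
from .uncertainty import Z_95

__all__ = [
    "ARMS",
    "MARKERS",
    "StratifiedPopulation",
    "TrialCounts",
    "PopulationRatios",
    "TrialEstimates",
    "population_from_effects",
    "direct_subgroup_rr",
    "simulate_trial",
    "estimate_from_counts",
]

ARMS = ("alpha", "beta")
MARKERS = ("pos", "neg")


@dataclass(frozen=True)
class StratifiedPopulation:
    """Population defined by marker prevalence and four cell event risks.

    ``risk[(arm, marker)]`` is P[event | arm, marker]; prevalence is assumed
    balanced between arms.
    """

    prevalence: float
    risk: dict[tuple[str, str], float]
    size: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must lie in [0,1], got {self.prevalence}")
        expected = {(a, m) for a in ARMS for m in MARKERS}
        if set(self.risk) != expected:
            raise ValueError(f"risk must have exactly the keys {sorted(expected)}")
        for cell, r in self.risk.items():
            if not 0.0 < r < 1.0:
                raise ValueError(f"risk{cell} = {r} must lie in (0,1)")

    def marginal_risk(self, arm: str) -> float:
        """P[event | arm], aggregating markers by prevalence."""
        p = self.prevalence
        return p * self.risk[(arm, "pos")] + (1.0 - p) * self.risk[(arm, "neg")]


@dataclass(frozen=True)
class TrialCounts:
    """Events and totals per (arm, marker) cell of a finite trial."""

    events: dict[tuple[str, str], int]
    totals: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        expected = {(a, m) for a in ARMS for m in MARKERS}
        if set(self.events) != expected or set(self.totals) != expected:
            raise ValueError(f"events and totals must have the keys {sorted(expected)}")
        for cell in expected:
            e, n = self.events[cell], self.totals[cell]
            if e < 0 or n < 0 or e > n:
                raise ValueError(f"cell {cell}: need 0 <= events <= total, got {e}/{n}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"arm": a, "marker": m, "events": self.events[(a, m)], "total": self.totals[(a, m)]}
            for a in ARMS
            for m in MARKERS
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialCounts":
        df = pd.read_csv(path)
        events = {(r.arm, r.marker): int(r.events) for r in df.itertuples()}
        totals = {(r.arm, r.marker): int(r.total) for r in df.itertuples()}
        return cls(events=events, totals=totals)


def population_from_effects(
    prevalence: float,
    baseline_risk: float,
    rr_assoc_beta: float,
    rr_pos: float,
    rr_neg: float,
) -> StratifiedPopulation:
    """Build a population from the estimator's own parameterization.

    ``baseline_risk`` anchors the comparator arm's marker-negative cell;
    the remaining cells follow from the comparator-arm association RR and
    the two subgroup treatment-effect RRs:

        risk[beta, neg]  = baseline_risk
        risk[beta, pos]  = rr_assoc_beta * baseline_risk
        risk[alpha, pos] = rr_pos * risk[beta, pos]
        risk[alpha, neg] = rr_neg * risk[beta, neg]

    This mirrors the indirect estimator's inputs, so round-trips through
    :func:`direct_subgroup_rr` are exact.  Any derived risk outside (0,1)
    is rejected with the offending cell named.
    """
    risk = {
        ("beta", "neg"): baseline_risk,
        ("beta", "pos"): rr_assoc_beta * baseline_risk,
    }
    risk[("alpha", "pos")] = rr_pos * risk[("beta", "pos")]
    risk[("alpha", "neg")] = rr_neg * risk[("beta", "neg")]
    for cell, r in risk.items():
        if not 0.0 < r < 1.0:
            raise InputInconsistencyError(
                f"derived risk{cell} = {r:.6g} lies outside (0,1); inputs "
                f"(prevalence={prevalence}, baseline_risk={baseline_risk}, "
                f"rr_assoc_beta={rr_assoc_beta}, rr_pos={rr_pos}, rr_neg={rr_neg}) "
                f"are inconsistent"
            )
    return StratifiedPopulation(prevalence=prevalence, risk=risk)


@dataclass(frozen=True)
class PopulationRatios:
    """Exact ratios computed directly from a stratified population."""

    rr_pos: float
    rr_neg: float
    rr_overall: float
    rr_assoc_alpha: float
    rr_assoc_beta: float


def direct_subgroup_rr(pop: StratifiedPopulation) -> PopulationRatios:
    """All five risk ratios, computed exactly from the population cells.

    The direct route: subgroup treatment-effect RRs are cell-by-cell
    ratios, the association RRs compare markers within an arm, and the
    overall RR is the ratio of prevalence-weighted marginal risks.  Feeding
    (rr_overall, rr_assoc_alpha, rr_assoc_beta, prevalence) back through the
    indirect estimator must recover (rr_pos, rr_neg).
    """
    r = pop.risk
    return PopulationRatios(
        rr_pos=r[("alpha", "pos")] / r[("beta", "pos")],
        rr_neg=r[("alpha", "neg")] / r[("beta", "neg")],
        rr_overall=pop.marginal_risk("alpha") / pop.marginal_risk("beta"),
        rr_assoc_alpha=r[("alpha", "pos")] / r[("alpha", "neg")],
        rr_assoc_beta=r[("beta", "pos")] / r[("beta", "neg")],
    )


def simulate_trial(
    pop: StratifiedPopulation,
    n_per_arm: int,
    seed: int,
    exact_allocation: bool = False,
) -> TrialCounts:
    """Simulate a finite two-arm trial from a stratified population.

    Marker status is assigned independently per subject at the population
    prevalence — identically distributed across arms, so prevalence is
    balanced between arms in expectation.  ``exact_allocation=True``
    instead assigns exactly round(n_per_arm * prevalence) marker-positive
    subjects per arm (variance reduction for simulation studies).  Events
    are then binomial within each cell.  Reproducible under ``seed``.
    """
    if n_per_arm < 1:
        raise ValueError(f"n_per_arm must be >= 1, got {n_per_arm}")
    rng = np.random.default_rng(seed)
    events: dict[tuple[str, str], int] = {}
    totals: dict[tuple[str, str], int] = {}
    for arm in ARMS:
        if exact_allocation:
            n_pos = round(n_per_arm * pop.prevalence)
        else:
            n_pos = int(rng.binomial(n_per_arm, pop.prevalence))
        totals[(arm, "pos")] = n_pos
        totals[(arm, "neg")] = n_per_arm - n_pos
        for marker in MARKERS:
            n_cell = totals[(arm, marker)]
            events[(arm, marker)] = int(rng.binomial(n_cell, pop.risk[(arm, marker)])) if n_cell else 0
    return TrialCounts(events=events, totals=totals)


@dataclass(frozen=True)
class TrialEstimates:
    """Scenario-like summary estimated from finite trial counts.

    Holds point estimates and 95% CIs for the overall treatment effect, the
    per-arm association RRs, and the *direct* subgroup treatment-effect RRs
    from the same trial — everything needed for an end-to-end
    indirect-vs-direct comparison.  ``prevalence`` is the pooled
    marker-positive fraction.  ``flags`` records cells that needed a 0.5
    continuity correction or were fully degenerate.
    """

    rr_overall: EffectEstimate
    rr_assoc_alpha: EffectEstimate
    rr_assoc_beta: EffectEstimate
    rr_pos: EffectEstimate
    rr_neg: EffectEstimate
    prevalence: float
    flags: list[str] = field(default_factory=list)


def _rr_with_ci(
    e1: float, n1: float, e2: float, n2: float, flags: list[str], label: str
) -> EffectEstimate:
    """Ratio of proportions e1/n1 over e2/n2 with a log-normal 95% CI.

    SE(log RR) = sqrt(1/e1 - 1/n1 + 1/e2 - 1/n2).  Zero-event cells get a
    0.5 continuity correction (added to events and totals of both cells of
    the comparison), recorded in ``flags``.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError(f"{label}: zero denominator")
    if e1 == 0 or e2 == 0:
        flags.append(f"{label}: zero-event cell, 0.5 continuity correction applied")
        e1, n1, e2, n2 = e1 + 0.5, n1 + 0.5, e2 + 0.5, n2 + 0.5
    if e1 == n1 or e2 == n2:
        flags.append(f"{label}: all-events cell; log-RR standard error unreliable")
    point = (e1 / n1) / (e2 / n2)
    se = math.sqrt(max(1.0 / e1 - 1.0 / n1 + 1.0 / e2 - 1.0 / n2, 0.0))
    return EffectEstimate(
        point=point,
        ci_low=point * math.exp(-Z_95 * se),
        ci_high=point * math.exp(Z_95 * se),
    )


def estimate_from_counts(counts: TrialCounts) -> TrialEstimates:
    """Estimate every scenario-level and subgroup-level RR from one trial.

    Returns the overall treatment-effect RR (from arm marginals), the
    within-arm association RRs, and the direct subgroup treatment-effect
    RRs, each with a log-normal 95% CI, plus the pooled marker prevalence.
    """
    e, n = counts.events, counts.totals
    flags: list[str] = []
    arm_events = {a: e[(a, "pos")] + e[(a, "neg")] for a in ARMS}
    arm_totals = {a: n[(a, "pos")] + n[(a, "neg")] for a in ARMS}
    for a in ARMS:
        if arm_totals[a] == 0:
            raise ValueError(f"arm {a!r} has no subjects")
    rr_overall = _rr_with_ci(
        arm_events["alpha"], arm_totals["alpha"],
        arm_events["beta"], arm_totals["beta"],
        flags, "rr_overall",
    )
    rr_assoc_alpha = _rr_with_ci(
        e[("alpha", "pos")], n[("alpha", "pos")],
        e[("alpha", "neg")], n[("alpha", "neg")],
        flags, "rr_assoc_alpha",
    )
    rr_assoc_beta = _rr_with_ci(
        e[("beta", "pos")], n[("beta", "pos")],
        e[("beta", "neg")], n[("beta", "neg")],
        flags, "rr_assoc_beta",
    )
    rr_pos = _rr_with_ci(
        e[("alpha", "pos")], n[("alpha", "pos")],
        e[("beta", "pos")], n[("beta", "pos")],
        flags, "rr_pos",
    )
    rr_neg = _rr_with_ci(
        e[("alpha", "neg")], n[("alpha", "neg")],
        e[("beta", "neg")], n[("beta", "neg")],
        flags, "rr_neg",
    )
    prevalence = (n[("alpha", "pos")] + n[("beta", "pos")]) / (
        arm_totals["alpha"] + arm_totals["beta"]
    )
    return TrialEstimates(
        rr_overall=rr_overall,
        rr_assoc_alpha=rr_assoc_alpha,
        rr_assoc_beta=rr_assoc_beta,
        rr_pos=rr_pos,
        rr_neg=rr_neg,
        prevalence=prevalence,
        flags=flags,
    )
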