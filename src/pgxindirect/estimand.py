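"""Core estimands and closed-form formulas for indirect subgroup estimation.

The setting: two treatments are compared for a binary clinical event, and a
dichotomous pharmacogenomic marker (e.g. carriage of a CYP2C19
loss-of-function allele) splits the population into a marker-positive (A)
and a marker-negative (A') subgroup.  A conventional (unstratified) RCT
gives the overall treatment-effect risk ratio; observational association
studies give, within each treatment arm, the risk ratio of the event for
marker-positive vs marker-negative patients; and the marker prevalence is
known.  The law of total probability links the marginal event risk in an
arm to the two conditional (subgroup) risks, which lets the subgroup
treatment effects be recovered *indirectly* without a stratified trial.

Direction conventions (fixed throughout the package):

* arm ``alpha`` is the new treatment, arm ``beta`` the comparator;
  ``rr_overall`` compares alpha vs beta, so values < 1 favour alpha;
* association risk ratios compare marker-positive (A) vs marker-negative
  (A') *within* one arm.

All computation is done at full precision; rounding to two decimals happens
only in the reporting layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "EffectEstimate",
    "Prevalence",
    "Scenario",
    "SubgroupEffect",
    "InputInconsistencyError",
    "ExtrapolationWarning",
    "DEFAULT_LABELS",
    "decompose_marginal_risk",
    "indirect_subgroup_rr",
    "subgroup_risk_table",
    "check_rare_event_assumption",
    "case_study_scenario",
]


class InputInconsistencyError(ValueError):
    """Raised when inputs are individually valid but jointly impossible.

    The classic case: a marginal risk, prevalence and association RR that
    together imply a subgroup event probability >= 1.  Such combinations are
    rejected rather than clamped, because clamping would silently hide a
    violated rare-event (HR/OR ~ RR) approximation.
    """


class ExtrapolationWarning(UserWarning):
    """A subgroup estimate refers to a subgroup with no members.

    At prevalence 0 (or 1) the marker-positive (resp. marker-negative)
    subgroup is empty; its RR is still algebraically defined but is an
    extrapolation beyond the observable mixture.
    """


@dataclass(frozen=True)
class EffectEstimate:
    """A ratio-scale effect estimate (risk ratio, or HR/OR used as an RR
    stand-in) with its two-sided confidence interval.

    Invariant: 0 < ci_low <= point <= ci_high.  A parameter fixed by
    assumption (e.g. "no association in the comparator-free arm") is encoded
    with ``ci_low == point == ci_high``.
    """

    point: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not (self.ci_low > 0 and self.point > 0 and self.ci_high > 0):
            raise ValueError(
                f"effect estimates are ratio-scale and must be strictly positive, "
                f"got point={self.point}, ci=({self.ci_low}, {self.ci_high})"
            )
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError(
                f"confidence interval ({self.ci_low}, {self.ci_high}) does not "
                f"bracket the point estimate {self.point}"
            )
        if not 0 < self.ci_level < 1:
            raise ValueError(f"ci_level must be in (0,1), got {self.ci_level}")

    @classmethod
    def fixed(cls, value: float) -> "EffectEstimate":
        """An estimate held fixed by assumption (degenerate CI)."""
        return cls(point=value, ci_low=value, ci_high=value)

    @property
    def is_fixed(self) -> bool:
        return self.ci_low == self.point == self.ci_high


@dataclass(frozen=True)
class Prevalence:
    """Marker-positive probability P[A], optionally with sampling uncertainty.

    ``sample_uncertainty`` opts the prevalence into Monte Carlo sampling
    (it is held fixed by default, matching the common situation where a
    prevalence is quoted without an interval).
    """

    point: float
    ci_low: float | None = None
    ci_high: float | None = None
    sample_uncertainty: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.point <= 1.0:
            raise ValueError(f"prevalence must lie in [0,1], got {self.point}")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError("prevalence CI requires both bounds")
        if self.ci_low is not None:
            if not (0.0 <= self.ci_low <= self.point <= self.ci_high <= 1.0):
                raise ValueError(
                    f"prevalence CI ({self.ci_low}, {self.ci_high}) must lie in "
                    f"[0,1] and bracket the point estimate {self.point}"
                )
        if self.sample_uncertainty and self.ci_low is None:
            raise ValueError(
                "sample_uncertainty=True requires a CI (or supply effective_n "
                "when fitting the beta distribution)"
            )

    @property
    def has_ci(self) -> bool:
        return self.ci_low is not None


DEFAULT_LABELS: dict[str, str] = {
    "arm_alpha": "treatment",
    "arm_beta": "comparator",
    "marker_pos": "marker-positive",
    "marker_neg": "marker-negative",
}


@dataclass(frozen=True)
class Scenario:
    """The full input bundle for an indirect subgroup analysis."""

    prevalence: Prevalence
    rr_assoc_alpha: EffectEstimate  # marker A vs A' under treatment alpha
    rr_assoc_beta: EffectEstimate   # marker A vs A' under comparator beta
    rr_overall: EffectEstimate      # alpha vs beta, unstratified
    marginal_risk_alpha: float | None = None  # P[e | alpha]
    marginal_risk_beta: float | None = None   # P[e | beta]
    labels: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_LABELS))

    def __post_init__(self) -> None:
        for name, risk in (
            ("marginal_risk_alpha", self.marginal_risk_alpha),
            ("marginal_risk_beta", self.marginal_risk_beta),
        ):
            if risk is not None and not 0.0 < risk < 1.0:
                raise ValueError(f"{name} must lie in (0,1), got {risk}")
        unknown = set(self.labels) - set(DEFAULT_LABELS)
        if unknown:
            raise ValueError(f"unknown label keys: {sorted(unknown)}")


@dataclass(frozen=True)
class SubgroupEffect:
    """Indirect treatment-effect RRs per marker subgroup.

    ``risk_by_arm_and_marker`` maps ``(arm, marker)`` with arm in
    {"alpha","beta"} and marker in {"pos","neg"} to P[e | arm, marker]; it is
    present only when marginal risks were supplied.
    """

    rr_marker_pos: float
    rr_marker_neg: float
    risk_by_arm_and_marker: dict[tuple[str, str], float] | None = None
    ci_marker_pos: tuple[float, float] | None = None
    ci_marker_neg: tuple[float, float] | None = None


def decompose_marginal_risk(
    marginal_risk: float, prevalence: float, rr_assoc: float
) -> tuple[float, float]:
    """Split a marginal event risk into subgroup risks within one arm.

    By total probability, P[e] = P[A]·P[e|A] + (1-P[A])·P[e|A'], and by the
    association risk ratio, P[e|A] = RR_assoc · P[e|A'].  Solving:

        P[e|A'] = P[e] / (P[A]·RR_assoc + 1 - P[A])
        P[e|A]  = RR_assoc · P[e|A']

    Returns ``(risk_marker_pos, risk_marker_neg)``.

    Raises
    ------
    ValueError
        If ``marginal_risk`` is outside (0,1) or ``rr_assoc`` is not positive.
    InputInconsistencyError
        If the implied marker-positive risk is >= 1 (the inputs are jointly
        impossible for a probability).
    """
    if not 0.0 < marginal_risk < 1.0:
        raise ValueError(f"marginal_risk must lie in (0,1), got {marginal_risk}")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must lie in [0,1], got {prevalence}")
    if rr_assoc <= 0:
        raise ValueError(f"rr_assoc must be strictly positive, got {rr_assoc}")

    risk_neg = marginal_risk / (prevalence * rr_assoc + 1.0 - prevalence)
    risk_pos = rr_assoc * risk_neg
    if risk_pos >= 1.0 or risk_neg >= 1.0:
        raise InputInconsistencyError(
            f"marginal_risk={marginal_risk}, prevalence={prevalence}, "
            f"rr_assoc={rr_assoc} imply subgroup risks "
            f"(pos={risk_pos:.6g}, neg={risk_neg:.6g}); probabilities must be < 1"
        )
    return risk_pos, risk_neg


def indirect_subgroup_rr(
    rr_overall: float,
    rr_assoc_alpha: float,
    rr_assoc_beta: float,
    prevalence: float,
) -> tuple[float, float]:
    """Indirectly estimate the per-subgroup treatment-effect risk ratios.

    Writing p for the prevalence, the marginal risks in each arm are
    prevalence-weighted mixtures of the subgroup risks, so the overall RR
    relates to the subgroup RRs through the two association RRs:

        RR_neg = RR_overall · (p·RR_assoc_beta + 1 - p) / (p·RR_assoc_alpha + 1 - p)
        RR_pos = RR_neg · RR_assoc_alpha / RR_assoc_beta

    Returns ``(rr_marker_pos, rr_marker_neg)``.

    At prevalence 0 (or 1) the marker-positive (resp. marker-negative)
    subgroup is empty; its value is still returned but an
    :class:`ExtrapolationWarning` is emitted.
    """
    for name, value in (
        ("rr_overall", rr_overall),
        ("rr_assoc_alpha", rr_assoc_alpha),
        ("rr_assoc_beta", rr_assoc_beta),
    ):
        if value <= 0:
            raise ValueError(f"{name} must be strictly positive, got {value}")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must lie in [0,1], got {prevalence}")

    rr_neg = (
        rr_overall
        * (prevalence * rr_assoc_beta + 1.0 - prevalence)
        / (prevalence * rr_assoc_alpha + 1.0 - prevalence)
    )
    rr_pos = rr_neg * rr_assoc_alpha / rr_assoc_beta

    if prevalence == 0.0:
        warnings.warn(
            "prevalence is 0: the marker-positive subgroup has no members; "
            "its RR is an extrapolation",
            ExtrapolationWarning,
            stacklevel=2,
        )
    elif prevalence == 1.0:
        warnings.warn(
            "prevalence is 1: the marker-negative subgroup has no members; "
            "its RR is an extrapolation",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return rr_pos, rr_neg


def subgroup_risk_table(scenario: Scenario) -> SubgroupEffect:
    """Full indirect subgroup analysis of a scenario at point estimates.

    Always computes the two subgroup treatment-effect RRs; when marginal
    event risks are supplied for the arms, additionally decomposes each
    arm's marginal risk into the four P[e | arm, marker] cells.
    """
    p = scenario.prevalence.point
    rr_pos, rr_neg = indirect_subgroup_rr(
        scenario.rr_overall.point,
        scenario.rr_assoc_alpha.point,
        scenario.rr_assoc_beta.point,
        p,
    )
    risks: dict[tuple[str, str], float] | None = None
    if scenario.marginal_risk_alpha is not None or scenario.marginal_risk_beta is not None:
        risks = {}
        if scenario.marginal_risk_alpha is not None:
            a_pos, a_neg = decompose_marginal_risk(
                scenario.marginal_risk_alpha, p, scenario.rr_assoc_alpha.point
            )
            risks[("alpha", "pos")] = a_pos
            risks[("alpha", "neg")] = a_neg
        if scenario.marginal_risk_beta is not None:
            b_pos, b_neg = decompose_marginal_risk(
                scenario.marginal_risk_beta, p, scenario.rr_assoc_beta.point
            )
            risks[("beta", "pos")] = b_pos
            risks[("beta", "neg")] = b_neg
    return SubgroupEffect(
        rr_marker_pos=rr_pos, rr_marker_neg=rr_neg, risk_by_arm_and_marker=risks
    )


def check_rare_event_assumption(
    scenario: Scenario, threshold: float = 0.10
) -> list[str]:
    """Warn where marginal event risks are too large for HR/OR ~ RR.

    Hazard and odds ratios approximate risk ratios only when the event is
    rare (baseline risk below roughly 10%).  Returns one warning string per
    supplied marginal risk strictly exceeding ``threshold``; an empty list
    if none do or none are supplied.
    """
    out: list[str] = []
    for arm_key, risk in (
        ("arm_alpha", scenario.marginal_risk_alpha),
        ("arm_beta", scenario.marginal_risk_beta),
    ):
        if risk is not None and risk > threshold:
            arm = scenario.labels.get(arm_key, arm_key)
            out.append(
                f"marginal event risk {risk:.3g} in arm '{arm}' exceeds "
                f"{threshold:.3g}: substituting a hazard or odds ratio for the "
                f"risk ratio may be invalid at this event rate"
            )
    return out


def case_study_scenario() -> Scenario:
    """The packaged CYP2C19/clopidogrel-vs-ticagrelor scenario.

    Ticagrelor (alpha) vs clopidogrel (beta) for cardiovascular events after
    acute coronary syndrome: overall hazard ratio 0.84 (0.77-0.92) used as a
    risk ratio; association RR for CYP2C19 LoF carriers vs non-carriers on
    clopidogrel 1.18 (1.09-1.28); no genotype effect assumed off clopidogrel
    (RR fixed at 1); LoF carriage prevalence 28.0%.
    """
    return Scenario(
        prevalence=Prevalence(point=0.28),
        rr_assoc_alpha=EffectEstimate.fixed(1.0),
        rr_assoc_beta=EffectEstimate(point=1.18, ci_low=1.09, ci_high=1.28),
        rr_overall=EffectEstimate(point=0.84, ci_low=0.77, ci_high=0.92),
        labels={
            "arm_alpha": "ticagrelor",
            "arm_beta": "clopidogrel",
            "marker_pos": "CYP2C19 LoF carrier",
            "marker_neg": "CYP2C19 LoF non-carrier",
        },
    )
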