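"""Deterministic one-way and two-way sensitivity analysis.

Sweeps one (or two) scenario inputs over a grid while pinning every other
input at its point estimate, re-evaluating the indirect subgroup
treatment-effect RRs at each grid point.  This is the classic way to
translate an uncertain association-study effect size into a range of
plausible subgroup treatment effects, and to locate the crossover value at
which a subgroup's preferred treatment flips.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .estimand import EffectEstimate, Prevalence, Scenario, indirect_subgroup_rr

__all__ = [
    "SWEEPABLE_PARAMETERS",
    "SweepGrid",
    "SweepResult",
    "run_sweep",
    "crossover_threshold",
    "plot_sweep",
]

SWEEPABLE_PARAMETERS = ("prevalence", "rr_overall", "rr_assoc_alpha", "rr_assoc_beta")


def _with_value(scenario: Scenario, name: str, value: float) -> Scenario:
    """Scenario with one input pinned at ``value`` (degenerate uncertainty)."""
    if name == "prevalence":
        return replace(scenario, prevalence=Prevalence(point=float(value)))
    if name in ("rr_overall", "rr_assoc_alpha", "rr_assoc_beta"):
        return replace(scenario, **{name: EffectEstimate.fixed(float(value))})
    raise ValueError(
        f"unknown sweep parameter {name!r}; expected one of {SWEEPABLE_PARAMETERS}"
    )


def _validate_values(name: str, values: Sequence[float]) -> np.ndarray:
    if name not in SWEEPABLE_PARAMETERS:
        raise ValueError(
            f"unknown sweep parameter {name!r}; expected one of {SWEEPABLE_PARAMETERS}"
        )
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError(f"empty value grid for {name!r}")
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise ValueError(f"grid values for {name!r} must be strictly increasing")
    if name == "prevalence":
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("prevalence grid values must lie in [0,1]")
    elif np.any(arr <= 0):
        raise ValueError(f"{name!r} grid values must be strictly positive")
    return arr


@dataclass(frozen=True)
class SweepGrid:
    """Grid over one (or, for two-way sweeps, two) scenario inputs."""

    parameter_name: str
    values: Sequence[float]
    second_parameter: str | None = None
    second_values: Sequence[float] | None = None

    def __post_init__(self) -> None:
        _validate_values(self.parameter_name, self.values)
        if (self.second_parameter is None) != (self.second_values is None):
            raise ValueError("a second parameter requires its own value grid")
        if self.second_parameter is not None:
            if self.second_parameter == self.parameter_name:
                raise ValueError("two-way sweep parameters must differ")
            _validate_values(self.second_parameter, self.second_values)


@dataclass(frozen=True)
class SweepResult:
    """One record per grid point, in grid order."""

    rows: pd.DataFrame

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def _preferred(rr: float, labels: dict[str, str]) -> str:
    # Strict RR < 1 prefers the treatment arm (lower event risk); RR = 1 is
    # indifference, not a preference.
    if rr < 1.0:
        return labels.get("arm_alpha", "alpha")
    if rr > 1.0:
        return labels.get("arm_beta", "beta")
    return "indifferent"


def run_sweep(scenario: Scenario, grid: SweepGrid) -> SweepResult:
    """Evaluate the indirect subgroup RRs at every grid point.

    All non-swept inputs are held at their point estimates (deterministic
    analysis).  Grid values are validated before any evaluation.  For
    two-way grids the rows iterate the second parameter fastest.
    """
    first = _validate_values(grid.parameter_name, grid.values)
    if grid.second_parameter is not None:
        second = _validate_values(grid.second_parameter, grid.second_values)
        points: Iterable[tuple[float, ...]] = (
            (v1, v2) for v1 in first for v2 in second
        )
        param_cols = [grid.parameter_name, grid.second_parameter]
    else:
        points = ((v,) for v in first)
        param_cols = [grid.parameter_name]

    records = []
    for point in points:
        modified = scenario
        for name, value in zip(param_cols, point):
            modified = _with_value(modified, name, value)
        rr_pos, rr_neg = indirect_subgroup_rr(
            modified.rr_overall.point,
            modified.rr_assoc_alpha.point,
            modified.rr_assoc_beta.point,
            modified.prevalence.point,
        )
        records.append(
            dict(zip(param_cols, point))
            | {
                "rr_marker_pos": rr_pos,
                "rr_marker_neg": rr_neg,
                "preferred_pos": _preferred(rr_pos, scenario.labels),
                "preferred_neg": _preferred(rr_neg, scenario.labels),
            }
        )
    columns = param_cols + [
        "rr_marker_pos",
        "rr_marker_neg",
        "preferred_pos",
        "preferred_neg",
    ]
    return SweepResult(rows=pd.DataFrame.from_records(records, columns=columns))


def crossover_threshold(
    scenario: Scenario,
    parameter_name: str,
    bracket: tuple[float, float],
    subgroup: str = "neg",
    target: float = 1.0,
    n_monotonicity_points: int = 65,
) -> float | None:
    """Parameter value at which a subgroup RR crosses ``target``.

    The subgroup RR as a function of the swept parameter is first checked
    for monotonicity on a dense grid over ``bracket``; a non-monotone
    response is reported as ambiguous (``ValueError``) rather than returning
    an arbitrary root.  If the RR does not cross ``target`` inside the
    bracket, ``None`` is returned; otherwise the crossing is located by
    Brent bisection to an absolute tolerance of 1e-8.

    ``subgroup`` selects ``"pos"`` (marker-positive) or ``"neg"``
    (marker-negative).
    """
    if subgroup not in ("pos", "neg"):
        raise ValueError(f"subgroup must be 'pos' or 'neg', got {subgroup!r}")
    lo, hi = bracket
    if not lo < hi:
        raise ValueError(f"bracket must satisfy low < high, got {bracket}")

    def f(x: float) -> float:
        modified = _with_value(scenario, parameter_name, x)
        rr_pos, rr_neg = indirect_subgroup_rr(
            modified.rr_overall.point,
            modified.rr_assoc_alpha.point,
            modified.rr_assoc_beta.point,
            modified.prevalence.point,
        )
        return (rr_pos if subgroup == "pos" else rr_neg) - target

    xs = np.linspace(lo, hi, n_monotonicity_points)
    ys = np.array([f(x) for x in xs])
    diffs = np.diff(ys)
    if not (np.all(diffs >= 0) or np.all(diffs <= 0)):
        raise ValueError(
            f"subgroup RR is not monotone in {parameter_name!r} over {bracket}; "
            f"crossover is ambiguous"
        )
    if ys[0] == 0.0:
        return float(xs[0])
    if ys[-1] == 0.0:
        return float(xs[-1])
    if ys[0] * ys[-1] > 0:
        return None
    root = optimize.brentq(f, lo, hi, xtol=1e-8)
    return float(root)


def plot_sweep(result: SweepResult, ax=None):
    """Plot subgroup RRs against the swept parameter, reference line at 1.

    Only one-way sweep results can be plotted.  Requires matplotlib
    (optional dependency); returns the axes.
    """
    import matplotlib.pyplot as plt

    param_cols = [
        c
        for c in result.rows.columns
        if c not in ("rr_marker_pos", "rr_marker_neg", "preferred_pos", "preferred_neg")
    ]
    if len(param_cols) != 1:
        raise ValueError("only one-way sweeps can be plotted")
    (param,) = param_cols
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.rows[param], result.rows["rr_marker_pos"], label="marker-positive")
    ax.plot(result.rows[param], result.rows["rr_marker_neg"], label="marker-negative")
    ax.axhline(1.0, color="grey", linestyle="--", linewidth=1)
    ax.set_xlabel(param)
    ax.set_ylabel("indirect subgroup treatment-effect RR")
    ax.legend()
    return ax
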