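"""Configuration, analysis dispatch and result serialization.

A run is described by a small YAML document: the scenario inputs (marker
prevalence, per-arm association RRs, overall treatment-effect RR, optional
marginal risks and labels) plus the analysis mode and its settings.  The
schema is validated strictly — unknown keys are rejected with their field
path — so a typo cannot silently fall back to a default.  Results are
bundled with an echo of the inputs, every warning raised along the way,
and provenance (seed, n_sims, package version), and can be rendered as
JSON (machine) or aligned text (human).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from . import __version__
from .estimand import (
    DEFAULT_LABELS,
    EffectEstimate,
    Prevalence,
    Scenario,
    check_rare_event_assumption,
    indirect_subgroup_rr,
    subgroup_risk_table,
)
from .oracle import estimate_from_counts, population_from_effects, simulate_trial
from .sensitivity import SweepGrid, run_sweep
from .uncertainty import credible_interval, fit_beta, fit_lognormal, interaction_test, run_psa

__all__ = [
    "RunConfig",
    "ResultBundle",
    "ConfigError",
    "load_config",
    "config_from_dict",
    "config_to_dict",
    "run_analysis",
    "case_study_config_path",
]

ANALYSES = ("estimate", "psa", "sweep", "simulate")

#: Reminder attached to every result: the method is only as good as the
#: exchangeability of the contributing studies.
EXCHANGEABILITY_NOTICE = (
    "Assumption: the included studies are exchangeable — they do not differ "
    "on patient, treatment, or study characteristics that modify the "
    "marker's prognostic or predictive effect. Violations bias the indirect "
    "subgroup estimates in ways the credible intervals do not reflect."
)


class ConfigError(ValueError):
    """A configuration document violates the schema; message carries the field path."""


@dataclass(frozen=True)
class RunConfig:
    """Validated description of one analysis run."""

    scenario: Scenario
    analysis: str = "estimate"
    n_sims: int = 10_000
    seed: int | None = None
    ci_level: float = 0.95
    grid: SweepGrid | None = None
    n_per_arm: int | None = None
    baseline_risk: float | None = None
    output: str | None = None

    def __post_init__(self) -> None:
        if self.analysis not in ANALYSES:
            raise ConfigError(f"analysis: must be one of {ANALYSES}, got {self.analysis!r}")
        if self.n_sims < 1:
            raise ConfigError(f"n_sims: must be >= 1, got {self.n_sims}")
        if not 0 < self.ci_level < 1:
            raise ConfigError(f"ci_level: must be in (0,1), got {self.ci_level}")


def _require_keys(mapping: dict, allowed: set[str], path: str) -> None:
    if not isinstance(mapping, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(mapping).__name__}")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)} (allowed: {sorted(allowed)})")


def _effect_from_dict(d: dict, path: str) -> EffectEstimate:
    _require_keys(d, {"point", "ci", "fixed", "ci_level"}, path)
    try:
        if "fixed" in d:
            if "point" in d or "ci" in d:
                raise ConfigError(f"{path}: 'fixed' excludes 'point'/'ci'")
            return EffectEstimate.fixed(float(d["fixed"]))
        if "point" not in d or "ci" not in d:
            raise ConfigError(f"{path}: need 'point' and 'ci' (or 'fixed')")
        lo, hi = d["ci"]
        return EffectEstimate(
            point=float(d["point"]),
            ci_low=float(lo),
            ci_high=float(hi),
            ci_level=float(d.get("ci_level", 0.95)),
        )
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _prevalence_from_dict(d: dict, path: str) -> Prevalence:
    _require_keys(d, {"point", "ci", "sample_uncertainty"}, path)
    try:
        if "point" not in d:
            raise ConfigError(f"{path}.point: required")
        lo = hi = None
        if "ci" in d and d["ci"] is not None:
            lo, hi = (float(v) for v in d["ci"])
        return Prevalence(
            point=float(d["point"]),
            ci_low=lo,
            ci_high=hi,
            sample_uncertainty=bool(d.get("sample_uncertainty", False)),
        )
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _scenario_from_dict(d: dict, path: str = "scenario") -> Scenario:
    allowed = {
        "prevalence",
        "rr_assoc_alpha",
        "rr_assoc_beta",
        "rr_overall",
        "marginal_risk_alpha",
        "marginal_risk_beta",
        "labels",
    }
    _require_keys(d, allowed, path)
    for key in ("prevalence", "rr_assoc_alpha", "rr_assoc_beta", "rr_overall"):
        if key not in d:
            raise ConfigError(f"{path}.{key}: required")
    labels = dict(DEFAULT_LABELS)
    if "labels" in d:
        _require_keys(d["labels"], set(DEFAULT_LABELS), f"{path}.labels")
        labels.update(d["labels"])
    try:
        return Scenario(
            prevalence=_prevalence_from_dict(d["prevalence"], f"{path}.prevalence"),
            rr_assoc_alpha=_effect_from_dict(d["rr_assoc_alpha"], f"{path}.rr_assoc_alpha"),
            rr_assoc_beta=_effect_from_dict(d["rr_assoc_beta"], f"{path}.rr_assoc_beta"),
            rr_overall=_effect_from_dict(d["rr_overall"], f"{path}.rr_overall"),
            marginal_risk_alpha=(
                float(d["marginal_risk_alpha"]) if d.get("marginal_risk_alpha") is not None else None
            ),
            marginal_risk_beta=(
                float(d["marginal_risk_beta"]) if d.get("marginal_risk_beta") is not None else None
            ),
            labels=labels,
        )
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _grid_from_dict(d: dict, path: str = "grid") -> SweepGrid:
    _require_keys(d, {"parameter", "values", "start", "stop", "step",
                      "second_parameter", "second_values"}, path)
    if "parameter" not in d:
        raise ConfigError(f"{path}.parameter: required")

    def values_of(dd: dict) -> list[float]:
        if "values" in dd:
            return [float(v) for v in dd["values"]]
        if {"start", "stop", "step"} <= set(dd):
            start, stop, step = float(dd["start"]), float(dd["stop"]), float(dd["step"])
            n = int(round((stop - start) / step)) + 1
            return [start + i * step for i in range(n)]
        raise ConfigError(f"{path}: need 'values' or start/stop/step")

    try:
        return SweepGrid(
            parameter_name=str(d["parameter"]),
            values=values_of(d),
            second_parameter=d.get("second_parameter"),
            second_values=(
                [float(v) for v in d["second_values"]] if d.get("second_values") else None
            ),
        )
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def config_from_dict(d: dict) -> RunConfig:
    allowed = {
        "scenario", "analysis", "n_sims", "seed", "ci_level",
        "grid", "n_per_arm", "baseline_risk", "output",
    }
    _require_keys(d, allowed, "config")
    if "scenario" not in d:
        raise ConfigError("config.scenario: required")
    try:
        return RunConfig(
            scenario=_scenario_from_dict(d["scenario"]),
            analysis=str(d.get("analysis", "estimate")),
            n_sims=int(d.get("n_sims", 10_000)),
            seed=int(d["seed"]) if d.get("seed") is not None else None,
            ci_level=float(d.get("ci_level", 0.95)),
            grid=_grid_from_dict(d["grid"]) if d.get("grid") is not None else None,
            n_per_arm=int(d["n_per_arm"]) if d.get("n_per_arm") is not None else None,
            baseline_risk=(
                float(d["baseline_risk"]) if d.get("baseline_risk") is not None else None
            ),
            output=d.get("output"),
        )
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"config: {exc}") from exc


def config_to_dict(config: RunConfig) -> dict:
    """Serialize a RunConfig back to its YAML-schema dictionary form."""

    def effect(e: EffectEstimate) -> dict:
        if e.is_fixed:
            return {"fixed": e.point}
        out = {"point": e.point, "ci": [e.ci_low, e.ci_high]}
        if e.ci_level != 0.95:
            out["ci_level"] = e.ci_level
        return out

    s = config.scenario
    prev: dict = {"point": s.prevalence.point}
    if s.prevalence.has_ci:
        prev["ci"] = [s.prevalence.ci_low, s.prevalence.ci_high]
    if s.prevalence.sample_uncertainty:
        prev["sample_uncertainty"] = True
    scenario = {
        "prevalence": prev,
        "rr_assoc_alpha": effect(s.rr_assoc_alpha),
        "rr_assoc_beta": effect(s.rr_assoc_beta),
        "rr_overall": effect(s.rr_overall),
        "labels": dict(s.labels),
    }
    if s.marginal_risk_alpha is not None:
        scenario["marginal_risk_alpha"] = s.marginal_risk_alpha
    if s.marginal_risk_beta is not None:
        scenario["marginal_risk_beta"] = s.marginal_risk_beta
    out = {"scenario": scenario, "analysis": config.analysis, "n_sims": config.n_sims,
           "ci_level": config.ci_level}
    if config.seed is not None:
        out["seed"] = config.seed
    if config.grid is not None:
        grid = {"parameter": config.grid.parameter_name,
                "values": [float(v) for v in config.grid.values]}
        if config.grid.second_parameter is not None:
            grid["second_parameter"] = config.grid.second_parameter
            grid["second_values"] = [float(v) for v in config.grid.second_values]
        out["grid"] = grid
    if config.n_per_arm is not None:
        out["n_per_arm"] = config.n_per_arm
    if config.baseline_risk is not None:
        out["baseline_risk"] = config.baseline_risk
    if config.output is not None:
        out["output"] = config.output
    return out


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raise ConfigError("config: empty document")
    return config_from_dict(raw)


def case_study_config_path():
    """Path to the packaged CYP2C19/clopidogrel-ticagrelor case-study config."""
    return resources.files("pgxindirect") / "data" / "case_study.yaml"


@dataclass(frozen=True)
class ResultBundle:
    """Results of one analysis, with inputs echo, warnings and provenance."""

    analysis: str
    inputs: dict
    results: dict
    warnings: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, default=_jsonable)

    def to_text(self) -> str:
        lines = [f"pgxindirect {self.analysis} analysis", "=" * 40]
        lines += _text_block("Results", self.results)
        if self.warnings:
            lines.append("")
            lines.append("Warnings:")
            lines += [f"  ! {w}" for w in self.warnings]
        lines.append("")
        lines += _text_block("Provenance", self.provenance)
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _text_block(title: str, mapping: dict, indent: str = "  ") -> list[str]:
    lines = [f"{title}:"]
    for key, value in mapping.items():
        if isinstance(value, dict):
            lines.append(f"{indent}{key}:")
            lines += _text_block("", value, indent + "  ")[1:]
        elif isinstance(value, float):
            lines.append(f"{indent}{key}: {value:.6g}")
        else:
            lines.append(f"{indent}{key}: {value}")
    return lines


def _round2(x: float) -> float:
    return round(x, 2)


def run_analysis(config: RunConfig) -> ResultBundle:
    """Dispatch a validated config to its analysis and bundle the results.

    Modes: ``estimate`` (point estimates), ``psa`` (Monte Carlo credible
    intervals + interaction test), ``sweep`` (deterministic sensitivity
    analysis), ``simulate`` (finite stratified trial, direct vs indirect).
    Every bundle carries the exchangeability reminder and any rare-event
    warnings; stochastic results always record their seed and n_sims.
    """
    scenario = config.scenario
    warnings_list = [EXCHANGEABILITY_NOTICE]
    warnings_list += check_rare_event_assumption(scenario)
    provenance: dict = {"version": __version__, "analysis": config.analysis}
    labels = scenario.labels

    effect = subgroup_risk_table(scenario)
    results: dict = {
        "rr_marker_pos": effect.rr_marker_pos,
        "rr_marker_pos_2dp": _round2(effect.rr_marker_pos),
        "rr_marker_neg": effect.rr_marker_neg,
        "rr_marker_neg_2dp": _round2(effect.rr_marker_neg),
        "comparison": f"{labels['arm_alpha']} vs {labels['arm_beta']}",
    }
    if effect.risk_by_arm_and_marker:
        results["risk_by_arm_and_marker"] = {
            f"{arm}:{marker}": risk
            for (arm, marker), risk in effect.risk_by_arm_and_marker.items()
        }

    if config.analysis == "estimate":
        pass

    elif config.analysis == "psa":
        draws = run_psa(scenario, n_sims=config.n_sims, seed=config.seed)
        ci_pos = credible_interval(draws.rr_marker_pos, config.ci_level)
        ci_neg = credible_interval(draws.rr_marker_neg, config.ci_level)
        results["ci_marker_pos"] = list(ci_pos)
        results["ci_marker_pos_2dp"] = [_round2(v) for v in ci_pos]
        results["ci_marker_neg"] = list(ci_neg)
        results["ci_marker_neg_2dp"] = [_round2(v) for v in ci_neg]
        try:
            test = interaction_test(scenario, draws)
            results["interaction"] = {
                "z": test.z, "p": test.p, "mc_prob": test.mc_prob, "report": test.report,
            }
        except ValueError as exc:
            warnings_list.append(f"interaction test unavailable: {exc}")
        provenance.update(seed=draws.seed, n_sims=draws.n_sims, ci_level=config.ci_level)
        # Audit trail for the fitted input distributions.
        provenance["fitted"] = {
            name: dataclasses.asdict(fit_lognormal(getattr(scenario, name)))
            for name in ("rr_overall", "rr_assoc_alpha", "rr_assoc_beta")
        }
        beta = fit_beta(scenario.prevalence) if scenario.prevalence.sample_uncertainty else None
        provenance["fitted"]["prevalence"] = (
            dataclasses.asdict(beta) if beta is not None else "fixed"
        )

    elif config.analysis == "sweep":
        if config.grid is None:
            raise ConfigError("config.grid: required for the sweep analysis")
        sweep = run_sweep(scenario, config.grid)
        results["sweep"] = sweep.rows.to_dict(orient="records")
        if config.output:
            sweep.to_csv(config.output)
            results["sweep_csv"] = config.output

    elif config.analysis == "simulate":
        if config.n_per_arm is None:
            raise ConfigError("config.n_per_arm: required for the simulate analysis")
        if config.seed is None:
            raise ConfigError("config.seed: required for the simulate analysis")
        baseline = config.baseline_risk
        if baseline is None:
            raise ConfigError("config.baseline_risk: required for the simulate analysis "
                              "(event risk in the comparator arm's marker-negative cell)")
        pop = population_from_effects(
            prevalence=scenario.prevalence.point,
            baseline_risk=baseline,
            rr_assoc_beta=scenario.rr_assoc_beta.point,
            rr_pos=effect.rr_marker_pos,
            rr_neg=effect.rr_marker_neg,
        )
        counts = simulate_trial(pop, n_per_arm=config.n_per_arm, seed=config.seed)
        est = estimate_from_counts(counts)
        ind_pos, ind_neg = indirect_subgroup_rr(
            est.rr_overall.point,
            est.rr_assoc_alpha.point,
            est.rr_assoc_beta.point,
            est.prevalence,
        )
        results["simulated_trial"] = {
            "counts": {f"{a}:{m}": f"{counts.events[(a, m)]}/{counts.totals[(a, m)]}"
                       for (a, m) in counts.events},
            "direct": {
                "rr_pos": est.rr_pos.point,
                "rr_pos_ci": [est.rr_pos.ci_low, est.rr_pos.ci_high],
                "rr_neg": est.rr_neg.point,
                "rr_neg_ci": [est.rr_neg.ci_low, est.rr_neg.ci_high],
            },
            "indirect_from_same_trial": {"rr_pos": ind_pos, "rr_neg": ind_neg},
            "population_truth": {"rr_pos": effect.rr_marker_pos, "rr_neg": effect.rr_marker_neg},
        }
        if est.flags:
            warnings_list += est.flags
        provenance.update(seed=config.seed, n_per_arm=config.n_per_arm)

    return ResultBundle(
        analysis=config.analysis,
        inputs=config_to_dict(config),
        results=results,
        warnings=warnings_list,
        provenance=provenance,
    )
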