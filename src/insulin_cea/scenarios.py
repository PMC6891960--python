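"""One-way sensitivity analysis: named scenarios and parameter sweeps.

A scenario is a list of transforms, each addressing a parameter by its dotted
path in :class:`~insulin_cea.parameters.ModelParameters` (for example
``event_costs.cost_severe`` or ``rate_ratios.nocturnal.ratio``) and either
replacing the value or multiplying it.  Applying a scenario never mutates the
base parameters.

:func:`standard_scenarios` builds the published scenario set: a 5-year
horizon, zero severe-event mortality, per-event costs +/-10%, no dose
difference, no hypoglycaemia-rate difference, an alternative flexible-dosing
utility (0.0130), a 50% flexible-dosing uptake, and no flexible-dosing
benefit.  Alternative published event-rate sets are supported as user-supplied
rate-replacement scenarios (their values are not part of the package).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .model import compare, evaluate
from .parameters import ModelParameters

__all__ = [
    "TransformOp",
    "Transform",
    "ScenarioSpec",
    "apply_scenario",
    "run_scenarios",
    "standard_scenarios",
    "tornado",
]


class TransformOp(str, enum.Enum):
    SET = "set"
    MUL = "mul"


@dataclass(frozen=True)
class Transform:
    path: str
    op: TransformOp
    value: object


@dataclass(frozen=True)
class ScenarioSpec:
    """A named perturbation of the base parameters (empty list = base case)."""

    name: str
    transforms: tuple[Transform, ...] = ()

    @staticmethod
    def build(name: str, *steps: tuple[str, str, object]) -> "ScenarioSpec":
        return ScenarioSpec(
            name, tuple(Transform(p, TransformOp(op), v) for p, op, v in steps)
        )


def _resolve(obj, parts: Sequence[str]):
    for part in parts:
        if not hasattr(obj, part):
            raise KeyError(f"unknown parameter path component {part!r}")
        obj = getattr(obj, part)
    return obj


def apply_scenario(params: ModelParameters, spec: ScenarioSpec) -> ModelParameters:
    """Return a modified deep copy of ``params``; the base is never touched."""
    out = params.model_copy(deep=True)
    for tr in spec.transforms:
        *head, leaf = tr.path.split(".")
        target = _resolve(out, head)
        if not hasattr(target, leaf):
            raise KeyError(f"unknown parameter path {tr.path!r}")
        if tr.op is TransformOp.SET:
            setattr(target, leaf, tr.value)
        else:
            setattr(target, leaf, getattr(target, leaf) * tr.value)
    return ModelParameters.model_validate(out.model_dump())


def standard_scenarios(params: ModelParameters) -> list[ScenarioSpec]:
    """The published one-way scenario set applicable to ``params``."""
    specs = [
        ScenarioSpec.build("horizon_5yr", ("horizon_years", "set", 5.0)),
        ScenarioSpec.build(
            "zero_mortality", ("utilities.mortality_risk_severe", "set", 0.0)
        ),
        ScenarioSpec.build(
            "event_costs_+10%",
            ("event_costs.cost_daytime", "mul", 1.10),
            ("event_costs.cost_nocturnal", "mul", 1.10),
            ("event_costs.cost_severe", "mul", 1.10),
        ),
        ScenarioSpec.build(
            "event_costs_-10%",
            ("event_costs.cost_daytime", "mul", 0.90),
            ("event_costs.cost_nocturnal", "mul", 0.90),
            ("event_costs.cost_severe", "mul", 0.90),
        ),
    ]
    dose_steps = [
        ("regimen.basal_dose_ratio", "set", 1.0),
        ("regimen.basal_ratio_significant", "set", True),
    ]
    if params.regimen.has_bolus:
        dose_steps += [
            ("regimen.bolus_dose_ratio", "set", 1.0),
            ("regimen.bolus_ratio_significant", "set", True),
        ]
    specs.append(ScenarioSpec.build("no_dose_difference", *dose_steps))
    specs.append(
        ScenarioSpec.build(
            "no_hypo_difference",
            ("rate_ratios.daytime.ratio", "set", 1.0),
            ("rate_ratios.daytime.significant", "set", True),
            ("rate_ratios.nocturnal.ratio", "set", 1.0),
            ("rate_ratios.nocturnal.significant", "set", True),
            ("rate_ratios.severe.ratio", "set", 1.0),
            ("rate_ratios.severe.significant", "set", True),
        )
    )
    specs += [
        ScenarioSpec.build(
            "flexible_utility_0.0130", ("utilities.flexible_dosing_utility", "set", 0.0130)
        ),
        ScenarioSpec.build(
            "flexible_benefit_50%", ("utilities.fraction_benefiting_flexible", "set", 0.5)
        ),
        ScenarioSpec.build(
            "no_flexible_benefit", ("utilities.flexible_dosing_utility", "set", 0.0)
        ),
    ]
    return specs


def _row(name: str, params: ModelParameters) -> dict:
    _, _, result = evaluate(params)
    return {
        "scenario": name,
        "delta_cost": result.delta_cost,
        "delta_qalys": result.delta_qalys,
        "icer": result.icer,
        "dominance": result.dominance.value,
    }


def run_scenarios(
    params: ModelParameters, specs: Iterable[ScenarioSpec]
) -> pd.DataFrame:
    """Evaluate the base case plus each scenario; one row per scenario."""
    rows = [_row("base_case", params)]
    rows += [_row(spec.name, apply_scenario(params, spec)) for spec in specs]
    return pd.DataFrame(rows)


def tornado(
    params: ModelParameters,
    sweeps: Mapping[str, tuple[float, float]],
) -> pd.DataFrame:
    """One-way low/high sweeps, ordered by ICER range width (tornado layout).

    ``sweeps`` maps a parameter path to (low, high) replacement values.  When a
    bound makes the ICER undefined (dominant/dominated draw), the bound's ICER
    is NaN and the bar width is computed from the defined end only.
    """
    base = _row("base", params)["icer"]
    rows = []
    for path, (low, high) in sweeps.items():
        if not low < high:
            if low == high:
                pass  # zero-width sweep is legal and yields a zero-width bar
            else:
                raise ValueError(f"{path}: low must not exceed high")
        icers = {}
        for bound, value in (("low", low), ("high", high)):
            spec = ScenarioSpec.build(f"{path}={value}", (path, "set", value))
            icers[bound] = _row(spec.name, apply_scenario(params, spec))["icer"]
        lo, hi = icers["low"], icers["high"]
        defined = [x for x in (lo, hi) if x is not None]
        if len(defined) == 2:
            width = abs(hi - lo)
        elif len(defined) == 1 and base is not None:
            width = abs(defined[0] - base)
        else:
            width = float("nan")
        rows.append(
            {
                "parameter": path,
                "low_value": low,
                "high_value": high,
                "icer_low": lo,
                "icer_high": hi,
                "icer_base": base,
                "width": width,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("width", ascending=False, ignore_index=True)
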