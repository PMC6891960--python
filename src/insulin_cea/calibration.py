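"""Back-derivation of unpublished unit parameters from published aggregates.

The published analysis prints doses, dose ratios, event rates, rate ratios,
per-event costs and per-arm annual cost/QALY totals — but not the pharmacy
unit prices, baseline utilities or per-event disutilities it used.  Because
every pathway in the model is linear in those parameters, they can be
recovered exactly by sequential linear solves:

1. **Unit prices.**  The basal-oral group has no bolus insulin, so its two
   insulin cells isolate the basal prices (price = annual cost / dose / days).
   For each basal-bolus group, the bolus price then follows from the glargine
   arm's residual insulin cost, and a per-group degludec basal price from the
   degludec arm's residual.  Solving the degludec basal price per group (rather
   than importing the basal-oral value) reproduces every insulin cell exactly;
   the cross-group price spread is reported, not hidden.
2. **Per-event costs.**  cost = glargine-arm hypoglycaemia cell / glargine
   rate, per group and category; the degludec arm provides a consistency check.
3. **Disutilities.**  The three incremental-QALY equations form a triangular
   system: the type 1 group's QALY gain involves only the nocturnal rate delta
   (plus the flexible-dosing utility), giving the nocturnal disutility; the
   basal-bolus type 2 group adds the daytime term; the basal-oral type 2 group
   adds the severe term.
4. **Baseline utilities.**  baseline = glargine-arm QALYs + glargine event
   burden, cross-checked against the degludec arm.

The printed tables are rounded to 2 decimals (QALYs to 4), so the groups'
implied unit parameters differ by O(1%); calibration is therefore per patient
group and the report carries every residual and cross-group spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

from .model import Arm, compare, degludec_doses, degludec_rates, evaluate_arm
from .parameters import (
    EventCosts,
    HypoRates,
    ModelParameters,
    PatientGroup,
    UnitPrices,
    UtilityInputs,
    save_parameters,
)
from .published import (
    ClinicalInputs,
    CostUtilitySummary,
    load_clinical_inputs,
    load_cost_utility_summary,
    load_event_cost_tables,
)

__all__ = [
    "CalibrationReport",
    "solve_unit_prices",
    "solve_event_costs",
    "solve_disutilities",
    "solve_baseline_utilities",
    "solve_inflation_factor",
    "calibrate",
    "calibrated_parameters",
]

_CATEGORIES = ("daytime", "nocturnal", "severe")

#: Relative tolerance the reproduced published cells must meet.
RESIDUAL_TOL = 0.002


def _relative_spread(values) -> float:
    vals = [v for v in values if v is not None]
    if len(vals) < 2:
        return 0.0
    mean = sum(vals) / len(vals)
    return (max(vals) - min(vals)) / mean if mean else 0.0


@dataclass
class CalibrationReport:
    """Solved parameters plus the evidence they reproduce the published cells."""

    prices: Dict[PatientGroup, UnitPrices]
    event_costs: Dict[PatientGroup, EventCosts]
    disutilities: tuple[float, float, float]
    baseline_utilities: Dict[PatientGroup, float]
    inflation_factors: Dict[str, float]
    flexible_dosing_utility: float
    mortality_risk_severe: float
    residuals: Dict[str, float] = field(default_factory=dict)
    cross_group_spread: Dict[str, float] = field(default_factory=dict)
    failures: list[str] = field(default_factory=list)

    @property
    def max_residual(self) -> float:
        """Largest relative error over the reproduced cost/QALY cells.

        ICER residuals are reported separately (``*/icer``, tolerance 1%):
        the printed ICERs carry the rounding drift of both increments, so
        they are intrinsically looser than the cells themselves.
        """
        cells = [v for k, v in self.residuals.items() if not k.endswith("/icer")]
        return max(cells) if cells else 0.0

    @property
    def ok(self) -> bool:
        return not self.failures

    def to_dict(self) -> dict:
        return {
            "prices": {g.value: p.model_dump(exclude_none=True) for g, p in self.prices.items()},
            "event_costs": {g.value: c.model_dump() for g, c in self.event_costs.items()},
            "disutilities": {
                "daytime": self.disutilities[0],
                "nocturnal": self.disutilities[1],
                "severe": self.disutilities[2],
            },
            "baseline_utilities": {g.value: u for g, u in self.baseline_utilities.items()},
            "inflation_factors": self.inflation_factors,
            "flexible_dosing_utility": self.flexible_dosing_utility,
            "mortality_risk_severe": self.mortality_risk_severe,
            "residuals": self.residuals,
            "max_residual": self.max_residual,
            "cross_group_spread": self.cross_group_spread,
            "failures": self.failures,
            "ok": self.ok,
        }


def solve_unit_prices(
    inputs: Dict[PatientGroup, ClinicalInputs],
    summary: CostUtilitySummary,
    days_per_year: float = 365.0,
) -> Dict[PatientGroup, UnitPrices]:
    """Solve per-group pharmacy unit prices from the published insulin cells."""
    bot_in = inputs[PatientGroup.T2DM_BOT]
    bot_cells = summary.groups[PatientGroup.T2DM_BOT]
    basal_gla_dose = bot_in.regimen.basal_dose_glargine
    basal_deg_dose, _ = degludec_doses(bot_in.regimen)
    gla_basal_price = bot_cells.glargine.insulin / (basal_gla_dose * days_per_year)
    deg_basal_price_bot = bot_cells.degludec.insulin / (basal_deg_dose * days_per_year)
    if gla_basal_price <= 0 or deg_basal_price_bot <= 0:
        raise ValueError("non-positive solved basal price: inconsistent inputs")

    prices: Dict[PatientGroup, UnitPrices] = {
        PatientGroup.T2DM_BOT: UnitPrices(
            price_basal_glargine=gla_basal_price,
            price_basal_degludec=deg_basal_price_bot,
            days_per_year=days_per_year,
        )
    }
    for group in (PatientGroup.T1DM_BB, PatientGroup.T2DM_BB):
        ci, cells = inputs[group], summary.groups[group]
        deg_basal, deg_bolus = degludec_doses(ci.regimen)
        bolus_price = (
            cells.glargine.insulin / days_per_year
            - ci.regimen.basal_dose_glargine * gla_basal_price
        ) / ci.regimen.bolus_dose_glargine
        deg_basal_price = (
            cells.degludec.insulin / days_per_year - deg_bolus * bolus_price
        ) / deg_basal
        if bolus_price <= 0 or deg_basal_price <= 0:
            raise ValueError(f"non-positive solved price for {group.value}")
        prices[group] = UnitPrices(
            price_basal_glargine=gla_basal_price,
            price_basal_degludec=deg_basal_price,
            price_bolus=bolus_price,
            days_per_year=days_per_year,
        )
    return prices


def solve_event_cost(cell: float, rate: float) -> Optional[float]:
    """Per-event cost implied by one annual-cost cell and its event rate.

    Returns ``None`` (unidentifiable) when both are zero; raises when the rate
    is zero but the cell is not.
    """
    if rate == 0:
        if cell == 0:
            return None
        raise ValueError(f"zero event rate cannot produce annual cost {cell}")
    return cell / rate


def solve_event_costs(
    inputs: Dict[PatientGroup, ClinicalInputs],
    summary: CostUtilitySummary,
    inflation_factor: float = 1.0,
) -> Dict[PatientGroup, EventCosts]:
    """Per-event costs from glargine-arm cells divided by glargine rates.

    The degludec arm serves as a consistency check downstream.  An
    unidentifiable category (zero rate and zero cell) is carried as cost 0,
    which reproduces the cell regardless.
    """
    out: Dict[PatientGroup, EventCosts] = {}
    for group, ci in inputs.items():
        cells = summary.groups[group].glargine
        rates = ci.glargine_rates.as_tuple()
        solved = []
        for cat, rate in zip(_CATEGORIES, rates):
            c = solve_event_cost(cells.hypo_cell(cat), rate)
            solved.append(0.0 if c is None else c)
        out[group] = EventCosts(
            cost_daytime=solved[0],
            cost_nocturnal=solved[1],
            cost_severe=solved[2],
            inflation_factor=inflation_factor,
        )
    return out


def solve_disutilities(
    inputs: Dict[PatientGroup, ClinicalInputs],
    summary: CostUtilitySummary,
) -> tuple[float, float, float]:
    """Triangular solve of (daytime, nocturnal, severe) per-event disutilities.

    Uses unrounded degludec rates.  The severe-event mortality pathway is
    absorbed into the severe disutility (the published QALY deltas cannot
    separate the two), so these values reproduce the published increments with
    the mortality term switched off.
    """
    flex = summary.flexible_dosing_utility
    deltas = {}
    for group, ci in inputs.items():
        deg = degludec_rates(ci.glargine_rates, ci.rate_ratios).as_tuple()
        gla = ci.glargine_rates.as_tuple()
        deltas[group] = tuple(g - d for g, d in zip(gla, deg))  # events avoided

    dq = {g: summary.groups[g].incremental_qalys for g in deltas}
    t1, bb, bot = PatientGroup.T1DM_BB, PatientGroup.T2DM_BB, PatientGroup.T2DM_BOT

    d_noct = (dq[t1] - flex) / deltas[t1][1]
    d_day = (dq[bb] - flex - deltas[bb][1] * d_noct) / deltas[bb][0]
    d_sev = (dq[bot] - flex - deltas[bot][1] * d_noct - deltas[bot][0] * d_day) / deltas[bot][2]
    for name, val in (("daytime", d_day), ("nocturnal", d_noct), ("severe", d_sev)):
        if val < 0:
            raise ValueError(
                f"negative solved {name} disutility ({val:.5f}): "
                "inconsistent flexible-dosing utility assumption"
            )
    return d_day, d_noct, d_sev


def solve_baseline_utilities(
    inputs: Dict[PatientGroup, ClinicalInputs],
    summary: CostUtilitySummary,
    disutilities: tuple[float, float, float],
) -> tuple[Dict[PatientGroup, float], Dict[str, float]]:
    """Baseline utilities (glargine arm) and the degludec-arm consistency residuals."""
    baselines: Dict[PatientGroup, float] = {}
    residuals: Dict[str, float] = {}
    flex = summary.flexible_dosing_utility
    for group, ci in inputs.items():
        cells = summary.groups[group]
        gla_burden = sum(r * d for r, d in zip(ci.glargine_rates.as_tuple(), disutilities))
        baseline = cells.glargine.qalys + gla_burden
        deg = degludec_rates(ci.glargine_rates, ci.rate_ratios).as_tuple()
        deg_burden = sum(r * d for r, d in zip(deg, disutilities))
        baseline_deg = cells.degludec.qalys + deg_burden - flex
        baselines[group] = baseline
        residuals[f"{group.value}/baseline_cross_arm"] = abs(baseline_deg - baseline) / baseline
    return baselines, residuals


def solve_inflation_factor(costs_2014: dict, costs_2018: dict) -> Dict[str, float]:
    """Category-wise 2018/2014 cost ratios plus their mean and spread."""
    factors = {cat: costs_2018[cat] / costs_2014[cat] for cat in _CATEGORIES}
    vals = list(factors.values())
    factors["mean"] = sum(vals) / len(vals)
    factors["spread"] = _relative_spread(vals)
    return factors


def calibrate(
    inputs: Optional[Dict[PatientGroup, ClinicalInputs]] = None,
    summary: Optional[CostUtilitySummary] = None,
) -> CalibrationReport:
    """Run the full calibration and verify it reproduces the published cells.

    With no arguments, uses the packaged published tables.  The report's
    ``residuals`` map the relative error of every reproduced cost and QALY
    cell (plus the three ICERs under ``*/icer``, checked at 1%); ``failures``
    lists anything out of tolerance.
    """
    inputs = inputs if inputs is not None else load_clinical_inputs()
    summary = summary if summary is not None else load_cost_utility_summary()

    c2014, c2018 = load_event_cost_tables()
    inflation = solve_inflation_factor(c2014, c2018)

    prices = solve_unit_prices(inputs, summary)
    event_costs = solve_event_costs(inputs, summary, inflation_factor=inflation["mean"])
    disutilities = solve_disutilities(inputs, summary)
    d_day, d_noct, d_sev = disutilities
    baselines, base_residuals = solve_baseline_utilities(inputs, summary, disutilities)

    report = CalibrationReport(
        prices=prices,
        event_costs=event_costs,
        disutilities=disutilities,
        baseline_utilities=baselines,
        inflation_factors=inflation,
        flexible_dosing_utility=summary.flexible_dosing_utility,
        mortality_risk_severe=summary.mortality_risk_severe,
    )
    report.residuals.update(base_residuals)

    # forward round trip against every published cell
    for group in inputs:
        params = _assemble(group, inputs[group], report)
        cells = summary.groups[group]
        for arm in (Arm.DEGLUDEC, Arm.GLARGINE):
            outcome = evaluate_arm(params, arm)
            target = cells.arm(arm)
            recomputed = {
                "insulin": outcome.insulin_cost,
                "daytime": outcome.hypo_cost_daytime,
                "nocturnal": outcome.hypo_cost_nocturnal,
                "severe": outcome.hypo_cost_severe,
                "total": outcome.total_cost,
                "qalys": outcome.qalys,
            }
            for cell, value in recomputed.items():
                printed = getattr(target, cell)
                if printed == 0:
                    continue
                report.residuals[f"{group.value}/{arm.value}/{cell}"] = abs(
                    value - printed
                ) / abs(printed)
        result = compare(evaluate_arm(params, Arm.DEGLUDEC), evaluate_arm(params, Arm.GLARGINE))
        icer_res = abs(result.icer - cells.icer) / cells.icer
        report.residuals[f"{group.value}/icer"] = icer_res
        if icer_res >= 0.01:
            report.failures.append(f"{group.value}/icer residual {icer_res:.4%} >= 1%")

    for key, res in report.residuals.items():
        if not key.endswith("/icer") and res >= RESIDUAL_TOL:
            report.failures.append(f"{key} residual {res:.4%} >= {RESIDUAL_TOL:.1%}")

    for cat in _CATEGORIES:
        report.cross_group_spread[f"event_cost_{cat}"] = _relative_spread(
            [getattr(ec, f"cost_{cat}") for ec in event_costs.values()]
        )
    report.cross_group_spread["price_basal_degludec"] = _relative_spread(
        [p.price_basal_degludec for p in prices.values()]
    )
    report.cross_group_spread["price_bolus"] = _relative_spread(
        [p.price_bolus for p in prices.values()]
    )
    for group, u in baselines.items():
        if not (0 < u <= 1):
            report.failures.append(f"{group.value} baseline utility {u:.4f} outside (0, 1]")
    return report


def _assemble(
    group: PatientGroup, ci: ClinicalInputs, report: CalibrationReport
) -> ModelParameters:
    d_day, d_noct, d_sev = report.disutilities
    return ModelParameters(
        group=group,
        regimen=ci.regimen,
        prices=report.prices[group],
        glargine_rates=ci.glargine_rates,
        rate_ratios=ci.rate_ratios,
        event_costs=report.event_costs[group],
        utilities=UtilityInputs(
            baseline_utility=report.baseline_utilities[group],
            disutility_daytime=d_day,
            disutility_nocturnal=d_noct,
            disutility_severe=d_sev,
            flexible_dosing_utility=report.flexible_dosing_utility,
            fraction_benefiting_flexible=1.0,
            mortality_risk_severe=report.mortality_risk_severe,
            qaly_loss_per_death=0.0,
        ),
    )


def calibrated_parameters(
    group: PatientGroup,
    report: Optional[CalibrationReport] = None,
) -> ModelParameters:
    """Fully calibrated base-case parameters for one patient group."""
    report = report if report is not None else calibrate()
    return _assemble(group, load_clinical_inputs()[group], report)


def write_calibrated_configs(outdir: Path, report: Optional[CalibrationReport] = None) -> list[Path]:
    """Write one complete parameter config per group; forward runs load these,
    so no derived number is ever hard-coded downstream."""
    report = report if report is not None else calibrate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for group in PatientGroup:
        params = calibrated_parameters(group, report)
        paths.append(save_parameters(params, outdir / f"{group.value}.yaml"))
    return paths
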