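"""Deterministic forward evaluation of one patient group.

The model structure: each arm accrues annual insulin acquisition cost
(dose x unit price x days/year) plus annual hypoglycaemia treatment cost
(event rate x per-event cost, for daytime non-severe, nocturnal non-severe and
severe events), and annual QALYs

    baseline_utility
      - sum_category rate x disutility
      - severe_rate x mortality_risk x QALY_loss_per_death
      + [degludec only] flexible_dosing_utility x fraction_benefiting

Degludec doses and event rates are the glargine values scaled by the
degludec/glargine ratios, with non-significant ratios applied as 1.  The
incremental cost-effectiveness ratio (ICER) is the incremental cost per QALY
gained.  With multi-year horizons costs and QALYs are both scaled by the same
(possibly discounted) annuity factor, so the ICER is horizon-invariant; the
ICER is computed from annualised increments, which makes that invariance exact
in floating point, not merely to rounding.
"""

from __future__ import annotations

import enum
import math
import warnings
from typing import Optional

from pydantic import BaseModel, ConfigDict

from .parameters import (
    Arm,
    EventCosts,
    HypoRateRatios,
    HypoRates,
    InsulinRegimen,
    ModelParameters,
    UnitPrices,
    UtilityInputs,
    effective_ratio,
)

__all__ = [
    "ArmOutcome",
    "ComparisonResult",
    "Dominance",
    "degludec_rates",
    "degludec_doses",
    "annual_insulin_cost",
    "annual_hypo_cost",
    "annual_qalys",
    "annuity_factor",
    "evaluate_arm",
    "evaluate",
    "compare",
    "net_monetary_benefit",
]


class Dominance(str, enum.Enum):
    """Position on the cost-effectiveness plane.

    ``quadrant_NE_icer``: more costly, more effective — ICER meaningful.
    ``dominant``: cheaper and at least as effective (one strictly) — no ICER.
    ``dominated``: costlier and at most as effective (one strictly) — no ICER.
    ``quadrant_SW_icer``: cheaper but less effective — ICER reported, flagged.
    ``indeterminate``: no difference on either axis.
    """

    QUADRANT_NE_ICER = "quadrant_NE_icer"
    DOMINANT = "dominant"
    DOMINATED = "dominated"
    QUADRANT_SW_ICER = "quadrant_SW_icer"
    INDETERMINATE = "indeterminate"


class ArmOutcome(BaseModel):
    """Per-arm cost breakdown and QALYs over the model horizon.

    ``annual_total_cost`` and ``annual_qalys`` carry the undiscounted per-year
    values; the headline fields are those scaled by the annuity factor.
    ``total_cost`` is the exact floating-point sum of its components.
    """

    model_config = ConfigDict(frozen=True)

    arm: Arm
    insulin_cost: float
    hypo_cost_daytime: float
    hypo_cost_nocturnal: float
    hypo_cost_severe: float
    total_cost: float
    qalys: float
    event_rates: HypoRates
    annual_total_cost: float
    annual_qalys: float
    horizon_factor: float

    @property
    def hypo_cost_total(self) -> float:
        return self.hypo_cost_daytime + self.hypo_cost_nocturnal + self.hypo_cost_severe


class ComparisonResult(BaseModel):
    """Incremental results, degludec minus glargine."""

    model_config = ConfigDict(frozen=True)

    delta_cost: float
    delta_qalys: float
    icer: Optional[float]
    dominance: Dominance


def degludec_rates(glargine_rates: HypoRates, ratios: HypoRateRatios) -> HypoRates:
    """Degludec event rates: glargine rate x effective rate ratio, unrounded."""
    return HypoRates(
        daytime_nonsevere=glargine_rates.daytime_nonsevere * ratios.daytime.effective,
        nocturnal_nonsevere=glargine_rates.nocturnal_nonsevere * ratios.nocturnal.effective,
        severe=glargine_rates.severe * ratios.severe.effective,
    )


def degludec_doses(regimen: InsulinRegimen) -> tuple[float, Optional[float]]:
    """Degludec (basal, bolus) doses in units/day; bolus is None without one."""
    basal = regimen.basal_dose_glargine * effective_ratio(
        regimen.basal_dose_ratio, regimen.basal_ratio_significant
    )
    bolus = None
    if regimen.has_bolus:
        bolus = regimen.bolus_dose_glargine * effective_ratio(
            regimen.bolus_dose_ratio, regimen.bolus_ratio_significant
        )
    return basal, bolus


def annual_insulin_cost(
    basal: float, bolus: Optional[float], prices: UnitPrices, basal_price: float
) -> float:
    """Annual insulin acquisition cost: (basal x basal_price + bolus x bolus_price) x days."""
    if basal < 0 or (bolus is not None and bolus < 0):
        raise ValueError("doses must be non-negative")
    daily = basal * basal_price
    if bolus is not None:
        if prices.price_bolus is None:
            raise ValueError("bolus dose given but price_bolus is not set")
        daily += bolus * prices.price_bolus
    return daily * prices.days_per_year


def annual_hypo_cost(rates: HypoRates, costs: EventCosts) -> tuple[float, float, float]:
    """Annual hypoglycaemia treatment cost per category (daytime, nocturnal, severe)."""
    return (
        rates.daytime_nonsevere * costs.cost_daytime,
        rates.nocturnal_nonsevere * costs.cost_nocturnal,
        rates.severe * costs.cost_severe,
    )


def annual_qalys(
    rates: HypoRates, utilities: UtilityInputs, is_degludec: bool, horizon: float = 1.0
) -> float:
    """Annual QALYs for one arm, scaled by ``horizon`` (undiscounted).

    Floored at zero with a warning: a negative value means the event burden
    exceeds the baseline utility, outside the model's intended range.
    """
    q = (
        utilities.baseline_utility
        - rates.daytime_nonsevere * utilities.disutility_daytime
        - rates.nocturnal_nonsevere * utilities.disutility_nocturnal
        - rates.severe * utilities.disutility_severe
        - rates.severe * utilities.mortality_risk_severe * utilities.qaly_loss_per_death
    )
    if is_degludec:
        q += utilities.flexible_dosing_utility * utilities.fraction_benefiting_flexible
    q *= horizon
    if q < 0:
        warnings.warn("annual QALYs negative; floored at 0", stacklevel=2)
        q = 0.0
    return q


def annuity_factor(horizon_years: float, discount_rate: float) -> float:
    """Sum of per-year discount weights over the horizon.

    Annual compounding with the first year undiscounted; a fractional final
    year contributes pro rata.  With a zero rate this is simply the horizon.
    """
    if discount_rate == 0:
        return horizon_years
    whole = int(math.floor(horizon_years))
    frac = horizon_years - whole
    factor = sum((1.0 + discount_rate) ** (-t) for t in range(whole))
    if frac > 0:
        factor += frac * (1.0 + discount_rate) ** (-whole)
    return factor


def evaluate_arm(params: ModelParameters, arm: Arm) -> ArmOutcome:
    """Evaluate one arm: cost breakdown and QALYs over the model horizon."""
    if arm is Arm.DEGLUDEC:
        basal, bolus = degludec_doses(params.regimen)
        basal_price = params.prices.price_basal_degludec
        rates = degludec_rates(params.glargine_rates, params.rate_ratios)
    else:
        basal = params.regimen.basal_dose_glargine
        bolus = params.regimen.bolus_dose_glargine
        basal_price = params.prices.price_basal_glargine
        rates = params.glargine_rates

    factor = annuity_factor(params.horizon_years, params.discount_rate)
    insulin = annual_insulin_cost(basal, bolus, params.prices, basal_price)
    day, noct, sev = annual_hypo_cost(rates, params.event_costs)
    annual_total = insulin + day + noct + sev
    q_annual = annual_qalys(rates, params.utilities, arm is Arm.DEGLUDEC, horizon=1.0)

    insulin_s, day_s, noct_s, sev_s = (x * factor for x in (insulin, day, noct, sev))
    return ArmOutcome(
        arm=arm,
        insulin_cost=insulin_s,
        hypo_cost_daytime=day_s,
        hypo_cost_nocturnal=noct_s,
        hypo_cost_severe=sev_s,
        total_cost=insulin_s + day_s + noct_s + sev_s,
        qalys=q_annual * factor,
        event_rates=rates,
        annual_total_cost=annual_total,
        annual_qalys=q_annual,
        horizon_factor=factor,
    )


def compare(deg: ArmOutcome, gla: ArmOutcome) -> ComparisonResult:
    """Incremental cost, incremental QALYs, ICER and dominance class.

    The ICER is computed from the annualised increments; both arms share the
    same annuity factor, so the ratio is identical (bitwise) across horizons.
    A zero or sign-discordant increment never raises: the dominance class
    carries the interpretation and the ICER is None where it has no meaning.
    """
    if deg.horizon_factor != gla.horizon_factor:
        raise ValueError("arms evaluated over different horizons cannot be compared")
    delta_cost = deg.total_cost - gla.total_cost
    delta_qalys = deg.qalys - gla.qalys
    dc = deg.annual_total_cost - gla.annual_total_cost
    dq = deg.annual_qalys - gla.annual_qalys

    icer: Optional[float] = None
    if dc > 0 and dq > 0:
        dominance = Dominance.QUADRANT_NE_ICER
        icer = dc / dq
    elif dc < 0 and dq < 0:
        dominance = Dominance.QUADRANT_SW_ICER
        icer = dc / dq
    elif dc <= 0 and dq >= 0 and (dc < 0 or dq > 0):
        dominance = Dominance.DOMINANT
    elif dc >= 0 and dq <= 0 and (dc > 0 or dq < 0):
        dominance = Dominance.DOMINATED
    else:
        dominance = Dominance.INDETERMINATE
    return ComparisonResult(
        delta_cost=delta_cost, delta_qalys=delta_qalys, icer=icer, dominance=dominance
    )


def evaluate(params: ModelParameters) -> tuple[ArmOutcome, ArmOutcome, ComparisonResult]:
    """Evaluate both arms and their comparison: (degludec, glargine, result)."""
    deg = evaluate_arm(params, Arm.DEGLUDEC)
    gla = evaluate_arm(params, Arm.GLARGINE)
    return deg, gla, compare(deg, gla)


def net_monetary_benefit(result: ComparisonResult, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold: wtp x dQALY - dCost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * result.delta_qalys - result.delta_cost
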