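"""Synthetic parameter sets with known structure for end-to-end testing.

Two generators:

* :func:`random_parameters` draws a fully valid :class:`ModelParameters` from
  configurable per-family ranges (uniform draws).  Default ranges bracket the
  published inputs: doses 10-60 units/day, event rates within 10x of the
  published values, per-event costs spanning sub-1 BGN self-treated episodes
  to ~1000 BGN severe events.  Collapsing a range to a point reproduces that
  point exactly, so the published tables are a special case.

* :func:`parameters_with_known_icer` constructs a parameter set whose forward
  ICER equals a requested target to machine precision.  It works backward:
  rates, ratios (all < 1, significant) and disutilities fix the QALY gain
  q > 0 and the hypoglycaemia cost offset h <= 0 in closed form; the degludec
  basal price — the only free parameter entering costs linearly and alone —
  is then set so the incremental cost is exactly target x q.  The bolus dose
  ratio is pinned at 1 so bolus costs cancel from the increment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .parameters import (
    EventCosts,
    HypoRateRatios,
    HypoRates,
    InsulinRegimen,
    ModelParameters,
    PatientGroup,
    RatioEstimate,
    UnitPrices,
    UtilityInputs,
)

__all__ = ["SyntheticSpec", "random_parameters", "parameters_with_known_icer"]

Range = Tuple[float, float]


@dataclass(frozen=True)
class SyntheticSpec:
    """Seeded recipe for one synthetic parameter set."""

    seed: int
    group: PatientGroup = PatientGroup.T2DM_BOT
    target_icer: Optional[float] = None
    dose_range: Range = (10.0, 60.0)
    dose_ratio_range: Range = (0.7, 1.3)
    rate_ranges: Dict[str, Range] = field(
        default_factory=lambda: {
            # within 10x of the published glargine rates
            "daytime": (3.0, 60.0),
            "nocturnal": (1.0, 30.0),
            "severe": (0.01, 5.0),
        }
    )
    rate_ratio_range: Range = (0.5, 1.5)
    cost_ranges: Dict[str, Range] = field(
        default_factory=lambda: {
            "daytime": (0.1, 2.0),
            "nocturnal": (5.0, 60.0),
            "severe": (100.0, 1000.0),
        }
    )
    price_range: Range = (0.02, 0.20)
    baseline_range: Range = (0.6, 0.99)
    disutility_ranges: Dict[str, Range] = field(
        default_factory=lambda: {
            "daytime": (0.0005, 0.01),
            "nocturnal": (0.001, 0.02),
            "severe": (0.01, 0.12),
        }
    )
    flexible_utility_range: Range = (0.0, 0.013)

    def _check(self) -> None:
        for lo, hi in [
            self.dose_range,
            self.dose_ratio_range,
            self.rate_ratio_range,
            self.price_range,
            self.baseline_range,
            self.flexible_utility_range,
            *self.rate_ranges.values(),
            *self.cost_ranges.values(),
            *self.disutility_ranges.values(),
        ]:
            if lo > hi:
                raise ValueError(f"infeasible range ({lo}, {hi})")


def _u(rng: np.random.Generator, r: Range) -> float:
    lo, hi = r
    return lo if lo == hi else float(rng.uniform(lo, hi))


def random_parameters(spec: SyntheticSpec) -> ModelParameters:
    """A random, fully valid parameter set; identical seeds give identical sets."""
    spec._check()
    rng = np.random.default_rng(spec.seed)
    group = spec.group

    regimen_kwargs = dict(
        basal_dose_glargine=_u(rng, spec.dose_range),
        basal_dose_ratio=_u(rng, spec.dose_ratio_range),
        basal_ratio_significant=bool(rng.random() < 0.7),
    )
    price_bolus = None
    if group.has_bolus:
        regimen_kwargs.update(
            bolus_dose_glargine=_u(rng, spec.dose_range),
            bolus_dose_ratio=_u(rng, spec.dose_ratio_range),
            bolus_ratio_significant=bool(rng.random() < 0.7),
        )
        price_bolus = _u(rng, spec.price_range)

    rates = HypoRates(
        daytime_nonsevere=_u(rng, spec.rate_ranges["daytime"]),
        nocturnal_nonsevere=_u(rng, spec.rate_ranges["nocturnal"]),
        severe=_u(rng, spec.rate_ranges["severe"]),
    )
    ratios = HypoRateRatios(
        **{
            cat: RatioEstimate(
                ratio=_u(rng, spec.rate_ratio_range),
                significant=bool(rng.random() < 0.7),
            )
            for cat in ("daytime", "nocturnal", "severe")
        }
    )
    costs = EventCosts(
        cost_daytime=_u(rng, spec.cost_ranges["daytime"]),
        cost_nocturnal=_u(rng, spec.cost_ranges["nocturnal"]),
        cost_severe=_u(rng, spec.cost_ranges["severe"]),
    )
    baseline = _u(rng, spec.baseline_range)
    disutils = {cat: _u(rng, spec.disutility_ranges[cat]) for cat in ("daytime", "nocturnal", "severe")}
    # keep the event burden below baseline so QALYs stay positive
    burden = sum(r * disutils[c] for r, c in zip(rates.as_tuple(), ("daytime", "nocturnal", "severe")))
    if burden >= 0.9 * baseline:
        scale = 0.9 * baseline / burden
        disutils = {c: d * scale for c, d in disutils.items()}

    return ModelParameters(
        group=group,
        regimen=InsulinRegimen(**regimen_kwargs),
        prices=UnitPrices(
            price_basal_glargine=_u(rng, spec.price_range),
            price_basal_degludec=_u(rng, spec.price_range),
            price_bolus=price_bolus,
        ),
        glargine_rates=rates,
        rate_ratios=ratios,
        event_costs=costs,
        utilities=UtilityInputs(
            baseline_utility=baseline,
            disutility_daytime=disutils["daytime"],
            disutility_nocturnal=disutils["nocturnal"],
            disutility_severe=disutils["severe"],
            flexible_dosing_utility=_u(rng, spec.flexible_utility_range),
        ),
    )


def parameters_with_known_icer(spec: SyntheticSpec, target: float) -> ModelParameters:
    """Construct parameters whose forward ICER equals ``target`` exactly.

    All rate ratios are drawn below 1 and marked significant, so the QALY gain
    q is strictly positive; the degludec basal price is then solved so that
    the incremental annual cost equals ``target x q``.  Raises if the solved
    price is not positive (unreachable with ratios < 1, since the
    hypoglycaemia offset h is then <= 0 and target x q - h > 0).
    """
    if target <= 0:
        raise ValueError("target ICER must be positive")
    spec._check()
    params = random_parameters(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2**16 + 1]))

    lo, hi = spec.rate_ratio_range
    hi = min(hi, 0.99)
    if lo >= hi:
        raise ValueError("rate ratio range admits no value below 1")
    update = {
        "rate_ratios": HypoRateRatios(
            **{
                cat: RatioEstimate(ratio=float(rng.uniform(lo, hi)), significant=True)
                for cat in ("daytime", "nocturnal", "severe")
            }
        )
    }
    regimen = params.regimen
    if regimen.has_bolus:
        regimen = regimen.model_copy(update={"bolus_dose_ratio": 1.0, "bolus_ratio_significant": True})
        update["regimen"] = regimen
    params = params.model_copy(update=update, deep=True)

    gla = params.glargine_rates.as_tuple()
    eff = tuple(r.effective for r in params.rate_ratios.as_tuple())
    du = params.utilities.disutilities()
    q = sum(g * (1 - e) * d for g, e, d in zip(gla, eff, du))
    q += params.utilities.flexible_dosing_utility * params.utilities.fraction_benefiting_flexible
    if q <= 0:
        raise ValueError("constructed QALY gain not positive")

    costs = params.event_costs.as_tuple()
    h = sum(g * (e - 1) * c for g, e, c in zip(gla, eff, costs))  # <= 0
    days = params.prices.days_per_year
    basal_gla_daily_cost = regimen.basal_dose_glargine * params.prices.price_basal_glargine
    deg_basal_dose = regimen.basal_dose_glargine * (
        regimen.basal_dose_ratio if regimen.basal_ratio_significant else 1.0
    )
    # target*q = (deg_basal_dose*p - basal_gla_daily_cost)*days + h
    price = (target * q - h + basal_gla_daily_cost * days) / (deg_basal_dose * days)
    if price <= 0:
        raise ValueError("infeasible target: solved degludec price not positive")
    return params.model_copy(
        update={"prices": params.prices.model_copy(update={"price_basal_degludec": price})},
        deep=True,
    )
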