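"""Loaders for the packaged published aggregates.

Two small YAML files ship with the package:

``clinical_inputs.yaml``
    Observed glargine doses, dose ratios, hypoglycaemia event rates and rate
    ratios per patient group, plus per-event costs at 2014 and 2018 price
    levels.  These are direct model inputs.

``cost_utility_summary.yaml``
    The published per-arm annual cost and QALY results.  Unit prices,
    baseline utilities and per-event disutilities were never published, so
    these aggregates serve as calibration targets (see
    :mod:`insulin_cea.calibration`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict

import yaml

from .parameters import Arm, HypoRates, HypoRateRatios, InsulinRegimen, PatientGroup

__all__ = [
    "ClinicalInputs",
    "ArmCells",
    "GroupSummary",
    "CostUtilitySummary",
    "load_clinical_inputs",
    "load_cost_utility_summary",
    "WTP_THRESHOLD",
]

#: Bulgarian willingness-to-pay threshold, 3x GDP per capita, BGN/QALY.
WTP_THRESHOLD = 39619.0

_CATEGORIES = ("daytime", "nocturnal", "severe")


def _read(name: str) -> dict:
    ref = resources.files("insulin_cea").joinpath("data", "published", name)
    return yaml.safe_load(ref.read_text())


@dataclass(frozen=True)
class ClinicalInputs:
    """Published clinical inputs for one patient group."""

    group: PatientGroup
    regimen: InsulinRegimen
    glargine_rates: HypoRates
    rate_ratios: HypoRateRatios


@dataclass(frozen=True)
class ArmCells:
    """One arm's published annual cost breakdown and QALYs."""

    insulin: float
    daytime: float
    nocturnal: float
    severe: float
    total: float
    qalys: float

    def hypo_cell(self, category: str) -> float:
        return getattr(self, category)


@dataclass(frozen=True)
class GroupSummary:
    degludec: ArmCells
    glargine: ArmCells
    incremental_cost: float
    incremental_qalys: float
    icer: float

    def arm(self, arm: Arm) -> ArmCells:
        return self.degludec if arm is Arm.DEGLUDEC else self.glargine


@dataclass(frozen=True)
class CostUtilitySummary:
    """All published calibration targets."""

    groups: Dict[PatientGroup, GroupSummary]
    wtp_threshold: float
    flexible_dosing_utility: float
    mortality_risk_severe: float


def load_clinical_inputs() -> Dict[PatientGroup, ClinicalInputs]:
    raw = _read("clinical_inputs.yaml")
    out: Dict[PatientGroup, ClinicalInputs] = {}
    for label, entry in raw["groups"].items():
        group = PatientGroup(label)
        out[group] = ClinicalInputs(
            group=group,
            regimen=InsulinRegimen.model_validate(entry["regimen"]),
            glargine_rates=HypoRates.model_validate(entry["glargine_rates"]),
            rate_ratios=HypoRateRatios.model_validate(entry["rate_ratios"]),
        )
    return out


def load_event_cost_tables() -> tuple[dict, dict]:
    """Per-event cost rows at 2014 and 2018 price levels (BGN/event)."""
    raw = _read("clinical_inputs.yaml")
    return raw["event_costs_2014"], raw["event_costs_2018"]


def load_cost_utility_summary() -> CostUtilitySummary:
    raw = _read("cost_utility_summary.yaml")
    groups: Dict[PatientGroup, GroupSummary] = {}
    for label, entry in raw["groups"].items():
        inc = entry["incremental"]
        groups[PatientGroup(label)] = GroupSummary(
            degludec=ArmCells(**entry["degludec"]),
            glargine=ArmCells(**entry["glargine"]),
            incremental_cost=float(inc["cost"]),
            incremental_qalys=float(inc["qalys"]),
            icer=float(inc["icer"]),
        )
    return CostUtilitySummary(
        groups=groups,
        wtp_threshold=float(raw["wtp_threshold"]),
        flexible_dosing_utility=float(raw["flexible_dosing_utility"]),
        mortality_risk_severe=float(raw["mortality_risk_severe"]),
    )
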