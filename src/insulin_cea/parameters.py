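"""Domain types and configuration surface for the short-term insulin cost-utility model.

The model compares insulin degludec against biosimilar glargine U100 over a
1-year horizon in three patient groups: type 1 diabetes on basal-bolus therapy,
type 2 diabetes on basal-oral therapy (basal insulin plus oral agents, no
bolus), and type 2 diabetes on basal-bolus therapy.  Everything the forward
model needs for one group is collected in :class:`ModelParameters`:

* the observed glargine regimen and degludec/glargine dose ratios,
* pharmacy unit prices,
* annual hypoglycaemia event rates on glargine and degludec/glargine rate
  ratios (daytime non-severe, nocturnal non-severe, severe),
* per-event treatment costs,
* utility inputs (baseline utility, per-event disutilities, the annual
  flexible-dosing utility gain for degludec, severe-event mortality risk).

A dose or rate ratio estimated without statistical significance is applied as
1 (:func:`effective_ratio`), mirroring standard practice of carrying only
significant treatment effects into the base case.

Configuration is plain YAML with a strict schema: unknown keys are rejected so
a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "PatientGroup",
    "Arm",
    "InsulinRegimen",
    "UnitPrices",
    "HypoRates",
    "RatioEstimate",
    "HypoRateRatios",
    "EventCosts",
    "UtilityInputs",
    "ModelParameters",
    "effective_ratio",
    "load_parameters",
    "dump_parameters",
    "save_parameters",
]


class PatientGroup(str, enum.Enum):
    """The three modelled patient groups."""

    T1DM_BB = "T1DM_BB"
    T2DM_BOT = "T2DM_BOT"
    T2DM_BB = "T2DM_BB"

    @property
    def has_bolus(self) -> bool:
        return self is not PatientGroup.T2DM_BOT


class Arm(str, enum.Enum):
    """Treatment arm of the comparison."""

    DEGLUDEC = "degludec"
    GLARGINE = "glargine"


def effective_ratio(ratio: float, significant: bool) -> float:
    """Return the ratio to apply in the model: ``ratio`` if significant, else 1.

    Non-significant dose and event-rate ratios are carried at 1 so that only
    statistically supported treatment differences enter the base case.

    Raises
    ------
    ValueError
        If ``ratio`` is not strictly positive.
    """
    if not ratio > 0:
        raise ValueError(f"ratio must be positive, got {ratio!r}")
    return float(ratio) if significant else 1.0


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class InsulinRegimen(_StrictModel):
    """Observed glargine doses and degludec/glargine dose ratios.

    Bolus fields are absent for basal-oral therapy.
    """

    basal_dose_glargine: float = Field(gt=0, description="units/day")
    basal_dose_ratio: float = Field(gt=0, description="degludec/glargine, dimensionless")
    basal_ratio_significant: bool
    bolus_dose_glargine: Optional[float] = Field(default=None, gt=0, description="units/day")
    bolus_dose_ratio: Optional[float] = Field(default=None, gt=0)
    bolus_ratio_significant: bool = False

    @property
    def has_bolus(self) -> bool:
        return self.bolus_dose_glargine is not None

    @model_validator(mode="after")
    def _bolus_fields_consistent(self) -> "InsulinRegimen":
        if self.bolus_dose_glargine is not None and self.bolus_dose_ratio is None:
            raise ValueError("bolus_dose_ratio required when bolus_dose_glargine is present")
        return self


class UnitPrices(_StrictModel):
    """Pharmacy selling prices per insulin unit, BGN (incl. VAT)."""

    price_basal_glargine: float = Field(gt=0, description="BGN/unit")
    price_basal_degludec: float = Field(gt=0, description="BGN/unit")
    price_bolus: Optional[float] = Field(default=None, gt=0, description="BGN/unit")
    days_per_year: float = Field(default=365.0, ge=360, le=366)


class HypoRates(_StrictModel):
    """Annual hypoglycaemia event rates, events/patient/year."""

    daytime_nonsevere: float = Field(ge=0)
    nocturnal_nonsevere: float = Field(ge=0)
    severe: float = Field(ge=0)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.daytime_nonsevere, self.nocturnal_nonsevere, self.severe)


class RatioEstimate(_StrictModel):
    """A degludec/glargine ratio together with its significance flag."""

    ratio: float = Field(gt=0)
    significant: bool

    @property
    def effective(self) -> float:
        return effective_ratio(self.ratio, self.significant)


class HypoRateRatios(_StrictModel):
    """Degludec/glargine hypoglycaemia rate ratios per event category."""

    daytime: RatioEstimate
    nocturnal: RatioEstimate
    severe: RatioEstimate

    def as_tuple(self) -> tuple[RatioEstimate, RatioEstimate, RatioEstimate]:
        return (self.daytime, self.nocturnal, self.severe)


class EventCosts(_StrictModel):
    """Per-event treatment costs, BGN, at 2018 price level."""

    cost_daytime: float = Field(ge=0, description="BGN/event")
    cost_nocturnal: float = Field(ge=0, description="BGN/event")
    cost_severe: float = Field(ge=0, description="BGN/event")
    inflation_factor: float = Field(default=1.0, gt=0, description="2014 -> 2018 scaling")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.cost_daytime, self.cost_nocturnal, self.cost_severe)


class UtilityInputs(_StrictModel):
    """Utility model: baseline, per-event disutilities and the flexibility gain.

    ``qaly_loss_per_death`` defaults to 0: the calibrated severe-event
    disutility already absorbs the published model's mortality pathway, so the
    explicit severe-event mortality term is switched off in the base case and
    exposed for sensitivity analysis.
    """

    baseline_utility: float = Field(gt=0, le=1, description="utility/year")
    disutility_daytime: float = Field(ge=0, description="utility loss/event")
    disutility_nocturnal: float = Field(ge=0)
    disutility_severe: float = Field(ge=0)
    flexible_dosing_utility: float = Field(ge=0, description="utility/year, degludec arm")
    fraction_benefiting_flexible: float = Field(default=1.0, ge=0, le=1)
    mortality_risk_severe: float = Field(default=0.0, ge=0, le=1, description="probability/event")
    qaly_loss_per_death: float = Field(default=0.0, ge=0, description="QALYs lost per death")

    def disutilities(self) -> tuple[float, float, float]:
        return (self.disutility_daytime, self.disutility_nocturnal, self.disutility_severe)


class ModelParameters(_StrictModel):
    """Complete, validated input set for one patient group."""

    group: PatientGroup
    regimen: InsulinRegimen
    prices: UnitPrices
    glargine_rates: HypoRates
    rate_ratios: HypoRateRatios
    event_costs: EventCosts
    utilities: UtilityInputs
    horizon_years: float = Field(default=1.0, gt=0)
    discount_rate: float = Field(default=0.0, ge=0, description="proportion/year")

    @model_validator(mode="after")
    def _group_regimen_consistent(self) -> "ModelParameters":
        if self.group is PatientGroup.T2DM_BOT and self.regimen.has_bolus:
            raise ValueError("T2DM_BOT has no bolus component")
        if self.group.has_bolus and not self.regimen.has_bolus:
            raise ValueError(f"{self.group.value} requires bolus dose fields")
        if self.regimen.has_bolus and self.prices.price_bolus is None:
            raise ValueError("price_bolus required for a basal-bolus regimen")
        return self


def load_parameters(source: Union[str, Path, dict]) -> ModelParameters:
    """Load and validate :class:`ModelParameters` from YAML text, a path or a mapping.

    Defaulting rules (365 days/year, 1-year horizon, no discounting) are
    applied by the schema; any missing required field, invalid value or
    unknown key raises ``pydantic.ValidationError`` naming the field path.
    """
    if isinstance(source, dict):
        data = source
    elif isinstance(source, Path):
        data = yaml.safe_load(source.read_text())
    else:
        text = source
        if "\n" not in source and len(source) < 4096 and Path(source).is_file():
            text = Path(source).read_text()
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("parameter source must parse to a mapping")
    return ModelParameters.model_validate(data)


def dump_parameters(params: ModelParameters) -> str:
    """Serialize parameters to canonical YAML (round-trips through ``load_parameters``)."""
    data = params.model_dump(mode="json", exclude_none=True)
    return yaml.safe_dump(data, sort_keys=False)


def save_parameters(params: ModelParameters, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(dump_parameters(params))
    return path
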