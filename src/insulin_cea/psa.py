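"""Probabilistic sensitivity analysis: distributions, propagation, CEAC, NMB.

Parameter uncertainty is propagated by Monte Carlo: each uncertain parameter
gets a distribution centred on its base-case value, ``n`` joint draws are
pushed through the deterministic model, and the resulting cloud of
(incremental cost, incremental QALY) pairs summarises decision uncertainty.
The cost-effectiveness acceptability curve (CEAC) reports, for each
willingness-to-pay value, the fraction of draws with positive net monetary
benefit.

Families follow the support of each parameter: gamma for per-event costs,
lognormal for dose and hypoglycaemia rate ratios, beta for utilities and
disutilities, and ``fixed`` for anything held constant.  Dispersion is given
as a coefficient of variation (CV).  The published analysis does not state
its distributional assumptions, so the defaults here (costs CV 0.20, ratios
CV 0.15, utility quantities CV 0.20, prices and doses fixed, n = 10,000) are
this package's own, documented choice; published acceptance probabilities are
treated as qualitative bands.

Ratios whose base-case estimate was non-significant are sampled around 1 —
their uncertainty is retained rather than collapsed — and each sampled ratio
is applied as drawn.  Every parameter path draws from its own counter-based
substream keyed by (seed, hash(path)), so adding or removing one parameter
does not perturb the draws of the others.
"""

from __future__ import annotations

import enum
import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import Arm, compare, evaluate_arm, net_monetary_benefit
from .parameters import ModelParameters
from .published import WTP_THRESHOLD
from .scenarios import ScenarioSpec, apply_scenario

__all__ = [
    "Family",
    "DistributionSpec",
    "default_distributions",
    "default_wtp_grid",
    "sample_parameters",
    "ceac",
    "run_psa",
    "PsaResult",
]

_RESAMPLE_CAP = 1000


class Family(str, enum.Enum):
    GAMMA = "gamma"
    LOGNORMAL = "lognormal"
    BETA = "beta"
    FIXED = "fixed"


@dataclass(frozen=True)
class DistributionSpec:
    """Distribution assigned to one parameter path.

    ``central`` is the base-case value (the distribution mean), ``cv`` the
    coefficient of variation.  ``significant_override`` marks ratio paths
    whose draw must be applied regardless of the base-case significance flag.
    """

    path: str
    family: Family
    central: float
    cv: float = 0.0
    significant_override: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError(f"{self.path}: CV must be non-negative")
        if self.family is Family.BETA and not 0 < self.central < 1:
            raise ValueError(f"{self.path}: beta requires a mean in (0, 1)")
        if self.family in (Family.GAMMA, Family.LOGNORMAL) and self.central <= 0:
            raise ValueError(f"{self.path}: {self.family.value} requires a positive mean")
        if self.family is Family.BETA:
            var = (self.cv * self.central) ** 2
            if var >= self.central * (1 - self.central):
                raise ValueError(f"{self.path}: beta CV too large for mean {self.central}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family is Family.FIXED or self.cv == 0:
            return np.full(n, self.central)
        m, c = self.central, self.cv
        if self.family is Family.GAMMA:
            shape = 1.0 / c**2
            return rng.gamma(shape, m * c**2, size=n)
        if self.family is Family.LOGNORMAL:
            sigma2 = np.log1p(c**2)
            mu = np.log(m) - sigma2 / 2.0
            return rng.lognormal(mu, np.sqrt(sigma2), size=n)
        var = (c * m) ** 2
        nu = m * (1 - m) / var - 1.0
        return rng.beta(m * nu, (1 - m) * nu, size=n)


def _stream(seed: int, path: str) -> np.random.Generator:
    digest = hashlib.sha256(path.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.Generator(np.random.Philox(np.random.SeedSequence([seed, key])))


def default_distributions(
    params: ModelParameters,
    cost_cv: float = 0.20,
    ratio_cv: float = 0.15,
    utility_cv: float = 0.20,
) -> list[DistributionSpec]:
    """Default uncertainty set for one parameter configuration.

    Per-event costs ~ gamma, dose and rate ratios ~ lognormal (non-significant
    ratios centred on 1), disutilities and the flexible-dosing utility ~ beta;
    unit prices, doses and the baseline utility are fixed (the baseline cancels
    from every increment).
    """
    specs = [
        DistributionSpec("event_costs.cost_daytime", Family.GAMMA, params.event_costs.cost_daytime, cost_cv),
        DistributionSpec("event_costs.cost_nocturnal", Family.GAMMA, params.event_costs.cost_nocturnal, cost_cv),
        DistributionSpec("event_costs.cost_severe", Family.GAMMA, params.event_costs.cost_severe, cost_cv),
        DistributionSpec(
            "regimen.basal_dose_ratio",
            Family.LOGNORMAL,
            params.regimen.basal_dose_ratio if params.regimen.basal_ratio_significant else 1.0,
            ratio_cv,
            significant_override="regimen.basal_ratio_significant",
        ),
    ]
    if params.regimen.has_bolus:
        specs.append(
            DistributionSpec(
                "regimen.bolus_dose_ratio",
                Family.LOGNORMAL,
                params.regimen.bolus_dose_ratio if params.regimen.bolus_ratio_significant else 1.0,
                ratio_cv,
                significant_override="regimen.bolus_ratio_significant",
            )
        )
    for cat in ("daytime", "nocturnal", "severe"):
        est = getattr(params.rate_ratios, cat)
        specs.append(
            DistributionSpec(
                f"rate_ratios.{cat}.ratio",
                Family.LOGNORMAL,
                est.ratio if est.significant else 1.0,
                ratio_cv,
                significant_override=f"rate_ratios.{cat}.significant",
            )
        )
    u = params.utilities
    for name in ("disutility_daytime", "disutility_nocturnal", "disutility_severe"):
        val = getattr(u, name)
        if val > 0:
            specs.append(DistributionSpec(f"utilities.{name}", Family.BETA, val, utility_cv))
    if u.flexible_dosing_utility > 0:
        specs.append(
            DistributionSpec(
                "utilities.flexible_dosing_utility", Family.BETA, u.flexible_dosing_utility, utility_cv
            )
        )
    return specs


def sample_parameters(
    params: ModelParameters,
    specs: Sequence[DistributionSpec],
    n: int,
    seed: int,
) -> list[ModelParameters]:
    """Draw ``n`` joint parameter sets; reproducible given ``seed``.

    Each draw is validated against the full parameter schema; a draw that
    violates an invariant is resampled from the same substreams, up to a cap.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    # oversample each stream so resampling never re-reads used numbers
    budget = n + _RESAMPLE_CAP
    columns = {spec.path: spec.sample(_stream(seed, spec.path), budget) for spec in specs}

    out: list[ModelParameters] = []
    cursor = 0
    attempts = 0
    while len(out) < n:
        if cursor >= budget:
            raise RuntimeError("resampling cap exhausted; distributions incompatible with invariants")
        steps = []
        for spec in specs:
            steps.append((spec.path, "set", float(columns[spec.path][cursor])))
            if spec.significant_override is not None:
                steps.append((spec.significant_override, "set", True))
        cursor += 1
        try:
            out.append(apply_scenario(params, ScenarioSpec.build(f"draw_{len(out)}", *steps)))
        except ValueError as exc:  # pydantic.ValidationError subclasses ValueError
            attempts += 1
            if attempts == 1:
                warnings.warn(f"PSA draw violated parameter invariants; resampling ({exc})", stacklevel=2)
            if attempts > _RESAMPLE_CAP:
                raise RuntimeError("too many invalid PSA draws") from exc
    return out


def default_wtp_grid(
    stop: float = 80000.0, step: float = 2000.0, threshold: float = WTP_THRESHOLD
) -> np.ndarray:
    """WTP grid from 0 to ``stop``, always containing the decision threshold."""
    grid = np.arange(0.0, stop + step, step)
    if threshold not in grid:
        grid = np.sort(np.append(grid, threshold))
    return grid


def ceac(
    draws: Sequence[tuple[float, float]], wtp_grid: Iterable[float]
) -> list[tuple[float, float]]:
    """Fraction of draws with positive net monetary benefit at each WTP value."""
    arr = np.asarray(list(draws), dtype=float)
    if arr.size == 0:
        raise ValueError("ceac requires at least one draw")
    dcost, dqaly = arr[:, 0], arr[:, 1]
    return [
        (float(w), float(np.mean(w * dqaly - dcost > 0))) for w in wtp_grid
    ]


@dataclass(frozen=True)
class PsaResult:
    """Monte-Carlo output for one patient group."""

    draws: np.ndarray  # (n, 2): incremental cost, incremental QALYs
    ceac: list[tuple[float, float]]
    mean_delta_cost: float
    mean_delta_qalys: float
    icer_of_means: Optional[float]
    prob_cost_effective_at_threshold: float
    wtp_threshold: float
    mean_nmb_at_threshold: float
    seed: int
    n: int

    def ceac_at(self, wtp: float) -> float:
        for w, p in self.ceac:
            if w == wtp:
                return p
        raise KeyError(f"WTP {wtp} not on the CEAC grid")


def run_psa(
    params: ModelParameters,
    specs: Optional[Sequence[DistributionSpec]] = None,
    n: int = 10000,
    seed: int = 0,
    wtp_grid: Optional[Iterable[float]] = None,
    wtp_threshold: float = WTP_THRESHOLD,
) -> PsaResult:
    """Full probabilistic analysis for one group; deterministic given ``seed``."""
    specs = default_distributions(params) if specs is None else specs
    grid = np.asarray(list(default_wtp_grid(threshold=wtp_threshold) if wtp_grid is None else wtp_grid))
    if wtp_threshold not in grid:
        grid = np.sort(np.append(grid, wtp_threshold))
    draws = np.empty((n, 2))
    for i, p in enumerate(sample_parameters(params, specs, n, seed)):
        result = compare(evaluate_arm(p, Arm.DEGLUDEC), evaluate_arm(p, Arm.GLARGINE))
        draws[i] = (result.delta_cost, result.delta_qalys)
    curve = ceac(draws, grid)
    mean_dc = float(draws[:, 0].mean())
    mean_dq = float(draws[:, 1].mean())
    icer_of_means = mean_dc / mean_dq if mean_dq != 0 else None
    prob = dict(curve)[float(wtp_threshold)]
    return PsaResult(
        draws=draws,
        ceac=curve,
        mean_delta_cost=mean_dc,
        mean_delta_qalys=mean_dq,
        icer_of_means=icer_of_means,
        prob_cost_effective_at_threshold=prob,
        wtp_threshold=float(wtp_threshold),
        mean_nmb_at_threshold=float(np.mean(wtp_threshold * draws[:, 1] - draws[:, 0])),
        seed=seed,
        n=n,
    )
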