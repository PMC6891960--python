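"""Deterministic cohort model: dose/rate scaling, costs, QALYs, ICER, dominance."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import insulin_cea as ic
from insulin_cea.model import ArmOutcome, annuity_factor
from insulin_cea.parameters import Arm, PatientGroup


# --- published dose and rate arithmetic -------------------------------------

@pytest.mark.parametrize(
    "group, expected_basal, expected_bolus",
    [
        (PatientGroup.T1DM_BB, 24.46, 32.67),   # 28.11 x 0.87, 37.13 x 0.88
        (PatientGroup.T2DM_BOT, 25.30, None),   # 28.11 x 0.90
        (PatientGroup.T2DM_BB, 30.36, 37.13),   # 28.11 x 1.08; bolus NS -> unchanged
    ],
)
def test_degludec_doses_match_published(clinical_inputs, group, expected_basal, expected_bolus):
    basal, bolus = ic.degludec_doses(clinical_inputs[group].regimen)
    assert round(basal, 2) == expected_basal
    if expected_bolus is None:
        assert bolus is None
    else:
        assert round(bolus, 2) == expected_bolus


@pytest.mark.parametrize(
    "group, expected",
    [
        (PatientGroup.T1DM_BB, (30.42, 7.07, 3.20)),
        # published nocturnal value is 8.57, but 13.38 x 0.64 = 8.5632: the
        # source evidently used an unrounded rate ratio; 8.56 is the exact
        # consequence of the published inputs
        (PatientGroup.T2DM_BOT, (23.12, 8.56, 0.01)),
        (PatientGroup.T2DM_BB, (25.25, 6.39, 0.70)),
    ],
)
def test_degludec_rates_match_published(clinical_inputs, group, expected):
    ci = clinical_inputs[group]
    rates = ic.degludec_rates(ci.glargine_rates, ci.rate_ratios)
    assert tuple(round(r, 2) for r in rates.as_tuple()) == expected


def test_degludec_severe_rate_carried_unrounded(clinical_inputs):
    """0.10 x 0.14 = 0.014 is used downstream, not its printed 2-dp rounding."""
    ci = clinical_inputs[PatientGroup.T2DM_BOT]
    rates = ic.degludec_rates(ci.glargine_rates, ci.rate_ratios)
    assert rates.severe == pytest.approx(0.014, rel=1e-12)


def test_all_ratios_nonsignificant_leaves_rates_unchanged(clinical_inputs):
    ci = clinical_inputs[PatientGroup.T1DM_BB]
    ratios = ic.HypoRateRatios(
        daytime={"ratio": 0.5, "significant": False},
        nocturnal={"ratio": 0.5, "significant": False},
        severe={"ratio": 0.5, "significant": False},
    )
    assert ic.degludec_rates(ci.glargine_rates, ratios) == ci.glargine_rates


# --- cost and QALY components -----------------------------------------------

def test_annual_insulin_cost_basal_only():
    prices = ic.UnitPrices(price_basal_glargine=0.055967, price_basal_degludec=0.0861)
    cost = ic.annual_insulin_cost(28.11, None, prices, 0.055967)
    assert cost == pytest.approx(28.11 * 0.055967 * 365, rel=1e-12)
    assert ic.annual_insulin_cost(0.0, None, prices, 0.055967) == 0.0
    with pytest.raises(ValueError):
        ic.annual_insulin_cost(-1.0, None, prices, 0.055967)


def test_annual_hypo_cost_componentwise():
    rates = ic.HypoRates(daytime_nonsevere=2.0, nocturnal_nonsevere=3.0, severe=0.5)
    costs = ic.EventCosts(cost_daytime=1.0, cost_nocturnal=30.0, cost_severe=500.0)
    assert ic.annual_hypo_cost(rates, costs) == (2.0, 90.0, 250.0)
    zero = ic.HypoRates(daytime_nonsevere=0, nocturnal_nonsevere=0, severe=0)
    assert ic.annual_hypo_cost(zero, costs) == (0.0, 0.0, 0.0)


def test_annual_qalys_trivial_and_floor():
    u = ic.UtilityInputs(
        baseline_utility=0.8,
        disutility_daytime=0,
        disutility_nocturnal=0,
        disutility_severe=0,
        flexible_dosing_utility=0,
    )
    zero = ic.HypoRates(daytime_nonsevere=0, nocturnal_nonsevere=0, severe=0)
    assert ic.annual_qalys(zero, u, is_degludec=False) == 0.8
    heavy = ic.HypoRates(daytime_nonsevere=0, nocturnal_nonsevere=0, severe=100)
    u2 = u.model_copy(update={"disutility_severe": 0.05})
    with pytest.warns(UserWarning, match="floored"):
        assert ic.annual_qalys(heavy, u2, is_degludec=False) == 0.0


def test_flexible_dosing_utility_only_accrues_to_degludec(calibrated):
    p = calibrated[PatientGroup.T1DM_BB]
    ratios_all_one = ic.HypoRateRatios(
        daytime={"ratio": 1.0, "significant": True},
        nocturnal={"ratio": 1.0, "significant": True},
        severe={"ratio": 1.0, "significant": True},
    )
    p = p.model_copy(update={"rate_ratios": ratios_all_one}, deep=True)
    deg = ic.annual_qalys(p.glargine_rates, p.utilities, is_degludec=True)
    gla = ic.annual_qalys(p.glargine_rates, p.utilities, is_degludec=False)
    assert deg - gla == pytest.approx(p.utilities.flexible_dosing_utility, rel=1e-12)


# --- evaluate_arm against the published totals ------------------------------

def test_published_total_costs_reproduced(calibrated, summary):
    published = {
        PatientGroup.T1DM_BB: (3143.28, 3073.92),
        PatientGroup.T2DM_BOT: (1101.32, 1083.97),
        PatientGroup.T2DM_BB: (2156.67, 1852.47),
    }
    for group, (deg_total, gla_total) in published.items():
        deg = ic.evaluate_arm(calibrated[group], Arm.DEGLUDEC)
        gla = ic.evaluate_arm(calibrated[group], Arm.GLARGINE)
        assert deg.total_cost == pytest.approx(deg_total, rel=2e-3)
        assert gla.total_cost == pytest.approx(gla_total, rel=2e-3)


def test_component_additivity(calibrated):
    for params in calibrated.values():
        for arm in Arm:
            o = ic.evaluate_arm(params, arm)
            assert o.total_cost == (
                o.insulin_cost
                + o.hypo_cost_daytime
                + o.hypo_cost_nocturnal
                + o.hypo_cost_severe
            )


def test_null_comparison_is_indeterminate(calibrated):
    """Ratios all 1 and no flexibility gain: the arms differ only in basal price."""
    p = calibrated[PatientGroup.T2DM_BOT].model_copy(deep=True)
    p.rate_ratios = ic.HypoRateRatios(
        daytime={"ratio": 1.0, "significant": True},
        nocturnal={"ratio": 1.0, "significant": True},
        severe={"ratio": 1.0, "significant": True},
    )
    p.prices = p.prices.model_copy(
        update={"price_basal_degludec": p.prices.price_basal_glargine}
    )
    p.regimen = p.regimen.model_copy(update={"basal_dose_ratio": 1.0})
    p.utilities = p.utilities.model_copy(update={"flexible_dosing_utility": 0.0})
    _, _, result = ic.evaluate(p)
    assert result.delta_cost == 0.0
    assert result.delta_qalys == 0.0
    assert result.dominance is ic.Dominance.INDETERMINATE
    assert result.icer is None


# --- comparison, dominance and NMB ------------------------------------------

def _outcome(cost: float, qalys: float, arm=Arm.DEGLUDEC) -> ArmOutcome:
    rates = ic.HypoRates(daytime_nonsevere=0, nocturnal_nonsevere=0, severe=0)
    return ArmOutcome(
        arm=arm,
        insulin_cost=cost,
        hypo_cost_daytime=0.0,
        hypo_cost_nocturnal=0.0,
        hypo_cost_severe=0.0,
        total_cost=cost,
        qalys=qalys,
        event_rates=rates,
        annual_total_cost=cost,
        annual_qalys=qalys,
        horizon_factor=1.0,
    )


@pytest.mark.parametrize(
    "dcost, dqaly, dominance, has_icer",
    [
        (17.35, 0.0435, ic.Dominance.QUADRANT_NE_ICER, True),
        (-5.0, 0.01, ic.Dominance.DOMINANT, False),
        (0.0, 0.01, ic.Dominance.DOMINANT, False),
        (5.0, -0.01, ic.Dominance.DOMINATED, False),
        (5.0, 0.0, ic.Dominance.DOMINATED, False),
        (-5.0, -0.01, ic.Dominance.QUADRANT_SW_ICER, True),
        (0.0, 0.0, ic.Dominance.INDETERMINATE, False),
    ],
)
def test_dominance_classification(dcost, dqaly, dominance, has_icer):
    result = ic.compare(_outcome(1000.0 + dcost, 0.5 + dqaly), _outcome(1000.0, 0.5, Arm.GLARGINE))
    assert result.dominance is dominance
    if has_icer:
        assert result.icer == pytest.approx(dcost / dqaly, rel=1e-9)
    else:
        assert result.icer is None


def test_published_increment_gives_published_icer():
    result = ic.compare(_outcome(1017.35, 0.7490), _outcome(1000.0, 0.7055, Arm.GLARGINE))
    assert result.icer == pytest.approx(398.85, abs=0.01)  # 17.35 / 0.0435


def test_net_monetary_benefit():
    result = ic.compare(_outcome(1017.35, 0.7490), _outcome(1000.0, 0.7055, Arm.GLARGINE))
    nmb = ic.net_monetary_benefit(result, 39619.0)
    assert nmb == pytest.approx(39619.0 * 0.0435 - 17.35, rel=1e-9)  # 1706.08
    assert ic.net_monetary_benefit(result, result.icer) == pytest.approx(0.0, abs=1e-9)
    assert ic.net_monetary_benefit(result, 0.0) == pytest.approx(-17.35, rel=1e-9)


# --- horizon and discounting -------------------------------------------------

def test_horizon_invariance_is_bitwise(calibrated):
    for params in calibrated.values():
        _, _, base = ic.evaluate(params)
        p5 = params.model_copy(update={"horizon_years": 5.0})
        _, _, r5 = ic.evaluate(p5)
        assert r5.icer == base.icer  # identical float, not approximately
        assert r5.delta_cost == pytest.approx(5 * base.delta_cost, rel=1e-12)


def test_discounting_applied_symmetrically(calibrated):
    """A nonzero discount rate rescales costs and QALYs alike: ICER unchanged."""
    params = calibrated[PatientGroup.T1DM_BB]
    _, _, base = ic.evaluate(params)
    pd_ = params.model_copy(update={"horizon_years": 5.0, "discount_rate": 0.05})
    deg, gla, rd = ic.evaluate(pd_)
    assert rd.icer == base.icer
    factor = annuity_factor(5.0, 0.05)
    assert factor == pytest.approx(sum(1.05 ** -t for t in range(5)), rel=1e-12)
    assert deg.horizon_factor == factor
    assert rd.delta_cost == pytest.approx(factor * base.delta_cost, rel=1e-12)


@given(ratio=st.floats(min_value=0.3, max_value=1.4))
def test_icer_monotone_in_nocturnal_rate_ratio(ratio):
    """Raising a degludec rate ratio (fewer events avoided) never lowers the
    ICER while the QALY gain stays positive."""
    base = ic.calibrated_parameters(PatientGroup.T1DM_BB)
    spec = ic.ScenarioSpec.build(
        "sweep",
        ("rate_ratios.nocturnal.ratio", "set", ratio),
        ("rate_ratios.nocturnal.significant", "set", True),
    )
    _, _, lo = ic.evaluate(ic.apply_scenario(base, spec))
    spec_hi = ic.ScenarioSpec.build(
        "sweep_hi",
        ("rate_ratios.nocturnal.ratio", "set", ratio * 1.05),
        ("rate_ratios.nocturnal.significant", "set", True),
    )
    _, _, hi = ic.evaluate(ic.apply_scenario(base, spec_hi))
    if (
        lo.dominance is ic.Dominance.QUADRANT_NE_ICER
        and hi.dominance is ic.Dominance.QUADRANT_NE_ICER
    ):
        assert hi.icer >= lo.icer - 1e-9


# --- independent spreadsheet-style oracle ------------------------------------

def _flat_recompute(p: ic.ModelParameters, arm: Arm):
    """Cell-by-cell recomputation using only primitive arithmetic."""
    eff = lambda r, s: r if s else 1.0
    if arm is Arm.DEGLUDEC:
        basal = p.regimen.basal_dose_glargine * eff(
            p.regimen.basal_dose_ratio, p.regimen.basal_ratio_significant
        )
        bolus = (
            p.regimen.bolus_dose_glargine
            * eff(p.regimen.bolus_dose_ratio, p.regimen.bolus_ratio_significant)
            if p.regimen.bolus_dose_glargine is not None
            else None
        )
        basal_price = p.prices.price_basal_degludec
        rd = p.glargine_rates.daytime_nonsevere * eff(
            p.rate_ratios.daytime.ratio, p.rate_ratios.daytime.significant
        )
        rn = p.glargine_rates.nocturnal_nonsevere * eff(
            p.rate_ratios.nocturnal.ratio, p.rate_ratios.nocturnal.significant
        )
        rs = p.glargine_rates.severe * eff(
            p.rate_ratios.severe.ratio, p.rate_ratios.severe.significant
        )
    else:
        basal = p.regimen.basal_dose_glargine
        bolus = p.regimen.bolus_dose_glargine
        basal_price = p.prices.price_basal_glargine
        rd = p.glargine_rates.daytime_nonsevere
        rn = p.glargine_rates.nocturnal_nonsevere
        rs = p.glargine_rates.severe
    daily = basal * basal_price + (bolus * p.prices.price_bolus if bolus is not None else 0.0)
    insulin = daily * p.prices.days_per_year
    cd = rd * p.event_costs.cost_daytime
    cn = rn * p.event_costs.cost_nocturnal
    cs = rs * p.event_costs.cost_severe
    u = p.utilities
    q = (
        u.baseline_utility
        - rd * u.disutility_daytime
        - rn * u.disutility_nocturnal
        - rs * u.disutility_severe
        - rs * u.mortality_risk_severe * u.qaly_loss_per_death
        + (
            u.flexible_dosing_utility * u.fraction_benefiting_flexible
            if arm is Arm.DEGLUDEC
            else 0.0
        )
    )
    return insulin + cd + cn + cs, q


@pytest.mark.parametrize("seed", range(100))
def test_oracle_equivalence_on_random_parameters(seed):
    group = list(PatientGroup)[seed % 3]
    params = ic.random_parameters(ic.SyntheticSpec(seed=seed, group=group))
    for arm in Arm:
        outcome = ic.evaluate_arm(params, arm)
        cost, qalys = _flat_recompute(params, arm)
        assert outcome.total_cost == pytest.approx(cost, rel=1e-9)
        assert outcome.qalys == pytest.approx(max(qalys, 0.0), rel=1e-9)
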