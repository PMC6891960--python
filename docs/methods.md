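# Methods

## Model structure and assumptions

The model is a deterministic annual cohort comparison: two treatment arms
(insulin degludec vs biosimilar glargine U100), three independent patient
groups, a 1-year horizon, no discounting in the base case. Each arm accrues

* **insulin acquisition cost** — daily dose × pharmacy unit price × days/year
  (365; back-derivation from the published annual costs is consistent with
  365). Degludec doses are glargine doses × dose ratio.
* **hypoglycaemia treatment cost** — annual event rate × per-event cost for
  daytime non-severe, nocturnal non-severe and severe events. Degludec rates
  are glargine rates × rate ratio.
* **QALYs** — baseline utility minus rate × disutility per category, plus an
  annual flexible-dosing utility gain (`u_flex`, base case 0.006) for the
  degludec arm, scaled by the fraction of patients benefiting (base case 1.0).

Ratios estimated without statistical significance are applied as 1, so only
statistically supported differences enter the base case. The model assumes
steady state: replicating the year leaves the ICER unchanged, which the
implementation makes exact by always computing the ICER from annualised
increments (the annuity factor cancels bitwise, not merely to rounding).
Multi-year scenarios with a nonzero discount rate apply one annual-compounding
annuity factor to costs and QALYs alike, preserving that invariance.

**Severe-event mortality.** The source model names a 1.12% mortality risk per
severe event but not its QALY pathway. The calibrated severe disutility
necessarily absorbs whatever that pathway contributed, so the base case
carries `mortality_risk_severe = 0.0112` with `qaly_loss_per_death = 0`
(term switched off); the zero-mortality scenario is exposed for sensitivity
analysis. Setting a nonzero `qaly_loss_per_death` double-counts unless the
severe disutility is re-estimated.

## Calibration

Unit prices, per-event costs, disutilities and baseline utilities are not
published; all are linear in the published aggregates and recovered exactly:

1. The basal-oral group has no bolus insulin, so its insulin cells isolate
   the two basal prices. Per basal-bolus group, the bolus price comes from
   the glargine arm's residual insulin cost and a per-group degludec basal
   price from the degludec arm's residual. (Re-using the basal-oral degludec
   price everywhere would leave a 0.38% residual on the type 1 degludec
   insulin cell; the per-group solve reproduces all six insulin cells
   exactly.)
2. Per-event costs are glargine-arm hypoglycaemia cells divided by glargine
   rates; the degludec arm agrees within 0.05%.
3. The three incremental-QALY equations are triangular in the disutilities:
   nocturnal from the type 1 group, daytime from the basal-bolus type 2
   group, severe from the basal-oral type 2 group.
4. Baseline utility = glargine-arm QALYs + glargine event burden,
   cross-checked against the degludec arm (agreement ~1e-16).

Because the published tables are rounded (costs to 2 dp, QALYs to 4 dp), the
groups' implied unit parameters differ by O(1%): per-event costs spread
≤1.8% across groups, the degludec basal price 0.64%, the bolus price 2.74%.
Calibration is therefore per group, and the report carries every residual and
spread rather than averaging them away. The forward round trip reproduces
every published cost/QALY cell within 0.2% (worst 0.049%) and the three
ICERs within 1% (worst 0.87%, the basal-oral group, where the printed
nocturnal degludec cell embeds an unrounded upstream rate ratio: the printed
inputs give 13.38 × 0.64 = 8.5632 events, i.e. 8.56 at 2 dp, against a
printed 8.57).

The calibrated parameters are written to per-group YAML configs; forward runs
load those files, so no derived number is hard-coded downstream.

## One-way sensitivity

Scenarios are lists of (parameter-path, set/multiply) transforms applied to a
deep copy of the base parameters. The standard set mirrors the published
analyses: 5-year horizon, zero severe-event mortality, event costs ±10%, no
dose difference, no hypoglycaemia-rate difference, alternative flexible-dosing
utility 0.0130, 50% flexible-dosing uptake, no flexible-dosing benefit.
Alternative published event-rate sets are supported as user-supplied rate
replacements (their values are not packaged). The no-hypoglycaemia-difference
ICER reduces exactly to insulin increment / flexible-dosing utility
(36,783 BGN/QALY basal-oral, published 36,739; 62,990 basal-bolus, published
63,239 — both within 1%, the residue being rounding in the printed
increments). The published type 1 no-dose-difference ICER (19,781) is ~2% off
its own closed form and is checked qualitatively only. A tornado table ranks
single-parameter low/high sweeps by ICER swing width.

## Probabilistic sensitivity analysis

The source analysis states that input uncertainty was propagated but not its
distribution families, dispersions or draw counts, so exact reproduction of
its acceptance probabilities (60.0/99.4/91.3%) is not possible; they are
treated as qualitative bands. This package's defaults — its own documented
choice — are:

| quantity | family | CV | rationale |
|---|---|---|---|
| per-event costs | gamma | 0.20 | non-negative, right-skewed resource use |
| dose & rate ratios | lognormal | 0.15 | positive, symmetric on the log scale |
| disutilities, `u_flex` | beta | 0.20 | bounded in (0, 1) |
| unit prices, doses, baseline utility | fixed | — | administered prices; baseline cancels from increments |

n = 10,000 draws. Non-significant ratios are sampled around 1 (uncertainty
retained, each draw applied as drawn) rather than pinned at 1 — pinning would
remove most of the type 1 group's uncertainty and push its acceptance
probability far above the published ~60%. Under these defaults the threshold
probabilities are ≈0.64 / 0.98 / 0.94, consistent with the published
60.0/99.4/91.3% pattern. Each parameter path draws from its own
counter-based stream (Philox keyed by seed + SHA-256 of the path), so adding
or removing a parameter leaves other parameters' draws untouched; draws
violating schema invariants are resampled with a cap. The CEAC reports the
fraction of draws with positive net monetary benefit on a WTP grid that
always contains the 39,619 BGN/QALY threshold.

## Synthetic scenarios

`random_parameters` draws fully valid parameter sets from configurable
uniform ranges bracketing the published inputs (rates within 10× the
published values; disutilities rescaled if the implied event burden would
exceed 90% of baseline utility). Collapsing ranges to points reproduces the
published inputs exactly. `parameters_with_known_icer` constructs sets whose
ICER is known by construction: rate ratios are drawn below 1 (QALY gain > 0,
hypoglycaemia cost offset ≤ 0), the bolus ratio is pinned at 1 so bolus costs
cancel, and the degludec basal price — the only parameter entering costs
linearly and alone — is solved so the incremental cost equals target × QALY
gain. Forward evaluation recovers the target to ~1e-15 relative.

What a green synthetic test establishes: the forward arithmetic, comparison
logic and backward construction are mutually consistent over a wide parameter
region. What it does not establish: anything about real patients — the
generator draws independent uniform parameters and inherits none of the
correlation between doses, rates and costs in real data.

## Numerical choices and limitations

* Currency is carried at full precision; rounding to 2 dp happens only in
  report writers.
* Dominance: ICER only in the NE quadrant (costlier, more effective);
  SW-quadrant ratios (cheaper, less effective) are computed but flagged, never
  ranked; ties on both axes are indeterminate. Division by a zero QALY delta
  never occurs.
* QALYs are floored at zero with a warning if the event burden exceeds the
  baseline utility (reachable only with extreme synthetic inputs).
* Limitations: no HbA1c-driven complication modelling (the treat-to-target
  design equalises glycaemic control), no adverse events beyond
  hypoglycaemia, no self-monitoring costs (out of pocket for the payer
  perspective modelled), no correlated PSA draws, no EVPI.
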