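"""Incremental cost-effectiveness computation and result assembly.

Runs one arm end-to-end (survival -> transition schedule -> cohort trace ->
discounted cost / life-year / QALY accrual with per-state decomposition)
and compares two arms: incremental cost and effect, dominance
classification, ICER, and net monetary benefit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costs import ArmSpec, WastagePolicy, build_cycle_costs
from .markov import (
    CohortTrace,
    ModelConfig,
    build_transition_schedule,
    discounted_accrual,
    life_years,
    qalys,
    run_cohort,
)

__all__ = [
    "StateBreakdown",
    "ArmResult",
    "CEComparison",
    "TwoArmModel",
    "evaluate_arm",
    "evaluate_model",
    "compare",
    "net_monetary_benefit",
    "results_table",
]

#: Willingness-to-pay thresholds: 1x / 2x / 3x China's 2019 per-capita GDP
#: in 2020 USD; the 3x value is the decision threshold.
WTP_THRESHOLDS = (10336.05, 20672.11, 31008.16)


@dataclass(frozen=True)
class StateBreakdown:
    cost: float
    ly: float
    qaly: float


@dataclass(frozen=True)
class ArmResult:
    """Discounted totals for one arm with DFS/PD state decomposition."""

    arm: str
    total_cost: float
    total_ly: float
    total_qaly: float
    by_state: dict[str, StateBreakdown]

    def __post_init__(self) -> None:
        for attr, key in (("total_cost", "cost"), ("total_ly", "ly"), ("total_qaly", "qaly")):
            total = getattr(self, attr)
            parts = sum(getattr(s, key) for s in self.by_state.values())
            if abs(total - parts) > 1e-9 * max(1.0, abs(total)):
                raise ValueError(f"{attr} does not match its state decomposition")
        if self.total_qaly > self.total_ly + 1e-9:
            raise ValueError("QALYs cannot exceed life-years")


@dataclass(frozen=True)
class CEComparison:
    """Incremental comparison of an intervention against a comparator."""

    delta_cost: float
    delta_effect: float
    verdict: str  # icer | dominant | dominated | weakly_dominant | weakly_dominated | equivalent
    icer_value: float | None
    wtp: float = WTP_THRESHOLDS[-1]
    effect_unit: str = "qaly"


@dataclass
class TwoArmModel:
    """The complete two-arm decision problem (the model fixture)."""

    gp: ArmSpec
    tpf: ArmSpec
    config: ModelConfig
    wtp_thresholds: tuple[float, ...] = WTP_THRESHOLDS
    wastage: WastagePolicy | None = None
    currency_note: str = "2020 USD (1 USD = 6.8606 RMB)"

    @property
    def wtp(self) -> float:
        return self.wtp_thresholds[-1]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_arm(
    arm: ArmSpec,
    config: ModelConfig,
    decomposition: str = "independent",
    drug_mode: str = "vial_based",
    policy: WastagePolicy | None = None,
) -> ArmResult:
    """Run one arm through the cohort model and accrue discounted outcomes."""
    schedule = build_transition_schedule(arm.dfs_model, arm.os_model, config, decomposition)
    trace = run_cohort(schedule, config)
    dfs_cost, pd_cost = build_cycle_costs(arm, config, drug_mode, policy)
    K = config.n_cycles
    cost_rewards = np.zeros((K, 3))
    cost_rewards[:, 0] = dfs_cost
    cost_rewards[:, 1] = pd_cost
    total_cost, cost_by_state = discounted_accrual(trace, cost_rewards, config)
    total_ly, ly_by_state = life_years(trace, config)
    total_qaly, qaly_by_state = qalys(trace, arm.utilities, config)
    by_state = {
        state: StateBreakdown(cost_by_state[i], ly_by_state[i], qaly_by_state[i])
        for i, state in enumerate(("DFS", "PD"))
    }
    return ArmResult(arm.name, total_cost, total_ly, total_qaly, by_state)


def evaluate_model(
    model: TwoArmModel,
    decomposition: str = "independent",
    drug_mode: str = "vial_based",
) -> tuple[ArmResult, ArmResult, CEComparison]:
    """Evaluate both arms and compare GP (intervention) vs TPF (comparator)."""
    gp = evaluate_arm(model.gp, model.config, decomposition, drug_mode, model.wastage)
    tpf = evaluate_arm(model.tpf, model.config, decomposition, drug_mode, model.wastage)
    return gp, tpf, compare(gp, tpf, wtp=model.wtp)


# ---------------------------------------------------------------------------
# incremental comparison
# ---------------------------------------------------------------------------

def _classify(delta_cost: float, delta_effect: float) -> tuple[str, float | None]:
    if delta_cost == 0.0 and delta_effect == 0.0:
        return "equivalent", None
    if delta_effect > 0.0:
        if delta_cost < 0.0:
            return "dominant", None
        if delta_cost == 0.0:
            return "weakly_dominant", None
        return "icer", delta_cost / delta_effect
    if delta_effect < 0.0:
        if delta_cost > 0.0:
            return "dominated", None
        if delta_cost == 0.0:
            return "weakly_dominated", None
        return "icer", delta_cost / delta_effect  # south-west trade-off
    # equal effect, unequal cost: cheaper arm weakly dominates
    return ("weakly_dominant", None) if delta_cost < 0 else ("weakly_dominated", None)


def compare(
    intervention: ArmResult | None = None,
    comparator: ArmResult | None = None,
    *,
    delta_cost: float | None = None,
    delta_effect: float | None = None,
    effect: str = "qaly",
    wtp: float = WTP_THRESHOLDS[-1],
) -> CEComparison:
    """Incremental comparison; accepts two ArmResults or raw increments.

    The ICER is reported only in the trade-off quadrants (more costly and
    more effective, or cheaper and less effective); dominance labels cover
    the rest, with a "weak" qualifier at exact ties so no undefined ratio
    is ever formed.
    """
    if delta_cost is None:
        if not isinstance(intervention, ArmResult) or not isinstance(comparator, ArmResult):
            raise TypeError("pass two ArmResults or delta_cost/delta_effect")
        delta_cost = intervention.total_cost - comparator.total_cost
        attr = {"qaly": "total_qaly", "ly": "total_ly"}[effect]
        delta_effect = getattr(intervention, attr) - getattr(comparator, attr)
    assert delta_effect is not None
    verdict, icer = _classify(delta_cost, delta_effect)
    return CEComparison(delta_cost, delta_effect, verdict, icer, wtp, effect)


def net_monetary_benefit(result: ArmResult, wtp: float) -> float:
    """NMB = wtp * QALYs - cost; linearizes the ICER decision rule."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * result.total_qaly - result.total_cost


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def results_table(gp: ArmResult, tpf: ArmResult) -> pd.DataFrame:
    """Base-case summary: total / DFS state / PD state rows per arm.

    Mirrors the standard cost-effectiveness report layout: discounted
    cost, life-years and QALYs with increments and per-LY / per-QALY
    ICERs (or a dominance verdict) per block.
    """
    rows = []
    for block in ("Total", "DFS state", "PD state"):
        if block == "Total":
            g = (gp.total_cost, gp.total_ly, gp.total_qaly)
            t = (tpf.total_cost, tpf.total_ly, tpf.total_qaly)
        else:
            state = "DFS" if block.startswith("DFS") else "PD"
            gs, ts = gp.by_state[state], tpf.by_state[state]
            g = (gs.cost, gs.ly, gs.qaly)
            t = (ts.cost, ts.ly, ts.qaly)
        d_cost, d_ly, d_qaly = (gi - ti for gi, ti in zip(g, t))
        per_ly = compare(delta_cost=d_cost, delta_effect=d_ly, effect="ly")
        per_qaly = compare(delta_cost=d_cost, delta_effect=d_qaly)
        for arm, vals in (("GP", g), ("TPF", t)):
            rows.append(
                {
                    "block": block,
                    "arm": arm,
                    "cost": vals[0],
                    "ly": vals[1],
                    "qaly": vals[2],
                    "incr_cost": d_cost if arm == "GP" else np.nan,
                    "incr_ly": d_ly if arm == "GP" else np.nan,
                    "incr_qaly": d_qaly if arm == "GP" else np.nan,
                    "icer_per_ly": (
                        per_ly.icer_value if per_ly.verdict == "icer" else per_ly.verdict
                    )
                    if arm == "GP"
                    else "",
                    "icer_per_qaly": (
                        per_qaly.icer_value if per_qaly.verdict == "icer" else per_qaly.verdict
                    )
                    if arm == "GP"
                    else "",
                }
            )
    return pd.DataFrame(rows)
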