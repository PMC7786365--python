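"""Cycle- and state-indexed cost accrual for one treatment arm.

The disease-free (DFS) cost stream follows the clinical pathway: three
21-day induction chemotherapy cycles, three concurrent chemoradiotherapy
(CCRT) cycles, then time-banded routine follow-up out to the 10-year
horizon.  One-time charges (PICC insertion, pre-radiotherapy imaging and
planning, expected adverse-event management) land on their designated
cycle.  The progressed-disease (PD) stream mixes subsequent-therapy and
best-supportive-care per-cycle costs by the proportion of patients who
receive subsequent therapy.

Chemotherapy drug acquisition supports two pricing modes: ``vial_based``
(whole single-use vials, the base case — wastage included) and
``exact_dose`` (the administered milligrams only), the difference being
the drug-wastage scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .markov import ModelConfig, UtilitySet
from .survival import ParametricSurvival

__all__ = [
    "CostItem",
    "AdverseEvent",
    "DrugDose",
    "WastagePolicy",
    "SurvivalUncertainty",
    "ArmSpec",
    "ConfigurationError",
    "expected_ae_cost",
    "build_cycle_costs",
    "drug_cost_per_cycle",
    "drug_cost_per_administration",
    "period_to_cycle_cost",
]

#: Number of induction chemotherapy cycles at model entry.
INDUCTION_CYCLES = 3
#: Number of CCRT cycles immediately after induction (cisplatin days 1/22/43).
CCRT_CYCLES = 3

_APPLIES = (
    "dfs_induction",
    "dfs_ccrt",
    "dfs_followup_band1",
    "dfs_followup_band2",
    "dfs_followup_band3",
    "pd",
    "one_time_cycle1",
    "one_time_ccrt_start",
)
#: Follow-up band edges in years (band 1: [0, 2), band 2: [2, 5), band 3: rest).
FOLLOWUP_BAND_EDGES_YEARS = (2.0, 5.0)

_REQUIRED_CATEGORIES = (
    "dfs_induction",
    "dfs_followup_band1",
    "dfs_followup_band2",
    "dfs_followup_band3",
)


class ConfigurationError(ValueError):
    """Raised when an arm specification is incomplete or inconsistent."""


@dataclass
class CostItem:
    """One priced resource with its uncertainty range and distribution."""

    label: str
    mean: float
    low: float
    high: float
    distribution: str = "gamma"  # gamma | beta | fixed
    applies_to: str = "dfs_induction"
    arm: str = "both"  # GP | TPF | both
    drug: str | None = None  # set for chemotherapy acquisition items

    def __post_init__(self) -> None:
        if not (self.low <= self.mean <= self.high):
            raise ValueError(f"{self.label}: range must satisfy low <= mean <= high")
        if self.mean < 0 or self.low < 0:
            raise ValueError(f"{self.label}: money must be non-negative")
        if self.applies_to not in _APPLIES:
            raise ValueError(f"{self.label}: unknown applies_to {self.applies_to!r}")
        if self.distribution not in ("gamma", "beta", "fixed"):
            raise ValueError(f"{self.label}: unknown distribution {self.distribution!r}")


@dataclass
class AdverseEvent:
    """One adverse-event class with its probability and management cost."""

    name: str
    grade_band: str  # g1_2 | g3_4
    probability: float
    unit_cost: float

    def __post_init__(self) -> None:
        if self.grade_band not in ("g1_2", "g3_4"):
            raise ValueError(f"{self.name}: unknown grade band {self.grade_band!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"{self.name}: probability must lie in [0, 1]")
        if self.unit_cost < 0:
            raise ValueError(f"{self.name}: cost must be non-negative")


@dataclass
class DrugDose:
    """Dosing rule for one drug within a cycle (per-administration dose)."""

    drug: str
    dose_mg_per_m2: float
    administrations_per_cycle: int = 1


@dataclass
class WastagePolicy:
    """Vial catalogue and pricing mode for chemotherapy acquisition.

    ``vials`` maps a drug name to (vial size in mg, price per vial) pairs.
    The catalogue here is synthetic: vial sizes follow standard Chinese
    presentations and per-vial prices are back-derived so that vial-based
    pricing at the representative body-surface area reproduces the per-cycle
    acquisition costs of the reference cost table.
    """

    mode: str = "vial_based"  # vial_based | exact_dose
    vials: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    body_surface_area_m2: float = 1.72

    def __post_init__(self) -> None:
        if self.mode not in ("vial_based", "exact_dose"):
            raise ValueError(f"unknown wastage mode {self.mode!r}")
        for drug, catalogue in self.vials.items():
            if any(size <= 0 for size, _ in catalogue):
                raise ValueError(f"{drug}: vial sizes must be positive")


@dataclass
class SurvivalUncertainty:
    """Standard errors (and scale-shape correlation) of a fitted curve."""

    scale_se: float
    shape_se: float | None = None
    correlation: float | None = None  # corr(log scale, shape)


@dataclass
class ArmSpec:
    """Everything needed to run one treatment arm through the model."""

    name: str
    dfs_model: ParametricSurvival
    os_model: ParametricSurvival
    cost_items: list[CostItem]
    ae: list[AdverseEvent]
    p_subsequent: float
    subsequent_cost_per_cycle: float
    bsc_cost_per_cycle: float
    utilities: UtilitySet
    regimen: list[DrugDose] = field(default_factory=list)
    dfs_uncertainty: SurvivalUncertainty | None = None
    os_uncertainty: SurvivalUncertainty | None = None

    def __post_init__(self) -> None:
        if self.name not in ("GP", "TPF"):
            raise ValueError("arm name must be GP or TPF")
        if not 0.0 <= self.p_subsequent <= 1.0:
            raise ValueError("p_subsequent must lie in [0, 1]")

    @property
    def pd_cost_per_cycle(self) -> float:
        """Expected PD cost: subsequent therapy or best supportive care."""
        return (
            self.p_subsequent * self.subsequent_cost_per_cycle
            + (1.0 - self.p_subsequent) * self.bsc_cost_per_cycle
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def expected_ae_cost(profile: Sequence[AdverseEvent]) -> float:
    """Expected adverse-event management cost: sum of probability x cost."""
    return float(sum(ae.probability * ae.unit_cost for ae in profile))


def period_to_cycle_cost(amount: float, period_days: float, cycle_days: float) -> float:
    """Convert a per-period cost to a per-cycle cost (pro rata by days)."""
    if period_days <= 0 or cycle_days <= 0:
        raise ValueError("periods must be positive")
    if period_days < cycle_days:
        raise ValueError("period must be at least one cycle long")
    return amount * cycle_days / period_days


def drug_cost_per_administration(
    dose_mg: float, catalogue: Sequence[tuple[float, float]], mode: str
) -> float:
    """Price one administration of ``dose_mg`` under the given pricing mode.

    ``vial_based`` finds the cheapest combination of whole vials covering
    the dose (dynamic programming over dispensed milligrams);
    ``exact_dose`` prices the administered milligrams at the best per-mg
    vial rate.  vial_based >= exact_dose always.
    """
    if not catalogue:
        raise ConfigurationError("empty vial catalogue")
    if dose_mg <= 0:
        return 0.0
    if mode == "exact_dose":
        per_mg = min(price / size for size, price in catalogue)
        return dose_mg * per_mg
    if mode != "vial_based":
        raise ValueError(f"unknown pricing mode {mode!r}")
    target = int(math.ceil(dose_mg - 1e-9))
    sizes = [(int(math.floor(size)), price) for size, price in catalogue]
    INF = float("inf")
    dp = [INF] * (target + 1)
    dp[0] = 0.0
    for t in range(1, target + 1):
        best = INF
        for size, price in sizes:
            c = dp[max(0, t - size)] + price
            if c < best:
                best = c
        dp[t] = best
    return dp[target]


def drug_cost_per_cycle(
    doses: Sequence[DrugDose], policy: WastagePolicy, mode: str | None = None
) -> float:
    """Total chemotherapy acquisition cost for one cycle of a regimen."""
    mode = mode or policy.mode
    total = 0.0
    for dose in doses:
        if dose.drug not in policy.vials:
            raise ConfigurationError(f"no vial catalogue for drug {dose.drug!r}")
        admin_mg = dose.dose_mg_per_m2 * policy.body_surface_area_m2
        total += dose.administrations_per_cycle * drug_cost_per_administration(
            admin_mg, policy.vials[dose.drug], mode
        )
    return total


def _drug_exact_costs(arm: ArmSpec, policy: WastagePolicy) -> dict[str, float]:
    """Per-cycle exact-dose cost per drug of the arm's regimen."""
    out: dict[str, float] = {}
    for dose in arm.regimen:
        if dose.drug not in policy.vials:
            raise ConfigurationError(f"no vial catalogue for drug {dose.drug!r}")
        admin_mg = dose.dose_mg_per_m2 * policy.body_surface_area_m2
        out[dose.drug] = dose.administrations_per_cycle * drug_cost_per_administration(
            admin_mg, policy.vials[dose.drug], "exact_dose"
        )
    return out


def build_cycle_costs(
    arm: ArmSpec,
    config: ModelConfig,
    drug_mode: str = "vial_based",
    policy: WastagePolicy | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle DFS and PD cost vectors (length = number of cycles).

    Index ``k`` holds the cost accrued during cycle ``k+1`` (whose start
    time is ``k`` cycle lengths after model entry).
    """
    if drug_mode not in ("vial_based", "exact_dose"):
        raise ValueError(f"unknown drug pricing mode {drug_mode!r}")
    if drug_mode == "exact_dose" and policy is None:
        raise ConfigurationError("exact_dose pricing needs a WastagePolicy")
    K = config.n_cycles
    present = {item.applies_to for item in arm.cost_items}
    for category in _REQUIRED_CATEGORIES:
        if category not in present:
            raise ConfigurationError(
                f"arm {arm.name}: no cost item in required category {category!r}"
            )
    exact = _drug_exact_costs(arm, policy) if drug_mode == "exact_dose" else {}

    start_years = np.arange(K) * config.cycle_years
    induction = slice(0, min(INDUCTION_CYCLES, K))
    ccrt = slice(INDUCTION_CYCLES, min(INDUCTION_CYCLES + CCRT_CYCLES, K))
    followup_start = INDUCTION_CYCLES + CCRT_CYCLES
    band1, band2 = FOLLOWUP_BAND_EDGES_YEARS
    in_followup = np.arange(K) >= followup_start
    masks = {
        "dfs_followup_band1": in_followup & (start_years < band1),
        "dfs_followup_band2": in_followup & (start_years >= band1) & (start_years < band2),
        "dfs_followup_band3": in_followup & (start_years >= band2),
    }

    dfs = np.zeros(K)
    pd_vec = np.full(K, arm.pd_cost_per_cycle)
    for item in arm.cost_items:
        value = item.mean
        if item.drug is not None and drug_mode == "exact_dose":
            value = exact.get(item.drug, value)
        if item.applies_to == "dfs_induction":
            dfs[induction] += value
        elif item.applies_to == "dfs_ccrt":
            dfs[ccrt] += value
        elif item.applies_to in masks:
            dfs[masks[item.applies_to]] += value
        elif item.applies_to == "pd":
            pd_vec += value
        elif item.applies_to == "one_time_cycle1":
            dfs[0] += value
        elif item.applies_to == "one_time_ccrt_start":
            if K > INDUCTION_CYCLES:
                dfs[INDUCTION_CYCLES] += value
    dfs[0] += expected_ae_cost(arm.ae)
    return dfs, pd_vec
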