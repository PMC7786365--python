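"""Three-state Markov cohort engine (DFS / PD / Death).

The whole cohort starts disease-free (DFS).  Each 21-day cycle a patient
may progress to PD or die; PD patients may die; death is absorbing.  The
per-cycle transition matrices are derived from two fitted survival curves:
the disease-free survival (DFS) curve supplies the hazard of leaving the
disease-free state, the overall survival (OS) curve supplies the hazard of
death.

Two decompositions are available:

``independent`` (default)
    The DFS-exit and death hazards act independently within a cycle:
    every alive state dies with the OS transition probability, and
    disease-free patients additionally progress with the DFS transition
    probability.  Cohort deaths then track ``1 - S_os`` exactly, and
    disease-free occupancy equals ``S_dfs * S_os``.  This decomposition
    reproduces the reference model's per-state life-year decomposition.

``partition``
    The DFS curve is read as an exit (progression-or-death) hazard:
    disease-free patients leave with the DFS transition probability, death
    takes ``min(tp_dfs, tp_os)`` of them, and the PD death probability is
    calibrated each cycle so that cumulative cohort deaths still track
    ``1 - S_os`` (clamped into [0, 1] with a warning where infeasible).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import ParametricSurvival

__all__ = [
    "STATES",
    "ModelConfig",
    "TransitionSchedule",
    "CohortTrace",
    "UtilitySet",
    "build_transition_schedule",
    "run_cohort",
    "discounted_accrual",
    "life_years",
    "qalys",
]

STATES = ("DFS", "PD", "Death")
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ModelConfig:
    """Global cycle/horizon/discounting settings."""

    cycle_length_days: float = 21.0
    horizon_years: float = 10.0
    annual_discount: float = 0.03
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if not self.cycle_length_days > 0:
            raise ValueError("cycle_length_days must be positive")
        if not 0 <= self.annual_discount < 1:
            raise ValueError("annual_discount must lie in [0, 1)")
        if self.n_cycles < 1:
            raise ValueError("horizon must cover at least one full cycle")

    @property
    def n_cycles(self) -> int:
        return int(math.floor(self.horizon_years * DAYS_PER_YEAR / self.cycle_length_days))

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR

    @property
    def cycle_discount(self) -> float:
        """Per-cycle discount factor (1+r)^(-cycle length in years)."""
        return (1.0 + self.annual_discount) ** (-self.cycle_years)

    def discount_factors(self) -> np.ndarray:
        """Discount factor applied to each cycle's accrual (cycle-start timing)."""
        return self.cycle_discount ** np.arange(self.n_cycles)


@dataclass
class TransitionSchedule:
    """Per-cycle 3x3 transition matrices over (DFS, PD, Death)."""

    matrices: np.ndarray  # shape (K, 3, 3)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1:] != (3, 3):
            raise ValueError("matrices must have shape (K, 3, 3)")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if np.max(np.abs(m.sum(axis=2) - 1.0)) > 1e-12:
            raise ValueError("every row must sum to 1")
        self.matrices = m

    def __len__(self) -> int:
        return int(self.matrices.shape[0])


@dataclass
class CohortTrace:
    """State occupancy per cycle, row 0 being the starting distribution."""

    occupancy: np.ndarray  # shape (K+1, 3)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != 3:
            raise ValueError("occupancy must have shape (K+1, 3)")
        if np.any(occ < -1e-12):
            raise ValueError("occupancy fractions must be non-negative")
        if np.max(np.abs(occ.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("occupancy rows must sum to 1")
        if np.any(np.diff(occ[:, 2]) < -1e-12):
            raise ValueError("death occupancy must be non-decreasing")
        self.occupancy = occ

    @property
    def n_cycles(self) -> int:
        return int(self.occupancy.shape[0] - 1)

    def to_frame(self, config: ModelConfig) -> pd.DataFrame:
        disc = np.concatenate([[1.0], config.discount_factors()])[: self.occupancy.shape[0]]
        return pd.DataFrame(
            {
                "cycle": np.arange(self.occupancy.shape[0]),
                "dfs": self.occupancy[:, 0],
                "pd": self.occupancy[:, 1],
                "dead": self.occupancy[:, 2],
                "discount_factor": disc,
            }
        )

    def to_csv(self, path, config: ModelConfig) -> None:
        self.to_frame(config).to_csv(path, index=False)


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utility weights; death is anchored at zero."""

    u_dfs: float = 0.76
    u_pd: float = 0.57
    u_dead: float = 0.0

    def __post_init__(self) -> None:
        if self.u_dead != 0.0:
            raise ValueError("u_dead must be exactly 0")
        if not 0.0 <= self.u_pd <= self.u_dfs <= 1.0:
            raise ValueError("utilities must satisfy 0 <= u_pd <= u_dfs <= 1")

    def as_vector(self) -> np.ndarray:
        return np.array([self.u_dfs, self.u_pd, self.u_dead])


# ---------------------------------------------------------------------------
# schedule construction
# ---------------------------------------------------------------------------

def _transition_probs(model: ParametricSurvival, config: ModelConfig) -> np.ndarray:
    """Vector of tp(k) = 1 - S(k*u)/S((k-1)*u) for k = 1..K."""
    u = config.cycle_length_days / model.unit_days
    if model.shape == 1.0:  # constant hazard: exactly cycle-index free
        return np.full(config.n_cycles, -np.expm1(-model.scale * u))
    k = np.arange(config.n_cycles + 1, dtype=float)
    h = model.cumulative_hazard(k * u)
    return np.minimum(-np.expm1(h[:-1] - h[1:]), np.nextafter(1.0, 0.0))


def build_transition_schedule(
    dfs: ParametricSurvival,
    os_model: ParametricSurvival,
    config: ModelConfig,
    decomposition: str = "independent",
) -> TransitionSchedule:
    """Per-cycle transition matrices from the DFS and OS curves."""
    if decomposition not in ("independent", "partition"):
        raise ValueError(f"unknown decomposition {decomposition!r}")
    K = config.n_cycles
    a = _transition_probs(dfs, config)       # DFS-exit probability per cycle
    b = _transition_probs(os_model, config)  # death probability per cycle
    mats = np.zeros((K, 3, 3))
    mats[:, 2, 2] = 1.0
    if decomposition == "independent":
        mats[:, 0, 0] = (1.0 - a) * (1.0 - b)
        mats[:, 0, 1] = a * (1.0 - b)
        mats[:, 0, 2] = b
        mats[:, 1, 1] = 1.0 - b
        mats[:, 1, 2] = b
        return TransitionSchedule(mats)

    # partition: DFS exits with tp_dfs, deaths capped by tp_os; PD deaths
    # calibrated so the cohort death curve still follows 1 - S_os.
    u_os = config.cycle_length_days / os_model.unit_days
    s_os = os_model.survival(np.arange(K + 1, dtype=float) * u_os)
    occ = np.array([1.0, 0.0, 0.0])
    clamped: list[int] = []
    for k in range(K):
        d_dfs = min(a[k], b[k])
        to_pd = a[k] - d_dfs
        # cumulative-target calibration: absorb any earlier shortfall
        required = (1.0 - s_os[k + 1]) - occ[2]
        deaths_from_dfs = occ[0] * d_dfs
        if occ[1] > 1e-15:
            p_pd_death = (required - deaths_from_dfs) / occ[1]
        else:
            p_pd_death = 0.0 if required <= deaths_from_dfs + 1e-15 else 1.5
        if p_pd_death < 0.0 or p_pd_death > 1.0:
            clamped.append(k + 1)
            p_pd_death = min(max(p_pd_death, 0.0), 1.0)
        mats[k, 0] = [1.0 - a[k], to_pd, d_dfs]
        mats[k, 1] = [0.0, 1.0 - p_pd_death, p_pd_death]
        occ = occ @ mats[k]
    if clamped:
        warnings.warn(
            "PD->Death calibration clamped to [0, 1] in cycles "
            f"{clamped[:10]}{'...' if len(clamped) > 10 else ''}",
            RuntimeWarning,
            stacklevel=2,
        )
    return TransitionSchedule(mats)


# ---------------------------------------------------------------------------
# cohort simulation and accrual
# ---------------------------------------------------------------------------

def run_cohort(
    schedule: TransitionSchedule,
    config: ModelConfig,
    start: np.ndarray | None = None,
) -> CohortTrace:
    """Propagate the cohort distribution through the schedule."""
    K = config.n_cycles
    if len(schedule) < K:
        raise ValueError(f"schedule has {len(schedule)} cycles, config needs {K}")
    if start is None:
        start = np.array([1.0, 0.0, 0.0])
    start = np.asarray(start, dtype=float)
    if start.shape != (3,) or abs(start.sum() - 1.0) > 1e-12 or np.any(start < 0):
        raise ValueError("start must be a probability vector over the 3 states")
    occ = np.empty((K + 1, 3))
    occ[0] = start
    for k in range(K):
        occ[k + 1] = occ[k] @ schedule.matrices[k]
    return CohortTrace(occ)


def discounted_accrual(
    trace: CohortTrace, rewards: np.ndarray, config: ModelConfig
) -> tuple[float, np.ndarray]:
    """Discounted reward total and its per-state decomposition.

    ``rewards`` has shape (K, 3): the reward earned during cycle k by a
    patient in each state.  Accrual uses the cycle-start occupancy (the
    distribution after k-1 transitions) discounted at the cycle-start
    time; with half-cycle correction on, the cycle-start and cycle-end
    occupancies are averaged.
    """
    rewards = np.asarray(rewards, dtype=float)
    K = config.n_cycles
    if rewards.shape != (K, 3):
        raise ValueError(f"rewards must have shape ({K}, 3), got {rewards.shape}")
    if trace.n_cycles < K:
        raise ValueError("trace is shorter than the configured horizon")
    occ = trace.occupancy
    occ_used = 0.5 * (occ[:K] + occ[1 : K + 1]) if config.half_cycle_correction else occ[:K]
    disc = config.discount_factors()
    by_state = (disc[:, None] * occ_used * rewards).sum(axis=0)
    return float(by_state.sum()), by_state


def life_years(trace: CohortTrace, config: ModelConfig) -> tuple[float, np.ndarray]:
    """Discounted life-years (cycle length in years per alive-state cycle)."""
    K = config.n_cycles
    rewards = np.zeros((K, 3))
    rewards[:, 0] = rewards[:, 1] = config.cycle_years
    return discounted_accrual(trace, rewards, config)


def qalys(
    trace: CohortTrace, utilities: UtilitySet, config: ModelConfig
) -> tuple[float, np.ndarray]:
    """Discounted quality-adjusted life-years."""
    K = config.n_cycles
    rewards = np.tile(utilities.as_vector() * config.cycle_years, (K, 1))
    return discounted_accrual(trace, rewards, config)
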