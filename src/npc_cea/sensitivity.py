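"""One-way (tornado) and probabilistic sensitivity analysis.

One-way analysis re-evaluates the full base case at each parameter's lower
and upper bound, holding everything else fixed, and ranks parameters by
the spread of the resulting cost-effectiveness ratios.

Probabilistic analysis draws every uncertain parameter from its assigned
distribution — gamma for costs, beta for probabilities and utilities
(method-of-moments from the published mean and range, treating the range
as a 95% interval), and correlated normal on (log scale, shape) for the
fitted survival parameters — rebuilds both arms, and records the joint
(incremental cost, incremental QALY) sample for the cost-effectiveness
plane and acceptability curve.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .costs import ArmSpec, SurvivalUncertainty
from .economics import TwoArmModel, evaluate_model
from .markov import UtilitySet
from .survival import ParametricSurvival

__all__ = [
    "ParamSpec",
    "PSAConfig",
    "PSAResult",
    "TornadoEntry",
    "default_range",
    "gamma_from_mean_bounds",
    "beta_from_mean_bounds",
    "apply_param",
    "owsa",
    "run_psa",
    "ceac",
]

RANGE_Z = 3.92  # width of a 95% interval in standard errors


# ---------------------------------------------------------------------------
# parameter specification and targeting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamSpec:
    """One uncertain parameter: base value, range, distribution, target.

    ``target`` addresses the model quantity the parameter perturbs, e.g.
    ``cost_item:both:Radiotherapy`` or ``p_subsequent:GP``.
    """

    name: str
    base: float
    low: float
    high: float
    family: str  # gamma | beta | fixed
    target: str

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValueError(f"{self.name}: need low <= base <= high")
        if self.family == "beta" and not (0 <= self.low and self.high <= 1):
            raise ValueError(f"{self.name}: beta requires values in [0, 1]")


def default_range(base: float) -> tuple[float, float]:
    """The +/-20% default range used when no empirical range is available."""
    lo, hi = 0.8 * base, 1.2 * base
    return (min(lo, hi), max(lo, hi))


def _arms(model: TwoArmModel, arm: str) -> list[ArmSpec]:
    if arm == "both":
        return [model.gp, model.tpf]
    if arm == "GP":
        return [model.gp]
    if arm == "TPF":
        return [model.tpf]
    raise KeyError(f"unknown arm {arm!r}")


def apply_param(model: TwoArmModel, target: str, value: float) -> None:
    """Write ``value`` into the (already copied) model at ``target``."""
    kind, _, rest = target.partition(":")
    if kind == "cost_item":
        arm, _, label = rest.partition(":")
        hit = False
        for spec in _arms(model, arm):
            for item in spec.cost_items:
                if item.label == label:
                    item.mean = value
                    hit = True
        if not hit:
            raise KeyError(f"no cost item {label!r} in arm {arm}")
    elif kind == "ae_cost":
        arm, _, band = rest.partition(":")
        hit = False
        for spec in _arms(model, arm):
            for ae in spec.ae:
                if ae.grade_band == band:
                    ae.unit_cost = value
                    hit = True
        if not hit:
            raise KeyError(f"no adverse events in band {band!r} for arm {arm}")
    elif kind == "ae_prob":
        arm, _, name = rest.partition(":")
        hit = False
        for spec in _arms(model, arm):
            for ae in spec.ae:
                if ae.name == name:
                    ae.probability = value
                    hit = True
        if not hit:
            raise KeyError(f"no adverse event {name!r} in arm {arm}")
    elif kind == "utility":
        # independent draws can rarely invert the DFS >= PD ordering; the
        # PD utility is capped at the DFS utility to keep the state ranking
        for spec in (model.gp, model.tpf):
            if rest == "dfs":
                spec.utilities = replace(
                    spec.utilities, u_dfs=value, u_pd=min(spec.utilities.u_pd, value)
                )
            elif rest == "pd":
                spec.utilities = replace(
                    spec.utilities, u_pd=min(value, spec.utilities.u_dfs)
                )
            else:
                raise KeyError(f"unknown utility target {rest!r}")
    elif kind == "p_subsequent":
        for spec in _arms(model, rest):
            spec.p_subsequent = value
    elif kind == "subsequent_cost":
        for spec in _arms(model, rest):
            spec.subsequent_cost_per_cycle = value
    elif kind == "bsc_cost":
        for spec in _arms(model, rest or "both"):
            spec.bsc_cost_per_cycle = value
    elif kind == "discount":
        model.config = replace(model.config, annual_discount=value)
    elif kind == "none":
        pass  # a parameter the model never reads (spread must come out zero)
    else:
        raise KeyError(f"unknown parameter target {target!r}")


# ---------------------------------------------------------------------------
# distribution builders (method of moments from mean and 95% range)
# ---------------------------------------------------------------------------

def gamma_from_mean_bounds(mean: float, low: float, high: float) -> tuple[float, float]:
    """(shape, rate) of a gamma with the given mean and range-implied SE."""
    if mean <= 0:
        raise ValueError("gamma mean must be positive")
    se = (high - low) / RANGE_Z
    if se <= 0:
        raise ValueError("bounds imply a non-positive standard error")
    shape = mean**2 / se**2
    rate = mean / se**2
    return shape, rate


def beta_from_mean_bounds(mean: float, low: float, high: float) -> tuple[float, float]:
    """(alpha, beta) matching the mean and range-implied SE.

    The SE is truncated just below the feasibility bound
    ``sqrt(mean*(1-mean))`` when the published range implies an infeasible
    variance for a beta on [0, 1].
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("beta mean must lie strictly in (0, 1)")
    se = (high - low) / RANGE_Z
    if se <= 0:
        raise ValueError("bounds imply a non-positive standard error")
    cap = 0.99 * math.sqrt(mean * (1.0 - mean))
    se = min(se, cap)
    nu = mean * (1.0 - mean) / se**2 - 1.0
    return mean * nu, (1.0 - mean) * nu


def _sampler(spec: ParamSpec) -> Callable[[np.random.Generator], float]:
    """Per-parameter sampling function; degenerate ranges collapse to base."""
    if spec.family == "fixed" or spec.high <= spec.low or spec.base == 0.0:
        return lambda rng: spec.base
    if spec.family == "gamma":
        shape, rate = gamma_from_mean_bounds(spec.base, spec.low, spec.high)
        return lambda rng: float(rng.gamma(shape, 1.0 / rate))
    if spec.family == "beta":
        a, b = beta_from_mean_bounds(spec.base, spec.low, spec.high)
        return lambda rng: float(rng.beta(a, b))
    raise ValueError(f"unknown distribution family {spec.family!r}")


# ---------------------------------------------------------------------------
# one-way sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    name: str
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _icer_ratio(model: TwoArmModel) -> float:
    """Raw incremental cost over incremental QALYs (sign retained)."""
    gp, tpf, _ = evaluate_model(model)
    return (gp.total_cost - tpf.total_cost) / (gp.total_qaly - tpf.total_qaly)


def owsa(model: TwoArmModel, specs: Sequence[ParamSpec]) -> list[TornadoEntry]:
    """Tornado analysis: full re-evaluation at each bound, ranked by spread."""
    entries = []
    for spec in specs:
        vals = []
        for bound in (spec.low, spec.high):
            perturbed = copy.deepcopy(model)
            apply_param(perturbed, spec.target, bound)
            vals.append(_icer_ratio(perturbed))
        entries.append(TornadoEntry(spec.name, vals[0], vals[1]))
    return sorted(entries, key=lambda e: e.spread, reverse=True)


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.name,
                "icer_at_low": e.icer_at_low,
                "icer_at_high": e.icer_at_high,
                "spread": e.spread,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

_DEFAULT_GRID = tuple(
    sorted(set(np.arange(0.0, 65000.0, 2500.0)) | {10336.05, 20672.11, 31008.16})
)


@dataclass(frozen=True)
class PSAConfig:
    n_samples: int = 10000
    seed: int = 0
    wtp_grid: tuple[float, ...] = _DEFAULT_GRID

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        grid = np.asarray(self.wtp_grid, float)
        if grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("wtp_grid must be non-empty and increasing")


@dataclass
class PSAResult:
    """Joint (incremental cost, incremental QALY) Monte Carlo samples."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return int(self.delta_cost.size)

    @property
    def n_nonfinite(self) -> int:
        return int((~(np.isfinite(self.delta_cost) & np.isfinite(self.delta_qaly))).sum())

    def prob_cost_effective(self, wtp: float) -> float:
        """Fraction of samples with positive incremental net monetary benefit."""
        nmb = wtp * self.delta_qaly - self.delta_cost
        return float(np.mean(nmb > 0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": np.arange(self.n),
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
            }
        )


def _perturb_survival(
    model: ParametricSurvival,
    unc: SurvivalUncertainty | None,
    rng: np.random.Generator,
) -> ParametricSurvival:
    """Correlated (log scale, shape) normal draw around the fitted curve."""
    z = rng.standard_normal(2)  # always consume two draws for reproducibility
    if unc is None:
        return model
    sigma_log_scale = unc.scale_se / model.scale
    log_scale = math.log(model.scale) + sigma_log_scale * z[0]
    if model.family == "exponential" or unc.shape_se is None:
        return replace(model, scale=math.exp(log_scale))
    rho = unc.correlation if unc.correlation is not None else 0.0
    w = rho * z[0] + math.sqrt(max(0.0, 1.0 - rho**2)) * z[1]
    shape = max(model.shape + unc.shape_se * w, 0.05)
    return replace(model, scale=math.exp(log_scale), shape=shape)


def run_psa(
    model: TwoArmModel,
    specs: Sequence[ParamSpec],
    config: PSAConfig,
    survival_mode: str = "lognormal",
) -> PSAResult:
    """Monte Carlo propagation of parameter uncertainty through both arms.

    Each replicate draws every parameter once (parameters shared between
    arms get a single draw), perturbs the four survival curves, rebuilds
    and reruns both arms, and records the incremental cost and QALYs.
    Non-finite replicates are kept (and counted) rather than dropped.
    """
    if survival_mode not in ("lognormal", "fixed"):
        raise ValueError(f"unknown survival_mode {survival_mode!r}")
    rng = np.random.default_rng(config.seed)
    samplers = [(spec, _sampler(spec)) for spec in specs]
    d_cost = np.empty(config.n_samples)
    d_qaly = np.empty(config.n_samples)
    for i in range(config.n_samples):
        m = copy.deepcopy(model)
        for spec, draw in samplers:
            apply_param(m, spec.target, draw(rng))
        for arm in (m.gp, m.tpf):
            if survival_mode == "lognormal":
                arm.dfs_model = _perturb_survival(arm.dfs_model, arm.dfs_uncertainty, rng)
                arm.os_model = _perturb_survival(arm.os_model, arm.os_uncertainty, rng)
        gp, tpf, _ = evaluate_model(m)
        d_cost[i] = gp.total_cost - tpf.total_cost
        d_qaly[i] = gp.total_qaly - tpf.total_qaly
    return PSAResult(d_cost, d_qaly, config.seed)


def ceac(result: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    grid = np.asarray(wtp_grid, float)
    probs = [result.prob_cost_effective(w) for w in grid]
    return pd.DataFrame({"wtp": grid, "probability": probs})


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def plot_tornado(entries: Sequence[TornadoEntry], base_icer: float, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = list(entries)[::-1]
    fig, ax = plt.subplots(figsize=(7, max(3, 0.35 * len(entries))))
    for i, e in enumerate(entries):
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))
        ax.barh(i, hi - lo, left=lo, color="#4878d0", alpha=0.8)
    ax.axvline(base_icer, color="k", lw=1, ls="--", label="base-case ICER")
    ax.set_yticks(range(len(entries)), [e.name for e in entries], fontsize=8)
    ax.set_xlabel("ICER, $ per QALY")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ce_plane(result: PSAResult, wtp: float, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(result.delta_qaly, result.delta_cost, s=3, alpha=0.25, color="#4878d0")
    lim = max(abs(result.delta_qaly).max(), 0.1)
    xs = np.linspace(-lim, lim, 9)
    ax.plot(xs, wtp * xs, "k--", lw=1, label=f"WTP ${wtp:,.2f}/QALY")
    ax.axhline(0, color="gray", lw=0.7)
    ax.axvline(0, color="gray", lw=0.7)
    ax.set_xlabel("Incremental QALYs (GP - TPF)")
    ax.set_ylabel("Incremental cost, $ (GP - TPF)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: pd.DataFrame, thresholds: Sequence[float], path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp"], curve["probability"], color="#4878d0", label="GP vs TPF")
    ax.plot(curve["wtp"], 1.0 - curve["probability"], color="#d65f5f", label="TPF vs GP")
    for t in thresholds:
        ax.axvline(t, color="gray", lw=0.7, ls=":")
    ax.set_xlabel("Willingness-to-pay, $ per QALY")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
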