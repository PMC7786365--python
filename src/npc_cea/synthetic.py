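"""Synthetic inputs: simulated time-to-event data and the reference fixture.

Nothing in this package is downloaded.  Two kinds of input are generated:

* censored individual-patient samples drawn from a known Weibull or
  exponential law (inverse-transform sampling), plus their Kaplan-Meier
  curves with at-risk tables — the inputs the curve-digitization /
  pseudo-IPD reconstruction workflow consumes in tests;

* :func:`reference_fixture` — the complete two-arm model specification of
  the GP-vs-TPF induction chemotherapy comparison in locoregionally
  advanced nasopharyngeal carcinoma: fitted survival parameters, the full
  cost catalogue with uncertainty ranges, utilities, adverse-event
  profiles, subsequent-therapy proportions, cycle/horizon/discount
  settings and willingness-to-pay thresholds, all in 2020 USD.

Quantities that the source cost table only carries in its unpublished
supplement (grade-1-2 adverse-event probabilities, the vial catalogue) are
synthetic stand-ins documented field by field below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .costs import (
    AdverseEvent,
    ArmSpec,
    CostItem,
    DrugDose,
    SurvivalUncertainty,
    WastagePolicy,
)
from .economics import TwoArmModel, WTP_THRESHOLDS
from .markov import ModelConfig, UtilitySet
from .sensitivity import ParamSpec, default_range
from .survival import DigitizedCurve, ParametricSurvival, PseudoIPD, km_estimate

__all__ = [
    "SimSpec",
    "simulate_ipd",
    "km_estimate",
    "reference_fixture",
    "default_param_specs",
    "GP_COHORT_SIZE",
    "TPF_COHORT_SIZE",
]

#: Real-world cohort sizes of the two study arms (used as default n in
#: parameter-recovery simulations).
GP_COHORT_SIZE = 71
TPF_COHORT_SIZE = 87


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimSpec:
    """Recipe for one simulated censored time-to-event sample.

    ``censoring`` is ``("none",)``, ``("uniform", T)`` for uniform(0, T)
    censoring times, or ``("administrative", T)`` for a fixed cutoff.
    """

    generating_model: ParametricSurvival
    n_subjects: int
    censoring: tuple = ("none",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.censoring[0] not in ("none", "uniform", "administrative"):
            raise ValueError(f"unknown censoring scheme {self.censoring[0]!r}")


def simulate_ipd(spec: SimSpec) -> PseudoIPD:
    """Draw event times by inverse transform; apply the censoring scheme."""
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=spec.n_subjects)
    t_event = spec.generating_model.inverse_survival(u)
    scheme = spec.censoring[0]
    if scheme == "none":
        return PseudoIPD(t_event, np.ones(spec.n_subjects, dtype=int))
    horizon = float(spec.censoring[1])
    if scheme == "uniform":
        t_cens = rng.uniform(0.0, horizon, size=spec.n_subjects)
    else:
        t_cens = np.full(spec.n_subjects, horizon)
    observed = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(int)
    return PseudoIPD(observed, events)


# ---------------------------------------------------------------------------
# the reference two-arm fixture
# ---------------------------------------------------------------------------

def _gp_arm() -> ArmSpec:
    cost_items = [
        CostItem("Gemcitabine", 559.26, 328.92, 902.79, "gamma", "dfs_induction", "GP",
                 drug="gemcitabine"),
        CostItem("Cisplatin", 13.47, 8.38, 16.75, "gamma", "dfs_induction", "both",
                 drug="cisplatin"),
        CostItem("Cisplatin", 13.47, 8.38, 16.75, "gamma", "dfs_ccrt", "both"),
        CostItem("Hydration", 53.16, 38.91, 68.13, "gamma", "dfs_induction", "GP"),
        CostItem("Antiemetic drugs", 82.78, 66.22, 99.33, "gamma", "dfs_induction", "both"),
        CostItem("Hospitalization", 115.47, 92.38, 138.57, "gamma", "dfs_induction", "GP"),
        CostItem("PICC", 235.74, 188.60, 282.89, "gamma", "one_time_cycle1", "GP"),
        CostItem("Laboratory test", 108.20, 86.57, 129.85, "gamma", "dfs_induction", "GP"),
        CostItem("Imaging examination", 201.50, 161.20, 241.80, "gamma",
                 "one_time_ccrt_start", "both"),
        CostItem("Radiotherapy", 2624.40, 2099.52, 3149.28, "gamma", "dfs_ccrt", "both"),
        CostItem("Preparation of radiotherapy", 1066.24, 852.99, 1279.48, "gamma",
                 "one_time_ccrt_start", "both"),
        CostItem("Follow-up, first 2 years", 147.26, 117.81, 176.71, "gamma",
                 "dfs_followup_band1", "both"),
        CostItem("Follow-up, years 3-5", 81.58, 65.27, 97.90, "gamma",
                 "dfs_followup_band2", "both"),
        CostItem("Follow-up, years 6-10", 40.79, 32.63, 48.95, "gamma",
                 "dfs_followup_band3", "both"),
    ]
    ae = [
        AdverseEvent("leucopenia", "g3_4", 0.1408, 655.52),
        AdverseEvent("neutropenia", "g3_4", 0.1408, 655.52),
        # grade 1-2 probability is a synthetic stand-in (not published)
        AdverseEvent("any_grade_1_2", "g1_2", 0.60, 372.42),
    ]
    return ArmSpec(
        name="GP",
        dfs_model=ParametricSurvival("weibull", 0.00059, 1.48831, "cycles"),
        os_model=ParametricSurvival("exponential", 0.00085, 1.0, "cycles"),
        cost_items=cost_items,
        ae=ae,
        p_subsequent=0.75,
        subsequent_cost_per_cycle=541.36,
        bsc_cost_per_cycle=52.53,
        utilities=UtilitySet(0.76, 0.57),
        regimen=[
            DrugDose("gemcitabine", 1000.0, 2),  # days 1 and 8
            DrugDose("cisplatin", 25.0, 3),      # days 1-3
        ],
        dfs_uncertainty=SurvivalUncertainty(0.00016, 0.07527, -0.97349),
        os_uncertainty=SurvivalUncertainty(0.00005),
    )


def _tpf_arm() -> ArmSpec:
    cost_items = [
        CostItem("Docetaxel", 764.46, 547.04, 1137.24, "gamma", "dfs_induction", "TPF",
                 drug="docetaxel"),
        CostItem("Fluorouracil", 148.40, 80.19, 200.48, "gamma", "dfs_induction", "TPF",
                 drug="fluorouracil"),
        CostItem("Cisplatin", 13.47, 8.38, 16.75, "gamma", "dfs_induction", "both",
                 drug="cisplatin"),
        CostItem("Cisplatin", 13.47, 8.38, 16.75, "gamma", "dfs_ccrt", "both"),
        CostItem("Prophylactic leucocyte (G-CSF)", 89.86, 71.89, 107.83, "gamma",
                 "dfs_induction", "TPF"),
        CostItem("Hydration", 49.36, 32.89, 69.90, "gamma", "dfs_induction", "TPF"),
        CostItem("Antiemetic drugs", 82.78, 66.22, 99.33, "gamma", "dfs_induction", "both"),
        CostItem("Hospitalization", 96.23, 76.98, 115.47, "gamma", "dfs_induction", "TPF"),
        CostItem("PICC", 347.24, 277.79, 416.69, "gamma", "one_time_cycle1", "TPF"),
        CostItem("Laboratory test", 119.03, 95.23, 142.84, "gamma", "dfs_induction", "TPF"),
        CostItem("Imaging examination", 201.50, 161.20, 241.80, "gamma",
                 "one_time_ccrt_start", "both"),
        CostItem("Radiotherapy", 2624.40, 2099.52, 3149.28, "gamma", "dfs_ccrt", "both"),
        CostItem("Preparation of radiotherapy", 1066.24, 852.99, 1279.48, "gamma",
                 "one_time_ccrt_start", "both"),
        CostItem("Follow-up, first 2 years", 147.26, 117.81, 176.71, "gamma",
                 "dfs_followup_band1", "both"),
        CostItem("Follow-up, years 3-5", 81.58, 65.27, 97.90, "gamma",
                 "dfs_followup_band2", "both"),
        CostItem("Follow-up, years 6-10", 40.79, 32.63, 48.95, "gamma",
                 "dfs_followup_band3", "both"),
    ]
    ae = [
        AdverseEvent("leucopenia", "g3_4", 0.3448, 770.69),
        AdverseEvent("neutropenia", "g3_4", 0.2414, 770.69),
        AdverseEvent("any_grade_1_2", "g1_2", 0.70, 345.50),
    ]
    return ArmSpec(
        name="TPF",
        dfs_model=ParametricSurvival("weibull", 0.00256, 1.14471, "cycles"),
        os_model=ParametricSurvival("weibull", 0.00097, 1.15449, "cycles"),
        cost_items=cost_items,
        ae=ae,
        p_subsequent=0.682,
        subsequent_cost_per_cycle=524.08,
        bsc_cost_per_cycle=52.53,
        utilities=UtilitySet(0.76, 0.57),
        regimen=[
            DrugDose("docetaxel", 60.0, 1),      # day 1
            DrugDose("fluorouracil", 600.0, 5),  # days 1-5
            DrugDose("cisplatin", 25.0, 3),      # days 1-3
        ],
        dfs_uncertainty=SurvivalUncertainty(0.00063, 0.06796, -0.97115),
        os_uncertainty=SurvivalUncertainty(0.00033, 0.09365, -0.95184),
    )


def _vial_catalogue() -> WastagePolicy:
    """Synthetic vial catalogue (standard presentations; prices back-derived).

    Per-vial prices are chosen so that cheapest whole-vial covering of the
    per-administration doses at a 1.72 m^2 body surface area reproduces
    the per-cycle acquisition costs of the reference cost table exactly.
    """
    return WastagePolicy(
        mode="vial_based",
        vials={
            "gemcitabine": [(1000.0, 155.35), (200.0, 31.07)],
            "cisplatin": [(30.0, 2.61), (10.0, 0.94)],
            "docetaxel": [(80.0, 509.64), (20.0, 127.41)],
            "fluorouracil": [(250.0, 5.936)],
        },
        body_surface_area_m2=1.72,
    )


def reference_fixture() -> TwoArmModel:
    """The complete GP-vs-TPF decision model (21-day cycles, 10 years, 3%)."""
    return TwoArmModel(
        gp=_gp_arm(),
        tpf=_tpf_arm(),
        config=ModelConfig(
            cycle_length_days=21.0,
            horizon_years=10.0,
            annual_discount=0.03,
            half_cycle_correction=False,
        ),
        wtp_thresholds=WTP_THRESHOLDS,
        wastage=_vial_catalogue(),
    )


# ---------------------------------------------------------------------------
# default sensitivity-parameter list
# ---------------------------------------------------------------------------

def default_param_specs(include_discount: bool = True) -> list[ParamSpec]:
    """Uncertain parameters for tornado and probabilistic analyses.

    Costs are gamma, probabilities and utilities beta; ranges are the
    published ones where available and +/-20% of baseline otherwise.  The
    discount rate enters the one-way analysis only (family ``fixed``).
    """
    specs: list[ParamSpec] = []

    def cost(name, arm, label, base, low, high):
        specs.append(ParamSpec(name, base, low, high, "gamma", f"cost_item:{arm}:{label}"))

    cost("Cost of gemcitabine (GP)", "GP", "Gemcitabine", 559.26, 328.92, 902.79)
    cost("Cost of docetaxel (TPF)", "TPF", "Docetaxel", 764.46, 547.04, 1137.24)
    cost("Cost of fluorouracil (TPF)", "TPF", "Fluorouracil", 148.40, 80.19, 200.48)
    cost("Cost of cisplatin", "both", "Cisplatin", 13.47, 8.38, 16.75)
    cost("Cost of G-CSF (TPF)", "TPF", "Prophylactic leucocyte (G-CSF)",
         89.86, 71.89, 107.83)
    cost("Cost of hydration (GP)", "GP", "Hydration", 53.16, 38.91, 68.13)
    cost("Cost of hydration (TPF)", "TPF", "Hydration", 49.36, 32.89, 69.90)
    cost("Cost of antiemetics", "both", "Antiemetic drugs", 82.78, 66.22, 99.33)
    cost("Cost of hospitalization (GP)", "GP", "Hospitalization", 115.47, 92.38, 138.57)
    cost("Cost of hospitalization (TPF)", "TPF", "Hospitalization", 96.23, 76.98, 115.47)
    cost("Cost of PICC (GP)", "GP", "PICC", 235.74, 188.60, 282.89)
    cost("Cost of PICC (TPF)", "TPF", "PICC", 347.24, 277.79, 416.69)
    cost("Cost of laboratory tests (GP)", "GP", "Laboratory test", 108.20, 86.57, 129.85)
    cost("Cost of laboratory tests (TPF)", "TPF", "Laboratory test", 119.03, 95.23, 142.84)
    cost("Cost of imaging", "both", "Imaging examination", 201.50, 161.20, 241.80)
    cost("Cost of radiotherapy", "both", "Radiotherapy", 2624.40, 2099.52, 3149.28)
    cost("Cost of radiotherapy preparation", "both", "Preparation of radiotherapy",
         1066.24, 852.99, 1279.48)
    cost("Cost of follow-up, years 0-2", "both", "Follow-up, first 2 years",
         147.26, 117.81, 176.71)
    cost("Cost of follow-up, years 3-5", "both", "Follow-up, years 3-5",
         81.58, 65.27, 97.90)
    cost("Cost of follow-up, years 6-10", "both", "Follow-up, years 6-10",
         40.79, 32.63, 48.95)

    specs += [
        ParamSpec("Cost of subsequent treatment (GP)", 541.36, 433.09, 649.63,
                  "gamma", "subsequent_cost:GP"),
        ParamSpec("Cost of subsequent treatment (TPF)", 524.08, 419.26, 628.89,
                  "gamma", "subsequent_cost:TPF"),
        ParamSpec("Cost of best supportive care", 52.53, 42.02, 63.04,
                  "gamma", "bsc_cost:both"),
        ParamSpec("Cost of AE management, grades 1-2 (GP)", 372.42, 124.57, 731.95,
                  "gamma", "ae_cost:GP:g1_2"),
        ParamSpec("Cost of AE management, grades 1-2 (TPF)", 345.50, 117.46, 708.22,
                  "gamma", "ae_cost:TPF:g1_2"),
        ParamSpec("Cost of AE management, grades 3-4 (GP)", 655.52, 399.58, 1093.12,
                  "gamma", "ae_cost:GP:g3_4"),
        ParamSpec("Cost of AE management, grades 3-4 (TPF)", 770.69, 296.43, 1820.50,
                  "gamma", "ae_cost:TPF:g3_4"),
        ParamSpec("Utility of DFS", 0.76, 0.61, 0.91, "beta", "utility:dfs"),
        ParamSpec("Utility of PD", 0.57, 0.46, 0.68, "beta", "utility:pd"),
        ParamSpec("Proportion receiving subsequent treatment (GP)", 0.75,
                  *default_range(0.75), "beta", "p_subsequent:GP"),
        ParamSpec("Proportion receiving subsequent treatment (TPF)", 0.682,
                  *default_range(0.682), "beta", "p_subsequent:TPF"),
        ParamSpec("Probability of grade 3-4 leucopenia (GP)", 0.1408,
                  *default_range(0.1408), "beta", "ae_prob:GP:leucopenia"),
        ParamSpec("Probability of grade 3-4 leucopenia (TPF)", 0.3448,
                  *default_range(0.3448), "beta", "ae_prob:TPF:leucopenia"),
        ParamSpec("Probability of grade 3-4 neutropenia (GP)", 0.1408,
                  *default_range(0.1408), "beta", "ae_prob:GP:neutropenia"),
        ParamSpec("Probability of grade 3-4 neutropenia (TPF)", 0.2414,
                  *default_range(0.2414), "beta", "ae_prob:TPF:neutropenia"),
        ParamSpec("Probability of grade 1-2 AEs (GP)", 0.60,
                  *default_range(0.60), "beta", "ae_prob:GP:any_grade_1_2"),
        ParamSpec("Probability of grade 1-2 AEs (TPF)", 0.70,
                  *default_range(0.70), "beta", "ae_prob:TPF:any_grade_1_2"),
    ]
    if include_discount:
        specs.append(
            ParamSpec("Annual discount rate", 0.03, *default_range(0.03),
                      "fixed", "discount")
        )
    return specs
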