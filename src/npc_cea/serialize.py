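"""YAML (de)serialization of the two-arm model specification.

The on-disk schema mirrors the dataclasses field by field so a fixture
round-trips losslessly; it is also the configuration format the command
line accepts.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .costs import (
    AdverseEvent,
    ArmSpec,
    CostItem,
    DrugDose,
    SurvivalUncertainty,
    WastagePolicy,
)
from .economics import TwoArmModel
from .markov import ModelConfig, UtilitySet
from .survival import ParametricSurvival

__all__ = ["model_to_dict", "model_from_dict", "save_model", "load_model"]


def _surv_to_dict(m: ParametricSurvival) -> dict:
    return {"family": m.family, "scale": m.scale, "shape": m.shape,
            "time_unit": m.time_unit}


def _arm_to_dict(arm: ArmSpec) -> dict:
    return {
        "name": arm.name,
        "dfs_model": _surv_to_dict(arm.dfs_model),
        "os_model": _surv_to_dict(arm.os_model),
        "cost_items": [asdict(i) for i in arm.cost_items],
        "ae": [asdict(a) for a in arm.ae],
        "p_subsequent": arm.p_subsequent,
        "subsequent_cost_per_cycle": arm.subsequent_cost_per_cycle,
        "bsc_cost_per_cycle": arm.bsc_cost_per_cycle,
        "utilities": asdict(arm.utilities),
        "regimen": [asdict(d) for d in arm.regimen],
        "dfs_uncertainty": asdict(arm.dfs_uncertainty) if arm.dfs_uncertainty else None,
        "os_uncertainty": asdict(arm.os_uncertainty) if arm.os_uncertainty else None,
    }


def _arm_from_dict(d: dict) -> ArmSpec:
    return ArmSpec(
        name=d["name"],
        dfs_model=ParametricSurvival(**d["dfs_model"]),
        os_model=ParametricSurvival(**d["os_model"]),
        cost_items=[CostItem(**i) for i in d["cost_items"]],
        ae=[AdverseEvent(**a) for a in d["ae"]],
        p_subsequent=d["p_subsequent"],
        subsequent_cost_per_cycle=d["subsequent_cost_per_cycle"],
        bsc_cost_per_cycle=d["bsc_cost_per_cycle"],
        utilities=UtilitySet(**d["utilities"]),
        regimen=[DrugDose(**r) for r in d.get("regimen", [])],
        dfs_uncertainty=(
            SurvivalUncertainty(**d["dfs_uncertainty"]) if d.get("dfs_uncertainty") else None
        ),
        os_uncertainty=(
            SurvivalUncertainty(**d["os_uncertainty"]) if d.get("os_uncertainty") else None
        ),
    )


def model_to_dict(model: TwoArmModel) -> dict:
    wastage = None
    if model.wastage is not None:
        wastage = {
            "mode": model.wastage.mode,
            "vials": {
                drug: [list(v) for v in catalogue]
                for drug, catalogue in model.wastage.vials.items()
            },
            "body_surface_area_m2": model.wastage.body_surface_area_m2,
        }
    return {
        "gp": _arm_to_dict(model.gp),
        "tpf": _arm_to_dict(model.tpf),
        "config": asdict(model.config),
        "wtp_thresholds": list(model.wtp_thresholds),
        "wastage": wastage,
        "currency_note": model.currency_note,
    }


def model_from_dict(d: dict) -> TwoArmModel:
    wastage = None
    if d.get("wastage"):
        w = d["wastage"]
        wastage = WastagePolicy(
            mode=w["mode"],
            vials={drug: [tuple(v) for v in cat] for drug, cat in w["vials"].items()},
            body_surface_area_m2=w["body_surface_area_m2"],
        )
    return TwoArmModel(
        gp=_arm_from_dict(d["gp"]),
        tpf=_arm_from_dict(d["tpf"]),
        config=ModelConfig(**d["config"]),
        wtp_thresholds=tuple(d["wtp_thresholds"]),
        wastage=wastage,
        currency_note=d.get("currency_note", ""),
    )


def save_model(model: TwoArmModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> TwoArmModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
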