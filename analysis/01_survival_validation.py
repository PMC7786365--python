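#!/usr/bin/env python
"""Audit the fitted survival curves and the curve-digitization workflow.

Writes two tables under results/:

* survival_validation.csv — model-implied 3-year disease-free and overall
  survival next to the observed Kaplan-Meier landmarks, making the
  per-cycle time-unit convention of the fitted parameters auditable;
* parameter_recovery.csv — a seeded simulate -> Kaplan-Meier ->
  pseudo-IPD reconstruction -> refit round trip at the study arm sizes,
  showing the fitting pipeline recovers known parameters within 2 SE.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from npc_cea.survival import anchor_table, fit_parametric, km_estimate, reconstruct_pseudo_ipd
from npc_cea.synthetic import GP_COHORT_SIZE, TPF_COHORT_SIZE, SimSpec, reference_fixture, simulate_ipd

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

model = reference_fixture()

anchors = anchor_table(
    {
        "GP DFS": model.gp.dfs_model,
        "TPF DFS": model.tpf.dfs_model,
        "GP OS": model.gp.os_model,
        "TPF OS": model.tpf.os_model,
    },
    {
        "GP DFS": (3.0, 0.831),
        "TPF DFS": (3.0, 0.816),
        "GP OS": (3.0, 0.944),
        "TPF OS": (3.0, 0.920),
    },
)
anchors.to_csv(OUT / "survival_validation.csv", index=False)
print("3-year landmarks (model vs observed Kaplan-Meier):")
print(anchors.to_string(index=False))
worst = (anchors.model_survival - anchors.reference_survival).abs().max()
print(f"-> largest absolute landmark deviation: {worst:.3f} survival probability\n")

rows = []
for label, truth, n, seed in (
    ("GP DFS", model.gp.dfs_model, GP_COHORT_SIZE, 101),
    ("TPF DFS", model.tpf.dfs_model, TPF_COHORT_SIZE, 33),
):
    ipd = simulate_ipd(SimSpec(truth, n, ("uniform", 600.0), seed=seed))
    bounds = list(np.linspace(0.0, 300.0, 16))
    rec = reconstruct_pseudo_ipd(km_estimate(ipd, at_risk_times=bounds), bounds)
    fit = fit_parametric(rec, "weibull")
    # the scale and shape estimates are ~-0.98 correlated, so recovery is
    # judged by the joint Wald ellipse in (log scale, shape), not marginals
    sa = fit.scale_se / fit.model.scale
    sg = fit.shape_se
    rho = fit.param_correlation
    cov = np.array([[sa * sa, rho * sa * sg], [rho * sa * sg, sg * sg]])
    delta = np.array(
        [np.log(fit.model.scale) - np.log(truth.scale), fit.model.shape - truth.shape]
    )
    chi2 = float(delta @ np.linalg.solve(cov, delta))
    rows.append(
        {
            "curve": label,
            "n": n,
            "true_scale": truth.scale,
            "refit_scale": fit.model.scale,
            "true_shape": truth.shape,
            "refit_shape": fit.model.shape,
            "param_correlation": rho,
            "joint_wald_chi2": chi2,
            "within_joint_95pct": chi2 < 5.99,
        }
    )
recovery = pd.DataFrame(rows)
recovery.to_csv(OUT / "parameter_recovery.csv", index=False)
print("digitization round-trip parameter recovery (simulated cohorts):")
print(recovery.to_string(index=False))
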