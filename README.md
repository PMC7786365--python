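# npc-cea

A Markov cohort cost-effectiveness model comparing two induction
chemotherapy regimens for locoregionally advanced nasopharyngeal carcinoma
(NPC) from the Chinese healthcare-system perspective:

* **GP** — gemcitabine (1 g/m² days 1, 8) + cisplatin (25 mg/m² days 1–3);
* **TPF** — docetaxel (60 mg/m² day 1) + fluorouracil (600 mg/m² days 1–5)
  + cisplatin (25 mg/m² days 1–3);

each given for three 21-day cycles before cisplatin-based concurrent
chemoradiotherapy.  The package is aimed at health-economics analysts and
methodologists who want a fully scripted, testable version of this class
of oncology decision model: every input is in code, every result is
recomputed from scratch, and the Monte Carlo machinery is seeded and
bit-reproducible.

## The model

Three exclusive health states — disease-free survival (DFS), progressed
disease (PD) and death — are tracked over 173 cycles of 21 days (a 10-year
horizon).  All patients start in DFS.  Transitions are driven by two
parametric survival curves per arm, in the
`S(t) = exp(−λ t^γ)` parameterization with `t` counted in 21-day cycles:

| curve | family | λ (SE) | γ (SE) |
|---|---|---|---|
| GP DFS | Weibull | 0.00059 (0.00016) | 1.48831 (0.07527) |
| TPF DFS | Weibull | 0.00256 (0.00063) | 1.14471 (0.06796) |
| GP OS | exponential | 0.00085 (0.00005) | — |
| TPF OS | Weibull | 0.00097 (0.00033) | 1.15449 (0.09365) |

Per-cycle transition probabilities are `tp(k) = 1 − S(k·u)/S((k−1)·u)`;
the DFS-exit and death hazards act independently within a cycle, so cohort
deaths track `1 − S_OS` exactly and DFS occupancy equals `S_DFS · S_OS`.
Cycle-indexed costs (induction drugs and supportive care, radiotherapy,
one-time items, time-banded follow-up, subsequent therapy vs best
supportive care in PD, first-cycle expected adverse-event management) and
utilities (0.76 DFS, 0.57 PD) are accrued with 3%/year discounting.  The
decision statistic is the incremental cost-effectiveness ratio
`ICER = ΔCost/ΔQALY`, judged against a willingness-to-pay of $31,008.16
per QALY (3× China's 2019 per-capita GDP); parameter uncertainty is
propagated by a one-way (tornado) analysis and a 10,000-replicate
probabilistic sensitivity analysis (gamma costs, beta probabilities and
utilities, correlated normal survival parameters) summarised as a
cost-effectiveness acceptability curve.  A drug-wastage scenario reprices
chemotherapy by exact administered dose instead of whole single-use vials.

The survival toolbox also covers the upstream workflow: simulating
censored cohorts, Kaplan-Meier estimation, pseudo individual-patient-data
reconstruction from digitized curves with at-risk tables, and
maximum-likelihood Weibull/exponential fitting with observed-information
standard errors.

## Worked example

```python
from npc_cea import evaluate_model, reference_fixture

model = reference_fixture()          # the complete two-arm specification
gp, tpf, comp = evaluate_model(model)
print(f"GP : ${gp.total_cost:,.2f}  {gp.total_ly:.2f} LY  {gp.total_qaly:.2f} QALY")
print(f"TPF: ${tpf.total_cost:,.2f}  {tpf.total_ly:.2f} LY  {tpf.total_qaly:.2f} QALY")
print(f"ICER: ${comp.icer_value:,.2f} per QALY ({comp.verdict})")
```

prints

```
GP : $39,384.63  8.05 LY  5.62 QALY
TPF: $35,540.98  7.38 LY  5.20 QALY
ICER: $9,017.46 per QALY (icer)
```

GP buys 0.43 extra QALYs for $3,843.65 — far below the willingness-to-pay
threshold, so GP is cost-effective; in the DFS state GP is both cheaper
and more effective (dominant), while the PD state carries GP's larger
subsequent-therapy spending.

The same analyses are available as numbered drivers
(`analysis/01_survival_validation.py` … `analysis/05_drug_wastage.py`),
which write their tables under `results/`, and as a CLI:

```bash
npc-cea base-case --out results
npc-cea psa --seed 1 --n 10000 --out results
npc-cea owsa --out results
npc-cea wastage --out results
npc-cea export-config --out model_config.yaml   # editable YAML fixture
```

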