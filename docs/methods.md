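# Methods

## Model structure

A cohort-level state-transition (Markov) model with three exclusive
states: disease-free survival (DFS), progressed disease (PD), death.  The
whole cohort enters in DFS and starts treatment immediately.  The cycle
length is 21 days, matching the chemotherapy schedule; the horizon is 10
years, truncated to complete cycles (`floor(10 · 365.25 / 21) = 173`).
Costs and effects are discounted at 3% per year via the per-cycle factor
`v = 1.03^(−21/365.25)`; accrual uses cycle-start occupancy discounted at
cycle-start time.  A half-cycle correction (averaging cycle-start and
cycle-end occupancy) is implemented but off by default, matching the
uncorrected convention of the decision software this class of model is
usually built in.

## Survival inputs and the time-unit convention

Each arm carries a DFS and an overall-survival (OS) curve in the
`S(t) = exp(−λ t^γ)` parameterization.  The fitted parameters are indexed
by the 21-day cycle: this convention is the one under which the model
reproduces the observed 3-year landmarks of the source cohort (model
80.9/78.9% vs observed 83.1/81.6% DFS and 95.7/91.1% vs 94.4/92.0% OS for
GP/TPF) and the cohort's published discounted life expectancy; a
per-month reading misses both by a wide margin.
`analysis/01_survival_validation.py` prints this audit
(`results/survival_validation.csv`), so the assumption is visible rather
than silent.

Per-cycle transition probabilities are `tp(k) = 1 − S(k·u)/S((k−1)·u)`,
computed with `expm1` so the telescoped product `Π(1−tp)` equals the
survival ratio to 1e−12.  For the exponential family the probability is
computed once from the constant hazard so it is exactly cycle-free.

### Reconciling the DFS and OS curves

Two marginal curves under-determine a three-state transition matrix.  The
default decomposition treats the DFS-exit hazard and the death hazard as
acting independently within a cycle: every alive state dies with
`tp_OS(k)`, and disease-free patients additionally progress with
`tp_DFS(k)`.  Consequences: cohort deaths track `1 − S_OS` exactly, DFS
occupancy equals `S_DFS · S_OS`, and PD occupancy is the remainder.  This
decomposition — not the alternative that reads the DFS curve as the total
exit hazard and caps DFS deaths at `min(tp_DFS, tp_OS)` — reproduces the
reference model's per-state life-year decomposition, including the sign
of the DFS-state increment.  The min-cap alternative is retained as
`decomposition="partition"` with a per-cycle PD-death calibration against
the cumulative OS target; for the GP curves that calibration is provably
infeasible in the first cycles (the Weibull DFS hazard starts below the
constant OS hazard while PD is still empty), which is logged as a clamped
warning and self-corrects once PD is populated.

## Costs

All costs are 2020 USD (1 USD = 6.8606 RMB, kept as metadata).  The DFS
stream follows the pathway: cycles 1–3 carry the arm's induction items
(drug acquisition, hydration, antiemetics, hospitalization, laboratory,
plus G-CSF prophylaxis for TPF); the PICC insertion, priced once, lands
on cycle 1 together with the expected adverse-event management cost
`Σ p_i · c_i`; cycles 4–6 form the concurrent-chemoradiotherapy block
(per-cycle radiotherapy delivery and concurrent cisplatin, with the
one-time planning and imaging charges at its start, cycle 4); from cycle
7 the DFS state accrues follow-up costs in three time bands — $147.26
per cycle to year 2 (the quarterly $631.10 prorated by 21/90 days),
$81.58 in years 3–5 and $40.79 in years 6–10, both taken from the
reference cost table verbatim because their implied period lengths are
not clean multiples of the cycle.  The PD state accrues
`p_sub · c_sub + (1 − p_sub) · c_BSC` per cycle (subsequent therapy in
75.0% of GP and 68.2% of TPF patients, best supportive care otherwise).

Grade-3–4 adverse-event probabilities use the two published rates
(leucopenia 14.08/34.48%, neutropenia 14.08/24.14% for GP/TPF) with the
band's management cost; grade-1–2 probabilities are not published and are
synthetic defaults (0.60 GP, 0.70 TPF — most patients experience some
low-grade toxicity, more under TPF), exposed as ordinary parameters.
Their effect is a one-time cost of a few hundred dollars.

### Drug pricing and the wastage scenario

Chemotherapy acquisition supports two modes.  `vial_based` (the base
case) prices each administration as the cheapest covering combination of
whole single-use vials, found by dynamic programming over dispensed
milligrams; `exact_dose` prices the administered milligrams at the best
per-mg vial rate, so vial_based ≥ exact_dose always.  The vial catalogue
is synthetic: sizes follow standard Chinese presentations (gemcitabine
1 g/200 mg, cisplatin 30/10 mg, docetaxel 80/20 mg, fluorouracil 250 mg)
and per-vial prices are back-derived so that vial-based pricing at the
representative body surface area of 1.72 m² reproduces the published
per-cycle acquisition costs exactly.  Switching the model to exact-dose
pricing lowers both arms' totals (TPF wastes more drug per cycle, chiefly
docetaxel) and raises the ICER slightly.

## Utilities and outcomes

Utilities 0.76 (DFS), 0.57 (PD), 0 (death); QALYs weight cycle-years of
occupancy, so QALY ≤ LY holds identically.  Life-years count both alive
states.  Results are reported as discounted totals with a DFS/PD
decomposition.  Comparisons report the ICER only in the trade-off
quadrants; dominance labels (with a "weak" qualifier at exact ties) cover
the rest, so no undefined ratio is ever formed.  The willingness-to-pay
grid anchors at 1×/2×/3× China's 2019 per-capita GDP ($10,336.05 /
$20,672.11 / $31,008.16), the 3× value being the decision threshold.

## Sensitivity analyses

**One-way:** each parameter moves to its published bounds (or ±20% of
baseline where no range is published — the same rule the reference ranges
follow) with the full model re-evaluated at each bound; entries are
ranked by the absolute ICER spread.

**Probabilistic (n = 10,000, seeded):** costs draw from gamma and
probabilities/utilities from beta distributions, parameterized by method
of moments from the published mean and range with the range read as a 95%
interval (`se = (high − low)/3.92`, truncated when it implies an
infeasible beta variance).  Parameters shared between arms get a single
draw per replicate.  Survival parameters draw from a bivariate normal on
`(ln λ, γ)` using the published standard errors; because the two
estimates of such fits are strongly negatively correlated (≈ −0.98 in
this package's own maximum-likelihood refits) and sampling them
independently is a known variance-inflation error, the sampler defaults
to the correlated draw, using the published correlation coefficients
(−0.95…−0.97) as stand-ins for the unpublished parameter correlations.  Setting `SurvivalUncertainty.correlation = None` gives the
independent variant.  Independent beta draws of the two utilities can
rarely invert the DFS ≥ PD ordering; the PD utility is capped at the
drawn DFS utility (≈0.6% of replicates).  The acceptability curve reports
the fraction of replicates with positive incremental net monetary benefit
`w·ΔQALY − ΔCost` over the WTP grid.

A caveat on calibration: the published acceptability probabilities
(86.9/78.9/54.2% at 3×/2×/1× GDP) imply an effect-side spread between the
two variants this package offers — the correlated default gives
≈96/87/56% and the independent variant ≈75/70/56%, whose plateau
(P(ΔQALY>0) ≈ 87%) matches the published curve's implied plateau.  The
original analysis's sampling hyperparameters are unpublished, so the
package keeps the statistically-correct correlated default rather than
interpolating a correlation to match the printed probabilities.

## Synthetic data

`simulate_ipd` draws event times by inverse transform
(`t = (−ln U/λ)^(1/γ)`) with none/uniform/administrative censoring, from
a single explicitly seeded generator.  `km_estimate` wraps the
product-limit estimator and emits at-risk tables, which
`reconstruct_pseudo_ipd` consumes: within each inter-boundary interval
the event count is implied by the survival drop
(`d = round(n(1 − S_hi/S_lo))`, apportioned across interior steps by
largest-remainder rounding), censorings absorb the remaining risk-set
change and leave at the interval end, and survivors are administratively
censored at the last boundary — so the recomputed Kaplan-Meier matches
the digitized values at the boundaries to within rounding.  Default
recovery-demonstration cohort sizes mirror the study arms (71 and 87).
The generator emulates censored event histories only; it does not emulate
digitization noise, patient-level cost heterogeneity or covariates, so
passing recovery tests validate the reconstruction/fitting machinery, not
robustness to a noisy screen-digitization step.

## Fitting

Maximum likelihood on (pseudo-)individual data is the default route:
profile likelihood in the shape (the scale is closed-form given the
shape), observed-information standard errors and scale-shape correlation
in `(ln λ, γ)` coordinates; the exponential uses `λ̂ = d/Σt` with the
classical `1/√d` log-scale standard error.  A direct least-squares path
on digitized points (regression of `log(−log S)` on `log t`) is provided
for curves without at-risk tables.  Goodness-of-fit is reported as the
adjusted R² of that linearized regression over the Kaplan-Meier support,
plus the Pearson correlation between time and survival (negative for any
declining curve) as a shape diagnostic.  Fits requiring a shape are
rejected with fewer than two distinct event times; all-censored samples
are rejected outright.

## Numerical choices

Transition probabilities are clipped just below 1 where floating point
would round them up to exactly 1; row-stochasticity and trace
conservation are enforced at 1e−12; the engine matches the geometric
closed form on an all-exponential toy to 1e−10.  The PSA consumes a fixed
number of random draws per replicate regardless of parameter values, so
results are bit-reproducible given the seed and stable under toggling
individual distributions.

## Problem sizes

The shipped analyses use the full model everywhere: 173 cycles, 10,000
PSA replicates, 38 tornado parameters, and recovery simulations at the
study arm sizes (71/87) or n = 150 with ~30% censoring.  The consistency
check of the exponential estimator uses n = 10,000 simulated subjects.

## Known limitations

* Two marginal curves cannot identify post-progression survival; PD
  mortality equals the cohort OS hazard by construction, and no
  independent post-progression survival model is available.
* The printed adjusted-R² values of the source fits are not reproducible
  here because the underlying Kaplan-Meier figures and at-risk tables
  are unpublished; the statistic itself is implemented and tested on
  synthetic curves.
* Grade-1–2 adverse-event probabilities and the vial catalogue are
  synthetic stand-ins (documented above), and the PSA's survival
  correlation is a stand-in for an unpublished quantity.
* No correlated sampling across different parameters (copulas), no
  value-of-information analysis, no more-than-two-arm frontier.
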