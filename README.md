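# psmcea — partitioned-survival cost-effectiveness analysis

`psmcea` implements a complete partitioned-survival cost-effectiveness
model for two-arm oncology trials, built around the comparison of
camrelizumab plus chemotherapy versus chemotherapy alone as first-line
treatment for advanced non-squamous NSCLC from a Chinese healthcare
perspective. It is aimed at health-economics analysts who need the whole
chain from published Kaplan–Meier figures to an ICER, with every stage
testable against synthetic trials of known ground truth.

## What the model does

1. **Pseudo-IPD reconstruction.** Published trials report survival as a
   plotted KM curve plus a numbers-at-risk table. The Guyot inversion
   rebuilds per-subject (time, event) records: within each risk-table
   interval censoring is assumed uniform and iteratively adjusted until the
   implied number at risk matches the table, while events are placed at the
   digitized drops via the product-limit relation
   S(t_k) = S(t_{k-1}) · (1 − d_k/n_k).
2. **Parametric extrapolation.** Six families (exponential, gamma,
   Gompertz, Weibull, log-logistic, log-normal) are fitted to the
   right-censored records by maximum likelihood,
   ℓ = Σ_events log f(t) + Σ_censored log S(t), and compared by
   AIC = −2ℓ + 2k and BIC = −2ℓ + k·ln n. The Weibull is preferred whenever
   its AIC and BIC are each within 5% of the best family.
3. **Three-state partitioned survival.** Per 21-day cycle,
   PFS = min(S_PFS, S_OS), progressed = max(S_OS − S_PFS, 0),
   dead = 1 − S_OS, over a 104-cycle horizon; early cycles read the KM curve
   directly (29 cycles in the combination arm, 26 in the control arm), later
   cycles the fitted Weibull.
4. **Economics.** Phase-dependent cycle costs (induction cycles 0–6,
   maintenance 7–34, a two-year camrelizumab cap from cycle 35), a one-time
   adverse-event + workup cost, utilities 0.804 (PFS) / 0.321 (progressed),
   5%/year discounting, and ICER = ΔC/ΔE against a willingness-to-pay of
   $35,936.09/QALY (3× China's 2021 GDP per capita).
5. **Sensitivity.** One-way DSA with tornado ranking, 1,000-draw PSA
   (gamma costs, beta utilities, SE = 20% of base, moment-matched), CEAC
   via the net-monetary-benefit rule λ·ΔE − ΔC > 0, and scenario analyses
   (alternative utilities 0.71/0.67; 20–70% camrelizumab price cuts).

Because the trial's patient-level data are not public, the package ships a
synthetic-trial generator (Weibull PFS/OS, exponential dropout,
administrative censoring, KM "digitization") whose defaults emulate the
trial's arm sizes, follow-up and reported medians, so the entire pipeline
runs and is tested without external data.

## Worked example

```bash
python analysis/01_simulate_trial.py
python analysis/02_reconstruct_and_fit.py
python analysis/03_base_case.py
```

The base-case driver prints (synthetic trial, shipped seed):

```
camrelizumab+chemotherapy: fitted medians PFS 10.80 / OS 20.41 months; 99.0% dead at cycle 104
chemotherapy: fitted medians PFS 8.59 / OS 21.23 months; 99.1% dead at cycle 104

costs: 22,799.01 vs 20,174.98 USD; QALYs: 1.122 vs 1.016
incremental: ΔC=2,624.03 USD, ΔE=0.1060 QALY
ICER = 24,766.52 USD/QALY (below the WTP threshold of 35,936.09 USD/QALY)
```

Reading this: the reconstructed-and-refitted PFS medians sit close to the
generator's ground truth (11.3 / 8.3 months), the horizon check confirms the
cohort is essentially extinct by cycle 104, and on this synthetic trial the
combination arm buys 0.106 QALYs for $2,624 — cost-effective at the Chinese
threshold. `analysis/04_sensitivity.py` and `analysis/05_scenarios.py` add
the tornado, PSA/CEAC and scenario tables under `results/`.

The same pipeline consumes externally digitized curves instead of
simulations: replace each arm's `simulate` block with a `files` block
pointing at `(time_months, survival)` and `(time_months, n_risk)` CSVs (see
`src/psmcea/data/paper_basecase.yaml` for the layout and
`docs/methods.md` for the digitization recipe). A `psmcea` command-line
interface (`simulate`, `reconstruct`, `fit`, `run`, `dsa`, `psa`,
`scenario`) wraps the same library calls.

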