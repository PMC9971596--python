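# Methods

## Model structure

The economic model is a partitioned survival model (PSM) with three
mutually exclusive states: progression-free (PFS), progressed disease (PD)
and dead. Unlike a Markov cohort model it uses no transition probabilities;
state occupancy is read directly off the two survival endpoints at each
cycle boundary:

    pfs(c)   = min(S_PFS(t_c), S_OS(t_c))
    pd(c)    = max(S_OS(t_c) − S_PFS(t_c), 0)
    death(c) = 1 − S_OS(t_c),        t_c = 21·c days

The min/max clamp handles the crossing that can occur because the two
endpoints are modelled independently; neither fitted curve is altered.
Cycle 0 is model entry (everyone progression-free). No half-cycle
correction is applied: costs and utilities accrue on the state occupied at
the cycle start, which keeps the phase boundaries (given in whole cycles)
exact. The horizon is 104 cycles (~6 years); a check reports the fraction
dead at the horizon and warns below 99%, since the valuation assumes the
cohort is essentially extinct.

Months and cycles convert at 30.4375 days/month; discounting and QALY time
use a 365-day year. Both constants are isolated in the code, not scattered.

## Survival inputs and the within-trial / extrapolation splice

Each arm-endpoint survival series is a splice: cycles 0..cutoff are the KM
step function evaluated at cycle boundaries (cutoffs 29 cycles / 20.3
months in the combination arm and 26 cycles / 18.2 months in the control
arm, mirroring the trial's follow-up), and later cycles come from the
fitted parametric model. The default `raw` mode uses the fitted curve
unrescaled — the fitted medians are then properties of the whole curve — and
an `anchored` option rescales the tail by S_KM(cutoff)/S_model(cutoff) for
exact continuity. A cumulative-minimum pass removes any infinitesimal
upward step the splice could introduce.

## Pseudo-IPD reconstruction

The reconstruction inverts the product-limit construction using the
digitized coordinates and the numbers-at-risk table (Guyot-style
algorithm). For each risk-table interval: (i) an initial censoring count is
guessed from the survival drop, censor times spread uniformly; (ii) events
at each digitized drop are estimated from the running KM estimate,
d_k = round(n_k · (1 − S_k / S_last-event)); (iii) the censoring count is
adjusted (±1000 iterations max, integer counts rounded half away from zero)
until the implied number at risk matches the table at the next risk time.
Two deliberate behaviours:

* the computed at-risk count is carried across intervals rather than reset
  to the printed table, and a censoring count that would have to go
  negative is clamped to zero with the (small) mismatch tolerated — with a
  finite digitization grid a click can straddle a risk time, so exact
  matching is not always possible; a hard error is reserved for an
  impossible (negative) at-risk count, reported with the offending
  interval;
* beyond the last risk time the previous interval's censoring rate is
  reused, or, when the total event count is supplied, censoring is tuned to
  match it (with a final one-click adjustment so the published total is
  honoured exactly). Survivors at the curve end are administratively
  censored there. Ties sort events before censorings (standard KM
  convention).

The reconstructed cohort size always equals the first risk-table entry.
Terminal digitization artifacts ("extreme points") are removed by explicit
truncation of the coordinate list — by inspection, not automatically —
matching how such points are handled in practice.

## Parametric fitting and family selection

Six families are fitted by right-censored maximum likelihood. Internally
all positive parameters are optimized on the log scale (BFGS) from three
deterministic starts — method-of-moments, exponential-equivalent and
unit-shape — and the best converged log-likelihood wins; this multi-start
guards against local optima without randomness. The Gompertz shape is
restricted positive so S(∞) = 0; an improper tail would leave patients
alive forever and invalidate the finite-horizon valuation. The Weibull fit
was verified against lifelines' independent implementation to 1e-4 in
log-likelihood and parameters.

Family choice uses the proximity rule: the preferred family (Weibull, the
conventional flexible choice for tumour survival) is retained when its AIC
and BIC are each within 5% (relative) of the comparison-table minima;
otherwise the AIC-minimizing family is returned. Fit failures of individual
families are logged and skipped, not fatal.

## Economics

Per-cycle costs follow the regimen phases: induction (cycles 0–6),
maintenance (cycles 7–34), progressed disease; in the combination arm a
two-year treatment cap routes every alive state to the PD cost from cycle
35. The eight per-cycle/one-time cost parameters are consumed as given
configuration values — they are not rebuilt from the drug-price atoms,
whose printed aggregation (dose intensity, imaging amortization,
subsequent-therapy mix) is not decomposable; the atoms are carried
separately for dose-cost arithmetic and for the price-cut scenarios, which
require the camrelizumab acquisition cost ($433.14/cycle) as an explicit
line item within the phase costs. The one-time cost (incidence-weighted
grade-3+ adverse-event management plus puncture and PD-L1 testing) enters
undiscounted at cycle 0 and *is* exactly decomposable — the test suite
rebuilds both arms' values to the cent. Carboplatin's per-cycle cost is
modelled as 750 mg × $4.49/50 mg = $67.35 (the AUC-based milligram dose is
not derivable from published inputs; the config carries the dose directly).

QALYs accrue as utility-weighted discounted cycle time,
Σ_c (1+r)^(−21c/365) · (pfs_c·u_pfs + pd_c·u_pd) · 21/365, with r = 5%/year.
ICER = ΔC/ΔE on unrounded values; ΔE = 0 raises an explicit undefined-ICER
error (surfaced as NaN in tabular output). NMB = λ·E − C.

## Sensitivity and scenarios

* **DSA:** each parameter in turn at its low/high bound, others at base;
  costs ±25%, utilities over their published 95% ranges (0.603–0.840 PFS,
  0.050–0.473 PD), discount rate 0–8%; rows ranked by ICER swing width.
  Undefined ICERs at an endpoint flag the row (NaN) without aborting.
* **PSA:** the ten base-case parameters (eight costs, two utilities) drawn
  independently — gamma for costs (shape = (μ/σ)², scale = σ²/μ) and beta
  for utilities (ν = μ(1−μ)/σ² − 1, a = μν, b = (1−μ)ν), each moment-matched
  with σ = 20% of base. 1,000 draws by default; every draw re-runs the
  economic valuation on the fixed occupancy curves (survival parameters are
  not varied, matching the parameter list the PSA is defined over).
* **CEAC:** at each λ on a 0–60,000 (step 1,000) USD/QALY grid, the fraction
  of draws with λ·ΔE − ΔC > 0; dominance draws are retained via the NMB
  rule rather than excluded.
* **Scenarios:** utilities 0.71/0.67, costs untouched; and price cuts
  x ∈ [0.2, 0.7] that reduce only the camrelizumab line inside the arm-1
  phase costs, so ΔE is unchanged and ICER(x) = ICER(0) − x·K/ΔE with K the
  discounted pre-cap camrelizumab spend — the tests verify this affine
  structure against an independent closed form.

## Synthetic trial generator

The generator emulates a two-arm randomized trial: marginal Weibull PFS and
OS times per subject, the ordering constraint enforced as
PFS := min(PFS, OS), independent exponential dropout shared between the two
endpoints of a subject, and administrative censoring at the end of
follow-up. The shipped base case uses n = 205/207, ~24/21 months follow-up,
0.01/month dropout, and marginal parameters chosen analytically (via
S_min = S_PFS·S_OS for independent draws) so the post-constraint medians
land on the trial-reported values — PFS 11.3/8.3 months, OS ≈21.3/20.7
months — with OS shape 1.6 so that >99% of the cohort is dead by cycle 104.
"Digitization" samples the KM step on an even 200-point grid; optional
Gaussian jitter is clipped to [0,1] and repaired by isotonic (non-increasing)
regression, mimicking manual point extraction.

What the generator does **not** emulate: correlated PFS/OS beyond the min
constraint, non-proportional or cure-fraction survival, informative
censoring, and real digitization artifacts (axis skew, plateau
mis-reading). Passing tests therefore demonstrate the machinery is correct
and calibrated under clean Weibull conditions, not that any published
trial's numbers are recovered. In particular, with ~100 OS events per arm
and a true OS median gap of only 0.6 months, the fitted OS ordering of a
single synthetic trial is within sampling noise — the shipped seed happens
to fit the control arm's OS slightly higher — mirroring the real trial,
where the combination arm's median OS was not reached and the OS contrast
is uncertain. Incremental QALYs on the synthetic base case are accordingly
smaller than the published analysis's, whose exact survival curves would be
needed (as digitized coordinate files) to reproduce its headline totals.

### Digitization recipe for the published figures

To analyse the actual trial figures rather than the synthetic stand-in:
extract (time, survival) coordinates from each arm's PFS and OS KM plot
(any plot digitizer; one point per visible step plus the plateaus), save
as `time_months,survival` CSV; transcribe the numbers-at-risk row as
`time_months,n_risk` CSV; remove terminal artifact points via
`truncate_after_months`; set the `files` block of each arm in the config
and keep the shipped cutoffs (29/26 cycles). `psmcea run --config ...`
then produces the base case, DSA/PSA and scenario tables from those
curves.

## Numerical and testing notes

* Problem sizes in the default suite and acceptance script (arms of ~200,
  20×500 recovery replicates, 1,000 PSA draws) keep a full run in seconds
  while leaving Monte-Carlo error well inside the asserted tolerances.
* All randomness flows from one top-level seed, fanned out to named
  substreams (per-arm simulation, PSA) via `SeedSequence`, so every
  pipeline artifact is bit-reproducible from a single integer.
* Fit oracles: closed-form exponential MLE, closed-form Weibull medians,
  and lifelines as an independent optimizer; economics oracles: brute-force
  undiscounted sums and hand-built linear closures.
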