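# spinesurvival

Longitudinal survival analysis of dendritic spines with and without a
synaptopodin (SP) cluster. In time-lapse imaging of hippocampal granule
cells, SP⁻ spines disappear with single-phase exponential kinetics,

    Y(t) = 100 · exp(−(t − offset)/τ_spine),

while SP⁺ spines are far more stable and follow a conditional two-stage
decay — the Bateman chain of sequential radioisotope decay — in which a
spine first loses its SP cluster (time constant τ_SP) and only then is
pruned like an SP⁻ spine (τ_spine):

    Y(t) = 100 · [ e^(−t/τ_SP) + (e^(−t/τ_SP) − e^(−t/τ_spine)) / (τ_SP/τ_spine − 1) ].

The package is aimed at anyone modeling longitudinal presence/absence data
of this kind. It provides, as importable modules driven by the numbered
scripts under `analysis/`:

* `simulate` — a per-spine continuous-time Markov simulator producing
  long-format observation tables (presence, SP state, head area per imaging
  day), with a denervation preset for accelerated loss;
* `models` — both survival functions, the 0.69·τ half-life convention, and
  exact median-survival root finding;
* `fitting` — day-0 cohort survival tables and 1/Y²-weighted least-squares
  fits (single-phase for SP⁻; two-stage with τ_spine pinned to the SP⁻ fit
  for SP⁺);
* `distribution` — numerical inversion of a fitted loss curve into the
  distribution of single-spine survival times (10⁷ time points over
  30·τ_max, 10⁵ fractional-survival bins, block-of-100 histogram);
* `comparison` — the resampled-median group comparison: medians of 10
  random cohorts per group at the observed cohort sizes, exact tie-aware
  Mann–Whitney U test;
* `metrics` — turnover/formation/loss ratios, head-size classes, greedy
  size matching, and SP-state fate trajectories (pruned via the SP⁻ state
  vs apparent direct loss, undulating spines);
* `io` / `cli` — validated CSV I/O, an end-to-end pipeline, and a
  `spinesurvival` subcommand CLI.

See `docs/methods.md` for the model assumptions, parameter conventions and
numerical choices.

## Worked example

```python
from spinesurvival import (
    SimulationConfig, simulate_population, build_survival_table,
    fit_single_phase, fit_two_stage, derive_survival_times,
    compare_groups, half_life, median_survival,
)

table = simulate_population(SimulationConfig(seed=20260920))   # 31 SP+, 392 SP-
st_neg = build_survival_table(table, "sp_neg")
st_pos = build_survival_table(table, "sp_pos")

fit_neg = fit_single_phase(st_neg)
fit_pos = fit_two_stage(st_pos, tau_spine_fixed=fit_neg.model.tau_spine)
print(f"tau_spine = {fit_neg.model.tau_spine:.2f} d, "
      f"half-life {half_life(fit_neg.model.tau_spine):.2f} d")
print(f"tau_SP    = {fit_pos.model.tau_sp:.2f} d, "
      f"SP+ median survival {median_survival(fit_pos.model):.1f} d")

dist_pos = derive_survival_times(fit_pos.model)
dist_neg = derive_survival_times(fit_neg.model)
result = compare_groups(dist_pos, 31, dist_neg, 392, seed=0)
print(f"U = {result.u_statistic:.0f}, p = {result.p_value:.2e}")
```

prints

```
tau_spine = 9.91 d, half-life 6.84 d
tau_SP    = 20.88 d, SP+ median survival 25.1 d
U = 100, p = 1.08e-05
```

The SP⁻ time constant is recovered to ~1% from a 361-spine day-0 cohort; the
SP⁺ constant is fitted from only ~30 spines and lands high on this seed
(the generative value is 11.1 d and the generative median ≈17.5 d) — at
n = 500 the fitted median is reliably within 15%. The comparison rejects at
p = 2/C(20,10) ≈ 1.1×10⁻⁵: all 10 resampled SP⁺ medians exceed all 10 SP⁻
medians.

The same flow as a shell pipeline:

```bash
spinesurvival simulate --seed 1 --out table.csv
spinesurvival survival table.csv --cohort sp_neg --out sp_neg.csv
spinesurvival fit sp_neg.csv --model single_phase
spinesurvival run --seed 1 --out report/
```

The numbered drivers under `analysis/` run the full study workflow —
simulate control + denervated cohorts, fit, invert, compare, and compute
turnover/fate metrics — writing their tables under `results/`:

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_fit_decay_models.py
python analysis/03_survival_time_distributions.py
python analysis/04_compare_groups.py
python analysis/05_turnover_and_fates.py
```

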