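# Methods

## The analysis in one paragraph

Dendritic spines of hippocampal granule cells either contain a synaptopodin
(SP) cluster or not, and the two populations disappear with different
kinetics under time-lapse imaging. SP⁻ spines follow single-phase
exponential decay; SP⁺ spines are described by a conditional two-stage
process — lose the SP cluster first, then be pruned as an SP⁻ spine. This
package simulates longitudinal cohorts under exactly that generative chain,
rebuilds the survival fractions a microscopist would score, fits both decay
models by 1/Y²-weighted least squares, inverts the fitted loss curves
numerically to obtain per-spine survival-time distributions, compares groups
by medians of resampled cohorts, and computes the standard turnover / size /
fate bookkeeping.

## Survival models

Single-phase (SP⁻ cohorts):

    Y(t) = 100 · exp(−(t − offset)/τ_spine),    Y clamped to 100 for t < offset

`offset` marks the start of the decay; the default study schedule images on
days −1, 0, 3, 6, 9, 12 with cohorts defined at day 0.

Two-stage (SP⁺ cohorts), the Bateman chain SP⁺ →(1/τ_SP)→ SP⁻ →(1/τ_spine)→
pruned, counting parent plus intermediate:

    Y(t) = 100 · [ e^(−t/τ_SP) + (e^(−t/τ_SP) − e^(−t/τ_spine)) / (τ_SP/τ_spine − 1) ]

which equals `100·(b·e^(−a·t) − a·e^(−b·t))/(b − a)` with `a = 1/τ_SP`,
`b = 1/τ_spine`. Two consequences worth knowing:

* the curve is **symmetric** in (τ_SP, τ_spine); co-fitting both constants is
  identifiable only up to a swap. The standard procedure avoids this by
  pinning τ_spine to the companion SP⁻ cohort's single-phase fit, which is the
  default in `fit_two_stage`;
* at τ_SP = τ_spine = τ the expression degenerates; we switch to the analytic
  limit `100·(1 + t/τ)·e^(−t/τ)` when the constants agree to a relative
  10⁻⁹, rather than perturbing the parameters.

The two-stage model carries no offset, matching the form the constants were
estimated with. Half-lives are *reported* as `0.69·τ` (the field's rounded
convention); *medians* are exact roots of `Y(t) = 50` found by bracketing +
Brent to 10⁻⁹ days, i.e. `τ·ln 2` for the single-phase model. The ≈0.5%
discrepancy between the two conventions is deliberate and surfaced in both
APIs. With the reference constants τ_SP = 11.1 d, τ_spine = 9.8 d the
two-stage median is ≈17.5 d.

## Synthetic cohorts

`simulate_population` runs one continuous-time Markov chain per spine
(Gillespie sampling) with rates 1/τ_SP (SP loss), 1/τ_spine (pruning of SP⁻
spines), and optional `rate_gain_sp` (SP re-gain, producing "undulating"
spines), `rate_prune_sp_pos` (direct SP⁺ pruning, off by default because the
two-stage model forbids it — apparent direct losses in sparse schedules are
missed intermediates), and `rate_new_spine` (homogeneous Poisson formation of
new SP⁻ spines, needed only for turnover metrics). The chain is sampled at
the observation days; pruning is absorbing, so with re-gain disabled presence
is monotone.

Spines are initialized in their assigned SP state at the **first** observation
day (default −1). Day-0 cohorts are therefore the spines still present and in
a given state at day 0 — slightly fewer than the configured counts after one
day of kinetics. Because the chain is Markov, every day-0-conditioned
survival analysis is exact regardless of this choice; tests that need exact
day-0 cohort sizes simply use schedules starting at 0.

Defaults are the study conditions: 31 SP⁺ / 392 SP⁻ spines, τ_SP = 11.1 d,
τ_spine = 9.8 d, days (−1, 0, 3, 6, 9, 12). The denervation preset rescales
the kinetics to the reported post-lesion medians: τ_spine = 3.4/0.69 ≈ 4.93 d
(the half-life convention applied backwards) and τ_SP solved by root finding
so the exact two-stage median equals 6.5 d (≈2.93 d).

Head areas are generated plumbing, calibrated but not mechanistic: a
state-conditional lognormal at first observation (log-sd 0.5; log-means set
so the state means are 0.364 µm² for SP⁻ and 0.801 µm² for SP⁺), a
multiplicative lognormal jump when the observed SP state changes between
consecutive imaging days (mean factor ≈2.2 = ratio of the state means; grow
on gain, shrink on loss), and mean-one lognormal jitter (relative sd 0.10)
per interval otherwise. No claim is made that real spine-size dynamics follow
this law; it exists so size classification, size matching and the
size–stability confound have realistic inputs.

Randomness: every spine owns a `numpy` `SeedSequence` child keyed on
(role, index) under the root seed, so enlarging a cohort or adding the
new-spine process never perturbs existing trajectories, and identical
config + seed reproduces tables byte-for-byte.

What the generator does **not** emulate: imaging noise and re-identification
errors (tables are exact unless you inject misses yourself), spatial dendrite
structure, steady-state transient populations (the day −1 → 0 loss fraction
of a fresh cohort is lower than in a population at turnover equilibrium), and
any coupling between head size and survival. Passing recovery tests
therefore show the estimation pipeline is correct under the assumed kinetics,
not that the kinetics are true of any particular tissue.

## Survival tables and fitting

`build_survival_table` conditions on presence (and SP state) at the cohort
day and counts survivors at each later imaging day. By default a spine absent
at day t but present later counts as surviving throughout — absences verified
against later reappearance are detection misses; `strict=True` treats first
absence as loss.

Fits minimize Σ (Yᵢ − Ŷ(tᵢ))²/Yᵢ² — least squares weighted by 1/Y², i.e.
relative residuals — with points at Y = 0 excluded (their weight is
undefined, and they carry no shape information for an exponential).
Optimization is bounded trust-region least squares (`scipy least_squares`)
with three deterministic starts; τ is bounded to [0.05, 500] d and the
single-phase offset to [−1, first day with an observed loss] (decay cannot
start after spines have already disappeared; the bound is overridable). The
τ initializer is a crude half-life read off the observed fractions, scaled
by 1/ln 2. Tests verify the returned optimum against an independent
recomputation of the objective and a τ grid search.

## Survival-time distributions

A loss curve is the complement of the CDF of single-spine survival times.
The inverse CDF is tabulated numerically: evaluate Y on 10⁷ equally spaced
times from 0 to 30·τ_max; partition fractional survival (0, 1] into 10⁵
equal-width bins; for each non-empty bin, the mean of the times falling in it
becomes the survival time at quantile 1 − (bin center). Empty bins (steep
curve regions) are skipped, not interpolated. Percentiles are order
statistics of the resulting equal-mass values; the histogram groups 100
consecutive sorted values per bar (≈1000 bars at full resolution — the
alternative reading, 100-day bins, would put the entire distribution into
one bar at these time scales and was rejected). Unit tests run at 10⁶/10⁴
resolution with proportionally looser tolerances; the full-resolution
procedure is exercised once against the analytic exponential quantiles,
which it matches to <0.5% at every displayed percentile.

## Group comparison

Groups are compared on the model-derived distributions, not on raw interval-
censored lifetimes: draw 10 random cohorts per group of the observed cohort
sizes (inverse-CDF sampling = uniform draws from the equal-mass values; each
group on its own child RNG stream, independent across groups), take each
cohort's median, and compare the two sets of 10 medians with a two-sided
Mann–Whitney U test. For per-group n ≤ 20 the test is exact: the null
distribution of the rank sum is built by a shift-algorithm dynamic program
over midranks doubled to integers, so ties are handled identically to the
brute-force enumeration (which the tests run as an oracle at small n); the
two-sided p is `min(1, 2·min(lower tail, upper tail))`. Complete separation
of 10 vs 10 medians gives p = 2/C(20,10) ≈ 1.08×10⁻⁵. Larger groups fall
back to the tie-corrected normal approximation. The exact 10-vs-10 test has
actual size ≈0.043 at nominal α = 0.05 (discreteness), which the calibration
test brackets at 0.05 ± 0.02.

## Turnover, size and fate metrics

Turnover bookkeeping uses the standard longitudinal formulas over the full
imaging window (N_total = spines seen at ≥1 day): turnover =
(N_gained + N_lost)/(2·N_total), formation = (N_total − N_initial)/N_total,
loss = (N_total − N_final)/N_total, so turnover ≡ (formation + loss)/2 —
enforced as a property on randomized tables. Size classes are the four
conventional head-area bins (<0.3, 0.3–0.55, 0.55–0.8, >0.8 µm²); boundary
values are assigned to the upper class (the printed bin labels leave the
boundaries ambiguous). Size matching is greedy nearest-neighbor without
replacement over group A in ascending area order, with a 10% relative
caliper — the matching algorithm itself is a design choice; only the
existence of size-matched pairs with indistinguishable areas is inherited
from the study design. Fate classification labels each day-0 spine
survived / pruned-via-SP⁻ / pruned-direct by its SP state on the last day
seen, with ≥2 SP-state changes flagged as undulating (an orthogonal flag, so
the three outcomes always partition the cohort). On synthetic data with
direct SP⁺ pruning disabled, apparent "direct" losses still occur at 3-day
imaging gaps and shrink as the schedule densifies — the missed-intermediate
effect.

## Problem sizes used by the test and analysis runs

Closed-form checks are instant. Simulation-based recovery uses 20 seeds at
the study cohort sizes (n = 392 SP⁻) and n = 500 SP⁺; binomial-consistency
checks use 10⁴–2·10⁴ spines; comparison calibration uses 1000 null seeds
and 100 alternative seeds at reduced distribution resolution (10⁵–10⁶ grid
points), where the derived quantiles are already accurate to well under the
tolerances being tested. The analysis drivers run the full 10⁷/10⁵
inversion, which is a few seconds per model.

## Known limitations

* The generator's head-size law and the matching caliper are conventions,
  not estimates; analyses of size *dynamics* on synthetic data test code
  paths, not biology.
* Survival-fraction fits treat the observed fractions as independent points;
  no binomial covariance is modeled (the estimator is deliberately the
  weighted-least-squares one, not an exponential MLE — see the fitting
  section).
* `fit_two_stage` at small SP⁺ cohort sizes (n ≈ 30) has large sampling
  variance in τ_SP; single-seed fits can land far from the generative value
  even though the recovered median stays within ~15% at n = 500.
* The comparison procedure inherits the study's resampling framing; its
  p-values quantify separation of the *fitted model* distributions at the
  observed cohort sizes, not inference on raw per-spine lifetimes.
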