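# Methods

## The growth process

`becgrowth` models biliary epithelial clone growth as a discrete-time (daily)
two-type branching process. A clone is the state (n_P, n_Q): counts of
proliferative and quiescent cells. Each day, independently per cell:

1. **Cell-cycle entry.** Every P cell divides with probability *m*
   (Bernoulli). At most one division per cell per day, so cell-cycle lengths
   are geometric with mean 1/*m* days — the model deliberately has
   *variable* inter-mitotic times rather than a fixed cycle length.
2. **Fate choice.** A division replaces the mother by two daughters with
   joint state PP (probability *r* + *s*), PQ (1 − 2*r*) or QQ (*r* − *s*).
   This mapping is the minimal one that (a) reduces to the balanced model
   PP = QQ = *r* at *s* = 0, the critical process used for homeostatic
   epidermis, and (b) makes *s* the pure expansion term: the expected net
   gain of P cells per division is exactly 2*s*, giving the closed form
   below. Validity requires *r* − *s* ≥ 0, *r* + *s* ≤ 1 and 1 − 2*r* ≥ 0;
   violations raise `ParameterDomainError` naming the broken inequality.
3. **Loss.** Every cell — P, Q, newborns included — is removed with
   probability *l*. Ordering within a day is fixed as divisions-then-loss;
   any fixed order is consistent with a daily census, and this one keeps the
   one-step kernel a clean composition (binomial division → multinomial
   fate → binomial thinning) shared verbatim by the simulator and the
   master equation.

The P→Q switch is irreversible (Q cells never divide), so n_P = 0 is
absorbing up to loss: from then on a clone can only shrink. There is no
density or space limitation: over the modeled 8-week injury window the
biliary tree still has room to expand, so adding a crowding term would fit
a parameter the data cannot constrain.

### Parameters

| parameter | meaning | unit | default |
|-----------|---------|------|---------|
| *p* | founder fraction initially proliferative | — | 0.465 |
| *m* | cell-cycle entry probability | day⁻¹ | 0.175 |
| *r* | fate stability | — | 0.15 |
| *s* | fate imbalance (expansion) | — | 0.06 |
| *l* | cell loss probability | day⁻¹ | 0.001 |
| `lag_days` | injury onset → first cell-cycle entry | day | 6 |

Defaults are the set fitted to the 8-week thioacetamide time course; with
them the fates are (PP, PQ, QQ) = (0.21, 0.70, 0.09). An observation at week
*w* maps to max(0, 7*w* − `lag_days`) growth days, so the 8-week point is
simulated for 50 days. The lag is a measured biological delay (proliferation
marker positivity rises only ~6 days into injury), not a fitting artifact;
ignoring it makes the week-2 size distribution distinctly too large, which
the inference tests reproduce.

## Deterministic twins

Two independent oracles check the Monte Carlo:

* **Closed-form means.** E[n_P(t)] = [(1 + 2*ms*)(1 − *l*)]^t and
  E[n_Q(t+1)] = (E[n_Q(t)] + *m*(1 − 2*s*) E[n_P(t)])(1 − *l*), from the
  per-division expectations of the fate mapping. At *s* = *l* = 0 the P
  count is a martingale (critical process).
* **Master equation.** The exact distribution over (n_P, n_Q) is evolved
  day by day. Because cells act independently, the colony transition from
  (i, j) factorizes into the i-fold convolution of the per-P-cell offspring
  pmf (a 3×3 kernel over ΔP, ΔQ with loss folded in) and binomial thinning
  of the j quiescent cells. The implementation precomputes iterated 2-D
  convolutions of the kernel once, applies Q-thinning as one triangular
  matrix product per day, and adds each P-row contribution via 1-D
  convolutions. The state space is the square [0, `max_cells`]²; escaping
  mass is accumulated as `truncated_mass` (reported, and an error above
  1e-6 by default). `max_cells = 64` keeps truncation below 1e-40 at the
  10-day horizons used for oracle comparisons; the cost grows roughly
  cubically in `max_cells`, which is why simulator-vs-oracle checks run at
  10 days rather than 50.

Agreement between the two implementations (total-variation distance of the
size pmf < 0.01 at 1.5×10⁵ replicates, and cohort means within 3 Monte
Carlo standard errors at t = 1, 10, 50) is the package's core correctness
evidence.

## Random numbers

All stochastic entry points take an explicit numpy `Generator` (or an int
seed). A cohort is advanced in lockstep as vectorized arrays on a single
stream rather than with per-colony substreams: identical seeds give
bit-identical cohorts (tested), and the vectorization is what makes
10⁵-replicate oracle checks and the grid fit run in seconds. The trade-off
is that a cohort's draws are not decomposable per colony; callers that need
per-clone streams can loop `simulate_colony`. The nested-binomial
decomposition of the multinomial fate split is exact, not approximate.

## Dual-labeling model

The labeling simulation tracks, per cell, its state and two boolean labels.
A division during a label window marks both daughters permanently (label
positivity is binary; no dilution, pharmacokinetics, S-phase duration or
detection threshold is modeled). Newborns inherit their mother's earlier
labels. The analytic anchor is 1 − (1 − *m*)^w, the chance that a
continuously proliferative cell divides during a w-day window — 0.78539
for (0.175, 8). Note the printed five-decimal value is the truncation of
0.7853990756.

Whether P→Q transitions during the schedule push the simulated
double-positive fraction above or below the analytic anchor is not obvious
a priori: transitions remove cells from the pulse-labeled pool, but
ancestral divisions also label descendants. The package therefore reports
both the analytic value and the simulated fraction (≈0.82 at the default
parameters) instead of asserting an ordering. The degenerate
`state_memory=False` mode redraws each cell's state daily; it reproduces
the independence prediction and is used as a test oracle for the
model-vs-model gap.

## Inference

Fitting is simulation-based distance minimization — no tractable likelihood
exists for the size distribution. Choices:

* **Statistic.** Colony sizes binned into half-open classes 1, 2, 3–5,
  6–10, 11–20, ≥21 (configurable); distance is the symmetric chi-square
  form Σ (p_i − q_i)²/(p_i + q_i) on proportions, summed over weeks. It is
  a premetric: non-negative, zero iff the binned distributions coincide,
  symmetric, bounded by 2. An unbinned Kolmogorov–Smirnov alternative is
  selectable.
* **Search.** Full grid (transparent, parallelizable, deterministic);
  ties broken by lexicographically smallest (*m*, *s*). No MCMC: the
  original fit was iterative simulate-compare-adjust, which a grid search
  formalizes. The near-optimal sub-grid (within 5% of the minimum) is
  returned as a rough uncertainty summary instead of profile intervals.
* **Common random numbers.** Each candidate is simulated with the same
  derived streams (`default_rng([seed, replicate])`), so the distance
  surface is a deterministic function of (dataset, seed, grid), and a
  dataset generated with `replicate_rng(seed, 0)` is recovered at distance
  exactly 0.
* **Replicates.** The distance is averaged over 6 simulated datasets per
  candidate. The (*m*, *s*) surface has a shallow anti-correlated ridge
  (raising *m* and lowering *s* nearly compensate), and with fewer
  replicates estimator noise — not dataset noise — dominates which ridge
  point wins. Six replicates make a 49-point fit of a 1450-colony study
  take ~5 s; recovery then lands within one grid step of the truth
  (|Δm| ≤ 0.05, |Δs| ≤ 0.03) in ~85–90% of replicate studies.
* **Extinct clones.** Simulated designs condition on size ≥ 1, mirroring
  that only visible clones are counted; discards are reported in metadata.

## Synthetic data generator

`StudyDesign` defaults encode the emulated study: weeks 0, 2, 4, 6, 8 with
257, 272, 304, 307, 310 colonies, pooled from five mice per time point,
single-cell labeling of 0.2% of BECs. Colonies are assigned to animals
round-robin with **no animal-level variance**, because empirical time points
pool animals; the generator also assumes complete colony observation (no
section truncation, imaging noise or under-counting) and daily censuses.
Passing tests on these data therefore demonstrates correctness of the
machinery and internal consistency of the model — not robustness to
overdispersion between animals or to measurement error in real tracing
data. Compartment tags ("duct"/"ductule") are decorative metadata drawn by a
rejection rule (duct-tagged colonies never exceed five cells, matching the
observation that large clones arise only in the peripheral ductules); they
are not a second mechanistic compartment.

## Numerical and degenerate-input choices

* Week-to-day conversion is 7 days/week, rounded to the nearest day before
  subtracting the lag; negative growth days clamp to 0 (week-0 colonies are
  founders).
* Fate-probability validation tolerates 1e-12 floating slack; the master
  equation conserves probability to 1e-9 (tested).
* `fate_probabilities(r=0.5, s=0)` (PQ probability 0) and *m* ∈ {0, 1},
  *l* ∈ {0, 1} are valid edge cases with the obvious degenerate behavior.
* Empty weeks, empty search spaces, datasets with only week 0, and
  size-0 records are explicit errors; weeks with fewer than 20 colonies
  warn.

## Problem sizes

Oracle comparisons use 1.5×10⁵ clones at 10 days (master equation at
`max_cells` 64); mean-dynamics checks 2–5×10⁴ clones; recovery experiments
20 replicate studies of 1450 colonies refit on a 7×7 (m, s) grid with steps
(0.025, 0.02), fixing (p, r, l, lag) at truth. These sizes make the full
test suite and the acceptance script each run in a few minutes on one CPU
while keeping Monte Carlo standard errors well inside the asserted
tolerances.

## Known limitations

* Only (*m*, *s*) are routinely identifiable from size distributions at
  these sample sizes; *p* and week-0 data pin the quiescent fraction, while
  *r* and *l* are weakly informed (the near-optimal sub-grid makes this
  visible).
* The daily time step means events within a day are unordered; continuous
  time (e.g. Gillespie) is out of scope, as are spatial structure of the
  biliary tree and density-limited (tumor-stage) growth.
* Mass per bin on the default widening bins is not a unimodality
  diagnostic: a monotonically decaying size density accumulates increasing
  mass in ever-wider bins. Shape assertions therefore use equal-width bins
  (the raw 50-day size pmf is unimodal with mode at 2 cells and monotone
  decay through the tail).
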