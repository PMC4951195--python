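# becgrowth

Stochastic two-state growth model of biliary epithelial cell (BEC) clonal
dynamics: simulator, exact master-equation oracle, dual-nucleotide labeling
predictions, simulation-based parameter inference, and a synthetic
clonal-tracing data generator.

## The problem

During chronic liver injury the intrahepatic biliary tree remodels
dramatically (the *ductular reaction*), driven by proliferation of the
pre-existing biliary epithelium. Clonal lineage tracing — permanently
labeling single BECs and counting their progeny in 3D — shows strong
heterogeneity: most labeled cells never expand, while a minority found large
colonies, giving unimodal, long-tailed colony-size distributions at every
time point. `becgrowth` is for quantitative biologists who want to simulate,
fit and probe the minimal stochastic model that explains this pattern.

## The model

Each clone starts from one founder, proliferative (P) with probability *p*,
quiescent (Q) otherwise. Per simulated day:

1. every P cell enters the cell cycle with probability *m* (Bernoulli entry;
   geometric inter-mitotic times with mean 1/*m* days);
2. a division replaces the mother by two daughters with fate

   | fate | daughters | probability |
   |------|-----------|-------------|
   | PP   | P + P     | *r* + *s*   |
   | PQ   | P + Q     | 1 − 2*r*    |
   | QQ   | Q + Q     | *r* − *s*   |

   so *r* sets colony-size stability and *s* the expansion imbalance
   (*s* = 0 is the balanced critical process of homeostatic epithelia);
3. every cell is lost with probability *l*.

Q cells never divide and never revert: the P→Q switch is irreversible, as
established by a consecutive BrdU/EdU dual-labeling experiment. Proliferation
starts only `lag_days` (measured: 6) after injury onset, so week *w* of
tracing corresponds to max(0, 7*w* − 6) growth days. The defaults
(*p* = 0.465, *m* = 0.175, *r* = 0.15, *s* = 0.06, *l* = 0.001) are the
values fitted to an 8-week thioacetamide-injury time course.

Closed-form means, E[n_P(t)] = [(1 + 2*ms*)(1 − *l*)]^t, and an exact
day-by-day master equation over (n_P, n_Q) states serve as deterministic
oracles for the Monte Carlo simulator.

## Worked example

```python
import numpy as np
from becgrowth import (ModelParameters, LabelSchedule, simulate_cohort,
                       cumulative_label_probability, predict_two_state,
                       StudyDesign, generate_study, fit)

params = ModelParameters()   # fitted parameter set, lag 6 days

# 8-week (50 growth-day) cohort of 2000 labeled founders
dist = simulate_cohort(2000, params, days=50, rng=1)
sizes = np.repeat(dist.support.astype(int), dist.counts.astype(int))
print(f"surviving clones: {dist.total:.0f} (extinct: {dist.n_extinct})")
print(f"median size: {np.median(sizes):.0f}, mean: {sizes.mean():.2f}, max: {sizes.max()}")

# dual-labeling predictions (8-day 1st label, 8-day gap, 1-day pulse)
print("analytic 1st-label prob:", round(cumulative_label_probability(params.m, 8), 5))
out = predict_two_state(LabelSchedule(), params, 100_000, np.random.default_rng(2))
print(f"simulated double+ fraction among 2nd-label+: {out.frac_double_pos_given_second:.3f}")

# synthetic tracing study (1450 colonies over weeks 0-8) and a refit of (m, s)
data = generate_study(StudyDesign(seed=3), params)
result = fit(data, {"m": [0.125, 0.15, 0.175, 0.2, 0.225],
                    "s": [0.02, 0.04, 0.06, 0.08, 0.1]}, seed=4)
print(f"refit: m={result.params.m}, s={result.params.s}, distance={result.distance:.4f}")
```

prints

```
surviving clones: 1951 (extinct: 49)
median size: 1, mean: 8.11, max: 92
analytic 1st-label prob: 0.7854
simulated double+ fraction among 2nd-label+: 0.816
refit: m=0.175, s=0.08, distance=0.0551
```

The median clone stays a single cell (most founders are or become quiescent)
while the largest reaches ~90 cells — the long tail. About 78.5% of
continuously proliferative cells divide at least once during an 8-day label
window, so under the two-state model ~80% of pulse-labeled cells already
carry the first label; under independent labeling that overlap would drop to
the population first-label fraction (~0.70 here, and far lower in tissue
where few cells cycle). The refit recovers *m* exactly and *s* within one
grid step on a single synthetic study.

The same stages are scriptable via the `becgrowth` command
(`simulate`, `fit`, `label`, `generate`), each taking `--config config.yaml
--seed N --out dir`.

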