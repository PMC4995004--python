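# burstkit

Transcriptional-bursting kinetics from single-cell expression counts.

Many genes are transcribed in stochastic bursts: the promoter switches
between an inactive and an active state, and mRNA is produced only while
it is active. In the two-state (telegraph) model this is captured by
three rates, each expressed per mRNA lifetime (normalised to the
degradation rate *K*<sub>d</sub>):

* *K*<sub>on</sub> — rate of promoter activation (burst frequency),
* *K*<sub>off</sub> — rate of inactivation,
* *K*<sub>t</sub> — transcription rate while active (burst magnitude).

At steady state the mRNA copy number *x* in a cell follows the
beta-Poisson law of Peccoud & Ycart,

```
P(x) = Γ(K_on + x) Γ(K_on + K_off) K_t^x
       ───────────────────────────────────  · 1F1(K_on + x, K_on + K_off + x, −K_t)
       Γ(x+1) Γ(K_on + K_off + x) Γ(K_on)
```

so a snapshot of counts across a population of cells — single-cell qPCR
or similar — carries information about the *dynamics* of transcription.
burstkit is for researchers who want to extract that information:

* **Estimation** — maximum likelihood over a precomputed lookup table of
  log *P*(*x* | *K*<sub>on</sub>, *K*<sub>off</sub>, *K*<sub>t</sub>).
  The whole likelihood surface for a population is a single
  histogram-by-table matrix product; the fit is its argmax.
  log-likelihood L(K_on, K_off, K_t | X) = Σᵢ ln P(xᵢ | K_on, K_off, K_t).
* **Normalization** — qPCR Ct values are scaled to bounded integer count
  surrogates, x = ⌊x_max · 2^(min Ct − Ct)⌋, with the per-gene scale
  shared across all populations.
* **SABEC** (Simulated Annealing for Bursty Expression Clustering) —
  cells are clustered into populations with homogeneous kinetics by
  alternating per-cluster ML estimation with annealed probabilistic
  reassignment, consensus over 50 restarts, a PAM cut of the consensus
  matrix, and pruning of cells that rarely co-cluster with their label.
* **EPiK** (Estimation of Parameter changes in Kinetics) — for a gene
  and a pair of populations, decides *which* rate changed, by
  intersecting BIC model selection over the 8 change scenarios, a
  marginal-probability overlap score per parameter, and a subsampling
  Kolmogorov–Smirnov statistic per parameter.
* **Synthetic data** — stationary-law samplers, an exact Gillespie
  simulator (independent oracle for the analytic law), binomial capture
  thinning, and the three validation benchmark designs.

## Worked example

Two simulated populations of 124 cells, one gene, where only the
activation rate differs (0.5 → 3.0 before transcript loss; 90% of
transcripts are lost to library preparation, which rescales
*K*<sub>t</sub> by 0.1 but leaves the switching rates intact):

```python
import numpy as np
from burstkit import build_lookup_table, ml_estimate, epik_test_pair
from burstkit.benchmarks import benchmark_grid
from burstkit.synthetic import sample_stationary_counts, apply_capture

table = build_lookup_table(benchmark_grid())       # 25,000 parameter sets
rng = np.random.default_rng(0)
a = apply_capture(sample_stationary_counts((0.5, 2.0, 300.0), 124, rng), 0.1, rng)
b = apply_capture(sample_stationary_counts((3.0, 2.0, 300.0), 124, rng), 0.1, rng)

for name, counts in [("A", a), ("B", b)]:
    fit = ml_estimate(counts, table)
    print(name, fit.params, round(fit.log_likelihood, 1))

call = epik_test_pair(a, b, table, seed=1)
print(sorted(call.bic_set), call.mp, call.ks, sorted(call.intersection))
```

prints (abridged):

```
population A: k_on=0.5 k_off=2.0 k_t=35 logL=-372.3
population B: k_on=3.5 k_off=2.0 k_t=30 logL=-414.4
regime: low
BIC scenario: ['k_on']
MP scores: {'k_on': -17.88, 'k_off': -2.31, 'k_t': -2.95}
KS statistics: {'k_on': 1.0, 'k_off': 0.11, 'k_t': 0.27}
intersection call: ['k_on'] direction: 1
```

The estimates land on the captured-count scale (*K*<sub>t</sub> ≈ 30
rather than 300 — absolute rates are not comparable across capture
efficiencies), the activation-rate change is recovered (0.5 vs 3.5), and
all three methods agree that *K*<sub>on</sub> — and only
*K*<sub>on</sub> — changed: the MP score for *K*<sub>on</sub> is far
below its −6.3 threshold, the KS statistic is 1.0 (the subsample
estimate distributions do not overlap), and BIC picks the
single-parameter scenario. `direction: 1` marks expression going up.

The same analyses are scriptable from the shell via the `burstkit` CLI
(`build-table`, `normalize`, `estimate`, `sabec`, `epik`, `simulate`,
`run`); `burstkit run --config run.yaml` executes the full pipeline
(normalise → estimate → cluster → prune → compare) with a JSON manifest
of every stage and seed.

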