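# lagnet

Supervised inference of **directed gene regulatory networks** from short
microarray expression time series (7–20 equally sampled points), for systems
biologists who need an auditable, knowledge-constrained alternative to
black-box network learners.

## The method

Given a log2-normalised expression matrix (genes × time points), every one of
the n(n−1)/2 unordered gene pairs is scored on two orthogonal evidence axes:

* **Pearson correlation** r = cov(X,Y)/(σ_X σ_Y), with its exact two-sided
  t-test p-value (n−2 df) — the linear route;
* **mutual information** I(X,Y) = Σ p(x,y)·log₂[p(x,y)/(p₁(x)p₂(y))] over an
  equal-width joint histogram, in bits — the nonlinear route.

The two are combined into an **associativity measure**
AM = √((ω₁·MI)² + (ω₂·|r|)²), the Euclidean magnitude of the weighted pair
projected onto a 2-D plane (default weights 1/centroid per axis, so both axes
have mean 1 over the pair universe).

Pairs are partitioned by the **pairwise gene hierarchy criterion (PGHC)**:
*authentic* pairs (APGs) clear the MI threshold **and** the correlation
threshold with a significant p-value; *questionable* pairs (QPGs) clear
exactly one route; the rest are *unauthentic* (UPGs). Both thresholds start
at the metric centroids and walk in fixed increments until the APG fraction
lands in a target band (default 30–45 % of all pairs). The loop sits inside
a multiobjective combinatorial-optimization wrapper that applies gain
constraints and acquired biological knowledge (forced / forbidden edges)
with exact set arithmetic. Significance-starved datasets first lift the
p-value threshold along a fixed ladder (0.05, 0.1, …, 1.0) until enough
pairs are eligible.

Directions come from signal processing: each authentic pair is an
input/output subsystem whose Welch cross-spectrum yields the coherence
|CPSD_ab|²/(PSD_aa·PSD_bb), and the transfer function CPSD_ab/PSD_aa with
gain (modulus) and phase (argument). At the pair's most coherent frequency,
a phase beyond ±5° orients the edge (negative phase: b lags a, so a → b); a
transfer gain below the gain threshold, or a near-zero phase, leaves the
association bilateral.

## Worked example

```python
import lagnet
from lagnet import simulate

planted = simulate.random_planted_network()   # 24 genes, 14 points, 20 edges
profile, truth = simulate.generate(planted)

results = lagnet.GeneNetworkModel(profile).fit()
print(results.summary())
```

```
Gene regulatory network inference
==================================================
genes: 24   time points: 14   pairs: 276
MI bins: 3
centroids: MI 0.4463  |r| 0.4449
p threshold: 0.05
terminal thresholds: MI 0.4463  |r| 0.4449
PGHC iterations: 0   status: classified
partition: APGs 95  QPGs 40  UPGs 141  (APG fraction 0.344)
gain threshold: 0.3   zero-phase tol: 0.0873 rad
edges: 70 directed, 25 undirected
mean total degree: 7.92
constraints: all satisfied
```

Reading the output: the 24 genes give 276 candidate pairs; the MI and |r|
centroids (0.446 / 0.445) already partition 34 % of pairs as authentic, so
the threshold walk stops immediately. Of the 95 authentic pairs, 70 receive
a direction from their cross-spectral phase and 25 stay bilateral. Scored
against the planted ground truth, 17 of the 20 planted edges are recovered
into the authentic group (85 %) and 82 % of those are oriented
source → target. `results.network`, `results.pair_stats_frame()` and
`results.save_bundle(outdir)` expose the full artifacts (SIF, GraphML,
edge/partition/phase tables, iteration log).

The same pipeline runs from the shell:

```bash
lagnet simulate -o data/                      # synthetic dataset + truth
lagnet infer data/expression.tsv -o run/ -g 0.3 -g 1.0
lagnet phase-sweep data/expression.tsv -o sweep.tsv
```

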