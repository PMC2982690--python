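# Methods

## Scope and model

lagnet infers a directed regulatory network among a small set of genes
(tens, not thousands) from one short, equally sampled expression time
series. The model is deliberately pairwise: regulation is read off the
statistical and spectral relationship of each gene pair in isolation, and
network-level structure enters only through the supervised partitioning of
the pair universe and through user-supplied knowledge constraints. No
attempt is made to distinguish direct from indirect regulation; a pair of
co-targets of a shared regulator will, and should, appear associated.

The pipeline has four stages, each behind its own module:

1. **Pairwise metrics** (`pairwise`). Pearson correlation with its exact
   t-transform p-value (n−2 df, two-sided), binned mutual information in
   bits, and the associativity measure
   AM = √((ω₁·MI)² + (ω₂·|r|)²), α = atan2(ω₂·|r|, ω₁·MI) ∈ [0, π/2].
   AM treats the two dependence metrics as orthogonal coordinates; α records
   the balance of evidence (α = 0: purely informational, α = π/2: purely
   linear). The zero vector takes α = 0 by convention. Default weights are
   the reciprocal centroids (the means of MI and |r| over all pairs), so
   both axes carry mean 1 before projection and neither dominates by scale.
   Thresholding uses |r| — anti-correlated regulation is evidence of
   coupling, not its absence — while signed r is reported.

2. **Partitioning** (`pghc`, `moco`). Pairs clear the *information route*
   (MI ≥ MI_th) and/or the *correlation route* (|r| ≥ CC_th and p ≤ p_th).
   Both routes: authentic (APG). One route: questionable (QPG). Neither:
   unauthentic (UPG). Both thresholds start at the centroids and move in
   fixed steps δ = 0.005 (undersized APGs: both down, refilling from the
   QPG pool; oversized: both up) until the APG fraction enters the target
   band, default (0.30, 0.45) — the sparse-network regime in which roughly
   a third of candidate pairs are retained. The walk stops in the band, at
   a domain boundary, when one step straddles the band, or at an iteration
   cap (10 000); it always returns the best partition visited, flagged by a
   status field, and logs a full threshold trace. Knowledge constraints are
   applied to the terminal partition with exact set arithmetic: forbidden
   pairs leave the APGs for the UPGs, forced pairs enter the APGs with a
   provenance flag, and a constraint report audits group arithmetic and
   both lists. The two optimisation objectives are handled lexicographically
   — reach the band first; among compliant thresholds the walk's stopping
   rule keeps the highest ones visited, which maximises the unauthentic
   group.

3. **Direction calling** (`spectral`). Welch estimates (Hann window,
   segment length min(T, 8), 50 % overlap, per-segment linear detrend) give
   PSDs and the CPSD; coherence = |CPSD_ab|²/(PSD_aa·PSD_bb), transfer
   function = CPSD_ab/PSD_aa. A single-segment periodogram would make the
   coherence identically 1; two overlapping segments are the minimal
   averaging a 7–14-point series affords. Per pair, the dominant frequency
   is the non-DC bin with maximal coherence (ties: lowest frequency — slow
   modes dominate cell-cycle series); DC is excluded because mean offsets
   are not lags. If the transfer gain at the dominant frequency is below
   the gain threshold (default 0.3), or the phase there is within ±5°
   (π/36 rad) of zero, the pair stays undirected; otherwise a negative
   phase (b lags a under the conj(A)·B convention) draws a → b and a
   positive phase draws b → a. Fixing the dominant frequency independently
   of the gain threshold makes the undirected count monotone in the
   threshold and nests stricter networks inside looser ones — properties a
   threshold sweep should have by construction, not empirically.

4. **Network assembly** (`network`). One edge per authentic pair: directed
   when called, bilateral otherwise; knowledge-forced pairs keep their
   forced orientation and provenance. All input genes remain as nodes, so
   isolates are visible. Exports: SIF (`activates-lead` / `associates`),
   GraphML with am/phase/gain edge attributes, and a delimited edge table
   that round-trips byte-identically.

The `GeneNetworkModel` / `GeneNetworkResults` pair packages these stages as
a fitted-model object: construction fixes the data and every supervision
knob; `fit()` is deterministic and returns estimates, partition,
diagnostics, `summary()`, and `save_bundle()`.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| MI bins | ⌊√T⌋ (3 at T = 14) | — | see below |
| p threshold | 0.05, ladder-adapted | — | standard significance; ladder for starved data |
| APG band | (0.30, 0.45) | fraction | sparse-network regime |
| δ_mi, δ_cc | 0.005 | bits / corr. | centroid-to-terminal distances are of this granularity |
| gain threshold | 0.3 | — | energetic-transfer floor; sweepable |
| zero-phase tol | π/36 (5°) | rad | below phase resolution of 2-segment Welch |
| iteration cap | 10 000 | — | termination guarantee |

**MI binning.** A b-bin joint histogram has b² cells and a finite-sample
bias of about (b−1)²/(2T ln 2) bits. One-dimensional rules (Sturges gives
5 bins at T = 14, i.e. 25 cells for 14 samples) push the bias to ~0.8 bits
— larger than the dependence signal a 14-point series can carry — and the
MI ranking degenerates toward noise. The default ⌊√T⌋ caps the joint table
near T cells (bias ~0.2 bits at T = 14), which both preserves ranking power
and yields centroid magnitudes in the range short real series produce. Any
bin count remains available via the `bins` argument.

**p-value ladder.** Weakly significant datasets (e.g. few replicate-averaged
points) may have almost no pairs at p ≤ 0.05; a network cannot be built from
them. When fewer than the band's lower fraction of pairs are significant,
the threshold is lifted along the fixed ladder 0.05, 0.1, 0.2, …, 0.9, 1.0
to the smallest rung admitting that fraction. This is the supervised step
the analyst would otherwise perform by hand; it is loud in the run log and
can be disabled (`adapt_p=False`).

## The synthetic generator

`simulate` emulates the statistical shape of short synchronised microarray
experiments: equally sampled series (default 14 points at 0.5 h), source
genes following one or two sinusoids (fundamental period drawn uniformly
from 0.45–0.95 of the window, random phase, optional half-period harmonic
at half amplitude) plus Gaussian noise; each planted edge copies its source
into the target after an integer-sample lag, scaled by a coupling in
(0, 1]; uninvolved genes are pure noise. The default regime plants 20 edges
among 24 genes with noise sd 0.2 at seed 42, with couplings in [0.6, 1.0]
and a one-interval lag (0.5 h on the half-hour grid): regulatory latency
short relative to the oscillation period, which is the regime a zero-lag
correlation route can see — a lag approaching a quarter period drives the
Pearson term toward zero by construction, and such couplings are invisible
to this method whatever the generator does.

What the generator does **not** model: dye/spot/array noise structure,
missing values, non-stationarity, unequal sampling, autoregulation, cycles
(the planted graph is acyclic), and indirect-vs-direct confounding beyond
what shared sources induce. Passing the end-to-end recovery test therefore
shows that the pipeline's stages compose correctly and recover plantable
structure under realistic noise; it does not certify performance on real
microarray data.

## Numerical choices and degenerate inputs

* Constant series are hard errors for correlation and spectra (undefined r,
  zero power); missing cells are hard errors unless interior linear
  interpolation is requested.
* MI's cell sum clips the ~1e-16 negative round-off to 0; coherence is
  clipped into [0, 1] and any excursion beyond 1 + 1e-9 is an internal
  error.
* Threshold comparisons are closed (≥ for metrics, ≤ for p), so vacuous
  thresholds classify exactly.
* Replicate averaging uses correctly rounded summation (fsum), making the
  result independent of replicate order to the last bit.
* All tie-breaks are total and documented (lowest frequency; ranking by
  descending AM, ascending p, lexicographic pair), so every stage is
  deterministic and reruns are bit-identical.
* Table writing renders floats with shortest round-trip `repr`, so
  read → write → read is bit-identical.

## Known limitations

* Phase is read at a single dominant frequency per pair; genuinely
  multi-band regulation is collapsed to one call.
* A two-segment Welch estimate has large variance; coherence contrast on
  7-point series (after replicate averaging) is weak, and direction calls
  there should be treated as hypotheses.
* The gain threshold filters amplitude asymmetry, not dependence: for
  equal-variance independent signals the transfer gain is O(1), so false
  directions among uncorrelated pairs must be (and are) prevented upstream
  by the partition stage, not by the gain cut.
* The pairwise design cannot separate a regulator→target edge from the
  co-target association it induces; knowledge constraints are the intended
  remedy.
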