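# Methods

This note documents the models and procedures implemented in `episodenet`,
the defaults and why they were chosen, and what the synthetic test systems
do and do not establish about real data.

## Signal model and segmentation

The input is a univariate pseudoperiodic series: an oscillatory, possibly
chaotic signal whose cycles repeat with varying shape and duration. Cycle
boundaries are defined as interior local minima (`x[t] < x[t-1]` and
`x[t] <= x[t+1]`; plateau minima take the leftmost index), following the
convention of cycle-based network analysis. Minima closer than `min_len`
samples (default 5) to the previously retained boundary are suppressed,
keeping the deeper one; this guards against noise-induced micro-cycles.
Samples before the first and after the last boundary are incomplete cycles
and are discarded. Indexing is 0-based with half-open intervals, so cycles
tile the segmented region exactly.

Episodes are non-overlapping blocks of `m` consecutive cycles (not sliding
windows), so `n_E = ⌊n_C / m⌋`; trailing remainder cycles are dropped.

No detrending or denoising is performed: segmentation quality on noisy
recordings rests entirely on `min_len`.

## Mutual-information estimation

`I(X, Y)` is estimated by the equal-width-bin histogram plug-in, with bin
ranges spanning each vector's own range. This makes the estimate exactly
invariant under affine rescaling of either input and keeps the whole
pipeline deterministic. Empty joint cells contribute zero. The logarithm
base is 2 (bits) and only rescales values globally.

Unequal episode lengths are handled by offset maximisation: with `L` the
shorter length, the metric is evaluated on every contiguous length-`L`
window of the longer episode and the maximum is returned. Bin edges are
recomputed per aligned slice so all offsets are scored on equal footing.
A Pearson-correlation metric with the same alignment scheme is provided for
contrast with correlation-based cycle networks.

Bin count:

* For general use (`MiConfig(n_bins=None)`) the count adapts to the
  alignment length as `⌊√L⌋`, clamped to [8, 32] and to at most `L/2`.
  This is a standard bias/variance compromise and keeps very short episodes
  (e.g. Duffing-map cycles of a handful of samples) estimable.
* **Inside the effective-length procedure the bin count is fixed (16) for
  every `m`.** The clustering-vs-`m` profile is meaningful only if the
  estimator is identical across `m`; an adaptive bin count smooths
  single-cycle estimates more aggressively than episode estimates and
  thereby confounds the profile with estimator resolution. Empirically this
  confound can invert the profile's behaviour at small `m`. A user-pinned
  `n_bins` is always honoured.

The plug-in estimator is biased upward by roughly `(B−1)²/(2N ln 2)` bits
for `B` bins and `N` samples; no bias correction is applied (kept
deliberately out of scope). Consequences are discussed under Limitations.

## Network construction

Edges are sorted by descending similarity (ties broken by ascending
lexicographic node pair — with continuous similarities exact ties have
measure zero) and added one at a time; construction stops the instant the
graph on all episodes becomes connected. The edge set is therefore exactly
the shortest prefix of the sorted edge list achieving connectivity. Edges
whose weight comes up before connectivity is reached are added even when
they close a triangle, so the network can be denser than a tree; the
stopping weight provably equals the bottleneck (minimum edge) weight of the
maximum spanning tree, which is implemented alongside as a contrast and
testing oracle. Tied edges *after* the completing edge are not added. An
all-zero similarity matrix is rejected rather than connected arbitrarily.

Measures: global clustering is the average local clustering over all nodes
(degree < 2 contributes 0); average path length is the mean BFS distance
over unordered distinct pairs; degree statistics are exact counts. All
graph work is delegated to networkx.

## Effective episode length

For an ensemble of `M` independent series, the per-`m` mean `C̄(m)` and
population standard deviation `s(m)` of global clustering are estimated by
running the full pipeline per replicate. Two protocols exist:
`fixed_series_length` re-uses one cycle budget (default 120 cycles) for all
`m`, so networks shrink as `m` grows; `fixed_network_size` requests
`m · N` cycles so every network has `N` nodes, which removes the size
confound at higher simulation cost.

Selection rule: `θ = max_m C̄(m)`; starting at the smallest `m` attaining
the peak, `m*` is the largest `m` such that `C̄(m′) + k·s(m′) ≥ θ` for every
`m′` between the peak and `m`; the first failure stops the scan, and if
every length passes, the largest is chosen (smallest network with
undiminished structure). The scan is anchored at the peak rather than at
`m = 1` because the clustering curve typically rises from `m = 1` before
flattening; `k` (default 1) widens the tolerated band and `m*` is
non-decreasing in `k`. With `M = 1` the standard deviations are zero and
the rule degenerates to "largest m attaining the exact maximum".

Replicate seeds are derived from a master seed via `SeedSequence`, so
ensembles are reproducible and independent per replicate.

A synthetic-recovery harness generates plateau-plus-drop profiles (each
per-`m` statistic computed from 20 noisy draws) and verifies that the rule
recovers the true plateau length; with a drop of ten noise SDs recovery
exceeds 95%. Drops below `k` noise SDs are undetectable by construction.

## Power-law tails

Tail analysis of similarity-value distributions uses the continuous
power-law model `p(x) ∝ x^(−α)` above a cutoff `x_min`: the MLE
`α̂ = 1 + n / Σ ln(x_i/x_min)`, the KS sup-distance against
`F(x) = 1 − (x/x_min)^(1−α)`, cutoff selection by KS minimisation over
observed values (requiring ≥ 10 tail points), and a semiparametric
bootstrap p-value: synthetic datasets of matched size draw tail points from
the fitted model and sub-cutoff points from the empirical data, the
exponent is refitted per replicate **at the fixed observed cutoff** (full
cutoff re-selection per replicate would be quadratic in the sample size and
changes little at these scales), and `p` is the fraction of replicate KS
statistics at or above the observed one. The default of 500 bootstrap
replicates resolves `p` to ±0.02-0.05 — adequate for screening, below what
one would use for publication-grade p-values near a decision boundary.

## Synthetic test systems

Rössler (`a = b = 0.2, c = 5.7`, `dt = 0.05`), Lorenz (`σ = 10, ρ = 28,
β = 8/3`, `dt = 0.01`) and the Duffing map (`x' = y`,
`y' = −bx + ay − y³`, `a = 2.75, b = 0.2`) at their canonical chaotic
parameter values; the x-components serve as series. Flows are integrated
with fixed-step classical RK4 — deterministic, reproducible, and accurate
to O(dt⁴) for these smooth systems; adaptive stepping is deliberately
avoided so identical specifications give bitwise-identical output. A
transient (10% of the recorded length by default) is discarded to land on
the attractor, and integration aborts with a divergence error if any state
component exceeds 1e6. Ensemble factories jitter the canonical initial
condition uniformly (±0.5 per component) from a seeded RNG and enlarge the
run until the requested number of complete cycles is present.

These simulators emulate clean, stationary, noise-free pseudoperiodicity
with well-separated cycles. They do not emulate measurement noise,
artifacts, nonstationarity, trend, or multichannel structure of real
recordings (e.g. EEG); passing tests on them validates the machinery, not
its robustness to those features. Default study sizes (120-cycle budgets,
ensembles of 10, `m` up to 8) were chosen as the smallest sizes at which
ensemble means are stable; all are configurable.

## Design choices made where the design was open

* **Welch t-test** (unequal variances) for group comparisons, with the
  pooled variant available via a flag; equal variances cannot be assumed
  for network populations from different regimes.
* **Population (divide-by-M) standard deviation** in clustering profiles:
  the ensemble is treated as the population the criterion addresses.
* **Diagonal of the similarity matrix forced to zero**, so self-pairs can
  never enter construction.
* **First-completion stopping**: construction halts at the first edge that
  achieves connectivity even if further edges tie at the same weight.
* **Windowing** for population studies is non-overlapping and
  sample-count-based.

## Limitations

* The plug-in MI bias grows with bin count and shrinks with alignment
  length. When the cycle population is strongly heterogeneous in length
  (e.g. Lorenz x-cycles, length CV ≈ 0.33), pairs involving short cycles
  are systematically bias-inflated relative to long-cycle pairs, the
  longest cycles become connectivity bottlenecks, and single-cycle (m = 1)
  networks come out dense and highly clustered. For such signals the
  clustering-vs-m profile can peak at m = 1 even though the m = 1 similarity
  estimates are the least reliable; a bias-corrected or kNN estimator would
  be needed to remove this artifact and is out of scope here. For signals
  with narrow cycle-length distributions (Rössler-like, CV ≈ 0.09) the
  profile shows the expected rise from m = 1 to m = 2 and `m* = 2`.
* Offset maximisation gives pairs with larger length differences more
  chances to achieve a high similarity; with many offsets this is a mild
  upward selection effect.
* Local-minima segmentation assumes one clear minimum per oscillation;
  signals needing phase-based (Hilbert) segmentation are out of scope.
* The bootstrap GOF conditions on the observed cutoff (see above).
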