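# episodenet

Parametric construction of **episode networks** from pseudoperiodic time
series, using mutual information.

Oscillatory — possibly chaotic — signals such as EEG recordings, chemical
oscillations or the coordinates of chaotic flows consist of repeating
*cycles* of varying shape and duration. `episodenet` transforms such a
signal into a complex network whose structure reflects the underlying
dynamics, so that the machinery of network analysis (clustering, path
lengths, degree distributions, group comparisons) can be applied to time
series. It is aimed at researchers analysing physiological or dynamical
time series who want a parametric, information-theoretic alternative to
visibility graphs and correlation-based cycle networks.

## Method

1. **Segmentation.** Cycle boundaries are the interior local minima of the
   series; cycles tile the segmented region.
2. **Episodes.** An *episode* is a block of `m` consecutive cycles
   (`n_E = ⌊n_C / m⌋` episodes). The episode length `m` is the model's
   parameter: longer episodes give better similarity estimates but smaller
   networks.
3. **Similarity.** For every episode pair, the mutual information

   `I(X, Y) = Σ p(x, y) log₂ [ p(x, y) / (p(x) p(y)) ]`

   is estimated by a histogram plug-in. Unequal episode lengths are handled
   by sliding the shorter episode across the longer one and taking the
   maximum over offsets.
4. **Construction.** Edges are added in descending order of similarity and
   the construction stops the moment the graph on all episodes first
   becomes connected (the *maximal connected component*). Unlike a maximum
   spanning tree, the result may contain cycles; the stopping weight equals
   the tree's bottleneck weight.
5. **Effective length.** Over an ensemble of series, the *effective* episode
   length `m*` is the largest `m` whose mean global clustering, plus `k`
   standard deviations, still reaches the peak of the clustering-vs-`m`
   curve — the smallest network that preserves the ensemble's structural
   signal.

Rössler, Lorenz and Duffing-map simulators are built in as test-bed data
sources, and a power-law tail fitter (continuous MLE, KS distance,
bootstrap goodness-of-fit) characterises the similarity distributions.

## Worked example

```python
from episodenet import EpisodeNetworkModel

res = EpisodeNetworkModel.from_simulation("rossler", n_cycles=120,
                                          seed=3, m=2).fit()
print(res.summary())
```

```
Episode Network Results
=================================
Samples              14106
Cycles               120
Episode length m     2
Episodes (nodes)     60
Edges                568
Similarity metric    mutual_information
Stopping weight      2.5260
Global clustering    0.8171
Average path length  3.2345
Max degree           33
Mean degree          18.9333
```

120 chaotic Rössler cycles give 60 two-cycle episodes. The greedy
construction needed 568 of the 1770 possible edges before the last episode
connected (the weakest of them carrying 2.53 bits), yielding a densely
clustered network (C = 0.82) with short paths — the signature of a strongly
self-similar pseudoperiodic signal. `res.tail_fit()` fits a power law to
the upper tail of the 1770 mutual-information values, and
`res.model.select_episode_length(...)` estimates `m*` from an ensemble.

The same pipeline is available from the shell:

```bash
episodenet simulate --system rossler --n-steps 20000 --out ts.txt
episodenet construct --input ts.txt --m 2 --out-dir out/
episodenet efflength --system rossler -M 10 --m-max 4
```

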