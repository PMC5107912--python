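# streamcom

How often must a stream community be sampled for a monitoring programme to
track its real temporal dynamics?  `streamcom` answers that question the way
it is answered in daily bio-monitoring studies of riverine algae: cluster the
sampling dates into temporal regimes, measure how quickly community
similarity decays with the interval between samples inside each regime, and
convert the decay into an **appropriate sampling frequency (ASF)** that can
be related to catchment wetness.

It is a library for ecologists and hydrologists designing or auditing
bio-monitoring protocols; the importable API plus the narrative scripts in
`examples/` are the interface.

## The method

Given a daily (gappy) date × taxon abundance table and a daily rainfall
series:

1. **Temporal clustering.** Daily profiles (relative abundances) are mapped
   onto a batch-trained Kohonen self-organizing map on a hexagonal lattice;
   the lattice size follows the 5√n heuristic (n = 348 samples → a 10×9 map,
   90 units).  The codebook is agglomerated with Ward linkage and the cut is
   chosen by the Davies–Bouldin index on the sample-level assignment; short
   label runs are absorbed into their enclosing calendar run by an explicit
   contiguity rule.
2. **Validation.** The multi-response permutation procedure (MRPP) tests
   whether composition differs among clusters, overall and pairwise, with a
   Monte-Carlo null (999 permutations by default; the smallest attainable
   p is 1/(1+999) = 0.001) and the chance-corrected agreement
   A = 1 − δ_obs/δ_exp.
3. **Similarity decay → ASF.** The percentage similarity index between two
   profiles is PSI = 100·Σₖ min(P_ik, P_jk) (Renkonen similarity; 100 =
   identical, 0 = no shared taxa).  Within each cluster the mean PSI is
   computed over all date pairs s calendar days apart, s = 1..30; the ASF is
   the last interval before the mean first drops below the 60% similarity
   threshold.  Curves that never cross are censored "> 30 days"; a cluster
   below threshold after one day is "< 1 day".
4. **Wetness.** The antecedent precipitation index
   API_t = k·API_{t−1} + P_{t−1} (monthly decay k ∈ [0.85, 0.98]) summarises
   catchment wetness; days are classed low/moderate/high by the quartiles of
   a long-term API record, and per-cluster mean API is correlated with ASF.

A synthetic generator closes the loop: regimes drift by a species-replacement
model whose expected PSI decay is exactly 100·(1−r)^s, so the true ASF is
known in closed form (ln(θ/100)/ln(1−r)) and every stage can be tested
against analytic truth, including the bias introduced by 300-valve
multinomial counting noise.

## Worked example

`python examples/sampling_frequency.py` simulates the default study-scale
year (371-day window, 348 samples, 113 taxa, 300 counted valves per sample)
and prints:

```
cluster  mean PSI at 1 d   at 13 d   estimated ASF   true crossing
   1        83.5          79.1        > 30 days    50.8 d
   2        79.1          67.8          20 days    25.0 d
   3        78.1          74.3        > 30 days    63.6 d
   4        54.0           0.0          < 1 day     0.9 d
   5        77.9          54.7          10 days    13.0 d
```

Clusters 1 and 3 drift so slowly that monthly sampling would still be
representative (censored above the 30-day horizon); the wet winter cluster 4
is already below 60% similarity after a single day and needs sub-daily
sampling; clusters 2 and 5 get finite ASFs.  At this counting depth the
estimates sit below the analytic crossings (20 vs 25 d, 10 vs 13 d):
finite counts depress observed similarity, a real caveat for valve-count
data.  `examples/wetness_and_asf.py` continues the analysis and prints a
Pearson r of −0.946 between mean API and ASF — wetter conditions, faster
turnover, shorter sampling intervals.

## Layout

- `src/streamcom/community.py` — data model, I/O, profiles, diversity indices
- `src/streamcom/som.py` — map-size heuristic, batch SOM, U-matrix, Ward cut,
  contiguity smoothing
- `src/streamcom/mrpp.py` — MRPP, overall and pairwise
- `src/streamcom/psi.py` — PSI, decay curves, ASF with censoring
- `src/streamcom/hydrology.py` — API recursion, wetness classes, ASF–API fit
- `src/streamcom/synthetic.py` — regime-structured simulator with closed-form
  similarity decay
- `src/streamcom/pipeline.py` — one-call driver over all stages
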