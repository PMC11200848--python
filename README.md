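# mcomeda

Multiscale angular-distance complexity analysis of electrodermal activity
(EDA / skin conductance).

The package computes a normalized phase-space complexity index for a
skin-conductance recording and summarizes its behaviour across time scales:

1. **Pre-processing** (`mcomeda.io_preprocess`) — load a one-channel CSV,
   downsample to 5 Hz with zero-phase anti-alias filtering, split
   tonic/phasic components (pluggable backend: zero-phase low-pass by
   default, external cvxEDA if installed), rebuild the noiseless signal as
   tonic + phasic, z-score.
2. **Embedding** (`mcomeda.embedding`) — lag from the first local minimum
   of the auto mutual information, dimension from false nearest neighbors
   (Kennel criteria), delay-vector construction.
3. **Single-scale index** (`mcomeda.comeda_core`) — cosine of the angle
   between every unordered pair of embedded vectors, diffusion kernel
   density estimate (improved Sheather–Jones bandwidth, DCT form) of those
   cosines, Sturges-rule bin masses, quadratic Rényi entropy, normalized to
   [0, 1].
4. **Multiscale summary** (`mcomeda.multiscale`) — non-overlapping
   block-average coarse-graining at scale factors β, index per scale with
   the scale-1 (τ, m) reused, trapezoidal area under the trend as the
   multiscale index.
5. **Statistics** (`mcomeda.stats_compare`) — sympathetic-band spectral
   index (mean PSD in 0.045–0.25 Hz over 30-s windows), per-condition
   averaging, Lilliefors normality screen, Friedman test, pairwise
   two-sided Wilcoxon signed-rank tests with Bonferroni correction.
6. **Synthetic data** (`mcomeda.synthetic`) — seeded EDA-like signals
   (tonic drift + Poisson-timed skin-conductance responses with a
   Bateman-shaped kernel + noise) and paired multi-subject cohorts.

## CLI

```sh
# generate a seeded synthetic cohort (CSV per recording + manifest)
mcomeda synth --n-subjects 10 --rates low=1,high=6 --seed 1 --outdir out/cohort

# compute per-stimulus metrics (tau, m, comeda, mcomeda, edasymp)
mcomeda compute out/cohort/manifest.csv --outdir out/metrics

# group statistics per metric (Lilliefors, Friedman, pairwise Wilcoxon + Bonferroni)
mcomeda stats out/metrics/metrics.csv --outdir out/stats

# full run on an externally downloaded dataset prepared as a manifest
mcomeda reproduce-case /path/to/manifest.csv --outdir out/case
```

A manifest is a CSV with columns `subject, condition, stimulus, path, fs`,
where each `path` points at a one-channel skin-conductance CSV.

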