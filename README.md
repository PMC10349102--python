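# nbstates

Linking movie-narrative semantics to dynamic brain states.

`nbstates` is for researchers analyzing naturalistic-stimulation fMRI: it
asks which brain systems track the evolving semantic content of a long
movie, at the level of per-subject dynamic states. The pipeline has three
pillars:

1. **Semantic contexts.** Timed text (SubRip subtitles) is binned onto the
   TR grid, smoothed with a 4-min window, tf-idf weighted
   (`tfidf(w,t) = tf(w,t) · ln(T/(1+n_w))`), and factored with
   nonnegativity-constrained latent semantic analysis (NMF, `M ≈ W H` with
   `W, H ≥ 0`). Each column of `W` is the per-timepoint expression of one
   semantic context; the matching row of `H` names it by its word weights.
2. **Hidden brain states.** Each subject's subregion series (per-segment
   detrended and z-scored; hippocampal and amygdalar subregions embedded by
   a hemisphere-shared PCA) feed region-network combinations
   `R = r_network + 2·r_limbic`, each modeled by a full-covariance
   Gaussian-emission hidden Markov model
   (`x_t | S_t = k ~ N(μ_k, Σ_k)`), fitted by multi-restart Baum–Welch EM
   with the restart selected by the strength of its semantic links.
3. **Association statistics.** Pearson correlation matrices between state
   presence γ and contexts/annotations; the top-10 link statistic with
   joint-shuffle permutation nulls; dwell-time and volatility summaries;
   and group-level single-component PLS signatures after Hungarian state
   alignment, validated with blocked 20-fold cross-validation.

A first-class synthetic-data generator plants known states, topics,
couplings and observer annotations at the study's data shapes, so the whole
pipeline is testable at desk scale. See `docs/methods.md` for the models,
assumptions and design choices.

## Worked example

Run the full pipeline at desk scale (3 synthetic subjects, 400 timepoints,
2 networks × 2 limbic structures):

```bash
nbstates run --demo --seed 1 --out demo_out
```

This simulates the dataset, extracts 20 semantic contexts, fits
3-restart HMMs for all 12 subject × combination series, computes linkage
and dwell tables and group PLS signatures, and writes `demo_out/report.md`.
The report's link-strength table starts:

```
| network | structure | median link r |
|---|---|---|
| NETA | AM | 0.0701 |
| NETA | HC | 0.0678 |
| NETB | HC | 0.0512 |
| NETB | AM | 0.0505 |
```

Each row is one region-network combination's median (across subjects)
top-10 semantics-brain link — the mean of each state's ten strongest
correlations between its presence trajectory and the context expressions.
The dwell table gives each combination's pooled mean spell duration in
seconds, and the group-PLS table the per-state held-out correlation between
the description and brain latent scores.

The same stages are available as library calls (sklearn-style estimators:
`NMFLSA`, `GaussianHMMStates`, `SharedHemispherePCA`, `PLS1`) and as CLI
subcommands (`simulate`, `semantics`, `fit-hmm`, `link`, `dwell`,
`group-pls`, `report`).

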