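# Methods

`nbstates` links the semantic structure of a long naturalistic movie to
per-subject dynamic brain states. This note documents the models, the
parameters that matter, the synthetic-data generator, and the numerical and
design choices behind them.

## The analysis model

### Semantic contexts from timed text

Timed text (SubRip subtitles) is binned onto the fMRI timepoint grid
(TR = 2 s by default): a cue contributes its tokens to every bin its time
span overlaps with positive measure. Tokens are case-folded, stripped of
punctuation, and filtered against a configurable stop-word list, giving a
timepoints-by-vocabulary bag-of-words count matrix `M` with `f_{w,t}`
occurrences of word `w` in bin `t`.

Because a 2-s bin holds at most a few words, counts are smoothed with a
centered boxcar of 4 minutes (2 min before and after, truncated at the
timeline edges). The window length matters: it sets the timescale at which
word usage is treated as "the current theme", and it is selectable by
`grid_search_window`, which scores candidate windows by the strength of the
resulting semantics–brain links.

The smoothed counts are tf-idf weighted,

    tfidf(w, t) = f_{w,t} / Σ_{w'} f_{w',t} · ln( T / (1 + n_w) ),

with `T` the number of timepoints and `n_w` the number of bins containing
`w`. One deliberate choice: `n_w` is counted on the **raw** (pre-smoothing)
bins. Counting it on the smoothed matrix makes any word recurring every few
minutes nonzero in essentially every bin — a multi-minute boxcar bridges the
gaps — which drives its idf toward zero and erases exactly the recurring
themes the decomposition is meant to find (a recurring character is the
canonical example of a useful semantic context). The printed formula permits
a negative idf for words present in ~all bins; such weights are kept, and
clipped to zero only at the factorization input, which requires
nonnegativity (clip counts are logged).

The weighted matrix is factored by nonnegativity-constrained latent semantic
analysis: NMF `M ≈ W H`, `W, H ≥ 0`, minimizing squared Frobenius error with
Lee–Seung multiplicative updates (seeded uniform init scaled by
`sqrt(mean(M)/s)`, at most 500 iterations, relative-objective tolerance
1e-6; the per-iteration objective is recorded and is nonincreasing). `s`
contexts are extracted (study default 200). H rows are scaled to unit
Euclidean norm with the scale absorbed into W, and contexts are sorted by
total expression — NMF has no inherent order or normalization, so both are
conventions for stable reporting. Unlike truncated SVD, NMF factors are not
orthogonal; the unit-norm-row convention is the closest well-defined
analogue, and we make no orthogonality claim.

### Observer annotations

Observers mark intervals (in seconds) where a character expresses an
attribute. Inter-observer agreement (IOA) at bin `t` is the fraction of
observers with an interval overlapping the bin. Bipolar attributes (arousal
high/low, direction self/other) are the difference of the two poles' IOA
series, in [−1, 1]. Episodes are maximal runs where any attribute's |IOA|
≥ 0.5 (the `≥` convention lets an exact even split count); per-episode
medians use the standard midpoint-average for even lengths. Aggregation
across characters takes the per-timepoint maximum for graded attributes and
presence (0/1) for discrete ones; location/time series pass through as
binary columns. The default synthetic attribute set has 52 indicators
(graded arousal/direction/valence, 22 discrete emotions, 4 place/time
flags, character-presence and miscellaneous narrative flags); the exact
composition is a configurable input.

### Signal preparation

Subregion BOLD series are detrended (least-squares line per column) and
z-scored (population sd) within each of the movie's 8 acquisition
segments; constant columns become zeros. Hippocampus (19 subregions per
hemisphere) and amygdala (9 per hemisphere) are embedded with one PCA per
structure fitted on the two hemispheres' series row-stacked along time, so
both hemispheres share one component basis (per-hemisphere means are
removed first so shared components capture shape, not offset; component
signs are fixed by making each component's largest-magnitude element
positive). Each hemisphere is projected onto 3 components, and a
region-network combination pairs one network's parcels with the 6 limbic
PCs: `R = r_network + 2·3` features. Standardization precedes the PCA fit.

### Hidden Markov brain states

Each subject × combination series is modeled as a first-order hidden Markov
chain over `n` states with full-covariance multivariate-Gaussian emissions
`x_t | S_t = k ~ N(μ_k, Σ_k)`. Inference is scaled forward–backward (exact
posteriors γ; per-frame max-shift avoids underflow at T ≈ 3500, R ≤ 30).
Fitting is Baum–Welch EM: means seeded at randomly chosen timepoints,
shared sample covariance, transitions initialized with 0.8 self-transition
mass; covariances floored at `1e-6 × mean diagonal variance × I`;
convergence at 1e-4 relative log-likelihood change or 500 iterations. The
log-likelihood trace is stored and must be nondecreasing.

Because EM is multimodal, each series is fitted from many restarts (study
default 100) and the kept restart is the one whose state-presence
trajectories have the largest model-level semantic link index: the mean
over states of the state's top-10 mean Pearson correlation with the
semantic-context expressions, using signed correlations (an absolute-value
variant is available by flag). The state count is selected by sweeping
n = 2..8 and reporting four criteria per candidate — the link index,
cross-subject state-presence similarity, and BIC with and without the
limbic columns, where `BIC = −2·LL + p·ln T` with
`p = (n−1) + n(n−1) + n(R + R(R+1)/2)`. The selection rule is argmin BIC
with ties broken by the link index; on synthetic 4-state data at study
length all criteria agree on 4. The BIC of a candidate is evaluated on the
link-selected restart (which restart the original protocol scored is not
determinable; at study length this does not change the selection).

### Linkage statistics

`P_semantic (s × n)` holds Pearson correlations between every context
expression and every state-presence trajectory (zero-variance columns give
r = 0 with a warning); `P_annotation (A × n)` likewise for annotations. The
top-10 link statistic averages each state's ten largest signed
correlations; the model index averages over states. Note the statistic is
selective only when the number of candidate features is much larger than
10 — with exactly 10 features it degenerates to the mean of all signed
correlations, which cancels across mutually exclusive states.

The permutation null applies one random row permutation jointly to all γ
columns (preserving the per-row simplex) and recomputes the index;
`p = (1 + #{null ≥ observed}) / (1 + B)` with B = 1000 by default. A plain
shuffle destroys temporal autocorrelation, so the null is sharp; a
circular-shift variant that preserves autocorrelation is available by flag.
Network comparisons are two-sample pooled-variance t-tests of the reference
network's per-subject indices against each other network's (Welch and
Bonferroni variants by flag; no correction by default).

### Temporal statistics

Timepoints are hard-assigned to their argmax state (ties to the lowest
index). A dwell spell is a maximal run × TR; the per-model summary pools
spells across states (sample sd, n−1). Local volatility is the sample sd of
per-segment mean dwells with runs truncated — not bridged — at segment
boundaries. The group table has one row per subject × combination (210 at
study scale).

### Group-level signatures

Subjects' state labels are matched to a template subject by the Hungarian
algorithm on the Euclidean distance between state mean vectors (μ only by
default: after z-scoring, means are scale-comparable; a flag adds a
Frobenius Σ term). The timeline is partitioned by aligned hard state, and
per-state brain blocks `G_k` and description blocks `E_k = [W | A]` are
concatenated across subjects. One PLS component per state is extracted by
power iteration on the centered cross-covariance `E_cᵀ G_c` (tolerance
1e-10), with description columns standardized (they mix expression and IOA
scales; flag-controlled) and the sign fixed by the largest-|weight|
description. Generalization uses blocked 20-fold CV: each subject's
state-specific rows are split into contiguous blocks (respecting temporal
autocorrelation), fold f concatenates block f across subjects, and the
held-out Pearson r between the two latent scores is reported per fold.
Limbic PC loadings are reported both in PC space and back-projected to
subregions through the shared-hemisphere components.

## The synthetic-data generator

The generator emulates the study's data shapes: 15 subjects × 3543
timepoints at TR = 2 s in 8 near-equal segments; 7 networks of 5–24
parcels; 38 hippocampal and 18 amygdalar subregions; 4 states per
combination; 9 observers; 52 attributes. Everything is reproducible bit
for bit from a seed.

Key generator choices (and what they do and do not emulate):

- **Chains are per network and shared across subjects.** States are
  stimulus-driven, which is what makes one shared token stream couplable to
  every subject; the hippocampus- and amygdala-paired combinations of one
  network share that network's chain. Subject individuality enters through
  emission noise only — real subjects also differ in their state
  sequences, so cross-subject similarity is optimistic here.
- **Self-transition defaults to 0.97** (mean dwell ≈ 67 s, the slow
  associative end of the observed range). The choice is made once, for
  realizability of semantic coupling at the 4-min smoothing scale: a
  120-bin boxcar against ~6-bin dwells caps the attainable
  expression–presence correlation well below the planted levels the tests
  require. It is configurable (the dwell-law checks use 0.8–0.95).
- **Emissions are white Gaussians** per the observation model — no
  hemodynamic convolution or autocorrelated noise, so permutation nulls on
  synthetic data are cleaner than on real BOLD.
- **Limbic subregions** are low-rank images of white latent PCs (one
  orthonormal basis per structure shared by both hemispheres, per-hemisphere
  independent latents with sds 1.5/1.0/0.7, isotropic residual 0.3), so the
  shared-hemisphere PCA is exactly the right inverse model. Limbic latents
  are state-independent; states live in the parcel dimensions.
- **Token stream:** per bin, `N ~ Poisson(4)` tokens with 0.3 zero-inflation
  (silent scenes). Tokens come from a Zipf background, from "scenery"
  topics with smooth bump activations, or from coupled topics whose mixture
  weight is `amplitude · (c·presence + (1−c)·decoy)`, where presence is the
  planted state indicator and the decoy is an independent on/off chain of
  matched occupancy. The state-locking fraction `c` is calibrated by
  bisection (averaging the realized correlation over 6 draws) so that the
  smoothed topic expression correlates with the planted presence at the
  configured ρ. The mixed driver keeps token mass roughly constant while
  dialing the correlation; a pure presence-proportional weight would force
  near-zero amplitude at moderate ρ (topics too rare to factorize), and a
  constant baseline would make topic words ubiquitous.
- **Annotations:** planted episodes (default 120, 10–60 s) carry an arousal
  pole, valence pole, direction and a discrete emotion; each observer marks
  each episode attribute independently with the configured agreement
  probability and exact interval bounds (no timing jitter, so IOA equals the
  binomial agreement rate on episode bins). Vocabulary is synthetic; no
  linguistic syntax is modeled.

Passing tests on this generator demonstrate that the implementation
recovers what it plants under the model's own assumptions; they do not
certify behavior under hemodynamic smoothing, subject-specific state
sequences, or real linguistic statistics.

## Problem sizes in the shipped checks

The test suite and the acceptance script run at sizes chosen to exercise
the study-scale regime where it matters and desk scale elsewhere: parameter
recovery, state-count selection, topic recovery and the network-dominance
experiment run at the full T = 3543 (one combination, 5 subjects for the
group experiment, 3–20 restarts); the permutation-calibration experiment
uses 200 replicates of T = 300 with B = 200; the pipeline smoke and
determinism runs use 3 subjects × 400 timepoints with 2 networks.

## Known limitations

- The restart-selection index uses signed correlations; with few candidate
  contexts the top-10 statistic loses selectivity (see above).
- Plain permutation nulls are anti-conservative on strongly autocorrelated
  real data; use the circular-shift flag there.
- One PLS component per state only; no bootstrap confidence intervals on
  loadings.
- The subtitle and audio-description corpora of a real study are processed
  independently; no corpus merging is implemented.
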