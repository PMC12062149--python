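# Methods

## Problem setting

A steady-state visual evoked potential (SSVEP) speller presents `Nf`
flickering targets (here 40, at 8–15.8 Hz in 0.2 Hz steps); gazing at one
entrains occipital EEG at that frequency and its harmonics.  Recognition
means deciding, from a short multi-channel epoch `X ∈ R^{Nc×Ns}`, which
target was attended.  Calibration-free CCA compares `X` against artificial
sine–cosine references `Y_n ∈ R^{2Nh×Ns}`; calibration-based TRCA learns a
spatial filter per stimulus that maximizes inter-trial reproducibility.
Both degrade when few training trials are available — CCA because it
ignores subject-specific topography, TRCA because its covariance estimates
become unreliable.  The hybrid recognizer implemented here combines both
sources of information and adds a candidate-shortlisting stage.

## Training phase

Per stimulus `n` (and per filter-bank sub-band), from `Nt` training trials:

- template `X̄_n` = element-wise trial average;
- `(w_a, w_b)` = first canonical pair of CCA between the `Nt`-times tiled
  template and the equally tiled reference.  Tiling leaves canonical pairs
  invariant (verified exactly in tests), so this equals CCA of the plain
  template — the construction is kept for fidelity to its definition;
- `(w_c, w_d)` = first canonical pair between the time-concatenated
  training trials and the tiled reference;
- `w_t` = TRCA filter: the leading generalized eigenvector of `S w = λ Q w`
  with `S = Σ_{i≠j} X_i X_jᵀ` (inter-trial cross-covariance, channel-
  centered trials) and `Q = Σ_i X_i X_iᵀ`.  Note the orientation: the
  objective maximizes inter-trial covariance relative to total variance.
  Trials are mean-centered per channel first; the eigenproblem is solved as
  a symmetric-definite pencil with a ridge `1e-9·tr(Q)/Nc` on `Q` when
  needed.  Only the leading eigenvector is kept, unit-norm, dominant entry
  positive.

## Test phase

Stage 1 computes, per stimulus and sub-band `b`, five correlations:
`r1` = first canonical correlation `ρ(X_b, Y_n)`; `r2` = Pearson
correlation of `w_aᵀX_b` with `w_aᵀX̄_n`; `r3` = `w_aᵀX_b` vs `w_bᵀY_n`;
`r4` = `w_cᵀX_b` vs `w_dᵀY_n`; `r5` = `w_cᵀX_b` vs `w_cᵀX̄_n`.  Each
component is fused across sub-bands as `Σ_b c_b r_b²` with
`c_b = b^{-1.25} + 0.25`, yielding a non-negative `Nf×5` feature matrix.

Candidate selection clusters the `Nf` feature rows: the cluster count `h`
is chosen by fitting full-covariance Gaussian mixtures for
`h ∈ {2,…,8}` (3 seeded restarts each) and minimizing the Davies–Bouldin
index of the hard assignment (ties → smallest `h`; degenerate fits fall
back to `h = 2`); the rows are then partitioned by k-means++ and the
cluster with the highest mean feature value becomes the candidate set.
With only two stimuli, clustering is meaningless and all stimuli are
candidates.

Stage 2 scores each candidate `k` by `C_k = T_k + D_k`: `T_k` sums the
five fused features; `D_k` is the sub-band-fused Pearson correlation of
the flattened matrices `X_bᵀW` and `X̄_{k,b}ᵀW`, where `W` stacks the
TRCA filters of all candidates (H-TRCCA) or of all `Nf` stimuli
(eH-TRCCA).  The prediction is `argmax_k C_k`; all ties break to the
lowest stimulus index.  A singleton candidate set short-circuits stage 2 —
a one-column ensemble adds the same term to its only competitor.

Baselines share the filter bank and fusion rule: CCA uses `r1` alone; TRCA
correlates `w_{t,n}ᵀX_b` with `w_{t,n}ᵀX̄_{n,b}`; eTRCA uses the full
`Nf`-column ensemble correlation.

## Interpretive choices

The fused-versus-raw placement of the sub-band combination is genuinely
open; fusing every feature component (and `D`) before clustering keeps
stage 1 defined on a single non-negative matrix and makes `T` and `D`
commensurate before they are added, with no extra normalization.  `T` is
therefore a sum of squared-and-weighted correlations, not of signed ones.
The "matrix correlation" of two equally shaped matrices is defined as the
Pearson correlation of their flattened entries.  The per-cluster score
used to pick the winning cluster is the mean over all five components of
all member rows.  Only the TRCA filters are ensembled in eH-TRCCA; the
CCA-derived filters remain per-stimulus.

## Filter bank

Type-I Chebyshev band-pass filters with lower passband/stopband edges
[6/4, 14/10, 22/16, 30/24, 38/32] Hz and common upper edges 90/100 Hz.
The order comes from `cheb1ord` at 3 dB passband / 40 dB stopband
tolerances; the filter itself is designed at 0.5 dB ripple — the
convention of the standard public filter-bank implementations for this
edge table — so that in-band tones survive the forward–backward (zero-
phase) application with well under 1 dB loss while the stopband still
exceeds 40 dB.  Epochs are filtered with `sosfiltfilt` (odd-reflect
padding); inputs shorter than the padding transient are rejected.
References are analytic sinusoids and are never band-filtered.  Below
`fs = 200 Hz` the upper edges are clipped to 0.9/0.95 of Nyquist with a
warning.

## Windowing conventions

Reference time samples run `t = 1/fs, 2/fs, …, Ns/fs` (index origin one),
matching the phase convention of the classical recognizer.  Analysis
windows are `[latency, latency + d)` with start sample
`round(latency·fs)`; fractional offsets round half-up, so a 0.13 s latency
at 250 Hz starts at sample 33.  Defaults: latency 0.14 s, nine
parieto-occipital channels (Pz, PO5, PO3, POz, PO4, PO6, O1, Oz, O2),
`Nh = 5`, `Nb = 5`.

## Numerical choices

CCA is solved by SVD of the whitened cross-covariance; covariance blocks
receive a ridge of `1e-10·tr/dim`, which also absorbs zero-variance
channels (logged).  Correlations are clipped to their theoretical ranges.
Weight signs follow a fixed convention (largest-magnitude entry of the
first-view weight positive, the paired weight flipped with it) so that
signed downstream correlations are reproducible.  Zero-variance
projections yield a feature of 0 with a warning.  Degenerate TRCA input
(identical trials) is detected and logged; the leading eigenvector is
still returned, and for clean matched data the resulting score is correct
regardless of the filter.  Every stochastic step (GMM restarts, k-means++
seeding, simulation) is driven by explicit seeds; a fixed seed makes the
whole pipeline byte-reproducible.

## Evaluation

Leave-one-block-out cross-validation: each of `B` blocks serves once as
the test set; a fresh model bank is trained per fold.  An `Nt` override
keeps only the first `Nt` training blocks (in block order) of each fold.
Accuracy is the fraction correct; ITR in bits/min is
`[log2 Nf + P log2 P + (1−P) log2((1−P)/(Nf−1))]·60/(Tw + Tg)` with the
`0·log 0 := 0` convention and `Tg = 0` by default (a configurable
gaze-shift term is provided because published SSVEP ITRs often add 0.5 s).
The bracket is convex with its minimum exactly at chance, so it is never
negative.  Sweeps over `Nt`, `Tw`, `Nc` (channel-list prefixes) and `Nb`
re-window and re-train per cell; infeasible cells are skipped with a
warning.

## Synthetic data generator

Each trial is `Σ_h a_h sin(2π h f_n (t − τ) + h φ_n)` for `t ≥ τ`
(visual latency `τ = 0.14 s`), zero before, with five harmonics decaying
as `a_h = 1/h` — five observable harmonics mirror the `Nh = 5` analysis
convention and keep genuine signal in every sub-band (the 5th harmonic of
15.8 Hz is 79 Hz, inside 6–90 Hz).  Per-stimulus phases step by `0.35π`,
with harmonic phases scaled by `h` (joint frequency–phase coding).  The
harmonic series is mixed into the channels through a fixed seeded gain
matrix; the nine occipital channels get 3× the gain of any additional
channels, so channel-count sweeps behave qualitatively like real
montages.  Noise is independent per channel: spectrally shaped `1/f`
noise (α = 1) plus a 0.2-amplitude white floor, scaled per trial so the
SNR — defined in the 6–90 Hz analysis band over the post-latency window —
hits the target exactly.  The default is −10 dB, a moderate level at
which calibration-based baselines remain clearly above chance while the
low-trial gap between methods is visible.  Clean and noise components are
stored so the realized SNR can be audited.

What passing tests on this generator show: correctness of the algebra,
the decision rules, the protocol, and the qualitative low-trial advantage
under the generator's assumptions (stable per-stimulus amplitude and
phase, stationary noise, no artifacts).  What they do not show: absolute
accuracy on real recordings, robustness to latency jitter, amplitude
drift, eye or muscle artifacts, or inter-subject variability — the
generator deliberately omits all of these.

## Problem sizes

The shipped evaluations use 40 stimuli, 9 channels, 3 blocks, 0.6–1.0 s
windows and two training blocks per fold — the smallest geometry that
exercises the full 40-class recognition problem and the low-trial regime
the method targets.  Larger block counts and sweeps run through the same
code paths via the CLI.

## Known limitations

- The per-subject averages reported for real datasets are not
  recomputable from mean accuracy alone (the ITR is convex in `P`), so no
  numeric comparison against published tables is attempted; the harness
  reports its own simulated-data numbers.
- The clustering stage assumes the feature rows separate into a high
  (target-like) and low group; with extremely short windows or very low
  SNR the winning cluster can be large, and stage 2 then approaches
  plain exhaustive scoring.
- Statistical inference (repeated-measures ANOVA and friends) is out of
  scope; the harness reports descriptive per-fold values only.
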