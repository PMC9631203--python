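# Methods

This note documents the models, defaults and numerical choices behind
`genesift`, and what the synthetic benchmarks do and do not demonstrate.

## Problem setting

The target task is binary classification of small expression cohorts
(tens of samples, hundreds of genes after a differential-expression
screen), where the goal of selection is a short gene signature that (a)
keeps the class signal, (b) drops redundant co-expressed copies of it, and
(c) improves downstream classifier generalization.  Labels follow the
case/control convention 1 = ruptured, 0 = unruptured.

## Stage 1: symmetrical uncertainty and the FCBF sweep

Entropies are empirical plug-in estimates in log base 2 with no smoothing;
symmetrical uncertainty is SU(X,Y) = 2[H(X) − H(X|Y)]/(H(X) + H(Y)),
clipped to [0, 1] against float noise.  When both variables are constant
the 0/0 ratio is defined as 0; a single constant argument yields 0
naturally (no information either way).

SU needs discrete variables, so expression values are binned per gene:

- `mdl` (default): supervised Fayyad–Irani recursive binary splitting.  A
  cut is accepted when its information gain exceeds
  `log2(N−1)/N + [log2(3^k − 2) − (k·H(S) − k₁·H(S₁) − k₂·H(S₂))]/N`;
  genes with no accepted cut collapse to one bin and therefore drop out of
  the ranking at δ = 0.  MDL is parameter-free and is the binning
  conventionally paired with FCBF.
- `equal_frequency` / `equal_width`: unsupervised alternatives with
  `n_bins` bins (default 10); degenerate quantile edges are merged, so ties
  can produce fewer bins than requested.

A constant gene always maps to a single bin.  Discretization is exactly
deterministic: same input, same codes.

The filter keeps genes with SU(g, C) strictly above `delta` (default 0,
i.e. any positive association), sorts them descending (ties broken by
ascending gene identifier so the order is reproducible), and applies the
predominant-feature sweep: walking from the top, each kept gene removes
every surviving lower-ranked gene whose SU with it is at least its SU with
the class (`≥`, following the original predominance definition).  Pairwise
SU values are computed lazily, only against currently kept genes — no
G×G matrix is ever formed.

## Stage 2: the PSO wrapper and its MLP fitness

### Fitness classifier

A deliberately small network: one hidden layer of `hidden_size = 10`
logistic units and a logistic output p(d) = 1/(1 + exp(−g(d))), trained by
full-batch gradient descent on mean squared error (learning rate 0.1, up
to 300 epochs, early stop when the per-epoch improvement falls below
1e-6).  Weights initialise uniform(−0.5, 0.5) from the supplied seed, so
training is bit-reproducible and — because updates are full-batch —
invariant to sample order.  Features are z-scored with training-fold
statistics (near-constant columns fall back to unit scale); this is
required for stable sigmoid training on expression-scale inputs.  The
model is a scorer for the wrapper, not a competitive classifier: no
momentum, minibatching, or adaptive optimizers.

### Swarm search

Positions live in [0, 1]^D with one dimension per candidate gene;
velocities are clamped to ±v_max (default 0.6) and positions clipped to
the cube.  Defaults: 30 particles, 100 iterations, ω = 0.7,
c₁ = c₂ = 2, decode threshold 0.5.  A decoded-empty mask is repaired by
including the single largest-component gene, so the fitness classifier
always has at least one feature.

Subset fitness is `ACC − λ_mse·MSE − λ_size·(size/D)` with λ_mse = 0.1 and
λ_size = 0.05, where ACC and MSE come from stratified 5-fold out-of-fold
MLP predictions (MSE against the 0/1 label).  The weights make accuracy
dominate while breaking exact ties toward smaller and better-calibrated
subsets; both are exposed in the config.  Fitness values are cached per
decoded mask within a run, and the per-subset CV seed derives from
(run seed, mask CRC), so a subset's fitness is a stable number inside one
run.

**Turbulence.**  Because fitness is constant inside each decode cell, a
fully converged swarm (pbest = gbest = x for every particle) has velocity
dynamics v ← ω·v and stalls geometrically — measurably, the search then
sticks one bit-flip short of the optimum on a noticeable fraction of
planted-mask problems.  The search loop therefore applies a classical
per-component velocity re-randomization: after the standard update, each
component is replaced with a U[−v_max, v_max] draw with probability
`turbulence = 0.05`.  This keeps per-dimension exploration alive
indefinitely; on D = 10 planted-mask problems (swarm 20, 50 iterations)
it raises exhaustive-optimum recovery from 294/300 to 299/300 random
problems.  Set `turbulence = 0` to recover the bare textbook update, whose
per-step contracts (`update_velocity`, `update_position`) are unchanged
either way.

Stopping is a fixed iteration budget only; the gbest composite history is
non-decreasing by construction and is emitted per iteration.

## Stage 3: benchmark

Ten classifier families (XGBoost, LightGBM, random forest, extra trees,
Gaussian NB, k-NN, logistic regression, decision tree, RBF SVM, LDA) run
under stratified k-fold CV (default k = 10, shuffled from a derived seed).
Hyperparameters are the widely used library defaults, pinned in
`config/benchmark_models.yaml`; every model sits in a StandardScaler
pipeline (required by the scale-sensitive families, harmless for trees).
Accuracy/recall/precision/F1 and the confusion matrix are computed from
pooled out-of-fold predictions with positive class 1; AUC is reported as
the per-fold mean ± SD (from predicted probabilities, or decision values
for the SVM).  Precision is defined as 0, with a logged warning, when a
model makes no positive predictions.  A class with fewer members than k
raises an error suggesting a smaller k.

## Protocols and leakage

`protocol: paper` selects on the full dataset and then cross-validates the
same samples — the design most published signature studies use.  It is
optimistically biased: on pure-noise data the selected "signature" still
scores well above chance because selection saw the evaluation samples.
`protocol: nested` repeats the entire selection inside each outer training
fold and scores only outer test folds; it is unbiased, k times slower, and
its per-fold subsets may differ (they are all reported).  The default is
`paper` for comparability, with the nested estimate recommended whenever
the accuracy number itself is the claim.

## Seeds

One master seed fans out to stage seeds through
`SeedSequence([master, crc32(stage_name)])`; all derived seeds stay below
2³¹.  Two runs with the same data, config and master seed produce
byte-identical artifact files.

## Synthetic data

The generator emulates a DEG-filtered, batch-corrected matrix on a
log2-like scale: informative genes are Normal(±effect·label, noise_sd)
with alternating shift signs (both up- and down-regulated markers),
redundant genes are a randomly chosen informative gene plus
Normal(0, redundancy_noise_sd), and noise genes are label-independent
Normal(0, noise_sd).  Defaults mirror a 48 case / 40 control cohort with
effect log2(1.5) ≈ 0.585 (the usual |fold change| > 1.5 screen scale),
noise_sd 1.0 and redundancy_noise_sd 0.1.  The accompanying
`deg_prefilter` is a Welch-t-test + mean-difference screen (|Δmean| >
log2(fc) on the log scale), available to emulate the upstream DEG step; it
is not a moderated-statistics (limma-style) reimplementation.

What it does not model: platform batch effects and their correction,
count-based RNA-seq noise (negative binomial), pathway-structured
correlation blocks, or immune-composition signal.  Passing the planted
benchmarks therefore shows the machinery is correct and the selection
behaves as designed under a clean Gaussian model — not that the same
accuracy would be reached on cross-platform clinical cohorts.

A known statistical limit of the planted design: with
redundancy_noise_sd = 0.1 a redundant copy retains ≈ 99.5% of its parent's
signal-to-noise ratio, so the estimated SU-with-class of parent and copy
differ by less than the sampling noise of the estimates (the gap and the
noise both shrink as 1/√n, so larger cohorts do not resolve it).  Which
group member tops the SU ranking is then close to a coin flip, and the
filter — which by design keeps exactly the top-ranked member of each
correlated group — recovers the *signal group* reliably but the labelled
"original" only about half the time.  Group-level recovery, not
identity-level recovery, is the meaningful planted metric at that noise
level.

## Problem sizes used in the shipped benchmarks

The test suite and `scripts/acceptance.py` run the end-to-end pipeline on
five planted cohorts of 60 + 60 samples × 615 genes with a swarm of 20 and
40 iterations — enough for the swarm's recovery behaviour to saturate on
these cohorts (the candidate space after filtering is 6–15 genes) while
keeping a full five-seed replication cheap on one CPU.  Oracle checks use
exhaustively enumerable sizes: all discrete vector pairs of length ≤ 5
over a ternary alphabet, 100 random 20×8 tables for the filter sweep, and
all 2¹⁰ masks for the swarm.

## Known limitations

- Binary labels only; multi-class SU ranking is out of scope.
- The MLP fitness is a point design (one hidden layer, MSE loss); the
  wrapper treats it as a black box, so swapping in another scorer is
  straightforward but unbenchmarked.
- The composite-fitness weights (0.1, 0.05) are sensible defaults, not
  tuned optima.
- `protocol: paper` inherits the optimistic bias of the published design
  it reproduces; use `nested` for honest error estimates.
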