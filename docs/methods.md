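# Methods

This note records the model, the numerical choices, and what the synthetic
benchmarks do and do not establish. It is written for a maintainer or a
reviewer deciding whether to trust a number the package produces.

## 1. Model and working scale

The dynamics are an explicit one-step Euler discretization
`x_post = x0 + F(x0)·Δt` of a gene-regulatory ODE, with the rate law

    F(x) = C · exp(W2 · log(max(W1·x + b1, ε)) + b2)

- `W1` (H×d), `b1`: inner affine layer, pinned to the identity/zero by
  default (see §3). The clamp at `ε = 1e-8` keeps the log finite if a
  pre-activation drifts non-positive during training; its gradient is zero
  in the clamped region, matching the piecewise forward pass.
- `W2` (M×d when `W1 = I`): one row per hidden *monomial*; the row is the
  exponent vector. `b2` holds the log-coefficients.
- `C` (d×M): signed combination of the positive monomial rates onto genes.
  This is how decay terms coexist with production terms inside a block
  whose exp output is strictly positive. The printed form of the block
  cannot decrease expression on its own; a signed output combination is
  the minimal extension that can, and it preserves the K(d+1)-plus-signs
  parameter count of an exact K-term embedding (a two-head variant cannot
  embed multi-term laws exactly with `W1 = I`, which is why it was not
  chosen).

**Exact embedding.** `embed_monomial_system` maps any signed monomial rate
law onto this block with `W1 = I`, one hidden row per term, and a ±1
assignment matrix in `C`. On positive states the forward pass equals
direct evaluation to float rounding (measured ≤ 1e-13 relative; the test
bound is 1e-10).

**Δt is not identifiable** from two snapshots: scaling Δt by a equals
adding log a to every `b2` entry (tested as an exact identity). Training
therefore fixes Δt = 1; all downstream readouts are rankings or ratios
that are invariant to this choice.

**Working scale.** The model consumes *library-size-normalized counts plus
the pseudocount* — a strictly positive, multiplicative scale — and its own
LOG layer produces the log representation internally. The preprocessing
z = log(x+ε) is still computed (it is the conventional reporting and QC
scale), and `build_snapshot_pairs(scale="log")` feeds it directly instead,
but the linear scale is the default: feeding already-logged values makes
the block model "monomials of logs", which both misstates the biology and
(empirically) cripples optimization, because the informative probe
contrasts shrink by an extra log. On the linear scale the knockout floor
of the time-0 edit defaults to the pseudocount — the value a fully
silenced gene takes — which is simultaneously the natural convention and
a well-conditioned input.

**Elasticity orientation.** `S[g, i] = ∂(predicted x_i)/∂x_g` — rows are
*sources*, columns are *targets*, so a row lists a gene's downstream
partners. The identity contribution of the residual path is excluded by
default (it only shifts the diagonal). The Jacobian is analytic
(closed-form, exact); finite differences serve as an independent oracle in
tests, not as the implementation.

## 2. Data preparation

- QC: genes detected in ≥3 cells, then cells with ≥200 detected genes
  (both inclusive, one pass each, gene-then-cell order).
- Normalization: per-cell scaling to a common library size (default: the
  median of per-cell totals), then log with pseudocount ε = 1 on the
  counts scale. Zero-total cells are dropped with a warning.
- HVG: variance of the normalized log values, ties broken
  lexicographically on gene id so the panel is reproducible. Note that on
  count data this statistic is confounded by the mean–variance
  relationship of counts; it is the simple, stated convention, not an
  attempt at a variance-stabilized HVG ranking.
- Time-0: the per-gene mean over control cells (per batch stratum when
  labels exist, global fallback with a warning), with exactly one
  coordinate edited — the floor for interference/KO, the mean observed
  post level of the target for activation/OE. No test cell's non-target
  coordinates are ever read, which is the leakage guarantee.
- Splits: whole (target × guide × batch) groups to train/val/test at
  80/10/10, seeded. Baseline cells only ever inform time-0; singlets
  train; multiplets test.
- For *network inference* (as opposed to benchmarking), the ensemble is
  fit on all available singlet pairs — the discovery protocol — because
  the Jacobian needs every target's probe; held-out targets would leave
  their rows of S uninformed.

## 3. Training

Analytic gradients + Adam. Three choices matter and were arrived at the
hard way:

1. **Identity-monomial initialization.** `n_hidden = None` means one
   hidden row per gene with `W2` initialized at the identity (+ jitter
   1e-2), `b2 = 0`, `C ~ N(0, 1e-4)`. The model starts as a learnable
   *linear* rate law `F = C·x` — the classic baseline for network
   inference — and training bends exponents toward interactions. A
   symmetric small random init leaves the optimizer on a plateau where no
   feature is coordinate-specific; on probe-structured screen data it
   never escapes.
2. **Per-layer learning rates.** Adam's step size is gradient-scale-free
   (≈ lr per parameter per step regardless of gradient magnitude), and
   exponent parameters act inside an exponential of log-scale inputs, so
   giving `W2` the same learning rate as `C` injects multiplicative
   feature noise that puts a hard floor under the loss. Default:
   `lr(W2) = lr × 0.01` (`exponent_lr_scale`; 0.05 suits small dense
   systems whose true exponents are large).
3. **Cosine decay** of the global rate to 1e-4 of its peak, for the same
   reason: constant-rate Adam leaves a permanent jitter floor.

Loss is Huber with δ = 0.1 (robust to the heavy right tail of expression
targets); early stopping on a seeded 10% validation split of the training
pairs (group-aware splitting is the caller's job and happens upstream);
optional wall-clock cap returns the best validation checkpoint produced in
time. Everything is bit-reproducible per seed. Divergence (non-finite
loss) raises rather than returning a broken model.

Evaluation: global RMSE/MAE/Pearson on flattened matrices; threshold-free
ROC/PR-AUC with a configurable label rule (default positive class:
"target > 0 on the modeling scale" — the detection event in zero-inflated
data); micro/macro F1 at per-gene thresholds frozen on training targets
via a quantile rule (default: the gene's training negative rate, i.e. a
prevalence-matched operating point).

## 4. Network inference and validation statistics

- **Seed expansion**: breadth-first, per frontier gene the union of its
  row (downstream) and column (upstream) |elasticity| entries is the
  candidate list; survivors need score ≥ floor (0.001) AND score > the
  `pct` percentile of that gene's own ranked candidate list; the top-N
  surviving neighbors (ties by gene id) are admitted with every passing
  directed edge; visited genes contribute edges but are not re-expanded.
  Union-of-directions (rather than per-direction quotas) is the default.
- **Benchmark recall/enrichment**: hits = |nodes ∩ benchmark| (seed genes
  counted by default; a flag excludes them), expected = |benchmark|·
  |nodes|/background, enrichment = hits/expected. This reproduces the
  published five-regime enrichment column exactly from the printed
  (genes, hits) integers.
- **BH machinery**: per-edge p from the rank of its score among all
  off-diagonal |S| entries; Benjamini–Hochberg at q; q = 1 is an exact
  passthrough (no FDR filtering) but the machinery is present for
  smaller q.
- **Matched-null co-expression**: null pairs drawn per edge from strata
  that jointly bin genes by expression and by in-/out-degree in the model
  graph (default quintiles × quintiles), ~400 pairs/edge by default;
  observed vs expected tail fractions at τ ∈ {0.2, 0.4} in unsigned,
  positive, negative, sign-matched and opposite-sign views. Edges without
  a reference value are excluded from both numerator and null; empty
  strata widen to the nearest populated bin with a warning; 0/0 tails
  report NaN folds rather than feigned enrichment.
- **Overlap**: one-tailed hypergeometric with the population = all
  unordered pairs over the chosen gene universe. The universe is an
  explicit argument because "all human gene pairs" and "subgraph genes"
  give very different populations; both are supported.
- **Density null**: size-matched uniform gene-set draws (default 1000),
  empirical p with add-one correction (1+#{null ≥ obs})/(1+n).
- **Rewiring**: Maslov–Sneppen double-edge swaps via networkx (degree
  sequence preserved exactly); "iterations" means attempted swaps
  (default 1000, configurable); graphs too small to swap return unchanged
  with a warning.
- **Proteomics**: clean (drop reverse/contaminant, upper-case symbols,
  average duplicates, zeros → missing) → MinProb imputation per sample
  column from N(μ−1.8σ, (0.3σ)²) using observed values only → log2 →
  per-run median centering → per-edge Spearman over ≥3 paired finite
  channels → degree-matched null (21 bins, 0..19 and 20+) →
  two-sided Wilcoxon rank-sum (exact for small tie-free samples).
  The impute→log2→center order follows the cited workflow convention and
  is applied uniformly.

## 5. The synthetic screen: what it emulates, and what it does not

`ScreenSimConfig` defaults define a compact, well-powered screen:

- a 20-gene dynamic panel governed by a sampled 30-term monomial law
  (≤3 genes/term, integer exponents in {−2,−1,1,2}, log-uniform
  coefficients 0.2–1.0, random signs) embedded among 80 stable
  housekeeping genes that carry most of the library;
- the control baseline (lognormal, σ = 0.2) is made an *exact* fixed
  point by balancing each gene with first-order self-degradation or
  constant production — homeostasis of unperturbed cells. This adds no
  off-diagonal interaction and avoids root-finding entirely;
- 500 control cells, 2,000 singlets (two guides per target), 200
  two-target multiplets; interference = 75% knockdown of the target,
  activation = 3× boost; one Euler step with a latent Δt = 0.5, so
  downstream responses land in the 10–50% range typical of strong
  Perturb-seq hits;
- 5% multiplicative biological noise, per-cell lognormal library sizes
  (mean 10k, CV 30%), negative-binomial counts (dispersion 10).

Design rationale worth recording: (i) without the steady-state balancing,
every perturbation shares a large background drift response that swamps
edge-specific signal; (ii) without the housekeeping background, editing
one gene of a 20-gene panel moves several percent of the library total and
library-size normalization smears a row-constant artifact across all
genes — with ~100 genes the compositional shift drops below the noise
floor, as it does in transcriptome-wide data; (iii) power-law repression
terms diverge as a knocked-out input approaches zero, which real (saturating)
repression does not do — the 75% knockdown keeps probe responses in a
physical range.

What passing the recovery benchmark (ROC-AUC ≥ 0.85 for the 3-replica
ensemble's |elasticity| ranking against the planted support) does **not**
show: robustness to batch effects, doublets, ambient RNA, guide
inefficiency or off-target edits (none are simulated); detectability of
interactions whose effects are below the count-noise floor; or anything
about absolute rates (unidentifiable by design). The statistic is also a property of the
particular random rate-law draw: systems differ in how many of their
edges are intrinsically weak, so the AUC varies somewhat from simulation
seed to simulation seed.

The reference-table generator plants a configurable correlation
(default 0.5) on true-interaction pairs in the co-expression table and the
protein matrix, and mixes true edges with decoys in the reference edge
list, so each validation statistic can be checked for both type-I control
(signal 0 ⇒ fold ≈ 1, unremarkable p) and power (planted signal detected).

## 6. Problem sizes and determinism

Tests run the full screen pipeline at d = 20 with 2,000 singlets and
400-epoch, 3-replica training (≈15 s); statistical calibrations use
hundreds of edges and thousands of null draws. `scripts/acceptance.py`
re-runs everything from scratch in about half a minute. Every stochastic
stage takes an explicit seed; CLI subcommands derive stage seeds from the
global `--seed` and write a resolved-config copy next to each output.

## 7. Known limitations

- Elasticities are local to the chosen baseline; states far from it
  (including the hard-KO probes themselves) are extrapolations of fitted
  monomials.
- The one-step formulation cannot represent delays or oscillations, and
  leaves Δt unidentified.
- A single log–exp pair only: deeper stacks are deliberately unsupported
  (they destabilize training for one-step data and are not needed for the
  monomial representation result).
- The HVG dispersion statistic is the plain variance of log values;
  count-depth confounding is documented above rather than corrected.
- `matched_null_enrichment` requires the reference table to cover the
  sampled null pairs; with sparse references the attempt budget may
  truncate the null sample (counts are reported).
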