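# Methods

## Problem and model

`typiselect` addresses training-set curation for weakly supervised subtype
classification of malignant-lymphoma whole-slide images (WSIs). Pathology
archives store, for every case, the set of immunohistochemical (IHC) stains a
pathologist applied to reach the definitive diagnosis. When the H&E morphology
of a case is typical for its subtype, a small subtype-standard panel suffices;
when morphology is ambiguous, stains covering several candidate subtypes are
ordered. The stain *set* (not the staining results) therefore carries a latent
signal about how typical the case's morphology is — and atypical cases are
exactly the ones expected to damage the generalization of a small-data image
classifier if used for training.

The typicality score is built in three steps:

1. **Encoding and distance.** The stains used for case *n* become a binary
   vector `S_n` over a vocabulary of the `L` stains used by at least
   `min_usage` cases (default 10; rarely ordered antibodies act as noise).
   Dissimilarity is the Hamming distance `d(S_m, S_n) = ||S_m − S_n||_1`.
2. **Embedding.** The `N×N` distance matrix is embedded into `M` dimensions
   (default `M = 3`) by metric MDS, giving coordinates `u_n`. No subtype
   labels enter the embedding.
3. **Density ratio.** For each subtype `k`, a kernel density estimate
   `f_k(u) = |J_k|^{-1} Σ_{i∈J_k} G_w(u − u_i)` is fitted on the coordinates
   of the cases labeled `k` (isotropic Gaussian kernel, shared bandwidth
   `w`). The typicality of a case at `u` is
   `t_k(u) = f_k(u) / Σ_j f_j(u)`; its *own-subtype* typicality is `t` at
   its diagnosed subtype. Scores near 1 mean the case sits inside its own
   subtype's cluster with little overlap from the others.

Within each subtype, cases ranked by own-subtype typicality are split into
three near-equal groups — typical, intermediate, atypical — which drive two
selection protocols:

* **Experiment I (testing selection).** Each subtype × group cell is split
  into five random subgroups; fold *f* tests on subgroup *f* of the target
  group (typical or atypical) and trains on everything outside subgroup *f*
  of every group. The training pool of a fold is identical whichever group is
  tested, so one model per fold is trained and evaluated on both test sets.
* **Experiment II (training selection).** A subtype-stratified five-fold
  split; from each fold's training pool a ratio `(r_t : r_i : r_a)` with
  entries in {1, 2, 3} keeps `r_g/3` of each group. `3:3:3` keeps everything
  and is the baseline; `3:2:1` biases training toward typical cases.

The slide classifier is attention-based multiple-instance learning: patches
sampled from tissue form bags; each patch is encoded to a feature `h_i`, a
small attention network yields softmax weights `a_i` within the bag, the bag
feature is `z = Σ a_i h_i`, and a softmax head gives bag probabilities.
Training minimizes bag-level cross-entropy; slide-level probabilities are the
normalized geometric mean of bag probabilities,
`p_k ∝ exp(mean_b log P(Y_b = k))`.

## Numerical and design choices

* **Kernel normalization.** A 1-D-style constant `1/(|J_k| w)` and the
  multivariate constant `(2π)^{-M/2} w^{-M} / |J_k|` differ only by a factor
  shared across the `K` subtype models, which cancels in the typicality
  ratio. We use the multivariate density-consistent constant; `t` is
  provably invariant to this choice (covered by a test).
* **Log-space evaluation.** All densities are computed with log-sum-exp and
  the shared maximum subtracted before exponentiation, so far-outlying cases
  cannot underflow to 0/0.
* **Bandwidth.** A single shared `w`. The default strategy (`"spread"`)
  grid-searches 25 log-spaced values on `[0.05, 5] ×` median pairwise
  embedded distance and keeps the `w` maximizing the variance of own-subtype
  typicality — an automatic proxy for choosing the bandwidth at which scores
  spread evenly between low and high values instead of saturating at 0 or 1.
  Scott's rule and fixed values are available.
* **MDS.** Stress majorization (SMACOF) initialized from classical Torgerson
  scaling; distances enter raw. This is exact (stress 0) whenever the
  distances are realizable in `M` dimensions and deterministic given
  `(D, M, seed)`. Convergence: relative stress change `< 1e-9` or 3000
  iterations. Reported stress is normalized raw stress
  `Σ(d̂ − d)² / Σ d²` (0 = perfect, 1 = all points collapsed).
* **Own-coordinate inclusion.** A case's coordinate is part of its subtype's
  KDE support when scored (the same instances are scored as fitted); a
  leave-one-out switch exists but is off by default.
* **Grouping arithmetic.** Per-subtype descending sort, ties broken by case
  id; group-size remainders are assigned typical-first (67 cases →
  23/22/22). Experiment II keep counts: the group-level target is
  round-half-up of `r/3 ×` group pool size, allocated across subtypes by
  largest remainder with at least one case kept per nonempty cell.
* **Train/validation split.** Stratified 75%/25% within the selected
  training pool, at least one validation case per subtype.
* **The network.** A compact numpy implementation with explicit gradients:
  the encoder mean-pools each patch to a 4×4×3 color grid and applies a
  one-hidden-layer tanh MLP to `Q = 32` features; attention is a two-layer
  tanh scorer with exponential (softmax) normalization over the bag; the
  head is linear-softmax. Adam (lr 1e-3 for the tiny preset), 4 bags per
  batch. Per epoch, patches and bags of the training slides are resampled;
  the checkpoint with the smallest validation bag loss is kept (earliest
  epoch on ties). Probabilities are clamped at 1e-12 before logs. A
  `paper_scale` configuration preset (224 px patches, `Q = 512`, 50 bags of
  100 patches) exercises the same pathway at WSI-scale geometry.
* **Tissue detection.** Otsu threshold on the blurred HSV saturation
  channel, capped at 0.1: glass background sits well below 0.1 saturation,
  and the cap prevents the two-mode split from landing between weakly and
  strongly stained tissue.
* **Heatmaps.** Attention weights min-max normalized per bag (a constant
  bag maps to zero), painted on patch footprints, overlaps averaged,
  rendered blue-to-red.

## The synthetic fixtures

The generators emulate a three-subtype archive (AITL / DLBCL / CHL) so every
stage is testable without patient data:

* **IHC side.** 87 candidate stains; a 3-stain shared screening panel used at
  probability 0.9; per-subtype 13-stain core panels (contiguous windows with
  3-stain overlap between adjacent subtypes) drawn at 0.42; Poisson(0.3)
  rare extras. A case is atypical with probability 0.3, borrowing 5 stains
  from a uniformly chosen other subtype's core — the "redundant stains"
  signature of an ambiguous workup. These defaults reproduce the aggregate
  shape of the motivating archive: 67/97/98 cases, ≈9.9 stains per case,
  and 36 stains surviving the min-usage-10 filter.
* **Image side.** A slide stand-in is an elliptical tissue region (pink
  stroma) on white glass; a disk covering 40% of the tissue carries a
  subtype-specific color texture with blob speckle. An atypical slide's disk
  is blended pixelwise 70% of the way toward another subtype's texture, so
  the lesion genuinely resembles the donor class: in training such slides
  supply conflicting supervision (similar appearance, different labels),
  and in testing they are hard for any classifier — matching the clinical
  picture of a case whose morphology suggests the wrong subtype. Each slide
  gets a
  multiplicative per-channel color cast (log-sd 0.18) emulating staining
  variation — without it the task is trivially separable and training-set
  composition has no measurable effect. A jitter-free `separable()` preset
  is kept as a sanity bound. The same per-case atypical flag drives both
  generators so IHC-derived grouping is coherently linked to image
  difficulty.

What the fixtures do **not** model: real histologic texture (nuclei, growth
patterns), stain-specific chromogens, per-subtype stain-frequency profiles
beyond the core/shared/rare structure, scanner artifacts, and any
correlation between the *number* of stains and image appearance beyond the
planted flag. Passing tests therefore demonstrate that the pipeline recovers
planted structure of this kind, not clinical-grade performance.

## Problem sizes

The selection experiments run on 45 slides (15 per subtype) of 256×256 px
with 32 px patches, 4 bags of 16 patches per slide, 10 epochs, five folds,
three seeds — sizes chosen so a full run completes in minutes on one core
while leaving the orderings of interest measurable. The IHC-side analyses
use the full 262-case generator defaults.

## Known limitations

* Typicality is computed once on all cases before any split, as in the
  motivating study; the resulting information flow from test cases' IHC
  patterns into the grouping is inherent to the protocol and recorded in
  run manifests.
* MDS has no out-of-sample extension here; new cases require re-embedding.
* The ordering claims (typical vs atypical test accuracy; 3:2:1 vs 1:2:3
  training) are stochastic properties of small fixtures; single seeds can
  deviate, which is why experiments report over three seeds.
* Real WSI backends (pyramidal formats) are out of scope; slides are plain
  raster images.
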