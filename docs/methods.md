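# Methods

This note records the models, parameter choices and numerical conventions
behind `hossnf`, and what the synthetic-data results do and do not show.

## Heap-based optimizer

The HBO is a population metaheuristic over a box-constrained continuous
search space, minimization convention. The K agents are arranged in an
array-encoded d-ary min-heap keyed by (fitness, agent index) — the index
tie-break makes every heap operation deterministic. Defaults: ternary heap
(d = 3), population 20, seeded `numpy` Generator for all randomness.

Per iteration p (of P total) each agent proposes a candidate built per
dimension by a roulette draw o ~ U(0,1) against cumulative segments

- o ≤ o1 — keep the coordinate, with o1 = 1 − p/P (agents move rarely at
  first; the proposal rate rises linearly),
- o1 < o ≤ o2 — step about the heap parent D: D + γβ|D − x|, with
  o2 = o1 + (1 − o1)/2,
- o ≤ 1 otherwise — step about a random sibling N: from N if N is fitter,
  otherwise away from it relative to self: x + γβ|N − x|.

β ~ U(−1,1) per dimension; γ = |2 − (p mod ⌈P/C⌉)/⌈P/4C⌉| cycles 2 → 0 → 2
within each of C cycles (default C = max(1, P/25)), alternating exploration
and exploitation. The root agent has no parent; its parent branch falls
through to the sibling rule. Candidates are clipped into the bounds and
accepted only on strict fitness improvement (ties reject), after which the
improved agent sifts up the heap. Consequences used throughout the tests:
the best-so-far history is non-increasing, the heap property survives every
iteration, and all positions stay in bounds.

`optimize` accepts optional `initial_positions` that replace the first
agents of the seeded uniform population. The classifier trainer uses this
to seed one agent with the structure-learning result, so greedy acceptance
guarantees fitting never ends worse than its initialization.

On the 5-D sphere with K = 30, P = 500, all of 20 seeds reach ≤ 1e−3
(measured by the acceptance script).

## Threshold segmentation

Segmentation is posed as multilevel thresholding of the 256-bin histogram:
n thresholds (default 2 → background/cytoplasm/nucleus) with pixel v in
class c when t_c < v ≤ t_{c+1}; labels are inverted so the darkest class
(the hematoxylin-stained nucleus) gets the highest label. The HBO searches
continuous [1,254]^n; positions are rounded, sorted and de-duplicated
before each evaluation.

Two objectives sit behind one interface:

- **Otsu** (pipeline default): between-class variance Σ ω_c(μ_c − μ)².
- **Kapur**: summed within-class Shannon entropies, computed from prefix
  sums of p and p·ln p.

Otsu is the default because Kapur's global optimum degenerates on
near-noiseless images: a class holding a single occupied bin has zero
entropy, so on a histogram of three narrow spikes the entropy sum is
maximized by *merging* regions, not separating them (verified against
exhaustive search: nucleus Dice ≈ 0.7 at the Kapur optimum on noise-free
phantoms vs 1.0 at the Otsu optimum). Kapur behaves well once regions have
internal spread (noise or texture), and remains config-selectable.

The threshold landscape is piecewise constant (only the partition of
occupied bins matters), so a single greedy HBO run can converge prematurely
on plateau structure. `ho_threshold_search` therefore runs seeded restarts
(default 8 restarts of population 40 × 60 iterations, ~1 s per image) and
keeps the best; an exhaustive enumeration over two representatives per
cut-equivalence interval (exact for n ≤ 2) provides the ground truth the
stochastic search is measured against. The end-to-end pipeline uses a
lighter search (2 restarts, 20 × 50) because the Otsu landscape on cell
histograms is benign.

Degenerate single-level histograms return evenly spaced thresholds with a
warning. Overlap scoring reports per-label Dice and IoU (empty-empty
labels score 1.0) and pixel accuracy.

## Texture features

All features are computed on the preprocessed image cropped to the bounding
box of the segmented cell plus a 2-px margin (the classifier should see the
cell, not the background field). Fixed order, 58 values.

- **GLCM (32)**: image re-quantized to 8 levels by uniform binning of
  [0,255]; co-occurrence matrices from scikit-image at distances {1,2} and
  angles {0°,45°,90°,135°} (partner pixel at (r + round(d sin a),
  c + round(d cos a))), symmetrized and normalized. Statistics per matrix:
  contrast Σ(i−j)²P, energy ΣP², entropy −ΣP log₂P, correlation
  Σ(i−μᵢ)(j−μⱼ)P/(σᵢσⱼ) with the convention correlation = 1 when a marginal
  is degenerate (constant image). A brute-force double-loop oracle in the
  tests pins these to 1e−12.
- **LBP (10)**: 8-bit codes from thresholding the discrete 8-neighborhood
  at the center value (≥ → 1). The discrete neighborhood (rather than
  interpolated circular sampling) keeps every code exactly enumerable by
  hand, which the tests exploit. Uniform-2 mapping: codes with ≤ 2 circular
  transitions bin by popcount (9 bins), the rest share one bin; histogram
  normalized to sum 1. Invariant to strictly increasing intensity remaps.
- **Gabor (16)**: real cosine kernels on a fixed 5×5 support,
  g(x,y) = exp(−(x′² + γ²y′²)/(2σ²))·cos(2πf·x′ + ψ) with σ = 2, ψ = 0,
  aspect γ = 1, frequencies {0.3, 0.6} cycles/px × orientations
  {0°,45°,90°,135°}, mean-subtracted so constant regions respond zero.
  Features are mean and std of |response| (reflect-padded convolution),
  frequency-major order.

An optional flag computes the LBP histogram on the summed absolute Gabor
response instead of the raw ROI; the raw ROI is the default.

Feature standardization is per-feature z-scoring fitted on the training
split; zero-variance features are dropped and the kept indices stored, so
test-time vectors get the identical mapping. An optional top-k selection by
raw-feature variance exists (off by default).

## The SsNF classifier

A TSK fuzzy system read as six layers: input pass-through; Gaussian
memberships μ = exp(−(x−d)²/σ²); product conjunction per rule,
f_j = exp(−Σ_m (x_m−d_jm)²/σ_jm²); simplex normalization of the firings;
linear consequents (k_j·x + b_j) per class scaled by the normalized firing;
per-class summation. Scores are therefore a convex combination of the rule
consequents; classification is argmax with ties to the lowest class index.
The forward pass computes normalized firings in log space (shift by the row
maximum), so deeply negative exponents cannot underflow a whole row; the
plain normalization contract (all-zero input → uniform with a warning)
remains available as `normalize_firings`.

**Structure learning.** Per-input membership grids sit at 3 pooled
quantiles. The default rule width per input is the mean adjacent grid
spacing × √n, floored at 0.1 (standardized units). The √n factor calibrates
the *product* firing to the dimensionality: without it the firing of a
typical same-cluster sample in n dimensions decays like exp(−c·n), every
sample looks novel to the growth rule, and the rule base degenerates to one
rule per training point. One rule per present class starts at the
class-conditional feature mean with a one-hot consequent bias. A single
online pass then grows a rule at any training sample whose maximum firing
falls below the novelty threshold F_min (default 0.1); repeated presentation
of the same point grows at most one rule, and rule count is bounded by
initial rules + training-set size.

**Parameter fitting.** All centers, widths, consequent weights and biases
flatten into one vector with box bounds (centers ±3, widths [0.1, 5],
weights/biases ±5, standardized units). The HBO minimizes the mean squared
error between raw scores and one-hot targets (averaged over samples and
classes) within an evaluation budget (default 2000; population 20). The
structure-learning vector seeds one agent. A ridge least-squares consequent
initialization (the classic TSK hybrid-learning step) is implemented but
off by default: at ~100 training samples its extra linear degrees of
freedom overfit, and the one-hot biases generalize better.

Models serialize to JSON (schema_version 1) including the stored feature
transform; loading verifies the schema version.

## Synthetic data

`render_cell` paints an elliptical cytoplasm (radii 22–26 px) containing an
elliptical nucleus on a 64×64 canvas, base intensities background 230 /
cytoplasm 160 / nucleus 70, plus band-limited texture (mean of three
sinusoids with random period 8–24 px, direction and phase) on the cell
region, plus i.i.d. Gaussian noise, clipped and rounded to uint8. The
nucleus center offset is bounded so the nucleus ellipse stays strictly
inside the cytoplasm. Masks are exact by construction (labels 0/1/2).

Class identity follows cytology: nucleus radius ramps strictly upward
across normal squamous (4.5–5.5 px), intermediate squamous (6–7), normal
columnar (7.5–8.5), LGD (9.5–10.5), moderate (11.5–12.5), HGD (13.5–14.5),
carcinoma in situ (16–17.5), giving a monotone N/C ratio; texture amplitude
rises with grade (2, 2, 3, 6, 8, 10, 12 intensity units). Noise sd defaults
to 5. These numbers are package choices — plausible ranges that give
adjacent classes overlapping feature distributions but separable groups —
not measurements of any real dataset.

`generate_dataset` writes `images/`, `masks/` and `manifest.csv`;
byte-identical across runs with the same seed. Per-class split sizes use
largest-remainder rounding so totals are exact.

`gaussian_feature_clusters` generates the classifier-recovery conditions:
7 classes in 8 features (eight matching the number of input clusters the
network settles on), cluster sd 1, orthogonal centers at per-axis offset
4.5 so every pair of centers is ≈ 6.4 sd apart. The offset is chosen
comfortably above the 4-sd floor the recovery check assumes because at the
floor itself the Bayes error of a 50-sample test draw is not negligible —
the check would measure sampling luck rather than the trainer.

**What passing synthetic tests shows — and does not.** The phantoms share
with real Pap images only the ordering of region intensities, a monotone
N/C ratio and a texture-severity gradient. They contain exactly one
non-overlapping cell, no staining variation, debris, or focus artifacts,
and their texture is stationary sinusoidal rather than chromatin-like.
Perfect synthetic scores therefore validate the pipeline's mechanics
(segmentation optimality, feature correctness, trainability), not clinical
performance on real smears.

## Numerical conventions and degenerate inputs

- RGB→gray: fixed ITU-R 601 weights, rounded half-up; manifest CSV header
  is exactly `image_path,class_label,split`; labels canonicalize to
  lowercase underscores.
- Median filter: reflect padding; kernel 1 is the identity; even kernels
  rejected. Wavelet shrinkage: db4, 2 levels, soft universal threshold
  σ̂√(2 ln n) with σ̂ = MAD(finest diagonal)/0.6745; a zero threshold
  estimate (noise-free input) makes the step a no-op; output clipped to
  [0,255] and rounded. Min-max normalization maps a constant image to 0.
  Default order median → wavelet → normalize, config-overridable. For
  noise-free inputs the natural configuration is `median_kernel: 1` with
  the wavelet step omitted: there is nothing to suppress, and any smoothing
  perturbs discretized region boundaries (a 3×3 median flips
  staircase-corner pixels on ellipse edges), which matters when exact masks
  are the goal.
- Thresholds: integers in [1,254], strictly increasing; duplicate-after-
  rounding repaired by +1 shifts with a walk-back at the top of the range.
- Kapur/Otsu evaluated via prefix sums; empty classes contribute 0.
- Per-image pipeline seeds derive from the run seed through
  `numpy.random.SeedSequence`, keeping every stage deterministic and
  independent of manifest ordering quirks.
- Undefined ratio metrics (zero denominator) are reported as null, never 0.

## Problem sizes

Study-scale runs used throughout the tests and the acceptance script: 20
seeds × (K=30, P=500) for the sphere benchmark; 20 phantoms for threshold
oracle equivalence (32-level quantization); 100 random 16×16 images for the
Haralick oracle; 1000 random model/input pairs for the firing contract;
100/50 train/test samples for recovery; 50 phantoms per class (35 train /
15 test) for the end-to-end runs at noise sd 5 and 0. These sizes keep a
full verification pass at a few minutes on one CPU while leaving each check
statistically meaningful.

## Known limitations

- Thresholding cannot separate touching or overlapping cells, and assumes
  the nucleus is the darkest region (true for hematoxylin staining).
- Kapur entropy is unreliable on spike histograms (see above); it is kept
  for parity and for the oracle-equivalence check.
- The MSE training loss is not calibrated to 0/1 accuracy; small MSE
  improvements can occasionally trade away a borderline classification.
- HBO exploration collapses once the population concentrates (step sizes
  scale with inter-agent distances); restarts, not longer runs, are the
  effective remedy on plateaued landscapes.
- The 7-class confusion between adjacent severity grades remains
  substantial on noisy phantoms by design (overlapping morphology ranges);
  the binary normal/abnormal report is the headline metric.
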