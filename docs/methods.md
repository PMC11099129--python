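# Methods

## The optimizer

FFO is a population metaheuristic for minimizing `h : R^s → R` over a box
`[Z_lb, Z_ub]`. The population of `l` individuals is kept fitness-sorted
(stable sort, so equal-fitness individuals keep their prior order), which
fixes the producer set (the best `producer_fraction · l`, at least one)
and each scrounger's rank. Three stages run per iteration — foraging,
accumulation/besiege, perching — with greedy acceptance after each stage:
a proposed position is evaluated and kept only if strictly better, which
makes the global best elitist without any separate archive.

### Random-draw protocol

All stochasticity flows from one `numpy` Generator seeded by
`FFOConfig.seed`. Per individual per iteration a fixed-order block of
draws is taken (`StageDraws.sample`): alarm `T`, besiege selector `z`,
perching selector `p`, `β ∈ (0,1]` (drawn as `1 − U[0,1)` to guard the
foraging exponent), a standard normal, four uniforms `n1..n4`, the
besiege draws `E₀ ~ U(−1,1)`, `V ~ U(0,2)`, `Q ~ N(0,1)`, and a ±1 row
vector `B`. The sampling order is the reproducibility contract: two runs
with the same config are bit-identical, and an external re-implementation
consuming the same stream reproduces the trajectory exactly (this is how
the reduced-mode equivalence test pins the sparrow-search limit).

### Stage semantics and conventions

Several symbols of the besiege/perching stages are not pinned down by any
single convention, so the implementation fixes them explicitly (all
config-exposed):

* escape energy `E = 2E₀(1 − k/k_max)`; `|E|` is exactly 0 at the last
  iteration;
* `B⁺ = Bᵀ(BBᵀ)⁻¹` has the closed form `B_j/s` for a ±1 row, used
  directly;
* the hard-besiege denominator `S_best − S_worst` (current best minus
  worst fitness) is floored at 1e−12 in magnitude, preserving sign;
* `Y_scr` (the "scrounger" reference of the besiege and dive moves) is
  bound to the best-ranked scrounger's current position;
* `Y_fal` and `Y_prey` in the perching stage are both the current global
  best; `Y_curr` is the individual itself;
* the soft-besiege mixture weights are `x1 = x2 = x3 = 1/3` and the dive
  constant `λ = 0.5`;
* the dive move replaces the base besiege move only when it improves
  fitness (the dive trigger is otherwise unspecified);
* the starving-scrounger condition is `rank > l/2` on the fitness rank
  (population size, not the decision dimension), with `rank²` in the
  denominator;
* the hard besiege runs when `z < 0.5` (soft when `z ≥ 0.5`): the two
  cases must partition the alarm regime or one is unreachable;
* the high-alarm producer move is multiplicative (`Y · N_rand`);
  `ssa_compat=True` restores the additive sparrow-search original;
* perching applies to the whole population by default
  (`perch_producers_only` restricts it);
* boundary handling is componentwise clipping; minimization throughout.

The global best is refreshed after the producer stage (scroungers chase
the producers' updated optimum) and again after each later stage; the
worst position is the snapshot from the start of the iteration. The only
stopping rule is the iteration budget `iter_max`.

### Defaults

`l = 30`, `P_alarm = 0.5`, `producer_fraction = 0.2`, `iter_max` per
problem. On the 2-d sphere with `l = 30`, 200 iterations reach < 1e−3
(in practice numerical zero, since both the foraging contraction and the
perching blend are strongly exploitative once the best is near the
origin). On multimodal objectives (Rastrigin) the optimizer reliably beats
uniform random search at an equal evaluation budget, which is the honest
desk-scale claim; no competitive benchmarking against modern baselines is
intended.

## Features

Images are denoised with fast non-local means (patch 7, search window 21,
`h = 10/255` on [0,1] intensities), resized bilinearly to 224×224×3 and
clamped to [0,1]. The eight statistics are computed on the grayscale
luminance of the standardized image (the choice of pooled-vs-per-channel
is free; pooled keeps the vector at 8): mean, population standard
deviation, sample variance (divisor q−1), median, third and fourth
standardized moments (kurtosis is `m₄/σ⁴`, not excess), harmonic mean
`q/Σ(1/Z)` and geometric mean `exp(mean(log Z))`. Zero pixels are offset
by `ε = 1e−8` before the harmonic/geometric means; constant images get
skewness = kurtosis = 0 by convention. A `paper_literal` flag evaluates an
alternative set of printed formula variants (a variance-like standard
deviation without the square root, the median's index `(q+1)/2` rather
than its value, a single-point z-score read at the median for skewness,
`(μ/σ)⁴` for kurtosis, `q·ΣZ` and the raw product) for side-by-side
comparison; nothing in the pipeline uses them.

The backbone is any deterministic map from the standardized raster to a
fixed-length vector. The default projects the 4×4-block-averaged
luminance (56×56 → 3136) through a frozen `N(0, 1/n)` matrix to 101
dimensions with a tanh squash — deterministic, dependency-free, and
dimensioned so the concatenated vector has the pipeline's canonical
length 8 + 101 = 109. A pretrained CNN backbone can be substituted behind
the same interface without touching anything downstream.

## The classifier

The canonical architecture (input 22×11×1) is
conv(16,3×3,same,relu) → pool → conv(32) → pool → conv(64) → pool →
dropout(0.25) → flatten(15,488) → dense(64,relu) → dense(2,softmax),
with shape-preserving max-pooling (pool 2, stride 1, same padding). The
kernel size and single-channel input are the unique combination consistent
with the layer parameter counts (160 = 3·3·1·16+16, 4,640, 18,496,
991,296, 130). The 109-vector is zero-padded to 242 and reshaped row-major
to the input plane; features are z-scored per dimension with statistics
fitted on the training part of each split before reshaping.

All layers are implemented in NumPy (shift-accumulated 3×3 convolutions,
window-stacked pooling with argmax gradient routing, inverted dropout);
at this input size a 30-epoch training run on ~100 samples takes seconds
on one CPU.

Training uses Adam (β₁ = 0.9, β₂ = 0.999) on the MSE between the softmax
output and one-hot targets, batch 32. **The default learning rate is
1e−4**: with a 15,488-wide fan-in into the first dense layer, Adam's
per-parameter steps are nearly sign-like once gradients are small, so they
shift the layer's outputs coherently by up to `fan_in · lr` per step. At
1e−3 the softmax saturates within a few batches, MSE gradients vanish,
and the run collapses to one class with an lr-invariant loss trajectory;
at 1e−4 the desk-scale task trains to zero training error in 30 epochs.
This interaction of MSE-on-softmax, Adam and very wide fan-in is the one
place the conventional 1e−3 default is provably wrong for this
architecture.

`ffo_tune` then treats the head's 130 weights+biases as the FFO decision
vector, with fitness the MSE on a tuning fold held out from the training
part (25% by default). The activations feeding the head are precomputed
once, so each fitness evaluation is one 64×2 product. The search box is
the current head ± 1.0 and the current head seeds the initial population,
so by elitism the tuned fitness can never exceed the incoming one;
`iter_max = 0` returns the model untouched.

## Evaluation

Malignant is the positive class. Accuracy, sensitivity and specificity
are reported in percent to two decimals; an empty denominator flags the
metric as undefined (NaN) rather than coercing it. k-fold splits are
stratified (each fold's class ratio within one sample of the global one)
and seeded; `k = n` degenerates to a seeded leave-one-out permutation,
where stratification is vacuous. k-fold reports aggregate by the
unweighted mean across folds. A 100% training split is rejected.

## Synthetic data

Each image is an elliptical lesion over a textured skin background: the
boundary radius is `r₀(1 + a·Σ c_m sin(mθ + φ_m))`, orders 2–6, with the
irregularity amplitude `a` and the axis ratio (asymmetry) drawn from
disjoint per-class ranges — benign 1.00–1.15 vs. malignant 1.45–2.00
aspect, 0.02–0.06 vs. 0.12–0.25 amplitude — plus Voronoi color patches
(1 vs. 2–4) inside the lesion, Gaussian pixel noise (σ = 0.03) and
hair-like Bézier strokes with probability 0.2. The generative parameters
are stored with each image, so oracle checks can recompute class margins
from them; because the asymmetry ranges are disjoint, thresholding that
stored parameter at 1.30 classifies every sample correctly, which is the
ceiling the pipeline is judged against.

The base radius is drawn from the narrow range 0.26–0.30 of the image
side: radius is a nuisance parameter, and a wide spread would bury the
class differences that the global luminance statistics pick up, defeating
the generator's separable-by-construction design. With this choice a
linear probe on the 109 features reaches 95–100% held-out accuracy
across seeds, so the pipeline criterion (≥ 90% at an 80% split) tests the
trainer rather than the features' ceiling.

The full-scale spec mirrors the reference dataset sizes (1800 benign /
1497 malignant, 3297 total); the desk-scale spec (60/50) uses identical
per-class parameter regimes. The generator emulates class-discriminating
geometry and photometry only — real dermoscopy variability (illumination
fields, ruler/gel artifacts, lesion sub-types, patient skin-tone
diversity) is absent, so passing tests demonstrate that the pipeline
recovers constructed separable classes, not clinical performance.

## Problem sizes and controls

The shipped harness profile trains 30 epochs (the 100-epoch full profile
remains available in `NetworkSpec.epochs`) on the 110-image set with an
80/20 split; the shuffled-label control averages 5 independent
permutations because a single 22-sample split has a binomial standard
deviation of ~10.7 percentage points, making the mean of five (≈4.8
points) the meaningful comparison against the 50% chance level.

## Known limitations

* The optimizer spends three objective evaluations per besieging
  individual (base, dive, acceptance); no batch or parallel evaluation.
* The NumPy CNN is CPU-only and intended for the canonical small input;
  it is not a general deep-learning framework.
* `paper_literal` statistics can overflow to 0/inf (raw product of
  thousands of sub-unit pixels) — they exist only for comparison.
* Head tuning explores a fixed ±1.0 box around the trained head; weights
  outside that box are unreachable by design.
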