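# Methods

## The optimizer

The osprey optimization algorithm (OOA) is a population metaheuristic
for minimising an objective over a box `[lb, ub] ⊂ R^m`. A population
of `N` candidate positions is initialised uniformly in the box. Each of
`T` iterations sweeps the population; for every member `i` two moves
are proposed, each clipped to the box and accepted only on **strict**
improvement of the objective (ties keep the incumbent; the best index
is tie-broken to the lowest index):

1. **Global phase (hunting).** The member's *fish set* is the set of
   strictly better members united with the global best (never empty).
   One fish `SA` is drawn uniformly and the candidate is
   `Y_i + r ⊙ (SA − I ⊙ Y_i)` with `r ∈ [0,1]^m` and random integers
   `I ∈ {1,2}^m`. With `I = 2` the move contracts/reflects through the
   fish, which is what gives the algorithm its geometric convergence on
   unimodal problems.
2. **Local phase (carrying the fish).** An additive perturbation
   `(lb_j + r_j (ub_j − lb_j)) / t` per coordinate, whose envelope
   shrinks as `1/t` with the iteration counter `t = 1..T`.

The best-so-far value is recorded once per iteration, so the returned
history is non-increasing by construction.

### The modified variant (MOP)

Two modifications:

* **Chaotic `r` draws.** The uniform `r` of both phases is replaced by
  iterates of the sinusoidal chaos map `p ← a·p²·sin(πp)` with
  `a = 2.3`, one independent stream per (member, coordinate). The
  stream seeds are successive iterates of a single master stream
  started at `p0 = 0.7` (burn-in 100), so the whole construction is
  deterministic in `p0`. At `a = 2.3` the iterates remain inside
  (0, 1) — empirically confined to about (0.49, 0.92) — and the map is
  chaotic rather than eventually periodic at double precision over the
  horizons used here (checked for 10⁵ iterates).
* **Multiplicative Gaussian mutation.** After the two phase moves,
  each member attempts a third update `Y ← Y ⊙ (1 + k·g)` with
  independent per-coordinate `g ~ N(0, 1)` and a randomly decreasing
  scale `k = u·(1 − t/T)`, `u ~ U(0, 1)` drawn once per member per
  iteration, again with greedy acceptance. Because the perturbation is
  *relative*, accepted mutations shrink coordinates geometrically
  toward zero-centred optima; this step is what carries MOP from the
  `~1/t` precision floor of the local phase down to near machine
  precision on the unimodal benchmarks.

An earlier design folded the mutation into each phase's candidate
before greedy selection. That variant is strictly worse in high
dimension: a full-vector relative perturbation of an `m ≈ 3000`
candidate is almost never an improvement, so the mutation destroys the
phase move it rides on, and MOP then *trails* plain OOA on the network
training task — inverting the method's defining property. Treating the
mutation as its own greedily-accepted update step preserves both phase
moves and restores the intended ordering; it also means one MOP
iteration costs 3NT objective calls against OOA's 2NT, consistent with
the method's higher per-run cost.

All randomness derives from one integer seed split into named
substreams (initialisation, fish choice, `I` draws, mutation, uniform
`r`), so OOA and MOP runs with the same seed share their initial
population (common random numbers) and every run is bit-reproducible.

### Defaults

| parameter | default | why |
|---|---|---|
| `N` | 30 | typical swarm size for these benchmarks; unstated in the source protocol |
| `T` | 200 | the benchmark protocol's iteration count |
| `chaos_a` | 2.3 | the classical sinusoidal-map choice inside the admissible (0, 4]; keeps iterates in (0, 1) |
| `chaos_p0`, burn-in | 0.7, 100 | arbitrary non-degenerate seed; burn-in discards transients |
| benchmark dimension | 10 | unstated in the protocol; desk-scale and constant across functions |

## Benchmark functions

Ten classical box-constrained test functions, F1–F5 unimodal and
F6–F10 multimodal, with bounds as published. Three printed formulas
are internally inconsistent and are corrected to their standard forms:
Ackley (the printed inner cosine term does not yield 0 at the origin;
the standard mean-based form is used), Alpine 2 (`√x_i` is undefined on
the symmetric domain; `∏|sin(x_i)·√|x_i||` keeps the minimum 0 at the
origin), and Rosenbrock (the printed absolute value is redundant).
Trid is kept exactly as printed — `Σ(x_i−1)² + Σ x_i x_{i−1}` with a
*positive* cross term — so its minimum is not 0 and it is excluded from
optimum-value assertions.

## The capsule network

A deliberately tiny capsule classifier, sized for derivative-free
training: 16×16 grayscale input → one 3×3 valid conv layer, 4 filters,
stride 2, tanh → reshape to 49 primary capsules of dimension 4 →
squash → per-pair linear predictions `û_{j|i} = W_{ij} x_i` into 2
class capsules of dimension 8 → dynamic routing (3 iterations,
log-priors initialised to zero, agreement = dot product) with a
per-class additive bias entering the coupled sum before the squash.
Class-vector lengths `‖v_j‖ ∈ [0, 1)` are the class scores; prediction
is the argmax (lowest index on ties). The squash of the zero vector is
defined as zero. Total parameter count 3,192 (conv weights 36 + conv
biases 4 + capsule transforms 3,136 + capsule biases 16); a hard cap of
20,000 parameters rejects architectures too large for this training
mode. There is no reconstruction decoder.

Training minimises the margin loss
`L = Σ_c T_c max(0, m₊−‖v_c‖)² + λ(1−T_c) max(0, ‖v_c‖−m₋)²` with
`m₊ = 0.9`, `m₋ = 0.1`, `λ = 0.5`, as a full-batch deterministic mean
over the training set (no minibatch noise, so the optimizer's greedy
acceptance is well-defined). The search space is the cube `[−1, 1]` per
parameter. The routing contractions are implemented as batched matrix
products with the im2col patches precomputed once per dataset; a
single full-batch evaluation on 60 images costs ~1.3 ms, which is what
makes 10⁴–10⁵ objective calls per training run practical on one CPU.

## Synthetic smear data

The generator emulates the one morphological cue that separates the two
classes in stained peripheral-blood microscopy: leukemic blasts have a
large, irregular, dark nucleus; normal lymphocytes a smaller, round
one. Each 32×32 grayscale image holds one centred nucleus (radius
0.28–0.40 of the image side for blasts, with radial harmonic
perturbations of relative amplitude 0.35; radius 0.12–0.18, nearly
circular, for lymphocytes) over a light background scattered with 3–7
faint disc distractors standing in for red cells, plus Gaussian pixel
noise (σ = 0.03). The blast radius interval sits strictly above the
lymphocyte interval, so the classes are separable by construction — a
trivial dark-area threshold exceeds 80% accuracy, which is asserted in
the tests so the training experiments provably attack a learnable
problem.

What the generator does **not** emulate: colour and stain variation,
touching/overlapping cells, multiple white cells per field, cytoplasm
texture, focus blur, illumination gradients. Passing results on this
data demonstrate that the optimizer can train the network on a
separable image discrimination task; they say nothing about performance
on real stained smears.

Augmentation composes rotation (±50°), shear (±0.1), random X/Y
reflection, translation (±10% per axis) and rescaling (0.9–1.1) about
the image centre, bilinear, out-of-frame pixels filled with the median
border value; originals are always retained and per-class counts stay
within ±1 of the source proportions. Salt-and-pepper noise corrupts
exactly `round(density · pixels)` uniformly chosen pixels to 0 or 1
with equal probability.

## Metrics

Precision, recall, accuracy, specificity and F1 are percent-scaled;
F-beta (β = 2) and kappa are unit-scaled. Weighted kappa uses linear
disagreement weights `w_ij = 1 − |i−j|/(k−1)`, reducing to plain
Cohen's kappa for k = 2. AUC is the Mann–Whitney rank statistic with
0.5 tie credit. The published F-beta formula carries an extra `(1+β²)`
prefactor that pushes values above 1; the standard form is the default
and the prefactored one is retained behind `variant="as_printed"` for
fidelity. Undefined metrics raise `UndefinedMetricError` rather than
returning sentinels; the cross-validation harness records such entries
as NaN in its report.

## Experiment harnesses and problem sizes

* **Benchmark study** — 20 seeded runs per function at dimension 10,
  `N = 30`, `T = 200`; run `r` uses seed `base_seed + r` for every
  function and variant so comparisons are seed-paired. STD is the
  population standard deviation (divisor R).
* **Ablation** — per seed: stratified split of the 150-image synthetic
  set into 100 train / 50 test, then three trainings with `N = 20`,
  `T = 50`: budget-matched uniform random search (the "plain" capsule
  net — it isolates the optimizer's contribution at an equal number of
  objective calls), OOA, and MOP. The training budget is chosen so the
  trained models sit below the accuracy ceiling: at `T ≥ 80` both
  metaheuristics reach ~99–100% test accuracy on this data and their
  comparison is pure noise. The plain model is additionally evaluated
  on test images corrupted by salt-and-pepper noise (density 0.05)
  applied at the network's 16×16 input resolution — at the generator
  resolution the downsampling averages the impulses away. Wall time is
  reported but never asserted.
* **Learnability run** — MOP with `N = 30`, `T = 300` on a 40-image
  balanced synthetic training set, checked to reach ≥90% training
  accuracy in ≥8 of 10 seeds.
* **Cross-validation** — stratified k ∈ {2, 3, 5} folds by seeded
  within-class shuffle and round-robin assignment; per-fold and mean
  metric panels.

## Known limitations

* The search cost of derivative-free training grows quickly with
  parameter count; the architecture cap is a hard error, not a
  soft warning.
* The chaos streams are deterministic in `p0` only; two configs
  differing in any chaos parameter produce unrelated streams.
* The random-search baseline is intentionally weak (it is the ablation
  control), and near-ceiling comparisons between OOA and MOP on easy
  data are not informative — use the margin-loss comparison, which does
  not saturate.
* Geometric augmentations are bilinear and clip to [0, 1]; repeated
  composition accumulates interpolation blur.
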