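# Methods

## The fractional update rule

The optimizer generalizes SGD by substituting a Caputo fractional
derivative of order α for the ordinary gradient. The Caputo derivative of
g on [a, x] with n−1 < α < n is an integral of g's n-th derivative
against the power-law kernel (x−τ)^(n−α−1) / Γ(n−α). Expanding g in a
Taylor series at x and integrating termwise turns it into the series

    D^α g(x) = Σ_{j=n..∞} C(α−n, j−n) · g^(j)(x) / Γ(j−α+1) · (x−a)^(j−α).

Two truncations make this a practical optimizer. First, the *short memory
principle* replaces the lower bound a with the previous iterate x_{e−1}
(fixed memory length 1), so only the most recent parameter change enters.
Second, near a stationary point g′ dominates, so the series is cut at its
leading j = 1 term. With an absolute value on the iterate difference (to
keep the power real, which extends the admissible order from (0,1) to
(0,2)) and a stabilizer ε for the x_e = x_{e−1} case, the per-coordinate
update is

    x_{e+1} = x_e − ρ · g′(x_e) · s_e,
    s_e = (|x_e − x_{e−1}| + ε)^(1−α) / Γ(2−α).

We use the descent sign throughout: the α = 1 limit must reduce to
x − ρ g′, and it does exactly — the exponent is the floating-point
constant 0.0 and Γ(1) = 1, so s_e ≡ 1 bitwise and the training loop
reproduces an independent plain-SGD implementation bit for bit (this is a
test).

Properties worth knowing:

- **Scale behavior in α.** For |Δx| < 1, d/dα log s = −log(|Δx|+ε) +
  ψ(2−α). The scale therefore *rises* with α while ψ(2−α) > log(|Δx|+ε)
  and falls beyond that point: the smaller the recent step, the later the
  turnover (|Δx| = 0.01 peaks near α ≈ 1.8; |Δx| = 0.9 already near
  α ≈ 0.57). In the regime that matters during training — step sizes of
  1e-2 and below — larger α means larger effective steps across the whole
  recommended range.
- **Behavior near an optimum.** For α > 1 the amplification
  (|Δx|+ε)^(1−α) grows without bound as steps shrink, so the iterate does
  not converge to machine zero: on a 1-D quadratic it descends
  monotonically into a neighborhood of the minimizer (about 1e-5 wide at
  ρ = 0.01) and then oscillates in a bounded limit cycle there. For
  α ≤ 1 the descent is monotone throughout. The tests assert exactly
  this.
- **First step.** x_{e−1} is undefined at step 0. The default
  (`first_step_mode="plain_sgd"`) uses scale 1 on the first update;
  the alternative `epsilon_power` initializes x_{e−1} = x_0, giving a
  first-step scale ε^(1−α)/Γ(2−α) ≈ 5.6e3 at α = 1.5 — retained for
  fidelity experiments, not recommended.
- **Granularity.** The derivation indexes by epoch; we apply the rule per
  mini-batch update (the natural reading of "modify the SGD update
  step"), and the memory is never reset between epochs.
- **Vector parameters.** The derivation is scalar; for arrays the scale
  is computed per coordinate. Γ(2−α) is evaluated once per
  configuration. An optional elementwise step clip (`clip_step`, off by
  default) guards the α > 1 amplification for ill-conditioned problems.

The package also carries the analytic machinery used to validate the
truncation: the closed-form Caputo derivative of monomials,
Γ(p+1)/Γ(p+1−α)·x^(p−α) on [0, x], and the truncated series itself. For
integer exponents the series terminates at j = p, so it must agree with
the closed form exactly and with direct quadrature of the defining
integral for nonzero lower bounds; both agreements are asserted to 1e-6
relative in the tests.

## Layers and their contracts

All tensors are NHWC. Convolution is cross-correlation (no kernel flip)
with valid padding and stride 1 — the only convention under which the
architecture's printed shape chain works out. The spatial attention gate
computes A = σ(W∗X + b) with a (1,1,C,1) kernel, giving a per-pixel
weight in (0,1) broadcast over channels; its backward pass carries both
the gated upstream term and the sigmoid path through the 1×1 kernel.
Mixed pooling concatenates [average, max] halves over non-overlapping
windows (channel count doubles, spatial dims floor-halved; trailing rows
or columns that do not fill a window are dropped, e.g. 61 → 30). The max
half routes gradients to the first row-major argmax in each window, a
deterministic tie-break. Weights are Glorot-uniform with a seeded
generator; biases start at zero; hidden dense layers use ReLU and the
head is softmax with categorical cross-entropy (the standard choice for
probability-based classification). The attention gate is applied to the
post-ReLU convolution output. Every backward pass is validated against
central finite differences (h = 1e-5, 1e-4 relative) over repeated seeds.

The convolution and pooling inner loops are numba-compiled (an im2col
gather feeding a BLAS matrix product, and fused pooling scans); this is
an implementation detail that leaves every numerical contract unchanged.

## Architecture accounting

Parameters: (k_s·C_i + 1)·C_o per convolution (k_s = kernel area),
(N_i + 1)·N_o per dense layer, C + 1 per attention gate (a (1,1,C,1)
kernel plus one bias); pooling, flatten and activations contribute
nothing. Model size is parameters × 4 bytes (float32) reported in MB to
two decimals. FLOPs: 2·H_o·W_o·C_o·(k_s·C_i) per convolution (the
attention gate counts as a 1×1 convolution with one output channel) and
2·N_i·N_o per dense layer. These formulas reproduce the full-size
network's table exactly: 5600 / 201 / 360100 / 101 / 18000100 / 5050 /
153 parameters per parametric layer, a 180000-wide flatten, 18,371,305
total, 70.08 MB. The summed FLOPs come to 2.89e9, dominated by the second
convolution (2.68e9): a headline figure of 1.84e8 sometimes quoted for
this architecture is not derivable from these formulas applied to this
layer table, and we make no attempt to match it.

## The synthetic task

The generator emulates axial brain slices at cartoon level: a bright
annulus ("cortical ribbon") over a mid-gray interior ("parenchyma") with
a dark central cavity ("ventricle") on a dark background. The three
classes differ in ribbon thickness and cavity size — AD-like: thin ribbon
(10% of the outer radius) and large cavity (45%); CI-like: 18% / 30%;
CN-like: 28% / 15% — mirroring, loosely, cortical atrophy and ventricular
enlargement. Each sample jitters the center and outer radius (Gaussian,
sd 2 px) and adds Gaussian texture noise (sd 0.05 on the [0,1] scale),
then clips to [0,1]. Defaults are 300 images per class at 64×64×1. With
noise and jitter at zero, within-class images are bit-identical. These
choices make the task easy but *localized*: the class information lives
in a specific annular/central region, which is what gives the attention
gate and the explainer something to find. A linear probe on 4×4 block
means exceeds 80% accuracy (tested), so the task is learnable but not
trivial at pixel level.

What passing tests on this generator do **not** show: anything about real
MRI — no scanner noise statistics, no anatomy beyond the two-ring
cartoon, no registration error, no class overlap. Results on the
synthetic task demonstrate that the optimizer, architecture and explainer
behave as designed, not that the pipeline reaches any particular accuracy
on clinical data.

Preprocessing mirrors a standard imaging pipeline: random
horizontal/vertical/both flips (uniform over the three, labels and pixel
histograms preserved), class balancing by flip-augmented oversampling
(and subsampling without replacement above target), [0,1] normalization
with an 8-bit heuristic (divide by 255 iff max > 1.5 — overridable by
normalizing upstream), and stratified splitting: per class,
round(0.15·n) samples to test (round half up, computed per class before
pooling), then round(0.15·remainder) to validation.

## Training protocol

Mini-batch training with seeded shuffling; defaults are 35 epochs,
learning rate 0.001, batch size 32, α = 1.5 — the recommended setting.
Per-epoch train and validation loss/accuracy are recorded; identical
configuration and seed give identical histories. A run whose loss or
parameters become non-finite aborts with the epoch and batch named and
the partial history attached (`TrainingDiverged`) — at α > 1 the step
amplification makes occasional blow-ups a real possibility, which is
also why an optional step clip exists. The order sweep trains one run
per α from identical initialization and data order and tabulates
final/best validation accuracy and loss; a diverged run is recorded
conservatively as final accuracy 0.0 with infinite loss and a
`diverged` flag, so instability counts fully against the order that
produced it.

Desk-scale experiments (the sweep and explanation tests) use a
width-reduced configuration of the same architecture — conv filters
(4, 4), dense units (16, 8), 64×64×1 input — chosen so a 5-seed ×
5-order sweep of 35-epoch runs completes in minutes on one core while
preserving every structural element (both attention gates, both mixed
pools, three dense layers, the same optimizer and schedule). On this
task, orders 1.3–1.5 reach ~1.0 validation accuracy within 35 epochs
while 0.8–0.9 remain near chance at the same learning rate, reproducing
the qualitative ordering that motivates the optimizer: at lr 0.001 the
low-order scale factor (< 1 for sub-unit steps) slows an already slow
schedule, while super-unit orders adaptively amplify small steps.

## The explainer

Standard perturbation-based local explanation. The instance is
partitioned into a deterministic g×g block grid (default g = 8; edge
blocks absorb remainder pixels; an SLIC-style refinement could be
substituted, but the grid keeps tests reproducible). Perturbed samples
switch segments off with independent Bernoulli(0.5) masks (the first row
is all-ones, reconstructing the instance); masked segments take the
image's mean color. The model's probability for the explained class
(default: its prediction on the instance) is regressed on the binary
masks with ridge regression, samples weighted by exp(−d²/0.25²) with d
the cosine distance to the all-ones mask; the all-zeros mask gets
distance 1 by convention. Weights are normalized to sum to one and the
ridge penalty is a small constant (0.01), which makes the fit invariant
to duplicating samples. Fidelity is the weighted R² (clamped at 0, and 0
by convention when the model is constant over the perturbation set). The
explanation is the top-k positive-coefficient segments (k = 5) and their
union as a highlight mask.

For recovery tests, the "class-discriminative region" is defined from
the generator: pixels where the class-conditional mean images
(noise-free, jitter included) differ by more than 0.02 — two percent of
the intensity range — across classes. At 64×64 the segmentation grid is
4 (16×16-px blocks, the same block size the default g = 8 yields at
128×128).

## Evaluation

Confusion-matrix metrics, one-vs-rest per class: for class c, TP is the
diagonal entry, FP the column remainder, FN the row remainder; precision
TP/(TP+FP), recall TP/(TP+FN), F1 their harmonic mean, accuracy
trace/total; macro rows are unweighted class means. Zero denominators
yield 0 with an explicit flag rather than NaN. Note the harmonic mean
lies between min(P, R) and max(P, R) — it can exceed the smaller of the
two — and the tests assert that envelope. Reports are emitted as one row
per class plus a macro row, with accuracy attached.

## Numerical choices and degenerate inputs

- float32 for training (speed), float64 available throughout; gradient
  checks run in float64.
- Softmax is computed with max-subtraction; cross-entropy guards log(0).
- Non-finite parameters after an update raise with the offending
  coordinate named; non-finite loss aborts training with epoch/batch.
- Checkpoints are HDF5, one group per layer with `weights`/`bias`
  datasets and a `kind` attribute, plus enough architecture metadata to
  rebuild the network.
- Stratified splitting refuses classes too small to hold out at least
  one sample per part.

## Known limitations

- Valid padding, stride 1, 2-D only; no batch norm, momentum, or
  learning-rate schedules; the optimizer is the plain fractional rule
  (no fractional Adam variant).
- The Caputo oracles cover monomials with the lower bounds the series
  supports; they exist to validate the optimizer's truncation, not as a
  general fractional-calculus library.
- The full-size (200/100-filter) network trains, but at NumPy speeds it
  is only practical for small inputs or few steps; the width-reduced
  configuration is the intended vehicle for experiments.
- LIME fidelity on a saturated classifier (probabilities pinned at 1) is
  intrinsically low — with little local variance to explain, coefficient
  rankings on such instances are noisy.
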