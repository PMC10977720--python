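# Methods

## The phenomenon under study

Convolutional networks trained to recognize visual objects develop individual
filters ("neurons" — one convolutional channel, its feature map averaged over
space) that respond selectively to the affective category of an input image
(pleasant, neutral or unpleasant, defined by thresholding a continuous 1–9
valence rating).  This package implements the full measurement chain for that
phenomenon:

1. per-neuron **tuning values** and **d′-based selectivity indices** computed
   from spatially averaged responses to an affective picture set,
2. **selection** of genuine emotion-selective neurons by SI-percentile
   thresholding within each of two independent picture sets and intersecting
   the per-emotion selections across sets,
3. functional validation by **gain enhancement** and **lesion** of the
   selected neurons, read out through a frozen-backbone two-unit emotion
   classifier, against matched random-neuron controls.

Because the canonical affective picture sets are access-restricted and no
pre-trained weights are shipped, every experiment here runs on synthetic
stimuli with planted, fully known ground truth (below).  The point of the
synthetic experiments is to validate the measurement chain — that it recovers
planted selectivity, that it finds nothing when nothing is planted, and that
its manipulations isolate the targeted neurons — not to reproduce the
original datasets' absolute numbers.

## Model and definitions

Every convolutional filter k in layer l computes

    x_lk = (1 + α_lk) · max(0, w_lk ∗ x_{l−1})

α = 0 is the ordinary ReLU, α = −1 silences the filter (lesion), α > 0
raises its gain (a model of feature-based attention).  The neuron's response
to an image is the spatial mean p̄ of this map.  Over a dataset of N images
with grand-mean response p̂, the tuning value for category e (N_e images) is

    S_e = (1/N_e) Σ_{n∈e} (p̄(n) − p̂) / √((1/N) Σ_n (p̄(n) − p̂)²)

and the one-vs-rest discriminability is

    d′(e) = (m_e − (m_o1 + m_o2)/2) / √((v_e + (v_o1 + v_o2)/2)/2)

with category means m and variances v.  SI = max_e d′(e); the argmax is the
neuron's selective emotion.

Two conventions in d′ are not decidable from its printed form and are
config-exposed: the denominator grouping (default pools the two non-target
variances first, mirroring the numerator; `denominator="flat"` gives
√((v_e+v_o1+v_o2)/2)) and the variance normalization (default population,
`variance="sample"` for N−1).  Degenerate (zero-variance, typically dead)
neurons get SI = 0, are flagged, and are never retained by selection.
Argmax ties are broken by the fixed order pleasant < neutral < unpleasant.

Selection retains the top floor(keep_fraction · K) neurons of a layer by SI
(default keep_fraction 0.8), partitions them by selective emotion, and
intersects per-emotion sets across the two datasets.  The chance-level
overlap of two uniform random subsets of sizes n1, n2 from K neurons is the
hypergeometric mean n1·n2/K (a seeded Monte-Carlo estimator is available and
agrees to within sampling error).

The readout replaces the backbone's final classification layer with a
two-unit head (one emotion vs the rest), trained with softmax cross-entropy
on frozen features; freezing is verified by hashing all non-head weights.
Performance is the positive-class F1 (macro-F1 behind a switch).  Inverse
prevalence class weights are the default: at desk scale the negative class
is twice the positive class and an unweighted head can collapse to the
majority when features are weak.  The recovery-fixture experiments override
this to plain cross-entropy (the protocol's stated objective): with class
weighting, the head's default on signal-absent images is decided by
per-image noise — effectively a per-seed coin flip that randomizes lesion
outcomes — whereas under the natural 2:1 prior, images in which no category
statistic is visible deterministically fall to the non-target class, so
lesioning a category's detectors collapses recall for exactly that
category.  The null calibration keeps the weighted loss, which holds the
baseline F1 away from zero so percent changes remain defined.  Manipulations are applied at evaluation time only; the
enhancement protocol sweeps α over 0..5 in steps of 0.1, picks the α
maximizing validation F1, and reports test F1 at that α.  Matched random
controls draw equal-size neuron sets from the manipulated layer excluding
the targeted set and run through the identical protocol function;
selective-vs-control significance is the one-sided empirical permutation
p-value (1 + #extreme)/(R + 1), R = 20 controls by default.

## Backbones

Two architectures are built in.  The `vgg16-layout` has the standard 13
convolutional layers (64…512 filters, 3×3 kernels, five pooling stages,
224×224 input); grayscale images are replicated to three channels and
normalized with fixed constants, since single-channel handling for 3-channel
networks is a convention the measurement does not depend on.  Weights are
random (seeded) or loaded from an npz container with a layout manifest.  The
desk-scale `mini-cnn` (default 20/24/28 filters, kernels 5/3/3, 2×2 pooling
after each layer, 32×32 single-channel input, a 64-unit penultimate layer)
is the workhorse for all synthetic experiments; its forward pass, the
gain-parameterized rectifier and full backpropagation are implemented in
numpy (float32, stride-1 same convolutions via im2col).  Layer indexing is
1-based over convolutional layers; responses are measured on the rectified,
gain-scaled maps before pooling.

## Synthetic ground truth

Each emotion category is linked to one low-level statistic: a mean-luminance
gradient across columns (pleasant), a dominant high spatial frequency
(checkerboard; neutral), and horizontal orientation energy (period-4
horizontal grating; unpleasant).  The three patterns are unit-RMS and
mutually orthogonal, and each is orthogonal to the matched detection kernels
of the other two categories, so cross-talk between planted detectors is
zero by construction.  An image is

    noise_level · white_noise + effect_size · a · pattern_category

with a per-image amplitude a ~ Gamma(shape=1) (exponential, mean 1).  The
heavy-tailed amplitude matters: every category contains weak exemplars, so
the absence of the other categories' statistics is not reliable evidence for
the positive class, and the readout must use the positive category's own
detectors.  With near-constant amplitudes a one-vs-rest readout can classify
by complement evidence alone, and lesioning the positive detectors is then
inconsequential — an artifact of over-clean synthetic data, not a property
of the measurement chain.  Valence ratings are drawn from truncated normals
centered at 3 / 5 / 7 (unpleasant / neutral / pleasant) within the bands
implied by the 4.3 and 6.0 thresholds; a soft-threshold half-width can mark
near-boundary ratings "unknown".

A planted backbone replaces designated layer-1 kernels with the matched
detector scaled to norm `strength` (2 by default); strength 0 plants
nothing, so a null-planted backbone is exactly the random build.  The
remaining (non-planted) layer-1 kernels are projected onto the orthogonal
complement of the pattern subspace — the DC direction, the three matched
detectors, and the quadrature phase of the periodic grating.  This step is
what makes the ground truth exact: a purely random kernel has chance
overlap with the category patterns (in particular, any kernel with net
luminance gain responds to the mean-luminance gradient), making it weakly
but genuinely selective; with the projection, non-planted neurons carry no
category signal by construction, so the planted sets are the complete truth
and lesioning them removes the only detectors of their category.  Planting
is verified empirically at build time on a probe set.  The recovery fixture
plants 5 neurons per emotion among 20 layer-1 filters: the 80% SI cut
retains 16 neurons, so recovered sets contain the 15 planted neurons plus
at most one free filter (precision ≥ 15/16; the cross-dataset intersection
usually removes that free filter too).

What the synthetic data deliberately does *not* emulate: the category signal
is low-level by construction (the original argument explicitly controls for
low-level features via an independent feature-extraction analysis, which is
out of scope here); there is no semantic content, no object/emotion
interaction, and dataset A and B differ only by sampling seed rather than by
curation style.  Passing tests therefore show that the measurement chain is
correct and calibrated, not that emotion selectivity in networks trained on
natural images is or is not low-level.

## Study conditions and problem sizes

Fixed desk-scale conditions, chosen once: recovery fixture at effect size 3,
noise 1, 150 images per category and per dataset, keep_fraction 0.8, R = 20
lesion controls, full 51-point α sweep; the shipped test fixture is one
fixed seeded configuration of these conditions.  Null calibration: effect size 0,
10 seeds, R = 5 controls per mode with a coarse α grid (step 0.5).
Emergence contrast: 5 seeds; object task with 4 classes × 150 images built
from the same statistic families plus a blob class; 10 epochs of momentum
SGD (lr 3e-3, gradient-norm clip 5 — a first pilot at lr 1e-2 collapsed on
some seeds); affective pairs at effect size 0.8 with 90 images per category,
an operating point chosen inside the assay's dynamic range (at effect 1.5 a
random-weight network's overlap count already sits at the retention ceiling
of floor(0.8·28) = 22, leaving the trained-vs-random contrast nothing to
move).

Readout training in the desk-scale experiments uses lr 0.3, 40 epochs,
batch 32 on standardized features.  `TrainConfig` defaults remain the
full-scale protocol (lr 1e-3, 10 epochs, batch 128, 50/25/25 stratified
split); those values target a 4096-dimensional feature space and underfit a
64-dimensional head on a few hundred images.

## Null calibration: what "centered at zero" means

Two protocol artifacts make *raw* percent changes non-zero-centered under
the null.  First, SI selection uses a whole dataset, so top-SI neurons carry
spurious label correlation into every split of that dataset; selecting
targets on dataset A and evaluating the readout on dataset B removes the
leak.  Second, choosing the best α on a validation split inflates F1
whenever features are uninformative, because from a low baseline F1 rises
mechanically with the positive-prediction rate; this bias is shared by the
matched random controls.  The null-calibration quantity is therefore the
cross-dataset, control-matched manipulation effect — the selective set's
percent change minus the mean control percent change — which is the
selectivity effect the manipulation experiments actually measure.  Raw
changes are reported alongside for transparency.

## Numerical choices

Float32 forward passes, float64 statistics.  Top-image ranking breaks
response ties by ascending image id; SI-threshold ties by (SI desc, layer
asc, filter asc); best-α ties by the smallest α.  F1 with an empty
denominator is 0.  Division-free degenerate cases (zero response variance)
are flagged rather than propagated as NaN.  All randomness flows through
`numpy.random.default_rng` seeds; experiment seeds are derived from one
master seed via `SeedSequence` and kept below 2³¹.

## Known limitations

The desk-scale engine is CPU-bound numpy: the vgg16 layout is buildable and
correct but impractical for full-dataset response extraction, and no
pre-trained object-recognition weights are bundled, so absolute F1 values
and per-layer neuron counts of the original full-scale setting are out of
reach (by design; see Non-goals in the module docstrings).  Enhancement
rarely improves an already converged desk-scale readout — the sweep's
validation anchor at α = 0 guarantees it never hurts — whereas lesion
effects are large and specific; at full scale the published protocol found
both.  The emergence contrast is directional, not calibrated: it shows
object training does not reduce (and typically increases) cross-dataset
consistent selectivity at toy scale.
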