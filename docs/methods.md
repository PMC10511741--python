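# Methods

## The problem and the models

Rheumatoid arthritis inflames the synovium of the small hand joints and
raises the overlying skin temperature by a degree or more; thermography
therefore sees the affected MCP/PIP/DIP joints as hot spots on a
false-colour image.  The package treats RA detection as binary image
classification of such thermograms and implements three routes: a compact
custom CNN (RANet), a quanvolutional network (QNN), and a hybrid pipeline
that validates the CNN's learned representation by classical machine
learning on its deep features.

### RANet

Six blocks of conv → batch-norm → 2×2 max-pool with filter counts
8, 16, 32, 64, 128, 256, kernels alternating 1×1 / 3×3 and stride 1
throughout, then global average pooling and dense layers 128/64/32/2 with a
two-way softmax.  Padding is the unique assignment that reproduces the
published feature-size sequence for a 256×256 input
(256 → 126 → 63 → 29 → 14 → 5): 1×1 convolutions preserve spatial size
('same'), 3×3 convolutions are unpadded ('valid'), and max pooling uses
floor semantics on odd sizes (63 → 31, 29 → 14, 5 → 2).  The parameter
account is computed in closed form from the declarative spec
(conv: k²·c_in·c_out + c_out; dense: n_in·n_out + n_out; batch norm: 4 per
channel, of which the 2 moving statistics are non-trainable) and totals
369,042 = 368,034 + 1,008.  A test asserts the live network's weight arrays
match the accountant exactly.

Training follows the published recipe: SGD with learning rate 0.01, batch
size 16, categorical cross-entropy, default 50 epochs, checkpointing on best
validation accuracy (the restored weights must reproduce the recorded
validation accuracy bit-for-bit — this is tested).  Choices the source left
open, fixed here: momentum 0 unless configured; seeded He-uniform weight
initialisation (uniform over ±√(6/fan_in), suited to ReLU); batch-norm
ε = 1e-3 and moving-statistics momentum 0.99 (Keras conventions).

The momentum of the batch-norm moving statistics matters at small scale:
with only a handful of mini-batches per epoch, 0.99-momentum statistics lag
the batch statistics and inference-mode accuracy can sit at chance while
training-mode loss is near zero.  `bn_momentum` is therefore an estimator
parameter; runs with fewer than ~50 batches per epoch should lower it
(0.8–0.9), and the small-fixture tests do.

### Reduced-scale configuration

The full 6-block architecture requires inputs of roughly 256×256 — at 64×64
the 3×3 valid convolutions exhaust the spatial extent.  End-to-end training
runs in this package therefore use a 4-block variant (filters 8–64, same
alternating kernels, same dense head) on 64×64 images; the third dense layer
still yields 32-dimensional features, so the hybrid pipeline is unchanged.
The packaged study conditions are 100 subjects per class, hot-spot effect
size 0.4, noise sd 0.05, with the full split/augment arithmetic, trained for
8 epochs (validation accuracy saturates within 2–3 epochs at these
conditions) over three seeds.

### Quanvolution

Each 2×2 patch (row-major pixel order → qubits 0–3) of each band is encoded
from |0000⟩ by Ry(π·x_q); a seeded random circuit is applied; the four
per-qubit Pauli-Z expectations are the output channels.  Simulation is exact
statevector evolution of the 16 complex amplitudes in little-endian basis
ordering (b = Σ_q bit_q·2^q); no shot noise unless `shots` is set, in which
case per-qubit expectations are replaced by binomial estimates.  The random
circuit family is one Ry per qubit (angles uniform in [0, 2π)) followed by a
CNOT ring per layer — the source specifies only "rotation" gates, so the
family is a documented choice and the gate set (RX/RY/RZ/X/H/CNOT) is
available for custom circuits.  Two readings of "four quantum filters or
channels" are supported: the default shares one circuit and reads all four
⟨Z_q⟩; `independent_kernels` draws four circuits and reads ⟨Z_0⟩ of each.
Inputs are used as rotation fractions of π with no rescaling beyond [0, 1]
pixel normalisation; channel values are guaranteed in [−1, 1]; output
spatial dims are floor(input/2) with odd edges truncated.

The classical head is conv 32 → pool → conv 16 → pool → conv 16 → pool →
conv 8 → pool → dense 128 (ReLU) → dense 1 (sigmoid), Adam lr 0.001, binary
cross-entropy, batch 64, 30 epochs.  The head uses 'same' padding so it
propagates at the reduced feature-map sizes used for testing (with valid
padding it only fits 128×128 inputs); this is a package choice, as the
source does not state padding.

### Hybrid deep-feature pipeline

FC_3 activations (post-ReLU, n×32) from the augmented training pool plus the
test images are split 70–30 at subject level; a 100-tree Gini random forest
fit on the training fold yields normalised mean-decrease-in-impurity
importances with across-tree standard deviations; the top k = 12 features
(the published elbow; configurable, ties broken by lower index) are
selected; SVM (C = 1, RBF with gamma = 1/(d·var)), k-NN (k = 5, Euclidean,
uniform weights) and gradient boosting (100 estimators, learning rate 1,
depth 1) are trained on standardised features (training-fold statistics)
with and without selection.  Importances and scaler statistics never see the
evaluation fold; a test verifies selection is invariant to shuffling the
evaluation-fold labels with the split held fixed.

The forest considers all features at every split (`max_features=None`)
rather than a random subset: for importance estimation, candidate
subsampling systematically dilutes the importance of a strongly informative
feature by letting weaker features win splits in its absence, and here the
forest's job is ranking, not generalisation.

### Evaluation

The positive class is RA throughout.  Per-class precision/recall/F1 are
combined into support-weighted averages; accuracy is algebraically the
support-weighted recall (property-tested).  ROC curves come from thresholding
decision scores; AUC is the trapezoidal integral, equal to the normalised
Mann–Whitney statistic with ties counted one half (verified on 200 random
score vectors to 1e-12).  Zero-denominator statistics are reported as 0 with
a `zero_division` flag.  Rendered tables round half-up to two decimals;
reports keep full precision.  One caution for anyone comparing against the
published confusion matrices: the printed rows for the three pre-trained
baselines are oriented with the opposite positive class to the custom-model
row; the package's tests use the orientation consistent with each row's
metric values.

## The synthetic generator

The generator emulates the statistical structure the classifiers rely on,
not hand anatomy.  A scalar "temperature" field in [0, 1] (unitless; no
radiometric calibration) is built from: a vertical background gradient
(0.12–0.30), a hand silhouette (palm ellipse + five finger capsules) at
0.48, and +0.10 inside a fixed template of 14 joint disks (MCP/PIP/DIP of
digits 2–5, thumb MCP/IP; radius 0.035 of the image side).  For the RA label
the in-disk intensity is raised by exactly `effect_size` before Gaussian
pixel noise (sd `noise_sd`) and clipping; the field is then mapped through a
fixed piecewise-linear blue→green→yellow→red palette into three bands.
Each subject receives one latent warmth/background jitter (sd 0.015, clipped
at ±0.03) shared by all six of their images and identical for either
hypothetical label — the RA elevation is deliberately not scaled by a random
severity so that the class contrast is exactly the configured effect size,
which the tests exploit.  Hands mirror left/right; views apply small
deterministic translations.  Defaults mirror the emulated acquisition: 50
subjects per class × 2 hands × 3 views = 600 images at 256×256.

What the generator does **not** model: FLIR radiometry and file formats,
anatomically accurate geometry, pose/segmentation variability, camera noise
statistics, or any verified property of real thermograms' intensity
distributions.  Passing tests therefore demonstrate that the pipelines are
correctly wired and can recover a known class-conditional intensity signal;
they say nothing about clinical performance.

## Augmentation and splitting

Elastic deformation draws per-pixel displacements uniform in [−1, 1],
smooths them with a Gaussian of sd σ = 2 px, scales by α = 8 px (α is
unstated in the source; 8 px gives a visible but label-preserving warp), and
resamples bilinearly with edge clamping.  Note the warp conserves total
intensity only in aggregate: the pointwise Jacobian of the smoothed field
fluctuates, so a single pixel's mass can change by tens of percent while a
smooth blob's total is conserved to a few percent (both tested against an
explicit dense resampling-matrix oracle).  Brightness is multiplicative with
factor drawn in [0.9, 1.1] (the ±10% stated for scaling is applied to
brightness as well, since its magnitude is unstated); zoom crops/pads
centrally by a factor in [0.9, 1.1] with bilinear resampling.  Augmentation
replaces originals — each training image yields exactly three outputs, which
is the only reading under which 480 inputs give exactly 1440.

Stratified splits give the smaller side floor(n_total·fraction) records,
apportioned across classes by largest remainder with seeded tie-breaks, so
per-class counts are within one of the exact fraction.  Subject-level
grouping is the default (all six-plus images of a subject land on one side;
image-level splitting of multi-view subjects leaks identity), with
image-level splitting available to reproduce the plain arithmetic; for the
emulated cohort both give 480/120 and 1008/432.

## Numerical choices and degenerate inputs

Gradients of every layer are validated against central finite differences in
float64; training runs in float32.  Max-pool backward routes gradient to the
first maximal element of each window.  Softmax/sigmoid losses fold the
nonlinearity into the loss for stability and clamp logs at 1e-12.  Empty
manifests split to empty manifests; empty training sets raise; k > d in
selection clips with a warning; single-class inputs to importance/ROC raise.
Seeds: every stochastic component (generator, splits, augmentation draws,
weight init, batch shuffling, circuits, shot sampling) takes an explicit
seed, and derived seeds are produced via `SeedSequence` and masked below
2^31.

## Known limitations

The NumPy engine is single-threaded BLAS-bound and intended for the package's
reduced problem sizes, not 256×256×1440-image training.  The quanvolution is
exact simulation — hardware noise is represented only by optional binomial
shot sampling.  The synthetic task at the packaged effect size (0.4) is easy
by design; reported synthetic accuracies near 100% characterise pipeline
correctness, not clinical difficulty.  Checkpoint "best validation accuracy"
breaks ties by the earlier epoch.
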