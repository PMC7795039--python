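# Methods

## The model

`adgnet` implements a weakly supervised multi-task convolutional network for
staging dementia from brain MRI, in 2D (slices) or 3D (volumes) with one
code path parameterized on dimensionality.

**Backbone.** Five downsampling convolution stages in the ResNet family: a
convolutional stem (stage 1) followed by four stages of basic residual
blocks (two 3x3 convolutions with batch norm, plus a projection shortcut
where shape changes), each stage halving every spatial extent.  Widths and
depths are configurable; defaults are (32, 64, 128, 256, 512) channels with
(1, 2, 2, 2, 2) blocks in 2D and (16, 32, 64, 64, 128) in 3D.  The final
stage is collapsed by global average pooling (GAP) into the shared feature
vector `Vf`.

**Channel attention.** After every stage the feature map `F` (shape
`C x H x W`, or `C x D x H x W` in 3D) is re-weighted channel-wise:

    CAF = sigmoid(FC(ReLU(BN(Conv1x1(flatten(maxpool(F)))))))     in (0,1)^C
    F'  = CAF (x) F                                               (element-wise)

The global max-pool reduces each channel to a single cell, so the factors
are invariant to spatial shuffling; the 1x1 convolution (acting on the
flattened `1x1xC` vector, hence a dense map) reduces `C -> C/r` (default
r = 4) and the fully connected layer restores `C`.  The sigmoid makes the
attention a per-channel contraction.  The final FC feeds the sigmoid
directly (no ReLU in between): the module's closed form with all-zero
weights and final bias `b` is then `sigmoid(b)` per channel, which is the
contract the tests pin down.  The batch norm inside the module uses batch
statistics during training and running statistics at evaluation; a
training-mode batch with a reduction count of 1 falls back to running
statistics to avoid a degenerate variance.

**Task heads.** The classification sub-network is a single affine map of
`Vf` followed by an element-wise sigmoid, giving per-class probabilities
`Vp` in (0,1) that are *not* constrained to sum to one (an optional softmax
sits behind `use_softmax`; the sigmoid form is the default as specified).
The predicted label is the argmax of `Vp`, ties toward the lowest index.
The reconstruction sub-network encodes `Vf` through two FC layers (ReLU
between them) into `Ve`, reshapes it to a small seed map, applies `M`
transposed convolutions (kernel 3, stride 2, one cell of output-side
padding, ReLU) that each exactly double every spatial extent, then a final
kernel-3 convolution restores the image channel count and a tanh bounds the
output to (-1, 1).  The plain stride-2/kernel-3/padding-1 transposed
convolution yields 2n-1; the symmetric output-padding convention is what
makes the decoder land exactly on the input size, and it is implemented as
the exact adjoint of the corresponding strided convolution.

**Objective.**

    L = lambda1 * Lcls + lambda2 * Lrec,    lambda1 = lambda2 = 1 by default

    Lcls = -(1/N) sum[ (1-i)^gamma log(1-i') + i^gamma log(i') ]
    Lrec = +(1/N) sum (Y - Yhat)^2

`Lcls` averages over all (sample, class) sigmoid terms in the batch with
predictions clamped to `[eps, 1-eps]` (eps = 1e-7); `gamma` (default 2 for
every class) exponentiates the *target* probabilities, so for hard labels
the loss is exactly binary cross-entropy.  Because that literal form only
departs from cross-entropy for soft targets, a conventional focal variant —
modulating the *predicted* probability, `(1-i')^gamma` on the positive term
— is available via `FocalParams(variant="focal")`; the literal form is the
default.  The reconstruction term is the mean squared error per pixel/voxel
(per-term averaging keeps the lambdas scale-free across image sizes).  A
zero lambda removes its term from the computation graph entirely, so the
corresponding head receives exactly zero gradient — the gating tests check
bit-identity of parameters after real optimizer steps.

## Training protocol

Weak supervision is simulated by stratified label retention: per class,
`round(fraction * n_c)` labels (at least one) stay visible, the rest are
masked.  Every optimization step minimizes `lambda1 * Lcls` over the
labeled items in the batch plus `lambda2 * Lrec` over all items, so
unlabeled images contribute only through reconstruction; masked items can
be excluded entirely with `use_unlabeled=False`.  Cross-validation uses
stratified k-fold splits (scikit-learn) on the ground-truth labels.  The
optimizer is Adam (lr 1e-3, batch 16 by default); model selection keeps the
parameters of the epoch with the best validation macro-F1, computed over
the *labeled* validation items only (with a small label fraction the
validation fold is mostly unlabeled and cannot be scored).  One integer
seed drives label subsetting, fold assignment, weight initialization and
batch order, which makes the full experiment report reproducible
byte-for-byte (timestamps aside).

## Numerical substrate

No deep-learning framework is used: `adgnet.nn` is a small reverse-mode
autodiff library over float64 numpy arrays with exactly the primitives the
model needs (dense maps, N-dimensional strided convolutions via cached
gather/scatter index plans, transposed convolutions as exact adjoints,
batch norm composed from differentiable primitives, global max/mean
pooling, the pointwise nonlinearities, Adam).  Double precision keeps
finite-difference gradient checks sharp (the end-to-end autodiff gradient
matches central differences to well under 1e-3 relative error).  Adam
leaves a parameter with an exactly-zero (or absent) gradient bit-identical,
which is what makes the lambda-gating contracts exact rather than
approximate.

## Synthetic phantoms

The phantom generator stands in for class-graded dementia MRI: an outer
elliptical "brain" of elevated intensity on a dark background with a
central low-intensity "ventricle" whose area (2D) or volume (3D) scales as
`1 + class_index * severity_effect` — a purely morphological, severity-graded
signal mirroring ventricular enlargement, not an intensity shortcut.
Position and eccentricity are jittered per instance (volume-preserving),
Gaussian noise (sd `noise_sd`) is added, and intensities live directly in
[-1, 1] to match the tanh reconstruction range.  `severity_effect = 0` is
the null construction: labels carry no signal, anchoring a ~0.5 macro-F1
floor.  What the phantoms do *not* emulate: anatomy, MRI physics (bias
fields, k-space artifacts), inter-scanner variation, or class imbalance —
so passing benchmarks show the pipeline's mechanics and the direction of
the ablation effects, not clinical performance.

Calibration under the default conditions (severity 0.6, noise 0.2, n = 500,
two classes): a fully supervised run reaches test macro-F1 above 0.9, and
no configuration beats ~0.6 on the null construction.

## Benchmark problem sizes

The ablation benchmark (`adgnet.experiment.phantom_benchmark`) trains the
full model and its no-reconstruction / no-attention ablations on 500
two-class 32x32 phantoms at a 20% label fraction, ten training seeds per
arm, with reduced widths (8, 16, 16, 32, 32), one stratified validation
fold for model selection, and 15 epochs — sizes chosen so the whole
benchmark runs on a single desktop CPU core in minutes, and at which the
supervised-learnability and null-floor calibrations above verifiably hold.
The comparison is directional (mean test macro-F1 ordering), which is the
part of the full-scale result that survives scaling down; absolute values
at this scale sit far below the reference-scale figures and are expected
to.  Ten seeds rather than the minimal five because the attention effect
is small even at full scale (half an F1 point) and per-seed test macro-F1
varies by several points at desk scale.

## Design choices where the design was open

- Stage 1 is a plain convolutional stem; stages 2-5 are residual.  All five
  stage outputs pass through attention.
- Attention bottleneck `C -> C/r -> C` with r = 4.
- Decoder seed map defaults: `base_channels = 8 * out_channels`, halving
  channel schedule floored at 4 channels.
- Undefined metrics (zero denominators) are reported as 0 with a per-metric
  `defined` flag, and excluded from macro averages and bootstrap samples
  (with the exclusion count reported) rather than raised.
- Multi-class problems are scored one-vs-rest per class and macro-averaged;
  a binarized mapping can be built by relabeling before scoring.
- The bootstrap resamples (truth, prediction) pairs (percentile method,
  B = 1000 default); the model is never retrained inside the bootstrap.
- NIfTI volumes already inside [-1, 1] are treated as pre-normalized and
  loaded untouched (making write/read round trips exact); raw-range volumes
  get a robust 1st-99th percentile rescale.

## Known limitations

- The sigmoid multi-class head can assign high probability to several
  classes at once; argmax still yields one label, but probabilities are not
  a distribution (use the softmax flag if that matters).
- Extreme class imbalance is out of scope beyond the per-class gamma
  weights.
- Training is single-threaded CPU numpy; the implementation targets
  correctness and reproducibility at desk scale, not GPU-scale throughput.
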