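# adgnet

Weakly supervised multi-task CNN for dementia-stage classification from
brain MRI, with a six-metric bootstrap evaluation suite and a synthetic
phantom benchmark.

## The problem

Staging dementia from MRI is a multi-class image classification problem in
which high-quality labels are scarce: annotating scans is slow and
expensive, while unlabeled scans are plentiful.  `adgnet` addresses this
with a multi-task network that learns from both: a shared convolutional
backbone feeds (i) a classification head trained on the labeled fraction
and (ii) an image-reconstruction head trained on *every* image.  The
reconstruction task forces the shared features to describe the whole image,
so the unlabeled majority still shapes the representation the classifier
uses.

## The model

- **Backbone** — five downsampling convolution stages with basic residual
  blocks, 2D or 3D, ending in global average pooling that yields the shared
  feature vector V_f.
- **Channel attention** — after every stage, an attention module computes
  per-channel factors CAF = σ(FC(ReLU(BN(Conv₁ₓ₁(flatten(maxpool(F))))))) ∈
  (0,1)^C and rescales the stage output channel-wise, F′ = CAF ⊗ F.
- **Classification head** — V_p = σ(FC(V_f)): independent per-class sigmoid
  probabilities; the label is argmax V_p.
- **Reconstruction head** — V_e = FC₂(ReLU(FC₁(V_f))) reshaped to a seed
  map, then M exact-doubling transposed convolutions and a tanh produce a
  reconstruction the size of the input.
- **Objective** — L = λ₁·L_cls + λ₂·L_rec, where L_cls is a class-weighted
  cross-entropy, L_cls = −(1/N) Σ[(1−i)^γ log(1−i′) + i^γ log(i′)] (γ = 2
  per class by default; exactly binary cross-entropy for hard labels), and
  L_rec is the per-pixel mean squared error.  Unlabeled items contribute
  only to L_rec.

Evaluation reports Cohen's kappa, sensitivity, specificity, precision,
accuracy and F1 (one-vs-rest, macro-averaged for multi-class) with
percentile-bootstrap confidence intervals.

Everything runs on plain numpy: the package carries its own small
reverse-mode autodiff library (`adgnet.nn`) with N-dimensional
convolutions, so no deep-learning framework is required.

## Worked example

Train on synthetic phantoms — noisy brain-like images whose inner
"ventricle" region grows with disease grade — using only 20% of the labels:

```python
import numpy as np
from adgnet.experiment import (
    BENCHMARK_PHANTOM, benchmark_arm,
)
from adgnet.phantoms import generate_dataset

split = generate_dataset(BENCHMARK_PHANTOM)   # 500 phantoms, 400/100 split
f1_full   = benchmark_arm(split, seed=0)                      # full model
f1_no_rsn = benchmark_arm(split, seed=0, use_rsn=False)       # no reconstruction
print(f"macro-F1 with reconstruction head: {f1_full:.3f}")
print(f"macro-F1 without:                  {f1_no_rsn:.3f}")
```

```
macro-F1 with reconstruction head: 0.640
macro-F1 without:                  0.585
```

Each call trains the network from scratch at a 20% label fraction and
scores it on the held-out 100 phantoms; the gap is the value of training
the reconstruction head on the 80% of images whose labels were masked.
(Exact numbers vary a few points with the training seed.)

The same protocol is scriptable from the shell:

```sh
adgnet simulate --config cfg.yaml           # write phantoms as PNG folders / NIfTI
adgnet train    --config cfg.yaml --label-fraction 0.2 --seed 1 --out run/
adgnet eval     --checkpoint run/checkpoint.npz --data phantoms/ts --bootstrap 1000
```

`adgnet train` emits `report.json` (per-fold and test metrics with 95%
bootstrap CIs), `checkpoint.npz` (parameters + config) and per-fold
JSON-lines training histories.

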