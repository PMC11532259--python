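# frcnn — fractional-order gradient descent for an explainable attention CNN

`frcnn` implements a generalized fractional stochastic gradient descent
optimizer (GFSGD) together with the convolutional architecture it was
designed to train: a compact CNN with sigmoid spatial-attention gates and
channel-concatenating mixed (average + max) pooling, aimed at 3-class
brain-MRI classification (Alzheimer's disease / cognitive impairment /
cognitively normal). It is written for researchers who want a transparent,
NumPy-level reference implementation of the fractional update rule, the
architecture's complexity accounting, and LIME-style local explanations —
with a synthetic MRI-like data generator so everything is testable without
any imaging download.

## The optimizer

GFSGD replaces the gradient in SGD with a Caputo fractional derivative of
order α, truncated by the short-memory principle to the single previous
iterate and to the leading term of its Taylor expansion. Per coordinate:

    x_{e+1} = x_e − ρ · g′(x_e) · (|x_e − x_{e−1}| + ε)^(1−α) / Γ(2−α)

with step size ρ, stabilizer ε = 1e-8, and fractional order 0 < α < 2
(the absolute value of the iterate difference keeps the power real, which
is what extends the admissible range beyond (0, 1)). At α = 1 the scale
factor is identically 1 and the update is *exactly* plain SGD — the
training loop reproduces an independent SGD implementation bit for bit.
For α > 1 the factor grows as successive iterates get close, which acts as
an adaptive per-coordinate step amplifier; on the synthetic task, orders
around 1.3–1.5 converge far faster than 0.8–0.9 at the same learning rate.

## The architecture

`build_frcnn()` assembles conv(200, 3×3) → attention → mixed-pool(2×2) →
conv(100, 3×3) → attention → mixed-pool → flatten → dense(100) →
dense(50) → dense(K, softmax), all with valid padding and stride 1. The
attention gate is a 1×1 convolution to a single channel plus sigmoid,
multiplied elementwise into the feature map (C + 1 parameters); mixed
pooling concatenates the average- and max-pooled halves, doubling the
channel count. Parameter counts follow (k_s·C_i + 1)·C_o for convolutions
and (N_i + 1)·N_o for dense layers; FLOPs follow 2·H_o·W_o·C_o·(k_s·C_i)
and 2·N_i·N_o. On a 128×128×3 input with 3 classes:

```
$ frcnn describe-model
     layer    output_shape   params      flops
    conv2d (126, 126, 200)     5600  171460800
      relu (126, 126, 200)        0          0
 attention (126, 126, 200)      201    6350400
mixed_pool   (63, 63, 400)        0          0
    conv2d   (61, 61, 100)   360100 2679120000
      relu   (61, 61, 100)        0          0
 attention   (61, 61, 100)      101     744200
mixed_pool   (30, 30, 200)        0          0
   flatten       (180000,)        0          0
     dense          (100,) 18000100   36000000
      relu          (100,)        0          0
     dense           (50,)     5050      10000
      relu           (50,)        0          0
     dense            (3,)      153        300
Total params: 18371305 (70.08 MB)
Total FLOPs: 2893685700
```

## Worked example

```python
import numpy as np
from frcnn import (FrCNNClassifier, SyntheticSpec, generate, split,
                   confusion, per_class_metrics)
from frcnn.lime import explain

batch = generate(SyntheticSpec(n_per_class=300, seed=0))   # 64x64 MRI-like
parts = split(batch, seed=0)                               # stratified 85/15

clf = FrCNNClassifier(alpha=1.5, learning_rate=0.001, conv_filters=(4, 4),
                      dense_units=(16, 8), epochs=20, random_state=0)
clf.fit(parts.train.values.astype(np.float32), parts.train.labels)
print("final validation accuracy:", round(clf.history_.val_accuracy[-1], 3))

preds = clf.predict(parts.test.values.astype(np.float32))
report = per_class_metrics(confusion(parts.test.labels, preds, 3))
print(report.to_frame(["AD", "CI", "CN"]).round(3).to_string(index=False))
print("test accuracy:", round(report.accuracy, 3))

res = explain(parts.test.values[0],
              lambda b: clf.predict_proba(np.asarray(b, dtype=np.float32)),
              k=5, n_samples=500, seed=0, grid=4)
print("explained class:", res.explained_class,
      "| top segments:", res.top_segments.tolist(),
      "| local fidelity:", round(res.fidelity, 3))
```

prints

```
final validation accuracy: 0.99
class  precision  recall  f1
   AD        1.0     1.0 1.0
   CI        1.0     1.0 1.0
   CN        1.0     1.0 1.0
macro        1.0     1.0 1.0
test accuracy: 1.0
explained class: 0 | top segments: [5, 10, 11, 1, 4] | local fidelity: 0.367
```

The classifier (a width-reduced configuration of the same architecture)
separates the three synthetic classes perfectly at fractional order 1.5;
the explainer's top segments are the central image blocks containing the
ventricular cavity and cortical-ribbon geometry that defines the classes.

The same workflow is available from the shell: `frcnn gen-data`,
`frcnn train --config run.json`, `frcnn evaluate`, `frcnn sweep-alpha`
and `frcnn explain` (see `frcnn --help`).

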