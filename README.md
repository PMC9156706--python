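# octguide

Computer-aided epidural needle guidance on forward-view optical coherence
tomography (OCT).

During epidural anesthesia a needle must stop inside the epidural space — a
1–6 mm gap between the ligamentum flavum and the dura mater — without
puncturing the dura and injuring the spinal cord. A forward-view endoscopic
OCT probe inside the needle bore images the tissue directly ahead of the tip
as depth-resolved B-scans. `octguide` implements the full analysis pipeline
for such imagery:

* **Synthetic B-scan simulation** of the five layers crossed during
  puncture (fat, interspinous ligament, ligamentum flavum, epidural space,
  spinal cord), with per-subject appearance variation, so every downstream
  component is testable without any data download.
* **A sequential cascade of four binary CNN classifiers** — fat vs
  interspinous ligament, ligament vs flavum, flavum vs epidural space,
  epidural space vs spinal cord — tracked by a sliding-window state
  machine: the active classifier's last 50 predictions are counted, the
  displayed fraction follows traffic-light colors (green below 26 class-1
  hits, yellow from 26, red from 35), and 35 deeper-layer hits in the last
  50 frames switch to the next classifier.
* **A needle-tip-to-dura distance regressor**: a CNN with a single
  identity-activation output neuron predicting the gap depth in µm, plus an
  analytic surface-detection estimator used as labeling oracle and
  non-learned baseline.
* **Subject-wise nested cross-validation/testing** (outer loop rotates a
  held-out test subject, inner loop rotates a validation subject for
  architecture selection) with accuracy, MAPE, MAE and ROC/AUC metrics:

  accuracy = (TP + TN) / (TP + TN + FP + FN),
  MAPE(%) = (100/n) Σ |Yᵢ − Xᵢ| / Yᵢ,
  MAE = (1/n) Σ |Yᵢ − Xᵢ|,

  with Yᵢ the ground-truth and Xᵢ the predicted distance.
* **Grad-CAM explanations** exposing which image regions drive each
  classifier.

All networks are trained with SGD with Nesterov momentum (learning rate
0.01, momentum 0.9, decay 0.01, batch size 32), sparse categorical
cross-entropy with early stopping at patience 10 for classification, and a
20-epoch MAPE objective for regression; images are centered by subtracting
the training-set mean pixel value. The CNN stack itself (convolution,
pooling, batch normalization, residual / inception-style / separable
blocks, backprop, the optimizer) is implemented on numpy inside the
package.

## Worked example

```python
import numpy as np
from octguide import (simulate_subject, simulate_insertion_sequence,
                      stage_frames, stage_binary_labels, TrainingConfig,
                      train_classifier, predict_proba, run_stream)
from octguide import models, cascade

# 4 synthetic subjects, 60 frames per tissue layer each
subjects = {s: simulate_subject(s, frames_per_layer=60, seed=100 + s)
            for s in range(1, 5)}
train = [f for s in (1, 2) for f in subjects[s].frames]
val, test = subjects[3].frames, subjects[4].frames

# stage 3: ligamentum flavum vs epidural space
cfg = TrainingConfig(max_epochs=6)
m3 = train_classifier(cfg, "stage3", stage_frames(train, 3),
                      stage_frames(val, 3), seed=0)
pred = predict_proba(m3, stage_frames(test, 3)).argmax(axis=1)
acc = (pred == stage_binary_labels(stage_frames(test, 3), 3)).mean()
print(f"held-out stage-3 accuracy: {acc:.3f}")

# run the truth-oracle cascade over a simulated insertion video
stream = simulate_insertion_sequence(seed=7)
annotated, switches = run_stream(stream, cascade.truth_oracle_predictor)
print("classifier switches at frames:", [i for _, i in switches])
```

Output:

```
held-out stage-3 accuracy: 1.000
classifier switches at frames: [135, 835, 935]
```

The stage-3 task is near-separable because the epidural space shows a dark
gap in front of the needle, so the held-out subject is classified
perfectly. On the default 100/700/100/100/150-frame insertion stream the
window rule fires 35 frames after each true tissue boundary (the count of
deeper-layer predictions in the sliding window reaches 35), so the
classifier switches at frames 135, 835 and 935.

A command-line interface mirrors the library:
`octguide simulate | train-classify | train-regress | nested-eval |
cascade-run | gradcam` (see `octguide --help`).

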