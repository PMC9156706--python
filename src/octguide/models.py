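"""Classifiers and the needle-to-dura distance regressor.

Training recipe (shared by all tasks): SGD with Nesterov momentum, learning
rate 0.01, momentum 0.9, decay 0.01 (hyperbolic per-update schedule), batch
size 32.  Classification minimizes sparse categorical cross-entropy with
early stopping at patience 10; regression trains a single identity-activation
output for 20 epochs under a MAPE objective.  Images are centered by
subtracting the training-set mean pixel value (computed from training frames
only and stored on the model).

Architecture names denote compact re-implementations built from the family's
signature block — plain conv stacks ("small-cnn"), skip connections
("resnet50-like"), parallel multi-scale branches ("inception-like"),
depthwise-separable convolutions ("xception-like") — sized so the whole
nested evaluation protocol runs on one CPU.  Regression variants collapse
the lateral axis first and convolve along depth, since the distance signal
lives entirely in the depth profile.

Also here: :func:`detect_surface_distance`, the non-learned analytic
estimator of the dark-gap height used as a labeling oracle and baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from . import _nn
from ._nn import (AppendDepthCoord, BatchNorm, BoxPool, BoxSmoothDepth,
                  ContrastNorm, Conv2D, CumMaxDepth, Dense, Flatten,
                  GlobalAvgMaxPool, GlobalAvgPool, InceptionBlock,
                  MaxPool2D, MeanOverWidth, Network, ParallelConcat, ReLU,
                  ResidualBlock, SeparableConvBlock)
from .synthetic_data import OCTFrame, TissueLabel, frames_to_array

__all__ = [
    "TrainingConfig", "TrainedModel", "ARCHITECTURES", "STAGE_CLASSES",
    "center_images", "train_classifier", "train_regressor",
    "predict_proba", "predict_distance", "detect_surface_distance",
    "SurfaceNotFoundError", "stage_frames", "stage_binary_labels",
    "save_model", "load_model",
]

ARCHITECTURES = ("small-cnn", "resnet50-like", "inception-like",
                 "xception-like")

#: Stage k discriminates class 0 (shallower) from class 1 (next-deeper layer).
STAGE_CLASSES = {
    1: (TissueLabel.FAT, TissueLabel.INTERSPINOUS_LIGAMENT),
    2: (TissueLabel.INTERSPINOUS_LIGAMENT, TissueLabel.LIGAMENTUM_FLAVUM),
    3: (TissueLabel.LIGAMENTUM_FLAVUM, TissueLabel.EPIDURAL_SPACE),
    4: (TissueLabel.EPIDURAL_SPACE, TissueLabel.SPINAL_CORD),
}

# regression targets are scaled to units of 100 um internally so the fixed
# lr-0.01 recipe is well-conditioned; the public API always speaks um
_OUTPUT_SCALE_UM = 100.0
# centered pixels are divided by this before entering the network
_PIXEL_SCALE = 255.0


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer and schedule constants; defaults are the study recipe."""

    learning_rate: float = 0.01
    momentum: float = 0.9
    decay: float = 0.01
    batch_size: int = 32
    patience: int = 10          # classification early stopping
    max_epochs: int = 100       # classification epoch cap
    regression_epochs: int = 20
    architecture: str = "small-cnn"

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}; "
                             f"choose from {ARCHITECTURES}")


@dataclass
class TrainedModel:
    """A fitted network plus everything needed to apply it consistently."""

    network: Network
    architecture: str
    task: str                       # 'stage1'..'stage4' | 'multiclass' | 'regression'
    config: TrainingConfig
    train_mean: float               # centering constant, from training frames only
    train_subjects: frozenset
    input_shape: tuple              # (depth_px, width_px)
    classes: Optional[tuple] = None  # TissueLabels, classification only
    history: list = field(default_factory=list)

    @property
    def is_regressor(self) -> bool:
        return self.task == "regression"


# ---------------------------------------------------------------------------
# architectures


def _gap_branch(mirror, rng, thresholds=(0.2, 0.35, 0.5, 0.65), gain=3.0):
    """Fixed side branch computing epidural gap maps.

    Per column: smooth along depth, contrast-normalize, take the causal
    cumulative max (the monotone brightness envelope), and rectify
    ``(t - envelope) / t`` at a bank of thresholds — positive exactly in
    the dark region above the first bright structure, the clinical
    signature of the epidural space in front of the needle.  ``gain`` sets
    the branch's output scale relative to the batch-normalized learned
    features (it controls how fast the dense head picks these maps up
    under SGD).  ``mirror`` is
    the (kernel, stride) chain of the learned stack, reproduced here with
    fixed box filters so the two branches stay spatially aligned.
    """
    bank = Conv2D(1, len(thresholds), 1, rng=rng)
    bank.W[...] = np.float32(-gain)
    bank.b[...] = np.float32(gain)
    bank.W[0, :] /= np.float32(thresholds)
    bank.trainable = False
    layers = [BoxSmoothDepth(9), ContrastNorm(), CumMaxDepth(),
              bank, ReLU()]
    layers += [BoxPool(k, s) for k, s in mirror]
    return layers


def _body_2d(name, rng):
    """Classification feature extractor.

    A depth-coordinate channel (CoordConv style, so shallow receptive
    fields can tell how deep a structure sits) feeds the family's conv
    stack; the fixed gap-map branch rides alongside and is concatenated to
    the final feature maps.
    """
    coord = [AppendDepthCoord()]
    if name == "small-cnn":
        main = coord + [Conv2D(2, 6, 5, stride=3, rng=rng), BatchNorm(6),
                        ReLU(),
                        Conv2D(6, 12, 3, stride=2, rng=rng), BatchNorm(12),
                        ReLU(),
                        Conv2D(12, 16, 3, stride=2, rng=rng), BatchNorm(16),
                        ReLU()]
        mirror = [(5, 3), (3, 2), (3, 2)]
    elif name == "resnet50-like":
        main = coord + [Conv2D(2, 8, 5, stride=3, rng=rng), BatchNorm(8),
                        ReLU(),
                        ResidualBlock(8, 16, stride=2, rng=rng),
                        BatchNorm(16),
                        ResidualBlock(16, 16, stride=2, rng=rng),
                        BatchNorm(16)]
        mirror = [(5, 3), (3, 2), (3, 2)]
    elif name == "inception-like":
        main = coord + [Conv2D(2, 8, 5, stride=3, rng=rng), BatchNorm(8),
                        ReLU(), MaxPool2D(2),
                        InceptionBlock(8, 4, 8, 4, rng=rng), BatchNorm(16),
                        MaxPool2D(2),
                        Conv2D(16, 16, 3, rng=rng), BatchNorm(16), ReLU()]
        mirror = [(5, 3), (2, 2), (2, 2), (3, 1)]
    elif name == "xception-like":
        main = coord + [Conv2D(2, 8, 5, stride=3, rng=rng), BatchNorm(8),
                        ReLU(),
                        SeparableConvBlock(8, 16, stride=2, rng=rng),
                        BatchNorm(16),
                        SeparableConvBlock(16, 16, stride=2, rng=rng),
                        BatchNorm(16)]
        mirror = [(5, 3), (3, 2), (3, 2)]
    else:
        raise ValueError(f"unknown architecture {name!r}")
    main[1].needs_input_grad = False   # nothing trainable below conv 1
    return [ParallelConcat(main, _gap_branch(mirror, rng))]


# the fixed front ends are non-learned: keeping them frozen preserves the
# contrast-normalized envelope's scale and avoids destabilizing the
# trainable threshold banks behind them


def _body_profile(name, rng):
    """Regression feature extractor.

    The distance signal is the depth of the first bright structure in the
    averaged A-line, so every variant shares a physics-shaped front end:
    lateral mean, learnable depth smoothing, per-frame contrast
    normalization (speckle amplitude varies between frames and subjects),
    and causal cumulative max pooling, which turns the profile into a
    monotone envelope stepping from background to 1 at the dura surface.
    The variants differ in the trainable stack that maps the envelope to
    threshold-crossing features, which the dense head converts into a
    depth count and hence a distance.
    """
    front = [MeanOverWidth(), BoxSmoothDepth(9), ContrastNorm(),
             CumMaxDepth()]
    if name == "small-cnn":
        return front + [Conv2D(1, 12, (1, 1), rng=rng), ReLU(),
                        GlobalAvgPool()]
    if name == "resnet50-like":
        return front + [ResidualBlock(1, 12, kernel=(3, 1), rng=rng),
                        GlobalAvgPool()]
    if name == "inception-like":
        return front + [InceptionBlock(1, 4, 4, 4, kernel_axis="depth",
                                       rng=rng),
                        GlobalAvgPool()]
    if name == "xception-like":
        return front + [SeparableConvBlock(1, 12, kernel=(3, 1), rng=rng),
                        GlobalAvgPool()]
    raise ValueError(f"unknown architecture {name!r}")


def build_network(architecture: str, input_shape, n_out: int, kind: str,
                  rng) -> Network:
    """Assemble body + head, inferring the head's input size by a dry run."""
    if kind == "classify":
        body = _body_2d(architecture, rng) + [GlobalAvgMaxPool()]
    else:
        body = _body_profile(architecture, rng) + [Flatten()]
    probe = Network(body)
    feat = probe.forward(np.zeros((1,) + tuple(input_shape) + (1,),
                                  dtype=np.float32))
    n_feat = feat.shape[1]
    # single dense output layer; for regression this is the one identity-
    # activation neuron on the pooled features
    return Network(body + [Dense(n_feat, n_out, rng=rng)])


# ---------------------------------------------------------------------------
# preprocessing


def center_images(train_frames: Sequence[OCTFrame],
                  other_frames: Sequence[OCTFrame] = ()):
    """Subtract the training-set mean pixel value from every frame.

    Returns ``(train_arrays, other_arrays, train_mean)`` where the arrays are
    float32 NHWC batches.  The mean comes from ``train_frames`` only.
    """
    if len(train_frames) == 0:
        raise ValueError("empty training set")
    train = frames_to_array(train_frames)
    mean = float(train.mean())
    others = frames_to_array(other_frames) if len(other_frames) else None
    return train - mean, (others - mean if others is not None else None), mean


def _preprocess(frames, mean):
    return (frames_to_array(frames) - mean) / _PIXEL_SCALE


# ---------------------------------------------------------------------------
# label plumbing


def stage_frames(frames, stage: int):
    """Frames belonging to stage ``stage``'s two classes, in input order."""
    c0, c1 = STAGE_CLASSES[stage]
    return [f for f in frames if f.label in (c0, c1)]


def stage_binary_labels(frames, stage: int) -> np.ndarray:
    c0, c1 = STAGE_CLASSES[stage]
    labels = np.empty(len(frames), dtype=np.int64)
    for i, f in enumerate(frames):
        if f.label == c0:
            labels[i] = 0
        elif f.label == c1:
            labels[i] = 1
        else:
            raise ValueError(
                f"frame label {f.label.name} not in stage {stage} "
                f"({c0.name} vs {c1.name})")
    return labels


def _task_labels(frames, task):
    if task == "multiclass":
        return np.array([int(f.label) for f in frames], dtype=np.int64), \
            tuple(TissueLabel)
    if task.startswith("stage"):
        stage = int(task[5:])
        if stage not in STAGE_CLASSES:
            raise ValueError(f"unknown task {task!r}")
        return stage_binary_labels(frames, stage), STAGE_CLASSES[stage]
    raise ValueError(f"unknown task {task!r}")


def _check_disjoint_subjects(train_frames, val_frames):
    tr = {f.subject_id for f in train_frames}
    va = {f.subject_id for f in val_frames}
    if tr & va:
        raise ValueError(f"train/validation subjects overlap: {sorted(tr & va)}")


# ---------------------------------------------------------------------------
# training loops


def _find_concat(net):
    for layer in net.layers:
        if isinstance(layer, ParallelConcat):
            return layer
    return None


def _precompute_side(net, x, batch_size=64):
    """Evaluate the parameter-free side branch once for a whole frame set;
    its per-frame output never changes during a training run."""
    pc = _find_concat(net)
    if pc is None or len(x) == 0:
        return None
    return np.concatenate([pc.run_side(x[i : i + batch_size])
                           for i in range(0, len(x), batch_size)])


def _epoch(net, loss_fn, opt, x, y, batch_size, rng, pc=None, side=None):
    net.set_training(True)
    order = rng.permutation(len(x))
    total = 0.0
    try:
        for start in range(0, len(x), batch_size):
            idx = order[start : start + batch_size]
            if pc is not None:
                pc.side_override = side[idx]
            out = net.forward(x[idx])
            loss, grad = loss_fn.loss_and_grad(out, y[idx])
            net.backward(grad)
            opt.step(net.params())
            total += loss * len(idx)
    finally:
        if pc is not None:
            pc.side_override = None
    return total / len(x)


def _predict_with_side(net, x, pc=None, side=None, batch_size=64):
    net.set_training(False)
    outs = []
    try:
        for i in range(0, len(x), batch_size):
            if pc is not None:
                pc.side_override = side[i : i + batch_size]
            outs.append(net.forward(x[i : i + batch_size]))
    finally:
        if pc is not None:
            pc.side_override = None
    return np.concatenate(outs, axis=0)


def _val_class_metrics(net, loss_fn, x, y, pc=None, side=None):
    logits = _predict_with_side(net, x, pc, side)
    loss, _ = loss_fn.loss_and_grad(logits, y)
    acc = float((logits.argmax(axis=1) == y).mean())
    return loss, acc


def train_classifier(config: TrainingConfig, task: str,
                     train_frames: Sequence[OCTFrame],
                     val_frames: Sequence[OCTFrame],
                     seed: int = 0) -> TrainedModel:
    """Fit a binary stage or five-class classifier.

    Stops when validation loss has not improved for ``config.patience``
    consecutive epochs (or at ``config.max_epochs``) and restores the
    best-validation-epoch weights.
    """
    y_train, classes = _task_labels(train_frames, task)
    y_val, _ = _task_labels(val_frames, task)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class")
    _check_disjoint_subjects(train_frames, val_frames)

    shape = train_frames[0].pixels.shape
    mean = float(frames_to_array(train_frames).mean())
    x_train = _preprocess(train_frames, mean)
    x_val = _preprocess(val_frames, mean)

    rng = np.random.default_rng(seed)
    net = build_network(config.architecture, shape, len(classes),
                        "classify", rng)
    loss_fn = _nn.SoftmaxCrossEntropy()
    opt = _nn.SGDNesterov(config.learning_rate, config.momentum, config.decay)

    pc = _find_concat(net)
    side_train = _precompute_side(net, x_train)
    side_val = _precompute_side(net, x_val)

    best_loss, best_weights, wait = np.inf, None, 0
    history = []
    for epoch in range(config.max_epochs):
        opt.epoch = epoch
        train_loss = _epoch(net, loss_fn, opt, x_train, y_train,
                            config.batch_size, rng, pc, side_train)
        val_loss, val_acc = _val_class_metrics(net, loss_fn, x_val, y_val,
                                               pc, side_val)
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "val_accuracy": val_acc})
        if val_loss < best_loss - 1e-7:
            best_loss, best_weights, wait = val_loss, net.get_weights(), 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    if best_weights is not None:
        net.set_weights(best_weights)

    return TrainedModel(network=net, architecture=config.architecture,
                        task=task, config=config, train_mean=mean,
                        train_subjects=frozenset(f.subject_id
                                                 for f in train_frames),
                        input_shape=tuple(shape), classes=classes,
                        history=history)


def train_regressor(config: TrainingConfig,
                    train_frames: Sequence[OCTFrame],
                    val_frames: Sequence[OCTFrame],
                    seed: int = 0) -> TrainedModel:
    """Fit the needle-to-dura distance regressor (fixed 20-epoch schedule).

    All frames must be epidural-space frames with positive distance labels.
    The single-output head has identity activation; its bias is initialized
    at the mean training distance so the network starts from an unbiased
    constant predictor.
    """
    for f in list(train_frames) + list(val_frames):
        if f.label != TissueLabel.EPIDURAL_SPACE or f.distance_um is None:
            raise ValueError("regression requires epidural-space frames "
                             "with distance labels")
        if f.distance_um <= 0:
            raise ValueError("distance labels must be strictly positive")
    _check_disjoint_subjects(train_frames, val_frames)

    shape = train_frames[0].pixels.shape
    mean = float(frames_to_array(train_frames).mean())
    x_train = _preprocess(train_frames, mean)
    y_train = np.array([f.distance_um for f in train_frames]) / _OUTPUT_SCALE_UM
    have_val = len(val_frames) > 0
    if have_val:
        x_val = _preprocess(val_frames, mean)
        y_val = np.array([f.distance_um
                          for f in val_frames]) / _OUTPUT_SCALE_UM

    rng = np.random.default_rng(seed)
    net = build_network(config.architecture, shape, 1, "regress", rng)
    # start exactly at the unbiased constant predictor: zero output weights,
    # bias at the mean training distance
    net.layers[-1].W[...] = 0.0
    net.layers[-1].b[...] = np.float32(y_train.mean())
    loss_fn = _nn.MAPELoss()
    opt = _nn.SGDNesterov(config.learning_rate, config.momentum, config.decay)

    history = []
    for epoch in range(config.regression_epochs):
        opt.epoch = epoch
        train_loss = _epoch(net, loss_fn, opt, x_train, y_train,
                            config.batch_size, rng)
        rec = {"epoch": epoch, "train_loss": train_loss}
        if have_val:
            val_loss, _ = loss_fn.loss_and_grad(net.predict(x_val), y_val)
            rec["val_loss"] = float(val_loss)
        history.append(rec)

    return TrainedModel(network=net, architecture=config.architecture,
                        task="regression", config=config, train_mean=mean,
                        train_subjects=frozenset(f.subject_id
                                                 for f in train_frames),
                        input_shape=tuple(shape), history=history)


# ---------------------------------------------------------------------------
# inference


def _check_geometry(model, frames):
    for f in frames:
        if tuple(f.pixels.shape) != tuple(model.input_shape):
            raise ValueError(
                f"frame geometry {f.pixels.shape} does not match model input "
                f"{model.input_shape}")


def predict_proba(model: TrainedModel, frames, batch_size: int = 64):
    """Per-frame class-probability vectors (rows sum to 1)."""
    if model.is_regressor:
        raise ValueError("predict_proba is for classifiers; "
                         "use predict_distance")
    _check_geometry(model, frames)
    logits = model.network.predict(_preprocess(frames, model.train_mean),
                                   batch_size)
    return _nn.SoftmaxCrossEntropy.probabilities(logits)


def predict_distance(model: TrainedModel, frames, batch_size: int = 64):
    """Predicted needle-to-dura distances in um."""
    if not model.is_regressor:
        raise ValueError("predict_distance is for the regressor")
    _check_geometry(model, frames)
    out = model.network.predict(_preprocess(frames, model.train_mean),
                                batch_size)
    return out[:, 0] * _OUTPUT_SCALE_UM


# ---------------------------------------------------------------------------
# checkpoints


def save_model(model: TrainedModel, path) -> None:
    """Checkpoint weights plus metadata (architecture, task, config, training
    mean, subject fingerprint) as a compressed npz."""
    import json

    meta = {
        "architecture": model.architecture,
        "task": model.task,
        "config": model.config.__dict__,
        "train_mean": model.train_mean,
        "train_subjects": sorted(model.train_subjects),
        "input_shape": list(model.input_shape),
        "classes": [int(c) for c in model.classes] if model.classes else None,
        "history": model.history,
    }
    weights = model.network.get_weights()
    np.savez_compressed(
        path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **{f"w{i}": w for i, w in enumerate(weights)})


def load_model(path) -> TrainedModel:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    config = TrainingConfig(**meta["config"])
    kind = "regress" if meta["task"] == "regression" else "classify"
    n_out = 1 if kind == "regress" else len(meta["classes"])
    rng = np.random.default_rng(0)
    net = build_network(meta["architecture"], meta["input_shape"], n_out,
                        kind, rng)
    net.set_weights(weights)
    classes = (tuple(TissueLabel(c) for c in meta["classes"])
               if meta["classes"] else None)
    return TrainedModel(network=net, architecture=meta["architecture"],
                        task=meta["task"], config=config,
                        train_mean=meta["train_mean"],
                        train_subjects=frozenset(meta["train_subjects"]),
                        input_shape=tuple(meta["input_shape"]),
                        classes=classes, history=meta["history"])


# ---------------------------------------------------------------------------
# analytic surface detector


class SurfaceNotFoundError(RuntimeError):
    """No depth row rises above the background: no tissue surface visible."""


def detect_surface_distance(frame: OCTFrame,
                            min_contrast: float = 15.0,
                            margin_fraction: float = 0.2) -> float:
    """Needle-to-dura distance from the first bright depth row.

    Averages each row laterally, smooths the resulting A-line profile with a
    3-sample box filter, estimates the background as its 10th percentile and
    returns ``pixel_size_um`` times the index of the first row exceeding
    background + ``margin_fraction`` x (peak - background).  Raises
    :class:`SurfaceNotFoundError` when the peak clears the background by
    less than ``min_contrast`` intensity counts.
    """
    profile = frame.pixels.astype(np.float64).mean(axis=1)
    smooth = uniform_filter1d(profile, size=3)
    background = float(np.percentile(smooth, 10))
    peak = float(smooth.max())
    if peak < background + min_contrast:
        raise SurfaceNotFoundError(
            f"no row exceeds background ({background:.1f}) by "
            f"{min_contrast} counts")
    threshold = background + margin_fraction * (peak - background)
    row = int(np.argmax(smooth > threshold))
    return row * frame.pixel_size_um
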