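"""Sequential four-stage binary classification cascade.

During needle advance a single binary classifier is active at a time:
(1) fat vs interspinous ligament, (2) interspinous ligament vs ligamentum
flavum, (3) ligamentum flavum vs epidural space, (4) epidural space vs
spinal cord.  Class 1 is always the next-deeper layer.  The cascade keeps
the most recent 50 binary predictions of the active stage; when 35 of them
are class 1 the needle is deemed to have entered the deeper layer and the
next classifier is activated.  The displayed fraction class1/denominator
uses denominator = min(frames seen in the stage, 50) and follows traffic
light colors: GREEN below 26 class-1 hits, YELLOW from 26, RED from 35.
Once stage 4 (the last classifier) is active no fraction or color is shown.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .synthetic_data import InsertionSequence, OCTFrame, TissueLabel

__all__ = [
    "Zone", "CascadeStage", "STAGES", "CascadeState", "AnnotatedFrame",
    "init_cascade", "update", "run_stream", "truth_oracle_predictor",
    "WINDOW_SIZE", "YELLOW_THRESHOLD", "RED_THRESHOLD",
]

WINDOW_SIZE = 50
YELLOW_THRESHOLD = 26   # green -> yellow at 26 class-1 hits in the window
RED_THRESHOLD = 35      # yellow -> red, and classifier switch, at 35


class Zone(Enum):
    GREEN = "green"
    YELLOW = "yellow"
    RED = "red"


@dataclass(frozen=True)
class CascadeStage:
    index: int
    class0: TissueLabel
    class1: TissueLabel

    @property
    def name(self) -> str:
        return f"{self.class0.name} vs {self.class1.name}"


STAGES = (
    CascadeStage(1, TissueLabel.FAT, TissueLabel.INTERSPINOUS_LIGAMENT),
    CascadeStage(2, TissueLabel.INTERSPINOUS_LIGAMENT,
                 TissueLabel.LIGAMENTUM_FLAVUM),
    CascadeStage(3, TissueLabel.LIGAMENTUM_FLAVUM,
                 TissueLabel.EPIDURAL_SPACE),
    CascadeStage(4, TissueLabel.EPIDURAL_SPACE, TissueLabel.SPINAL_CORD),
)


@dataclass
class CascadeState:
    """Mutable cascade tracker.  Global frame indices are 1-based."""

    stage: int = 1
    window: deque = field(default_factory=lambda: deque(maxlen=WINDOW_SIZE))
    frames_processed: int = 0
    switch_log: list = field(default_factory=list)   # (completed_stage, frame)
    closed: bool = False
    last_fraction: Optional[str] = None   # display snapshot of the latest
    last_zone: Optional[Zone] = None      # frame, taken before any reset
    window_size: int = WINDOW_SIZE
    yellow_threshold: int = YELLOW_THRESHOLD
    red_threshold: int = RED_THRESHOLD
    reset_window_on_switch: bool = True

    @property
    def class1_count(self) -> int:
        return int(sum(self.window))

    @property
    def denominator(self) -> int:
        return len(self.window)

    @property
    def fraction(self) -> Optional[str]:
        """Displayed 'count/denominator', absent once stage 4 is active."""
        if self.stage >= 4:
            return None
        return f"{self.class1_count}/{self.denominator}"

    @property
    def zone(self) -> Optional[Zone]:
        if self.stage >= 4:
            return None
        c = self.class1_count
        if c >= self.red_threshold:
            return Zone.RED
        if c >= self.yellow_threshold:
            return Zone.YELLOW
        return Zone.GREEN

    @property
    def active_stage(self) -> CascadeStage:
        return STAGES[self.stage - 1]


@dataclass(frozen=True)
class AnnotatedFrame:
    """Per-frame display record: fraction and color at the moment the frame
    was processed (by the classifier active when it arrived)."""

    frame_index: int                 # 1-based global index
    stage: int
    classifier: str
    fraction: Optional[str]
    zone: Optional[Zone]
    truth: Optional[TissueLabel]
    predicted: TissueLabel


def init_cascade(window_size: int = WINDOW_SIZE,
                 yellow_threshold: int = YELLOW_THRESHOLD,
                 red_threshold: int = RED_THRESHOLD,
                 reset_window_on_switch: bool = True) -> CascadeState:
    """Fresh state: stage 1 active, empty window, zone GREEN."""
    if not 0 < yellow_threshold <= red_threshold <= window_size:
        raise ValueError("need 0 < yellow <= red <= window size")
    return CascadeState(window=deque(maxlen=window_size),
                        window_size=window_size,
                        yellow_threshold=yellow_threshold,
                        red_threshold=red_threshold,
                        reset_window_on_switch=reset_window_on_switch)


def update(state: CascadeState, prediction: int) -> CascadeState:
    """Advance the cascade by one binary prediction for the active stage.

    Returns the same (mutated) state.  When the class-1 count reaches the
    red threshold and a deeper classifier exists, the stage increments, the
    switch is logged with the 1-based global frame index, and the window is
    cleared (unless configured otherwise).  Stage 4 never switches.
    """
    if state.closed:
        raise RuntimeError("cascade stream already closed")
    if prediction not in (0, 1):
        raise ValueError(f"prediction must be 0 or 1, got {prediction!r}")
    state.frames_processed += 1
    state.window.append(int(prediction))
    state.last_fraction = state.fraction
    state.last_zone = state.zone
    if state.stage < 4 and state.class1_count >= state.red_threshold:
        state.switch_log.append((state.stage, state.frames_processed))
        state.stage += 1
        if state.reset_window_on_switch:
            state.window.clear()
    return state


def truth_oracle_predictor(frame: OCTFrame, stage: CascadeStage) -> int:
    """Perfect predictor from ground truth: class 1 iff the frame's layer is
    at least as deep as the stage's class-1 tissue."""
    return int(frame.label >= stage.class1)


Predictor = Callable[[OCTFrame, CascadeStage], int]


def run_stream(frames: Union[InsertionSequence, Sequence[OCTFrame]],
               stage_models: Union[dict, Predictor],
               state: Optional[CascadeState] = None):
    """Run the cascade over a temporal frame stream.

    ``stage_models`` is either a dict {1..4 -> TrainedModel} (each frame is
    classified only by the stage active when it arrives) or a callable
    ``predictor(frame, stage) -> 0|1`` such as
    :func:`truth_oracle_predictor`.  Returns ``(annotated, switch_log)``;
    the state is closed afterwards.
    """
    frames = list(frames.frames) if isinstance(frames, InsertionSequence) \
        else list(frames)
    if state is None:
        state = init_cascade()

    if callable(stage_models):
        def predict(i, frame, stage):
            return int(stage_models(frame, stage))
    else:
        missing = [k for k in (1, 2, 3, 4) if k not in stage_models]
        if missing:
            raise ValueError(f"missing stage models: {missing}")
        # batch-precompute each stage's argmax labels over the whole stream;
        # the replay below consumes only the active stage's column
        from .models import predict_proba
        table = {}
        for k in (1, 2, 3, 4):
            proba = predict_proba(stage_models[k], frames)
            table[k] = proba.argmax(axis=1)

        def predict(i, frame, stage):
            return int(table[stage.index][i])

    annotated = []
    for i, frame in enumerate(frames):
        stage = state.active_stage
        pred = predict(i, frame, stage)
        update(state, pred)
        annotated.append(AnnotatedFrame(
            frame_index=state.frames_processed,
            stage=stage.index,
            classifier=stage.name,
            fraction=state.last_fraction,
            zone=state.last_zone,
            truth=frame.label,
            predicted=stage.class1 if pred == 1 else stage.class0))
    state.closed = True
    return annotated, list(state.switch_log)
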