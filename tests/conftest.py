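"""Shared fixtures: small-geometry datasets for fast unit tests and the
default insertion stream reused by the cascade tests."""

import numpy as np
import pytest

from octguide import synthetic_data as sd

#: small frame geometry for fast training tests (500 um deep)
SMALL = sd.FrameGeometry(width_px=60, depth_px=80)
#: epidural distance range that fits the small geometry with room to spare
SMALL_DISTANCES = (100.0, 400.0)


def small_subject(subject_id, frames_per_layer=12, seed=0, appearances=None):
    return sd.simulate_subject(
        subject_id, appearances=appearances,
        frames_per_layer=frames_per_layer, seed=seed, geometry=SMALL,
        distance_range_um=SMALL_DISTANCES)


def label_frame(label, subject_id=1, distance_um=None):
    """A minimal frame carrying only labels (for state-machine tests)."""
    if label == sd.TissueLabel.EPIDURAL_SPACE and distance_um is None:
        distance_um = 10.0
    return sd.OCTFrame(pixels=np.zeros((2, 2), dtype=np.uint8),
                       subject_id=subject_id, label=label,
                       distance_um=distance_um)


@pytest.fixture(scope="session")
def small_subjects():
    """Four small-geometry subjects with 12 frames per layer each."""
    return {s: small_subject(s, frames_per_layer=12, seed=4200 + s)
            for s in range(1, 5)}


@pytest.fixture(scope="session")
def default_stream():
    """The standard 100/700/100/100/150 insertion stream."""
    return sd.simulate_insertion_sequence(seed=777)
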