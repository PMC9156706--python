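"""Classifier/regressor training contracts, preprocessing provenance, the
analytic surface detector, and checkpoint round-trips."""

import numpy as np
import pytest

from octguide import models
from octguide import synthetic_data as sd
from octguide.models import (SurfaceNotFoundError, TrainingConfig,
                             center_images, detect_surface_distance,
                             load_model, predict_distance, predict_proba,
                             save_model, stage_binary_labels, stage_frames,
                             train_classifier, train_regressor)
from octguide.synthetic_data import TissueLabel

from conftest import SMALL, SMALL_DISTANCES, label_frame, small_subject

FAST = TrainingConfig(max_epochs=2, patience=2)


def _stage_sets(small_subjects, stage):
    train = stage_frames(
        [f for s in (1, 2) for f in small_subjects[s].frames], stage)
    val = stage_frames(small_subjects[3].frames, stage)
    return train, val


def test_training_config_defaults_are_study_recipe():
    cfg = TrainingConfig()
    assert (cfg.learning_rate, cfg.momentum, cfg.decay) == (0.01, 0.9, 0.01)
    assert cfg.batch_size == 32
    assert cfg.patience == 10
    assert cfg.regression_epochs == 20
    with pytest.raises(ValueError, match="unknown architecture"):
        TrainingConfig(architecture="alexnet")


def test_center_images_uses_training_mean_only():
    bright = sd.OCTFrame(pixels=np.full((6, 5), 100, np.uint8), subject_id=1,
                         label=TissueLabel.FAT)
    other = sd.OCTFrame(pixels=np.full((6, 5), 120, np.uint8), subject_id=2,
                        label=TissueLabel.FAT)
    train, val, mean = center_images([bright], [other])
    assert mean == 100.0
    assert np.all(train == 0.0)
    assert np.all(val == 20.0)
    # recomputing from the validation set would give a different constant
    assert float(np.full((6, 5), 120.0).mean()) != mean
    with pytest.raises(ValueError):
        center_images([])


def test_classifier_rejects_bad_tasks_and_labels(small_subjects):
    train, val = _stage_sets(small_subjects, 1)
    with pytest.raises(ValueError, match="unknown task"):
        train_classifier(FAST, "stage9", train, val)
    flavum_only = [f for f in small_subjects[1].frames
                   if f.label == TissueLabel.LIGAMENTUM_FLAVUM]
    val3 = stage_frames(small_subjects[3].frames, 3)
    with pytest.raises(ValueError, match="single class"):
        train_classifier(FAST, "stage3", flavum_only, val3)
    with pytest.raises(ValueError, match="not in stage"):
        stage_binary_labels(small_subjects[1].frames, 1)


def test_classifier_rejects_subject_overlap(small_subjects):
    train, _ = _stage_sets(small_subjects, 1)
    overlap_val = stage_frames(small_subjects[1].frames, 1)
    with pytest.raises(ValueError, match="overlap"):
        train_classifier(FAST, "stage1", train, overlap_val)


def test_classifier_determinism_and_probability_contract(small_subjects):
    train, val = _stage_sets(small_subjects, 3)
    m1 = train_classifier(FAST, "stage3", train, val, seed=11)
    m2 = train_classifier(FAST, "stage3", train, val, seed=11)
    assert [h["val_loss"] for h in m1.history] == \
        [h["val_loss"] for h in m2.history]

    proba = predict_proba(m1, val)
    assert proba.shape == (len(val), 2)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
    assert proba.min() >= 0
    # batching must not change the result
    proba_small_batches = predict_proba(m1, val, batch_size=3)
    np.testing.assert_allclose(proba, proba_small_batches, atol=1e-5)


def test_classifier_learns_gap_signature(small_subjects):
    """Scaled-down analog of the near-separable flavum-vs-epidural task."""
    train, val = _stage_sets(small_subjects, 3)
    m = train_classifier(TrainingConfig(max_epochs=5), "stage3", train, val,
                         seed=0)
    assert m.history[-1]["val_accuracy"] >= 0.9
    assert m.train_subjects == frozenset({1, 2})


def test_shuffled_labels_give_chance_accuracy(small_subjects):
    """Permutation null: destroying the label-image link leaves validation
    accuracy within binomial noise of 0.5."""
    train, val = _stage_sets(small_subjects, 3)
    rng = np.random.default_rng(0)
    shuffled = list(train)
    labels = [f.label for f in shuffled]
    perm = rng.permutation(len(labels))
    relabeled = []
    for f, j in zip(shuffled, perm):
        d = 150.0 if labels[j] == TissueLabel.EPIDURAL_SPACE else None
        relabeled.append(sd.OCTFrame(pixels=f.pixels,
                                     subject_id=f.subject_id,
                                     label=labels[j], distance_um=d))
    m = train_classifier(TrainingConfig(max_epochs=3), "stage3", relabeled,
                         val, seed=1)
    acc = m.history[-1]["val_accuracy"]
    n = len(val)
    assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / n) + 0.05


def test_geometry_mismatch_rejected(small_subjects):
    train, val = _stage_sets(small_subjects, 3)
    m = train_classifier(FAST, "stage3", train, val, seed=0)
    big = sd.simulate_frame(TissueLabel.LIGAMENTUM_FLAVUM,
                            sd.default_appearances()[
                                TissueLabel.LIGAMENTUM_FLAVUM],
                            rng=np.random.default_rng(0))
    with pytest.raises(ValueError, match="geometry"):
        predict_proba(m, [big])
    with pytest.raises(ValueError, match="predict_distance"):
        predict_proba(m, val) if False else predict_distance(m, val)


def test_model_checkpoint_round_trip(tmp_path, small_subjects):
    train, val = _stage_sets(small_subjects, 3)
    m = train_classifier(FAST, "stage3", train, val, seed=5)
    path = tmp_path / "stage3.npz"
    save_model(m, path)
    loaded = load_model(path)
    np.testing.assert_allclose(predict_proba(m, val),
                               predict_proba(loaded, val), atol=1e-6)
    assert loaded.train_mean == m.train_mean
    assert loaded.train_subjects == m.train_subjects
    assert loaded.classes == m.classes


def _small_regression_subject(subject_id, n, seed):
    return sd.simulate_subject(subject_id, frames_per_layer=n, seed=seed,
                               task="regress", geometry=SMALL,
                               distance_range_um=SMALL_DISTANCES)


def test_regressor_requires_positive_epidural_distances(small_subjects):
    fat = [f for f in small_subjects[1].frames
           if f.label == TissueLabel.FAT]
    with pytest.raises(ValueError, match="epidural-space frames"):
        train_regressor(FAST, fat, [])


def test_regressor_degenerate_equal_targets():
    """With a constant target the identity head converges onto it."""
    frames = []
    rng = np.random.default_rng(0)
    app = sd.default_appearances()[TissueLabel.EPIDURAL_SPACE]
    for s in (1, 2):
        for _ in range(24):
            f = sd.simulate_frame(TissueLabel.EPIDURAL_SPACE, app,
                                  geometry=SMALL, distance_um=250.0,
                                  rng=rng, subject_id=s)
            frames.append(f)
    m = train_regressor(TrainingConfig(regression_epochs=3),
                        frames[:24], frames[24:], seed=0)
    pred = predict_distance(m, frames[24:])
    mape = 100 * np.mean(np.abs(pred - 250.0) / 250.0)
    assert mape <= 1.0


def test_detector_round_trip_and_error_paths():
    app = sd.default_appearances()[TissueLabel.EPIDURAL_SPACE]
    rng = np.random.default_rng(3)
    f = sd.simulate_frame(TissueLabel.EPIDURAL_SPACE, app, distance_um=625,
                          rng=rng)
    assert abs(detect_surface_distance(f) - 625) <= 6.25

    f0 = sd.simulate_frame(TissueLabel.EPIDURAL_SPACE, app, distance_um=0,
                           rng=rng)
    assert abs(detect_surface_distance(f0) - 0) <= 6.25

    noise = sd.OCTFrame(
        pixels=rng.integers(0, 25, (241, 181)).astype(np.uint8),
        subject_id=1, label=TissueLabel.EPIDURAL_SPACE, distance_um=100.0)
    with pytest.raises(SurfaceNotFoundError):
        detect_surface_distance(noise)


def test_detector_monotone_in_gap_depth():
    """On noise-free frames the detected distance strictly increases with
    the simulated gap."""
    app = sd.TissueAppearance(surface_brightness=200,
                              attenuation_length_px=45,
                              heterogeneity_scale=0.0, speckle_variance=0.0,
                              noise_floor=5.0)
    rng = np.random.default_rng(0)
    detected = []
    for d in (200, 400, 600, 800, 1000, 1200):
        f = sd.simulate_frame(TissueLabel.EPIDURAL_SPACE, app,
                              distance_um=d, rng=rng)
        detected.append(detect_surface_distance(f))
    assert all(a < b for a, b in zip(detected, detected[1:]))
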