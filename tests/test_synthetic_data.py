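"""Synthetic B-scan generator: determinism, geometry, label rules, and the
per-class appearance signatures the downstream classifiers rely on."""

import numpy as np
import pytest

from octguide import synthetic_data as sd
from octguide.synthetic_data import TissueLabel

from conftest import SMALL, SMALL_DISTANCES, small_subject


def fit_signature_features(frame, window=120):
    """Independent feature oracle anchored at the frame top: log-linear
    attenuation fit, near-surface brightness, lateral coefficient of
    variation.  The epidural gap shows up as a dark top, so these three
    separate all adjacent class pairs."""
    img = frame.pixels.astype(float)
    profile = img.mean(axis=1)
    bright = profile[:20].max()
    seg = np.clip(profile[8 : 8 + window] - 12.0, 1e-3, None)
    slope = np.polyfit(np.arange(len(seg)), np.log(seg), 1)[0]
    attenuation = -1.0 / slope if slope < 0 else 300.0
    cols = img[8:68].mean(axis=0)
    cv = cols.std() / max(cols.mean(), 1e-9)
    return attenuation, bright, cv


def test_identical_seeds_give_bit_identical_frames():
    a = small_subject(1, frames_per_layer=3, seed=99)
    b = small_subject(1, frames_per_layer=3, seed=99)
    assert len(a.frames) == len(b.frames)
    for fa, fb in zip(a.frames, b.frames):
        assert np.array_equal(fa.pixels, fb.pixels)
        assert fa.distance_um == fb.distance_um
    c = small_subject(1, frames_per_layer=3, seed=100)
    assert any(not np.array_equal(fa.pixels, fc.pixels)
               for fa, fc in zip(a.frames, c.frames))


def test_default_geometries():
    f = sd.simulate_frame(TissueLabel.FAT, sd.default_appearances()[
        TissueLabel.FAT], rng=np.random.default_rng(0))
    assert f.pixels.shape == (241, 181)        # depth-major classification
    r = sd.simulate_subject(1, frames_per_layer=1, seed=0, task="regress")
    assert r.frames[0].pixels.shape == (681, 241)
    assert sd.CLASSIFICATION_GEOMETRY.pixel_size_um == 6.25


def test_subject_dataset_counts_and_labels():
    ds = small_subject(2, frames_per_layer=4, seed=1)
    assert len(ds.frames) == 5 * 4
    for lab in TissueLabel:
        assert sum(f.label == lab for f in ds.frames) == 4
    assert all(f.subject_id == 2 for f in ds.frames)


def test_epidural_distance_range_respected():
    ds = small_subject(1, frames_per_layer=40, seed=3)
    dists = [f.distance_um for f in ds.frames
             if f.label == TissueLabel.EPIDURAL_SPACE]
    assert min(dists) >= SMALL_DISTANCES[0]
    assert max(dists) <= SMALL_DISTANCES[1]


def test_deep_gap_saturates_at_frame_depth():
    """Distances beyond the crop depth render as pure background and the
    stored label saturates at the frame depth."""
    ds = sd.simulate_subject(1, frames_per_layer=60, seed=11,
                             task="classify")
    depth_um = sd.CLASSIFICATION_GEOMETRY.depth_um
    epid = [f for f in ds.frames if f.label == TissueLabel.EPIDURAL_SPACE]
    assert all(f.distance_um <= depth_um for f in epid)
    assert any(f.distance_um == depth_um for f in epid)
    full_gap = next(f for f in epid if f.distance_um == depth_um)
    assert full_gap.pixels.mean() < 30      # nothing but noise floor


def test_distance_rules_enforced():
    app = sd.default_appearances()
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="requires distance"):
        sd.simulate_frame(TissueLabel.EPIDURAL_SPACE,
                          app[TissueLabel.EPIDURAL_SPACE], rng=rng)
    with pytest.raises(ValueError, match="exceeds frame depth"):
        sd.simulate_frame(TissueLabel.EPIDURAL_SPACE,
                          app[TissueLabel.EPIDURAL_SPACE],
                          distance_um=99999, rng=rng)
    with pytest.raises(ValueError, match="only valid for EPIDURAL_SPACE"):
        sd.simulate_frame(TissueLabel.FAT, app[TissueLabel.FAT],
                          distance_um=100, rng=rng)


def test_epidural_gap_starts_at_expected_row():
    """A 625 um gap puts the first tissue row at index 100 (625 / 6.25)."""
    app = sd.default_appearances()[TissueLabel.EPIDURAL_SPACE]
    rng = np.random.default_rng(5)
    f = sd.simulate_frame(TissueLabel.EPIDURAL_SPACE, app, distance_um=625,
                          rng=rng)
    profile = f.pixels.astype(float).mean(axis=1)
    background = np.median(profile[:80])
    first_bright = int(np.argmax(profile > background + 25))
    assert abs(first_bright - 100) <= 1

    f0 = sd.simulate_frame(TissueLabel.EPIDURAL_SPACE, app, distance_um=0,
                           rng=rng)
    top = f0.pixels[:4].astype(float).mean()
    assert top > 40            # tissue from row zero, no dark gap


def test_ligament_attenuates_deeper_than_flavum():
    """Per-column decay fits over generated sets: the interspinous ligament
    penetrates deeper than the ligamentum flavum."""
    app = sd.default_appearances()
    rng = np.random.default_rng(8)
    def mean_att(label, n=60):
        vals = []
        for _ in range(n):
            f = sd.simulate_frame(label, app[label], rng=rng)
            vals.append(fit_signature_features(f)[0])
        return float(np.mean(vals))
    assert mean_att(TissueLabel.INTERSPINOUS_LIGAMENT) > \
        mean_att(TissueLabel.LIGAMENTUM_FLAVUM) + 20


def test_default_appearance_orderings():
    app = sd.default_appearances()
    att = {k: v.attenuation_length_px for k, v in app.items()}
    assert att[TissueLabel.INTERSPINOUS_LIGAMENT] > att[TissueLabel.FAT]
    assert abs(att[TissueLabel.FAT] - att[TissueLabel.SPINAL_CORD]) <= 5
    assert att[TissueLabel.FAT] > att[TissueLabel.LIGAMENTUM_FLAVUM]
    bright = {k: v.surface_brightness for k, v in app.items()}
    assert max(bright, key=bright.get) == TissueLabel.LIGAMENTUM_FLAVUM
    assert app[TissueLabel.FAT].heterogeneity_scale > \
        app[TissueLabel.SPINAL_CORD].heterogeneity_scale


def test_adjacent_class_signatures_separated_by_two_pooled_sd():
    """For each adjacent pair used by the cascade, at least one of the
    three signature features differs by more than two pooled SDs across
    subjects."""
    feats = {lab: [] for lab in TissueLabel}
    for s in range(8):
        rng = np.random.default_rng(500 + s)
        mult = sd.draw_subject_multipliers(rng)
        app = {lab: a.scaled(mult)
               for lab, a in sd.default_appearances().items()}
        for lab in TissueLabel:
            for _ in range(12):
                d = (float(rng.uniform(200, 2500))
                     if lab == TissueLabel.EPIDURAL_SPACE else None)
                if d is not None:
                    d = min(d, sd.CLASSIFICATION_GEOMETRY.depth_um)
                f = sd.simulate_frame(lab, app[lab], distance_um=d, rng=rng)
                feats[lab].append(fit_signature_features(f))
    pairs = [(TissueLabel.FAT, TissueLabel.INTERSPINOUS_LIGAMENT),
             (TissueLabel.INTERSPINOUS_LIGAMENT,
              TissueLabel.LIGAMENTUM_FLAVUM),
             (TissueLabel.LIGAMENTUM_FLAVUM, TissueLabel.EPIDURAL_SPACE),
             (TissueLabel.EPIDURAL_SPACE, TissueLabel.SPINAL_CORD)]
    for a, b in pairs:
        fa, fb = np.asarray(feats[a]), np.asarray(feats[b])
        sep = np.abs(fa.mean(0) - fb.mean(0)) / \
            np.sqrt((fa.var(0) + fb.var(0)) / 2 + 1e-12)
        assert sep.max() > 2.0, (a.name, b.name, sep)


def test_confusable_configuration_brings_fat_close_to_cord():
    conf = sd.confusable_appearances()
    fat, cord = conf[TissueLabel.FAT], conf[TissueLabel.SPINAL_CORD]
    assert fat.surface_brightness == cord.surface_brightness
    assert fat.attenuation_length_px == cord.attenuation_length_px
    assert abs(fat.heterogeneity_scale - cord.heterogeneity_scale) < 0.05
    # the default configuration keeps them far apart laterally
    dflt = sd.default_appearances()
    assert dflt[TissueLabel.FAT].heterogeneity_scale > \
        4 * dflt[TissueLabel.SPINAL_CORD].heterogeneity_scale


def test_insertion_sequence_defaults(default_stream):
    assert len(default_stream) == 1150
    assert default_stream.segment_lengths == (100, 700, 100, 100, 150)
    labels = default_stream.labels
    # cumulative-sum boundary: frames 800 and 801 straddle segment 2/3
    assert labels[799] == TissueLabel.INTERSPINOUS_LIGAMENT
    assert labels[800] == TissueLabel.LIGAMENTUM_FLAVUM
    dists = [f.distance_um for f in default_stream.frames
             if f.label == TissueLabel.EPIDURAL_SPACE]
    assert all(a >= b for a, b in zip(dists, dists[1:]))  # needle advances


def test_insertion_sequence_degenerate_segments():
    seq = sd.simulate_insertion_sequence((0, 0, 0, 0, 5), seed=1)
    assert len(seq) == 5
    assert all(f.label == TissueLabel.SPINAL_CORD for f in seq.frames)


def test_insertion_sequence_rejects_bad_lengths():
    with pytest.raises(ValueError):
        sd.simulate_insertion_sequence((1, 2, 3), seed=0)
    with pytest.raises(ValueError):
        sd.simulate_insertion_sequence((1, -1, 1, 1, 1), seed=0)


def test_frame_invariants_validated():
    with pytest.raises(ValueError, match="\\[0, 255\\]"):
        sd.OCTFrame(pixels=np.full((4, 4), 300.0), subject_id=1,
                    label=TissueLabel.FAT)
    with pytest.raises(ValueError, match="distance_um"):
        sd.OCTFrame(pixels=np.zeros((4, 4), np.uint8), subject_id=1,
                    label=TissueLabel.EPIDURAL_SPACE)
    with pytest.raises(ValueError):
        sd.SubjectDataset(subject_id=1, frames=[
            sd.OCTFrame(pixels=np.zeros((4, 4), np.uint8), subject_id=2,
                        label=TissueLabel.FAT)])
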