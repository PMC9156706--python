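"""Synthetic forward-view OCT B-scans of the five epidural tissue layers.

The generator is a phenomenological stand-in for real porcine backbone
imagery.  Each tissue class is rendered from a small set of appearance
parameters — surface brightness, exponential depth attenuation, transverse
banding, lateral heterogeneity, multiplicative speckle and a noise floor —
chosen so the classes carry the qualitative signatures seen on real scans:

* interspinous ligament: deepest penetration plus periodic transverse stripes
  from its thick fiber bundles;
* ligamentum flavum: brightest surface, shallowest penetration;
* fat vs spinal cord: similar depth profile, but fat is laterally uneven
  (adipocyte pockets) while cord backscatter is homogeneous;
* epidural space: a dark gap between the needle tip and the dura surface,
  whose height in pixels encodes the needle-to-dura distance.

A B-scan is stored depth-major: row 0 is the shallowest depth (at the needle
tip), row index grows with Z.  Classification frames are 181 (X) x 241 (Z)
pixels, regression frames 241 (X) x 681 (Z), both at 6.25 um per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

__all__ = [
    "TissueLabel", "FrameGeometry", "OCTFrame", "TissueAppearance",
    "SubjectDataset", "InsertionSequence",
    "CLASSIFICATION_GEOMETRY", "REGRESSION_GEOMETRY", "PIXEL_SIZE_UM",
    "default_appearances", "confusable_appearances",
    "simulate_frame", "simulate_subject", "simulate_insertion_sequence",
    "DEFAULT_SEGMENT_LENGTHS", "DEFAULT_DISTANCE_RANGE_UM",
    "CLASSIFY_DISTANCE_RANGE_UM", "frames_to_array",
]

PIXEL_SIZE_UM = 6.25

#: Insertion-stream segment lengths, in puncture order (frames per layer).
DEFAULT_SEGMENT_LENGTHS = (100, 700, 100, 100, 150)

#: Needle-tip-to-dura distance range for regression frames (um).
DEFAULT_DISTANCE_RANGE_UM = (200.0, 2500.0)

#: Epidural distances are drawn from DEFAULT_DISTANCE_RANGE_UM for every
#: task.  The 241-px classification crop holds at most ~1500 um of gap, so
#: a deeper gap renders as a frame of pure background (the dura lies beyond
#: the imaging depth, as in the real acquisitions) and the stored distance
#: label saturates at the frame depth.
CLASSIFY_DISTANCE_RANGE_UM = DEFAULT_DISTANCE_RANGE_UM

#: e-folding depth (px) of the system's sensitivity/defocus roll-off: signal
#: from deeper structures is attenuated regardless of tissue, as in a real
#: swept-source endoscopic scanner whose focus sits near the lens tip.  At
#: 6.25 um/px this is a 1 mm e-folding, ~ -12 dB at the bottom of the
#: classification crop; a dura surface seen across a deep epidural gap is
#: correspondingly dim.
SENSITIVITY_ROLLOFF_PX = 160.0


class TissueLabel(IntEnum):
    """The five epidural layers, ordered by needle puncture sequence."""

    FAT = 0
    INTERSPINOUS_LIGAMENT = 1
    LIGAMENTUM_FLAVUM = 2
    EPIDURAL_SPACE = 3
    SPINAL_CORD = 4


@dataclass(frozen=True)
class FrameGeometry:
    """Frame size: ``width_px`` along X, ``depth_px`` along Z."""

    width_px: int
    depth_px: int
    pixel_size_um: float = PIXEL_SIZE_UM

    @property
    def depth_um(self) -> float:
        return self.depth_px * self.pixel_size_um


CLASSIFICATION_GEOMETRY = FrameGeometry(width_px=181, depth_px=241)
REGRESSION_GEOMETRY = FrameGeometry(width_px=241, depth_px=681)


@dataclass
class OCTFrame:
    """One 8-bit B-scan with its labels.

    ``distance_um`` (needle tip to dura) is present iff the frame shows the
    epidural space.
    """

    pixels: np.ndarray                      # (depth_px, width_px) uint8
    subject_id: int
    label: TissueLabel
    pixel_size_um: float = PIXEL_SIZE_UM
    distance_um: Optional[float] = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D (depth, width) grid")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.label == TissueLabel.EPIDURAL_SPACE:
            if self.distance_um is None:
                raise ValueError("epidural-space frames require distance_um")
            if not 0 <= self.distance_um <= self.depth_px * self.pixel_size_um:
                raise ValueError(
                    f"distance_um={self.distance_um} outside the frame depth "
                    f"({self.depth_px * self.pixel_size_um} um)")
        elif self.distance_um is not None:
            raise ValueError(
                f"distance_um given for non-epidural label {self.label.name}")

    @property
    def depth_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class TissueAppearance:
    """Generative appearance parameters for one tissue class.

    For the epidural space these describe the dura/cord surface visible
    below the dark gap.
    """

    surface_brightness: float       # peak intensity at the tissue surface
    attenuation_length_px: float    # e-folding depth of the decay
    stripe_period_px: float = 0.0   # transverse band period (0 = no bands)
    stripe_amplitude: float = 0.0   # relative band modulation depth
    heterogeneity_scale: float = 0.0  # lateral low-frequency variation
    speckle_variance: float = 0.25  # unit-mean multiplicative noise variance
    noise_floor: float = 12.0       # mean background intensity

    def scaled(self, m: dict) -> "TissueAppearance":
        """Return a copy with each parameter multiplied by ``m[name]``."""
        return TissueAppearance(**{
            k: getattr(self, k) * m.get(k, 1.0)
            for k in self.__dataclass_fields__})


def default_appearances() -> dict:
    """Per-class defaults satisfying the qualitative orderings above:
    attenuation lig > fat ~ cord > flavum; flavum brightest;
    fat far more heterogeneous than cord; only the ligament striped."""
    return {
        TissueLabel.FAT: TissueAppearance(
            surface_brightness=150, attenuation_length_px=55,
            heterogeneity_scale=0.40, speckle_variance=0.30),
        TissueLabel.INTERSPINOUS_LIGAMENT: TissueAppearance(
            surface_brightness=175, attenuation_length_px=110,
            stripe_period_px=16, stripe_amplitude=0.45,
            heterogeneity_scale=0.10),
        TissueLabel.LIGAMENTUM_FLAVUM: TissueAppearance(
            surface_brightness=235, attenuation_length_px=22,
            heterogeneity_scale=0.10),
        TissueLabel.EPIDURAL_SPACE: TissueAppearance(
            surface_brightness=200, attenuation_length_px=45,
            heterogeneity_scale=0.08),
        TissueLabel.SPINAL_CORD: TissueAppearance(
            surface_brightness=150, attenuation_length_px=55,
            heterogeneity_scale=0.08),
    }


def confusable_appearances() -> dict:
    """Defaults, but with fat rendered statistically close to spinal cord
    (the hard pair for a flat five-class model; the sequential cascade never
    has to tell them apart)."""
    app = default_appearances()
    cord = app[TissueLabel.SPINAL_CORD]
    app[TissueLabel.FAT] = replace(
        cord, heterogeneity_scale=0.10, speckle_variance=0.26)
    return app


@dataclass
class SubjectDataset:
    """All frames simulated for one subject, plus the per-subject appearance
    multipliers that make subjects differ systematically."""

    subject_id: int
    frames: list
    appearance_multipliers: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(f.subject_id != self.subject_id for f in self.frames):
            raise ValueError("all frames must share the dataset's subject_id")


@dataclass
class InsertionSequence:
    """A simulated needle-advance video: frames in puncture order."""

    frames: list
    segment_lengths: tuple

    def __len__(self):
        return len(self.frames)

    @property
    def labels(self):
        return [f.label for f in self.frames]


# ---------------------------------------------------------------------------
# frame synthesis


def _lateral_field(width: int, scale: float, rng) -> np.ndarray:
    """Unit-mean low-frequency lateral modulation with SD ~ ``scale``."""
    if scale <= 0:
        return np.ones(width)
    raw = gaussian_filter1d(rng.standard_normal(width + 60), sigma=12.0,
                            mode="wrap")[30:-30]
    raw = raw / max(raw.std(), 1e-9)
    return np.clip(1.0 + scale * raw, 0.15, None)


def simulate_frame(label: TissueLabel,
                   appearance: TissueAppearance,
                   geometry: FrameGeometry = CLASSIFICATION_GEOMETRY,
                   distance_um: Optional[float] = None,
                   rng: Optional[np.random.Generator] = None,
                   subject_id: int = 1) -> OCTFrame:
    """Render one labeled B-scan.

    For the epidural space ``distance_um`` sets the dark-gap height: rows
    shallower than ``round(distance_um / pixel_size)`` contain only noise
    floor, and the dura surface starts at that row.  Other labels must not
    pass a distance; their surface row is jittered within a few pixels of
    the top (tissue pressed against the needle tip).
    """
    if rng is None:
        rng = np.random.default_rng()
    label = TissueLabel(label)
    depth, width = geometry.depth_px, geometry.width_px
    a = appearance

    if label == TissueLabel.EPIDURAL_SPACE:
        if distance_um is None:
            raise ValueError("EPIDURAL_SPACE requires distance_um")
        if not 0 <= distance_um <= geometry.depth_um:
            raise ValueError(
                f"distance_um={distance_um} exceeds frame depth "
                f"{geometry.depth_um} um")
        z0 = int(round(distance_um / geometry.pixel_size_um))
    else:
        if distance_um is not None:
            raise ValueError(
                f"distance_um only valid for EPIDURAL_SPACE, got {label.name}")
        z0 = int(rng.integers(2, 9))

    z = np.arange(depth)
    profile = np.zeros(depth)
    inside = z >= z0
    profile[inside] = a.surface_brightness * np.exp(
        -(z[inside] - z0) / max(a.attenuation_length_px, 1e-6))
    if a.stripe_period_px > 0 and a.stripe_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        bands = 1.0 + a.stripe_amplitude * np.cos(
            2 * np.pi * (z - z0) / a.stripe_period_px + phase)
        profile *= np.clip(bands, 0.0, None)
    profile *= np.exp(-z / SENSITIVITY_ROLLOFF_PX)

    signal = np.outer(profile, _lateral_field(width, a.heterogeneity_scale, rng))

    if a.speckle_variance > 0:
        shape = 1.0 / a.speckle_variance
        signal = signal * rng.gamma(shape, 1.0 / shape, size=signal.shape)

    background = rng.exponential(a.noise_floor, size=(depth, width))
    img = gaussian_filter(signal + background, sigma=1.0)
    img = np.clip(img, 0, 255).astype(np.uint8)

    return OCTFrame(pixels=img, subject_id=subject_id, label=label,
                    pixel_size_um=geometry.pixel_size_um,
                    distance_um=float(distance_um) if distance_um is not None
                    else None)


# ---------------------------------------------------------------------------
# datasets

# log-normal sigma of the per-subject multiplier for each appearance parameter
_SUBJECT_SIGMA = {
    "surface_brightness": 0.10,
    "attenuation_length_px": 0.10,
    "stripe_period_px": 0.08,
    "stripe_amplitude": 0.15,
    "heterogeneity_scale": 0.15,
    "speckle_variance": 0.15,
    "noise_floor": 0.08,
}


def draw_subject_multipliers(rng) -> dict:
    return {k: float(np.exp(rng.normal(0.0, s)))
            for k, s in _SUBJECT_SIGMA.items()}


def simulate_subject(subject_id: int,
                     appearances: Optional[dict] = None,
                     frames_per_layer: int = 1000,
                     distance_range_um: Optional[tuple] = None,
                     seed: int = 0,
                     task: str = "classify",
                     geometry: Optional[FrameGeometry] = None) -> SubjectDataset:
    """Simulate one subject's frame collection.

    ``task='classify'`` yields ``frames_per_layer`` frames for each of the
    five layers at classification geometry (181 x 241); ``task='regress'``
    yields ``frames_per_layer`` epidural-space frames at regression geometry
    (241 x 681) with distances drawn uniformly from ``distance_range_um``.
    """
    if frames_per_layer < 1:
        raise ValueError("frames_per_layer must be >= 1")
    if task not in ("classify", "regress"):
        raise ValueError(f"unknown task {task!r}")
    appearances = appearances or default_appearances()
    if geometry is None:
        geometry = (CLASSIFICATION_GEOMETRY if task == "classify"
                    else REGRESSION_GEOMETRY)
    if distance_range_um is None:
        distance_range_um = (CLASSIFY_DISTANCE_RANGE_UM if task == "classify"
                             else DEFAULT_DISTANCE_RANGE_UM)
    lo, hi = distance_range_um
    if not 0 <= lo <= hi:
        raise ValueError(f"invalid distance range {distance_range_um}")
    if task == "regress" and hi > geometry.depth_um:
        raise ValueError(
            f"regression distance range {distance_range_um} outside frame "
            f"depth {geometry.depth_um} um")

    rng = np.random.default_rng(seed)
    mult = draw_subject_multipliers(rng)
    scaled = {lab: app.scaled(mult) for lab, app in appearances.items()}

    labels = (list(TissueLabel) if task == "classify"
              else [TissueLabel.EPIDURAL_SPACE])
    frames = []
    for lab in labels:
        for _ in range(frames_per_layer):
            # gaps deeper than the crop render as pure background; the
            # label saturates at the frame depth
            d = (min(float(rng.uniform(lo, hi)), geometry.depth_um)
                 if lab == TissueLabel.EPIDURAL_SPACE else None)
            frames.append(simulate_frame(lab, scaled[lab], geometry,
                                         distance_um=d, rng=rng,
                                         subject_id=subject_id))
    return SubjectDataset(subject_id=subject_id, frames=frames,
                          appearance_multipliers=mult)


def simulate_insertion_sequence(segment_lengths: Sequence[int] = DEFAULT_SEGMENT_LENGTHS,
                                appearances: Optional[dict] = None,
                                seed: int = 0,
                                subject_id: int = 1,
                                distance_range_um: tuple = CLASSIFY_DISTANCE_RANGE_UM
                                ) -> InsertionSequence:
    """Simulate a needle-advance stream: the five layers in puncture order.

    Within the epidural segment the needle approaches the dura, so the
    distance labels decrease monotonically from the top to the bottom of
    ``distance_range_um``.
    """
    segment_lengths = tuple(int(n) for n in segment_lengths)
    if len(segment_lengths) != 5 or any(n < 0 for n in segment_lengths):
        raise ValueError("segment_lengths must be five nonnegative counts")
    appearances = appearances or default_appearances()
    rng = np.random.default_rng(seed)
    mult = draw_subject_multipliers(rng)
    scaled = {lab: app.scaled(mult) for lab, app in appearances.items()}

    lo, hi = distance_range_um
    frames = []
    depth_um = CLASSIFICATION_GEOMETRY.depth_um
    for lab, n in zip(TissueLabel, segment_lengths):
        if lab == TissueLabel.EPIDURAL_SPACE:
            dists = np.minimum(np.linspace(hi, lo, num=max(n, 1))[:n],
                               depth_um)
        for i in range(n):
            d = float(dists[i]) if lab == TissueLabel.EPIDURAL_SPACE else None
            frames.append(simulate_frame(lab, scaled[lab],
                                         CLASSIFICATION_GEOMETRY,
                                         distance_um=d, rng=rng,
                                         subject_id=subject_id))
    return InsertionSequence(frames=frames, segment_lengths=segment_lengths)


def frames_to_array(frames) -> np.ndarray:
    """Stack frames into an (N, depth, width, 1) float32 batch."""
    return np.stack([f.pixels for f in frames]).astype(np.float32)[..., None]
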