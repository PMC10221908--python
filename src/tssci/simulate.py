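"""Parametric simulator of six cyclic physiotherapy exercises.

Emits keypoint time series shaped like single-camera pose-detector
output, so the whole pipeline (normalization, encoding, classification,
generation, scoring) is exercisable without recorded video.  Each
exercise is a set of sinusoidal joint-offset trajectories around a fixed
standing pose, cycled a configurable number of times (default ten) with
idle padding before and after; a noise model adds coordinate jitter and
confidence dropout emulating blurry, unstable home recordings.

The six classes: AFR (arm full range), ARO (arm rotation), LBE (backward
leg extension), LFC (lifting from chair), SLL (side leg lift), TRO
(trunk rotation).  The arm exercises are performed in two parts — right
side cyclically for the first half, then the left side — which is what
draws the central contrast line across their encoded images.  LBE and
SLL both move mostly the leg, deliberately making them the confusable
pair of the set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .codec import Sampler, TSSCIImage, encode, sample_frames_stratified
from .preprocess import DEFAULT_CONFIDENCE_THRESHOLD, orient_buffer
from .scoring import CLASS_LABELS
from .skeleton import MID_HIP, MotionBuffer, TourOrder

#: Standing rest pose, pixel coordinates (x right, y down), exactly
#: mirror-symmetric about x = 200 in a nominal 400x600 frame.
BASE_POSE = np.array([
    (200.0, 110.0),  # 0  Nose
    (200.0, 160.0),  # 1  Neck
    (165.0, 160.0),  # 2  RShoulder
    (150.0, 215.0),  # 3  RElbow
    (145.0, 265.0),  # 4  RWrist
    (235.0, 160.0),  # 5  LShoulder
    (250.0, 215.0),  # 6  LElbow
    (255.0, 265.0),  # 7  LWrist
    (200.0, 300.0),  # 8  MidHip
    (180.0, 300.0),  # 9  RHip
    (175.0, 380.0),  # 10 RKnee
    (172.0, 455.0),  # 11 RAnkle
    (220.0, 300.0),  # 12 LHip
    (225.0, 380.0),  # 13 LKnee
    (228.0, 455.0),  # 14 LAnkle
    (192.0, 100.0),  # 15 REye
    (208.0, 100.0),  # 16 LEye
    (185.0, 105.0),  # 17 REar
    (215.0, 105.0),  # 18 LEar
    (232.0, 475.0),  # 19 LBigToe
    (240.0, 473.0),  # 20 LSmallToe
    (224.0, 462.0),  # 21 LHeel
    (168.0, 475.0),  # 22 RBigToe
    (160.0, 473.0),  # 23 RSmallToe
    (176.0, 462.0),  # 24 RHeel
])

MIDLINE_X = 200.0

#: Left-right joint correspondence (self-paired joints map to themselves).
MIRROR_MAP = {
    0: 0, 1: 1, 8: 8,
    2: 5, 3: 6, 4: 7, 5: 2, 6: 3, 7: 4,
    9: 12, 10: 13, 11: 14, 12: 9, 13: 10, 14: 11,
    15: 16, 16: 15, 17: 18, 18: 17,
    19: 22, 20: 23, 21: 24, 22: 19, 23: 20, 24: 21,
}

Trajectory = Callable[[np.ndarray], np.ndarray]


def _lift(theta: np.ndarray) -> np.ndarray:
    """Smooth 0->1->0 cycle profile."""
    return (1.0 - np.cos(theta)) / 2.0


def _offsets(theta: np.ndarray) -> np.ndarray:
    return np.zeros((len(theta), 25, 2))


def _afr(theta: np.ndarray) -> np.ndarray:
    # Right arm raised from hanging to overhead through its full range.
    off = _offsets(theta)
    lift = _lift(theta)
    off[:, 4] = np.stack([20.0 * lift, -260.0 * lift], axis=1)   # RWrist
    off[:, 3] = np.stack([10.0 * lift, -150.0 * lift], axis=1)   # RElbow
    off[:, 2, 1] = -15.0 * lift                                  # RShoulder
    return off


def _aro(theta: np.ndarray) -> np.ndarray:
    # Right wrist traces a circle (radius 55 px), elbow follows at half.
    off = _offsets(theta)
    off[:, 4] = np.stack([55.0 * np.sin(theta), 55.0 * (np.cos(theta) - 1.0)], axis=1)
    off[:, 3] = np.stack([27.0 * np.sin(theta), 27.0 * (np.cos(theta) - 1.0)], axis=1)
    return off


def _lbe(theta: np.ndarray) -> np.ndarray:
    # Right leg extended backward: foot sweeps up and out, knee follows.
    off = _offsets(theta)
    lift = _lift(theta)
    for j in (11, 22, 23, 24):  # ankle + foot
        off[:, j] = np.stack([-40.0 * lift, -70.0 * lift], axis=1)
    off[:, 10] = np.stack([-20.0 * lift, -35.0 * lift], axis=1)  # RKnee
    off[:, 9, 1] = -8.0 * lift                                   # RHip
    return off


def _lfc(theta: np.ndarray) -> np.ndarray:
    # Sit-to-stand: pelvis and upper body drop and rise, knees bend out.
    off = _offsets(theta)
    sit = _lift(theta)
    upper = (0, 1, 2, 3, 4, 5, 6, 7, 15, 16, 17, 18)
    for j in upper:
        off[:, j, 1] = 110.0 * sit
    for j in (8, 9, 12):  # pelvis
        off[:, j, 1] = 110.0 * sit
    off[:, 10] = np.stack([-25.0 * sit, 55.0 * sit], axis=1)  # RKnee
    off[:, 13] = np.stack([25.0 * sit, 55.0 * sit], axis=1)   # LKnee
    return off


def _sll(theta: np.ndarray) -> np.ndarray:
    # Right leg abducted sideways, knee kept straight.
    off = _offsets(theta)
    lift = _lift(theta)
    for j in (11, 22, 23, 24):
        off[:, j] = np.stack([-110.0 * lift, -25.0 * lift], axis=1)
    off[:, 10] = np.stack([-55.0 * lift, -12.0 * lift], axis=1)  # RKnee
    return off


def _tro(theta: np.ndarray) -> np.ndarray:
    # Hands held to chest, trunk twisting side to side.
    off = _offsets(theta)
    twist = np.sin(theta)
    off[:, 4] = np.stack([40.0 + 25.0 * twist, -75.0 * np.ones_like(twist)], axis=1)
    off[:, 7] = np.stack([-40.0 + 25.0 * twist, -75.0 * np.ones_like(twist)], axis=1)
    off[:, 3] = np.stack([10.0 + 15.0 * twist, -40.0 * np.ones_like(twist)], axis=1)
    off[:, 6] = np.stack([-10.0 + 15.0 * twist, -40.0 * np.ones_like(twist)], axis=1)
    off[:, 2, 0] = 28.0 * twist   # shoulders shift with the twist
    off[:, 5, 0] = 28.0 * twist
    for j in (0, 15, 16, 17, 18):  # head follows
        off[:, j, 0] = 18.0 * twist
    return off


_TRAJECTORIES: dict[str, Trajectory] = {
    "AFR": _afr, "ARO": _aro, "LBE": _lbe, "LFC": _lfc, "SLL": _sll, "TRO": _tro,
}


@dataclass
class ExerciseTemplate:
    """One exercise: trajectory, cycle count, active side, idle padding."""

    label: str
    cycles: int = 10
    side: str = "right"            # "left", "right"; arm exercises override
    two_part: bool = False         # right-side half then mirrored left-side half
    idle_pad_frames: int = 30
    amplitude: float = 1.0         # multiplies all joint offsets
    phase_offset: float = 0.0      # radians, shifts the cycle start
    base_pose: np.ndarray = field(default_factory=lambda: BASE_POSE.copy())

    @property
    def trajectory(self) -> Trajectory:
        return _TRAJECTORIES[self.label]


def default_template(label: str) -> ExerciseTemplate:
    if label not in CLASS_LABELS:
        raise ValueError(f"unknown exercise {label!r}; choose from {CLASS_LABELS}")
    return ExerciseTemplate(label=label, two_part=label in ("AFR", "ARO"))


@dataclass
class NoiseModel:
    """Detector imperfections: jitter, confidence dropout, base confidence."""

    coord_sigma: float = 2.0       # px, Gaussian jitter per coordinate
    dropout_rate: float = 0.05     # P(confidence falls below the 0.3 gate)
    confidence_base: float = 0.9   # mean confidence of visible keypoints
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")


def mirror_offsets(offsets: np.ndarray) -> np.ndarray:
    """Reflect joint offsets about the body midline (swap left/right joints)."""
    out = np.empty_like(offsets)
    for j, m in MIRROR_MAP.items():
        out[:, j, 0] = -offsets[:, m, 0]
        out[:, j, 1] = offsets[:, m, 1]
    return out


def mirror_pose(pose: np.ndarray) -> np.ndarray:
    """Reflect absolute joint positions about the midline."""
    out = np.empty_like(pose)
    for j, m in MIRROR_MAP.items():
        out[..., j, 0] = 2.0 * MIDLINE_X - pose[..., m, 0]
        out[..., j, 1] = pose[..., m, 1]
    return out


def generate_motion(
    template: ExerciseTemplate,
    n_frames: int = 3000,
    fps: float = 30.0,
    noise: NoiseModel | None = None,
    subject_scale: float = 1.0,
) -> MotionBuffer:
    """Simulate one recording of the exercise as a motion buffer.

    Idle padding (base pose) is prepended and appended; the active span
    runs the template's cycles.  Two-part templates perform the right
    side for the first half of the active span and the mirrored left
    side for the second.  Deterministic given the noise model's seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    pad = min(template.idle_pad_frames, max((n_frames - 1) // 2, 0))
    active = n_frames - 2 * pad
    offsets = np.zeros((n_frames, 25, 2))
    if active > 0:
        if template.two_part:
            first = active // 2
            parts = []
            for length, mirrored in ((first, False), (active - first, True)):
                if length == 0:
                    continue
                theta = (
                    2.0 * np.pi * template.cycles * np.arange(length) / max(length, 1)
                    + template.phase_offset
                )
                part = template.trajectory(theta)
                parts.append(mirror_offsets(part) if mirrored else part)
            offsets[pad : pad + active] = np.concatenate(parts)
        else:
            theta = (
                2.0 * np.pi * template.cycles * np.arange(active) / active
                + template.phase_offset
            )
            part = template.trajectory(theta)
            if template.side == "left":
                part = mirror_offsets(part)
            offsets[pad : pad + active] = part
    coords = template.base_pose[None, :, :] + template.amplitude * offsets
    if subject_scale != 1.0:
        center = template.base_pose[MID_HIP]
        coords = center[None, None, :] + subject_scale * (coords - center[None, None, :])

    data = np.empty((n_frames, 25, 3))
    data[..., :2] = coords
    if noise is None:
        data[..., 2] = 0.95
    else:
        rng = np.random.default_rng(noise.seed)
        data[..., :2] += rng.normal(0.0, noise.coord_sigma, size=coords.shape)
        visible = np.clip(
            rng.normal(noise.confidence_base, 0.05, size=(n_frames, 25)),
            DEFAULT_CONFIDENCE_THRESHOLD + 0.05,
            1.0,
        )
        dropped = rng.random((n_frames, 25)) < noise.dropout_rate
        low = rng.uniform(0.0, DEFAULT_CONFIDENCE_THRESHOLD * 0.8, size=(n_frames, 25))
        data[..., 2] = np.where(dropped, low, visible)
    return MotionBuffer(data, fps=fps)


def perturb_orientation(buffer: MotionBuffer, angle: int) -> MotionBuffer:
    """Rotate every frame by 90/180/270 degrees (orientation test fixture)."""
    if angle not in (90, 180, 270):
        raise ValueError(f"angle must be 90, 180 or 270, got {angle}")
    return orient_buffer(buffer, angle)


def generate_dataset(
    n_per_class: int,
    noise: NoiseModel | None = None,
    sampler: Sampler = sample_frames_stratified,
    seed: int = 0,
    n_frames: int = 1000,
    fps: float = 30.0,
    rows: int = 49,
    tour: TourOrder | None = None,
) -> list[TSSCIImage]:
    """Encoded, labeled images for all six classes with randomized subjects.

    Per image, the cycle phase, movement amplitude (+-20%), and subject
    scale (+-15%) are randomized, and the sampler draws its own rows.
    Deterministic given the master seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if noise is None:
        noise = NoiseModel()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(CLASS_LABELS) * n_per_class)
    images: list[TSSCIImage] = []
    for ci, label in enumerate(CLASS_LABELS):
        for i in range(n_per_class):
            child = children[ci * n_per_class + i]
            rng = np.random.default_rng(child)
            template = default_template(label)
            template.amplitude = rng.uniform(0.8, 1.2)
            template.phase_offset = rng.uniform(0.0, 2.0 * np.pi)
            scale = rng.uniform(0.85, 1.15)
            noise_i = replace(noise, seed=int(rng.integers(2**31)))
            buffer = generate_motion(
                template, n_frames=n_frames, fps=fps, noise=noise_i, subject_scale=scale
            )
            images.append(
                encode(
                    buffer,
                    tour=tour,
                    sampler=sampler,
                    seed=int(rng.integers(2**31)),
                    rows=rows,
                    label=label,
                )
            )
    return images
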