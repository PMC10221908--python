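"""Encode a motion buffer as a single color image, and decode it back.

The image (default 49x49x3) has one row per sampled frame and one column
per Euler-tour position; channels hold the min-max-normalized x (red),
y (green) and the raw detector confidence (blue).  A whole exercise thus
becomes one static object that any image model can consume.

Lossless interchange is a float array (``.npz``) with a JSON sidecar
carrying the normalization parameters; PNG (8-bit) is provided for
visualization and interchange at quantization precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from PIL import Image

from .errors import InsufficientFramesError, MissingParamsError
from .preprocess import (
    DEFAULT_CONFIDENCE_THRESHOLD,
    NormalizationParams,
    complete_rows,
    denormalize_coords,
    minmax_normalize_buffer,
)
from .skeleton import N_JOINTS, MotionBuffer, TourOrder, body25_tour

DEFAULT_ROWS = 49

Sampler = Callable[[int, int, int], np.ndarray]


@dataclass
class TSSCIImage:
    """Rows x cols x 3 float image in [0, 1] plus its normalization sidecar."""

    pixels: np.ndarray
    params: NormalizationParams | None = None
    label: str | None = None
    source_positions: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected (rows, cols, 3) pixels, got {self.pixels.shape}")

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class EditWindow:
    """Half-open [start_frame, end_frame) trim of one video, 0-based."""

    video_id: str
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_frame < self.end_frame:
            raise ValueError(
                f"need 0 <= start < end, got [{self.start_frame}, {self.end_frame})"
            )


def read_edit_windows(csv_path: str | Path) -> dict[str, EditWindow]:
    """Edit CSV with header ``video_id,start_frame,end_frame``."""
    import pandas as pd

    table = pd.read_csv(csv_path)
    required = {"video_id", "start_frame", "end_frame"}
    if not required.issubset(table.columns):
        raise ValueError(f"edit CSV must have columns {sorted(required)}")
    return {
        str(row.video_id): EditWindow(str(row.video_id), int(row.start_frame), int(row.end_frame))
        for row in table.itertuples()
    }


def apply_edit_window(buffer: MotionBuffer, window: EditWindow | None) -> MotionBuffer:
    """Trim the buffer to [start, end) of its frame indices; None is identity."""
    if window is None:
        return buffer
    idx = buffer.frame_indices
    if window.start_frame < idx[0] or window.end_frame > idx[-1] + 1:
        raise ValueError(
            f"window [{window.start_frame}, {window.end_frame}) outside "
            f"buffer frames [{idx[0]}, {idx[-1] + 1})"
        )
    keep = np.nonzero((idx >= window.start_frame) & (idx < window.end_frame))[0]
    return buffer.subset(keep)


def sample_frames_uniform_random(n_total: int, k: int, seed: int) -> np.ndarray:
    """k distinct frame indices drawn uniformly, returned in time order.

    Random (rather than regular) sampling lets encoded rows reflect
    acceleration and deceleration within the exercise.
    """
    if n_total < k:
        raise InsufficientFramesError(f"need {k} frames, have {n_total}")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_total, size=k, replace=False))


def sample_frames_stratified(n_total: int, k: int, seed: int) -> np.ndarray:
    """One frame drawn from each of k equal consecutive segments.

    Segment i is [floor(i*n/k), floor((i+1)*n/k)); stratification smooths
    out fluctuations and internal accelerations.
    """
    if n_total < k:
        raise InsufficientFramesError(f"need {k} frames, have {n_total}")
    rng = np.random.default_rng(seed)
    bounds = (np.arange(k + 1) * n_total) // k
    return np.array([rng.integers(bounds[i], bounds[i + 1]) for i in range(k)])


def encode(
    buffer: MotionBuffer,
    tour: TourOrder | None = None,
    sampler: Sampler = sample_frames_stratified,
    seed: int = 0,
    rows: int = DEFAULT_ROWS,
    threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    eq4_literal: bool = False,
    label: str | None = None,
) -> TSSCIImage:
    """Encode a buffer: sample rows, normalize jointly, expand, complete.

    Pipeline: the sampler picks ``rows`` frames in time order; the sampled
    frames are min-max normalized *together*; each frame's 25 keypoints
    are expanded to the tour's columns; low-confidence positions are
    completed from the left; rows are stacked top (earliest) to bottom.
    """
    tour = tour or body25_tour()
    positions = np.asarray(sampler(len(buffer), rows, seed))
    sampled = buffer.subset(positions)
    normalized, params = minmax_normalize_buffer(sampled, threshold, eq4_literal)
    expanded = normalized.data[:, list(tour.sequence), :]  # (rows, cols, 3)
    pixels = complete_rows(expanded, threshold)
    return TSSCIImage(pixels, params=params, label=label, source_positions=positions)


def decode(
    image: TSSCIImage,
    tour: TourOrder | None = None,
    collapse: str = "mean",
) -> MotionBuffer:
    """Decode an image back into a motion buffer (one frame per row).

    Each row's tour columns are collapsed to 25 joints — by the arithmetic
    mean of a joint's duplicate columns (default; generated images show
    minor divergence between duplicates) or by the first instance — and
    de-normalized through the image's parameter sidecar.
    """
    if image.params is None:
        raise MissingParamsError("image has no normalization sidecar; cannot decode")
    tour = tour or body25_tour()
    if image.cols != len(tour):
        raise ValueError(f"image has {image.cols} cols, tour has {len(tour)}")
    if collapse not in ("mean", "first"):
        raise ValueError("collapse must be 'mean' or 'first'")
    joints = np.zeros((image.rows, N_JOINTS, 3))
    for joint, positions in tour.duplicate_groups.items():
        cols = image.pixels[:, list(positions), :]
        joints[:, joint, :] = cols.mean(axis=1) if collapse == "mean" else cols[:, 0, :]
    restored = denormalize_coords(joints, image.params)
    restored[..., 2] = joints[..., 2]
    return MotionBuffer(restored)


# ---------------------------------------------------------------------------
# Storage


def save_tssci(image: TSSCIImage, path: str | Path) -> None:
    """Lossless container: float array (.npz) + JSON params sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), pixels=image.pixels)
    sidecar: dict = {"label": image.label}
    if image.params is not None:
        sidecar["params"] = {
            "x_min": image.params.x_min,
            "x_len": image.params.x_len,
            "y_min": image.params.y_min,
            "y_len": image.params.y_len,
            "confidence_threshold": image.params.confidence_threshold,
            "eq4_literal": image.params.eq4_literal,
        }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_tssci(path: str | Path) -> TSSCIImage:
    path = Path(path)
    pixels = np.load(path.with_suffix(".npz"))["pixels"]
    params = label = None
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        label = sidecar.get("label")
        if sidecar.get("params"):
            params = NormalizationParams(**sidecar["params"])
    return TSSCIImage(pixels, params=params, label=label)


def write_png(image: TSSCIImage, path: str | Path) -> None:
    """8-bit PNG for visualization; quantization error <= 1/510 per channel."""
    quantized = np.round(np.clip(image.pixels, 0.0, 1.0) * 255.0).astype(np.uint8)
    Image.fromarray(quantized, mode="RGB").save(path)


def read_png(path: str | Path, params: NormalizationParams | None = None) -> TSSCIImage:
    pixels = np.asarray(Image.open(path).convert("RGB"), dtype=float) / 255.0
    return TSSCIImage(pixels, params=params)
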