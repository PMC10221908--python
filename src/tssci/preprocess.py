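"""Confidence gating, orientation correction and coordinate normalization.

Two normalizations are used at different stages:

* *Centering* maps each axis affinely onto [-0.5, +0.5]
  (``xn = x/(max-min) - (max+min)/(2(max-min))``), which is the frame in
  which the 90/180/270-degree orientation fixes are pure coordinate
  swaps/negations; it is inverted afterwards so downstream code sees
  original-scale pixels.
* *Min-max* maps the gated keypoints of an entire buffer jointly onto
  [0, 1], producing the pixel values of the encoded image.  Gating drops
  keypoints whose confidence is below a threshold (default 0.3): their
  coordinates are detector noise.

Missing (gated-out) tour positions are filled by "completing from the
left": each takes the value of its nearest valid neighbor to the left,
cascading so a filled value can serve later positions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateExtentError, EmptyGateError, IndeterminateOrientationError
from .skeleton import MID_HIP, NECK, MotionBuffer

DEFAULT_CONFIDENCE_THRESHOLD = 0.3

#: Named alternative whole-buffer normalization strategies.  Only
#: ``minmax`` is wired into the encoding pipeline; the others are exposed
#: for experimentation on raw coordinate arrays.
NORMALIZATION_STRATEGIES = ("minmax", "zscore", "zeromean", "rms", "unitnorm")


@dataclass
class NormalizationParams:
    """Min-max parameters of one encoded buffer (needed to decode).

    ``eq4_literal`` selects the scale-only form ``x/xL`` instead of the
    default ``(x - xmin)/xL``; the flag is recorded so decoding inverts
    whichever form produced the image.
    """

    x_min: float
    x_len: float
    y_min: float
    y_len: float
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
    eq4_literal: bool = False

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationParams":
        with open(path) as fh:
            return cls(**json.load(fh))


def center_normalize(values) -> np.ndarray:
    """Affinely map values onto [-0.5, +0.5] (endpoints attained)."""
    values = np.asarray(values, dtype=float)
    vmax, vmin = float(values.max()), float(values.min())
    extent = vmax - vmin
    if extent == 0.0:
        raise DegenerateExtentError("all values equal; cannot center-normalize")
    return values / extent - (vmax + vmin) / (2.0 * extent)


def restore_coordinates(normalized, vmin: float, vmax: float) -> np.ndarray:
    """Invert :func:`center_normalize` given the original extent."""
    normalized = np.asarray(normalized, dtype=float)
    return (vmax - vmin) * normalized + (vmax + vmin) / 2.0


_ROTATIONS = {
    # (x, y) -> rotated (x, y), counterclockwise, on centered coordinates
    90: lambda x, y: (y, -x),
    180: lambda x, y: (-x, -y),
    270: lambda x, y: (-y, x),
}


def rotate(keypoints: np.ndarray, angle: int) -> np.ndarray:
    """Rotate centered keypoints by 90/180/270 degrees CCW.

    ``keypoints`` is (..., 3); confidence is untouched.  Coordinates are
    expected to be center-normalized (the swaps assume a symmetric range).
    """
    if angle not in _ROTATIONS:
        raise ValueError(f"angle must be one of {sorted(_ROTATIONS)}, got {angle}")
    keypoints = np.asarray(keypoints, dtype=float)
    out = keypoints.copy()
    rx, ry = _ROTATIONS[angle](keypoints[..., 0], keypoints[..., 1])
    out[..., 0], out[..., 1] = rx, ry
    return out


def detect_orientation(
    buffer: MotionBuffer, threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
) -> int:
    """Correcting rotation (0/90/180/270 CCW) for a mis-oriented recording.

    Home recordings arrive in four orientations (upright, lying on either
    side, upside down).  The heuristic takes the median neck-to-mid-hip
    vector over confident frames and returns the rotation after which it
    points downward in image coordinates (y growing down).  An explicit
    user-supplied angle should take precedence over this heuristic.
    """
    neck = buffer.data[:, NECK]
    hip = buffer.data[:, MID_HIP]
    ok = (neck[:, 2] >= threshold) & (hip[:, 2] >= threshold)
    if not np.any(ok):
        raise IndeterminateOrientationError("no frame with confident neck and mid-hip")
    vx = float(np.median(hip[ok, 0] - neck[ok, 0]))
    vy = float(np.median(hip[ok, 1] - neck[ok, 1]))
    best, best_down = 0, -np.inf
    for angle in (0, 90, 180, 270):
        if angle == 0:
            rx, ry = vx, vy
        else:
            rx, ry = _ROTATIONS[angle](vx, vy)
        if ry > best_down:  # most downward-pointing trunk wins
            best, best_down = angle, ry
    return best


def orient_buffer(buffer: MotionBuffer, angle: int) -> MotionBuffer:
    """Apply a 90/180/270 rotation to every frame, in original scale.

    Centers each axis, applies the coordinate swap, then restores scale;
    for 90/270 the long/short frame sides swap, so x is restored with the
    pre-rotation y extent and vice versa.  ``angle = 0`` is the identity.
    """
    if angle == 0:
        return buffer
    if angle not in _ROTATIONS:
        raise ValueError(f"angle must be one of (0, 90, 180, 270), got {angle}")
    xs, ys = buffer.data[..., 0], buffer.data[..., 1]
    x_min, x_max = float(xs.min()), float(xs.max())
    y_min, y_max = float(ys.min()), float(ys.max())
    centered = buffer.data.copy()
    centered[..., 0] = center_normalize(xs)
    centered[..., 1] = center_normalize(ys)
    rotated = rotate(centered, angle)
    out = rotated.copy()
    if angle == 180:
        out[..., 0] = restore_coordinates(rotated[..., 0], x_min, x_max)
        out[..., 1] = restore_coordinates(rotated[..., 1], y_min, y_max)
    else:  # frame sides swap
        out[..., 0] = restore_coordinates(rotated[..., 0], y_min, y_max)
        out[..., 1] = restore_coordinates(rotated[..., 1], x_min, x_max)
    return MotionBuffer(
        out,
        fps=buffer.fps,
        frame_indices=buffer.frame_indices.copy(),
        first_time_mark=buffer.first_time_mark,
        last_time_mark=buffer.last_time_mark,
    )


def minmax_normalize_buffer(
    buffer: MotionBuffer,
    threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    eq4_literal: bool = False,
) -> tuple[MotionBuffer, NormalizationParams]:
    """Jointly min-max normalize every frame of the buffer onto [0, 1].

    The extents are computed over the *gated* keypoints (c >= threshold)
    of all frames together, so skeletons stay mutually consistent from
    frame to frame.  Gated coordinates land exactly in [0, 1]; ungated
    ones (noise, later overwritten by left-completion) are clipped into
    range.  The confidence channel passes through unchanged.
    """
    gate = buffer.data[..., 2] >= threshold
    if not np.any(gate):
        raise EmptyGateError(f"no keypoint with confidence >= {threshold}")
    gx = buffer.data[..., 0][gate]
    gy = buffer.data[..., 1][gate]
    x_min, x_len = float(gx.min()), float(np.ptp(gx))
    y_min, y_len = float(gy.min()), float(np.ptp(gy))
    if x_len == 0.0 or y_len == 0.0:
        raise DegenerateExtentError("gated keypoints have zero extent on an axis")
    params = NormalizationParams(x_min, x_len, y_min, y_len, threshold, eq4_literal)
    out = buffer.data.copy()
    if eq4_literal:
        # printed scale-only form; lands in [0, 1] only when x_min = 0,
        # so it is reproduced verbatim, without clipping
        out[..., 0] = out[..., 0] / x_len
        out[..., 1] = out[..., 1] / y_len
    else:
        out[..., 0] = np.clip((out[..., 0] - x_min) / x_len, 0.0, 1.0)
        out[..., 1] = np.clip((out[..., 1] - y_min) / y_len, 0.0, 1.0)
    normalized = MotionBuffer(
        out,
        fps=buffer.fps,
        frame_indices=buffer.frame_indices.copy(),
        first_time_mark=buffer.first_time_mark,
        last_time_mark=buffer.last_time_mark,
    )
    return normalized, params


def denormalize_coords(
    normalized: np.ndarray, params: NormalizationParams
) -> np.ndarray:
    """Invert :func:`minmax_normalize_buffer` on a (..., 3) array."""
    out = np.asarray(normalized, dtype=float).copy()
    if params.eq4_literal:
        out[..., 0] = out[..., 0] * params.x_len
        out[..., 1] = out[..., 1] * params.y_len
    else:
        out[..., 0] = out[..., 0] * params.x_len + params.x_min
        out[..., 1] = out[..., 1] * params.y_len + params.y_min
    return out


def complete_from_left(
    row: np.ndarray, threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
) -> np.ndarray:
    """Fill low-confidence tour positions from their left neighbor.

    ``row`` is (tour_length, 3) in tour order.  Every position whose
    confidence is below the threshold takes the full (x, y, c) value of
    the nearest valid position to its left; fills cascade left-to-right,
    so a filled position serves the ones after it.  Positions before the
    first valid one borrow from the nearest valid position on the right;
    an entirely missing row becomes all zeros.
    """
    row = np.asarray(row, dtype=float)
    out = row.copy()
    valid = row[:, 2] >= threshold
    if not np.any(valid):
        return np.zeros_like(row)
    first_valid = int(np.argmax(valid))
    out[:first_valid] = row[first_valid]
    last = row[first_valid]
    for i in range(first_valid, len(row)):
        if valid[i]:
            last = row[i]
        else:
            out[i] = last
    return out


def complete_rows(
    rows: np.ndarray, threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
) -> np.ndarray:
    """Apply :func:`complete_from_left` to each row of (n, tour, 3)."""
    return np.stack([complete_from_left(r, threshold) for r in rows])


# -- alternative whole-array normalizations (not part of the default path) --


def normalize_strategy(values: np.ndarray, strategy: str) -> np.ndarray:
    """Apply a named normalization to a coordinate array.

    ``minmax`` maps onto [0, 1]; ``zscore`` to zero mean / unit SD;
    ``zeromean`` subtracts the mean; ``rms`` scales the root-mean-square
    to one; ``unitnorm`` scales the L2 norm to one.
    """
    values = np.asarray(values, dtype=float)
    if strategy == "minmax":
        extent = np.ptp(values)
        if extent == 0:
            raise DegenerateExtentError("zero extent")
        return (values - values.min()) / extent
    if strategy == "zscore":
        sd = values.std()
        if sd == 0:
            raise DegenerateExtentError("zero standard deviation")
        return (values - values.mean()) / sd
    if strategy == "zeromean":
        return values - values.mean()
    if strategy == "rms":
        rms = np.sqrt(np.mean(values**2))
        if rms == 0:
            raise DegenerateExtentError("zero RMS")
        return values / rms
    if strategy == "unitnorm":
        norm = np.linalg.norm(values)
        if norm == 0:
            raise DegenerateExtentError("zero norm")
        return values / norm
    raise ValueError(f"unknown strategy {strategy!r}; choose from {NORMALIZATION_STRATEGIES}")
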