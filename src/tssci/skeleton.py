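"""Body-25 skeleton graph, Euler-tour column ordering, and OpenPose input.

A pose time series is re-represented as an image whose columns follow a
depth-first *Euler tour* of the skeleton tree: the walk re-emits a joint
every time it returns to it, so adjacent columns are always adjacent
joints of the body graph.  For a tree with E edges the tour has 2E + 1
entries; the 25-joint OpenPose BODY_25 graph (24 edges) therefore yields
49 columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .errors import MalformedTreeError

N_JOINTS = 25
TOUR_LENGTH = 49

#: OpenPose BODY_25 joint names, in index order.
JOINT_NAMES = (
    "Nose", "Neck", "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist", "MidHip", "RHip",
    "RKnee", "RAnkle", "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar", "LBigToe",
    "LSmallToe", "LHeel", "RBigToe", "RSmallToe", "RHeel",
)

NOSE, NECK, MID_HIP = 0, 1, 8

# Canonical child ordering: left-side branches before right-side ones,
# distal chains before sibling branches.  This ordering is what makes the
# tour open with 0, 1, 5, 6, 7, 6, 5, 1, 8, 12, ...
_BODY25_CHILDREN: Mapping[int, tuple[int, ...]] = {
    0: (1, 16, 15),
    1: (5, 8, 2),
    2: (3,),
    3: (4,),
    5: (6,),
    6: (7,),
    8: (12, 9),
    9: (10,),
    10: (11,),
    11: (22, 24),
    12: (13,),
    13: (14,),
    14: (19, 21),
    15: (17,),
    16: (18,),
    19: (20,),
    22: (23,),
}


class Keypoint2D(NamedTuple):
    """One joint observation: coordinates plus detector confidence in [0, 1]."""

    x: float
    y: float
    c: float


@dataclass(frozen=True)
class SkeletonFrame:
    """Exactly 25 keypoints (as a (25, 3) float array) at one frame index."""

    keypoints: np.ndarray
    frame_index: int = 0
    missing: bool = False

    def __post_init__(self) -> None:
        kp = np.asarray(self.keypoints, dtype=float)
        if kp.shape != (N_JOINTS, 3):
            raise ValueError(f"expected ({N_JOINTS}, 3) keypoints, got {kp.shape}")
        object.__setattr__(self, "keypoints", kp)

    def keypoint(self, joint: int) -> Keypoint2D:
        return Keypoint2D(*self.keypoints[joint])


@dataclass
class MotionBuffer:
    """Ordered skeleton frames with frame rate and first/last time marks.

    ``data`` is the (n_frames, 25, 3) stack of keypoints; ``frame_indices``
    keeps the original (strictly increasing) video frame numbers so that
    edit windows and sampling refer to real positions in the video.
    """

    data: np.ndarray
    fps: float = 30.0
    frame_indices: np.ndarray | None = None
    first_time_mark: float = 0.0
    last_time_mark: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1:] != (N_JOINTS, 3):
            raise ValueError(f"expected (n, {N_JOINTS}, 3) data, got {self.data.shape}")
        if self.frame_indices is None:
            self.frame_indices = np.arange(len(self.data))
        else:
            self.frame_indices = np.asarray(self.frame_indices, dtype=int)
            if np.any(np.diff(self.frame_indices) <= 0):
                raise ValueError("frame indices must be strictly increasing")
        if self.last_time_mark is None:
            self.last_time_mark = self.first_time_mark + max(len(self.data) - 1, 0) / self.fps
        if self.last_time_mark < self.first_time_mark:
            raise ValueError("last_time_mark must be >= first_time_mark")

    def __len__(self) -> int:
        return len(self.data)

    def frame(self, i: int) -> SkeletonFrame:
        return SkeletonFrame(self.data[i], int(self.frame_indices[i]))

    def subset(self, positions: Sequence[int]) -> "MotionBuffer":
        positions = np.asarray(positions, dtype=int)
        return MotionBuffer(
            self.data[positions],
            fps=self.fps,
            frame_indices=self.frame_indices[positions],
            first_time_mark=self.first_time_mark + float(positions[0]) / self.fps,
            last_time_mark=self.first_time_mark + float(positions[-1]) / self.fps,
        )


@dataclass(frozen=True)
class SkeletonTree:
    """Rooted tree over the joints; child order fixes the tour."""

    n_nodes: int
    root: int
    children: Mapping[int, tuple[int, ...]]

    @property
    def edges(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (parent, child)
            for parent, kids in sorted(self.children.items())
            for child in kids
        )

    def validate(self) -> None:
        edges = self.edges
        if len(edges) != self.n_nodes - 1:
            raise MalformedTreeError(
                f"tree on {self.n_nodes} nodes needs {self.n_nodes - 1} edges, has {len(edges)}"
            )
        seen: set[int] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node in seen:
                raise MalformedTreeError(f"node {node} reached twice: cycle")
            seen.add(node)
            stack.extend(self.children.get(node, ()))
        if len(seen) != self.n_nodes:
            raise MalformedTreeError(
                f"only {len(seen)} of {self.n_nodes} nodes reachable from root"
            )


@dataclass(frozen=True)
class TourOrder:
    """Euler-tour joint sequence defining the image columns.

    ``duplicate_groups`` maps each joint to the (sorted) tour positions at
    which it appears; the groups partition ``range(len(sequence))``.
    """

    sequence: tuple[int, ...]
    duplicate_groups: Mapping[int, tuple[int, ...]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.duplicate_groups is None:
            groups: dict[int, list[int]] = {}
            for pos, joint in enumerate(self.sequence):
                groups.setdefault(joint, []).append(pos)
            object.__setattr__(
                self, "duplicate_groups", {j: tuple(p) for j, p in groups.items()}
            )

    def __len__(self) -> int:
        return len(self.sequence)


def build_body25_tree() -> SkeletonTree:
    """The fixed BODY_25 limb graph rooted at the nose (joint 0)."""
    tree = SkeletonTree(n_nodes=N_JOINTS, root=NOSE, children=_BODY25_CHILDREN)
    tree.validate()
    return tree


def euler_tour(tree: SkeletonTree) -> TourOrder:
    """DFS walk re-emitting a node each time the walk returns to it.

    Raises :class:`MalformedTreeError` for cyclic or disconnected input.
    """
    tree.validate()
    sequence: list[int] = []

    def walk(node: int) -> None:
        sequence.append(node)
        for child in tree.children.get(node, ()):
            walk(child)
            sequence.append(node)

    walk(tree.root)
    return TourOrder(tuple(sequence))


#: Frozen canonical tour of the BODY_25 tree (regression-tested against
#: :func:`euler_tour`).  Columns of every encoded image follow this order.
CANONICAL_TOUR: tuple[int, ...] = (
    0, 1, 5, 6, 7, 6, 5, 1, 8, 12, 13, 14, 19, 20, 19, 14, 21,
    14, 13, 12, 8, 9, 10, 11, 22, 23, 22, 11, 24, 11, 10, 9, 8,
    1, 2, 3, 4, 3, 2, 1, 0, 16, 18, 16, 0, 15, 17, 15, 0,
)


def body25_tour() -> TourOrder:
    """Canonical 49-position tour used throughout the package."""
    return TourOrder(CANONICAL_TOUR)


def select_primary_skeleton(
    detections: Sequence[np.ndarray], frame_index: int = 0
) -> SkeletonFrame:
    """First detected skeleton in the frame, or a zero-confidence frame.

    Detectors list people in detection order; the first one is taken as
    the subject.  An empty frame yields 25 keypoints with c = 0, flagged
    ``missing``, so long videos with detector dropouts still encode.
    """
    if len(detections) == 0:
        return SkeletonFrame(np.zeros((N_JOINTS, 3)), frame_index, missing=True)
    return SkeletonFrame(np.asarray(detections[0], dtype=float), frame_index)


# ---------------------------------------------------------------------------
# OpenPose JSON input/output


def _people_to_arrays(people: Iterable[Mapping]) -> list[np.ndarray]:
    out = []
    for person in people:
        flat = np.asarray(person["pose_keypoints_2d"], dtype=float)
        out.append(flat.reshape(N_JOINTS, 3))
    return out


def read_openpose_frame(path: str | Path) -> list[np.ndarray]:
    """Candidate (25, 3) skeletons from one per-frame OpenPose JSON file."""
    with open(path) as fh:
        doc = json.load(fh)
    return _people_to_arrays(doc.get("people", []))


def load_openpose_dir(directory: str | Path, fps: float = 30.0) -> MotionBuffer:
    """Assemble a buffer from a directory of per-frame ``*_keypoints.json``.

    Files are taken in sorted name order (OpenPose zero-pads frame numbers,
    so lexicographic order is frame order).
    """
    paths = sorted(Path(directory).glob("*_keypoints.json"))
    if not paths:
        paths = sorted(Path(directory).glob("*.json"))
    frames = [
        select_primary_skeleton(read_openpose_frame(p), i).keypoints
        for i, p in enumerate(paths)
    ]
    return MotionBuffer(np.stack(frames), fps=fps)


def load_openpose_array(path: str | Path) -> MotionBuffer:
    """One-file-per-video variant: ``{"fps": ..., "frames": [[75 floats], ...]}``."""
    with open(path) as fh:
        doc = json.load(fh)
    frames = np.asarray(doc["frames"], dtype=float).reshape(-1, N_JOINTS, 3)
    return MotionBuffer(frames, fps=float(doc.get("fps", 30.0)))


def write_openpose_dir(buffer: MotionBuffer, directory: str | Path) -> None:
    """Write a buffer as standard per-frame OpenPose JSON files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(len(buffer)):
        doc = {
            "version": 1.3,
            "people": [
                {"pose_keypoints_2d": [round(v, 6) for v in buffer.data[i].ravel()]}
            ],
        }
        name = f"frame_{int(buffer.frame_indices[i]):012d}_keypoints.json"
        with open(directory / name, "w") as fh:
            json.dump(doc, fh)
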