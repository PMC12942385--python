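"""Occluder-pose classification from fiducial-marker sets and iris landmarks.

The 3D-printed occluder carries four ArUco markers: id 1 (occluder raised to
cover the right eye, i.e. testing the LEFT eye), id 2 (covering the left
eye, testing the RIGHT eye), and ids 3 / 4 on the pinhole flap for the left
and right test poses respectively. A frame's detected id set maps to one of
five labels -- Left, Right, Left_ph, Right_ph, Invalid -- and a geometric
check verifies that the covered eye's iris actually sits inside the
occluder's bounding region (full occlusion usually hides the landmark
entirely, which counts as covered). Singleton pinhole-marker detections
({3} or {4}) fall back to the base eye pose: a partially lowered pinhole
flap still reads as a valid base pose, reproducing the validation table of
the physical system as observed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

LEFT_FAMILY = frozenset({1, 3})
RIGHT_FAMILY = frozenset({2, 4})
VALID_IDS = LEFT_FAMILY | RIGHT_FAMILY


class PoseError(ValueError):
    pass


class PoseLabel(str, Enum):
    LEFT = "Left"
    RIGHT = "Right"
    LEFT_PH = "Left_ph"
    RIGHT_PH = "Right_ph"
    INVALID = "Invalid"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


@dataclass(frozen=True)
class Box:
    """Axis-aligned bounding region from four corner points (pixels,
    origin top-left, x right / y down)."""

    corners: tuple[tuple[float, float], ...]

    @property
    def x_min(self) -> float:
        return min(p[0] for p in self.corners)

    @property
    def x_max(self) -> float:
        return max(p[0] for p in self.corners)

    @property
    def y_min(self) -> float:
        return min(p[1] for p in self.corners)

    @property
    def y_max(self) -> float:
        return max(p[1] for p in self.corners)

    @property
    def diagonal(self) -> float:
        return math.hypot(self.x_max - self.x_min, self.y_max - self.y_min)

    @classmethod
    def from_center(cls, cx: float, cy: float, w: float, h: float) -> "Box":
        return cls(
            corners=(
                (cx - w / 2, cy - h / 2),
                (cx + w / 2, cy - h / 2),
                (cx + w / 2, cy + h / 2),
                (cx - w / 2, cy + h / 2),
            )
        )

    def union(self, other: "Box") -> "Box":
        return Box(corners=self.corners + other.corners)

    def contains(self, point: tuple[float, float], margin_frac: float = 0.0) -> bool:
        m = margin_frac * self.diagonal
        x, y = point
        return (self.x_min - m) <= x <= (self.x_max + m) and (self.y_min - m) <= y <= (self.y_max + m)


@dataclass(frozen=True)
class PoseObservation:
    """One frame's detections: marker ids with their boxes plus iris and
    face landmarks (``None`` when the landmark was not found)."""

    marker_ids: frozenset[int]
    marker_boxes: dict = field(default_factory=dict)
    iris_left: Optional[tuple[float, float]] = None
    iris_right: Optional[tuple[float, float]] = None
    face_box: Optional[Box] = None
    frame_index: int = 0

    def __post_init__(self) -> None:
        missing = [i for i in self.marker_ids if i not in self.marker_boxes]
        if missing:
            raise PoseError(f"marker ids {missing} lack bounding boxes")


@dataclass(frozen=True)
class PoseClassification:
    label: PoseLabel
    iris_check_passed: bool
    source_ids: frozenset[int]
    reason: str = ""


#: Expected classification for the nine validation poses (golden table):
#: pose id -> final label. Poses 5-9 are physically invalid; 7 and 8 still
#: read as valid base poses because the hidden pinhole marker is the only
#: cue that the flap moved.
EXPECTED_FINAL_POSE = {
    1: PoseLabel.LEFT,
    2: PoseLabel.RIGHT,
    3: PoseLabel.LEFT_PH,
    4: PoseLabel.RIGHT_PH,
    5: PoseLabel.INVALID,
    6: PoseLabel.INVALID,
    7: PoseLabel.LEFT,
    8: PoseLabel.RIGHT,
    9: PoseLabel.INVALID,
}

POSE_DESCRIPTIONS = {
    1: "Left (occluder covering right eye)",
    2: "Right (occluder covering left eye)",
    3: "Left pinhole",
    4: "Right pinhole",
    5: "Partial eye cover (L)",
    6: "Partial eye cover (R)",
    7: "Pinhole partially lowered (L)",
    8: "Pinhole partially lowered (R)",
    9: "No occluder",
}


def classify_markers(marker_ids: Iterable[int]) -> PoseLabel:
    """Map a detected marker-id set to a pose label.

    Pure function of the set: {1}->Left, {2}->Right, {1,3}->Left_ph,
    {2,4}->Right_ph; lone pinhole markers {3}/{4} fall back to the base
    pose; the empty set and any mix of left- and right-family ids are
    Invalid.
    """
    ids = frozenset(marker_ids)
    bad = ids - VALID_IDS
    if bad:
        raise PoseError(f"unknown marker ids {sorted(bad)}")
    left = ids & LEFT_FAMILY
    right = ids & RIGHT_FAMILY
    if not ids or (left and right):
        return PoseLabel.INVALID
    if left:
        return PoseLabel.LEFT_PH if left == LEFT_FAMILY else PoseLabel.LEFT
    return PoseLabel.RIGHT_PH if right == RIGHT_FAMILY else PoseLabel.RIGHT


def covered_eye(label: PoseLabel) -> str:
    """The eye the occluder must cover for this pose (opposite of the
    tested eye: labels name the eye under test)."""
    if label in (PoseLabel.LEFT, PoseLabel.LEFT_PH):
        return "right"
    if label in (PoseLabel.RIGHT, PoseLabel.RIGHT_PH):
        return "left"
    raise PoseError("Invalid pose has no covered eye")


def _occluder_box(obs: PoseObservation) -> Optional[Box]:
    boxes = [obs.marker_boxes[i] for i in sorted(obs.marker_ids)]
    if not boxes:
        return None
    out = boxes[0]
    for b in boxes[1:]:
        out = out.union(b)
    return out


def iris_within_region(obs: PoseObservation, candidate: PoseLabel, margin_frac: float = 0.10) -> bool:
    """Geometric occlusion check for a candidate (non-Invalid) pose.

    True iff the covered eye's iris lies inside the occluder region
    (inflated by ``margin_frac`` of its diagonal) and the tested eye's iris
    lies outside it. A missing covered-eye iris landmark counts as covered:
    full occlusion removes the landmark. No face detected fails the check.
    """
    if candidate == PoseLabel.INVALID:
        raise PoseError("iris check undefined for Invalid pose")
    if obs.face_box is None:
        return False
    box = _occluder_box(obs)
    if box is None:
        return False
    cov = covered_eye(candidate)
    covered_iris = obs.iris_right if cov == "right" else obs.iris_left
    tested_iris = obs.iris_left if cov == "right" else obs.iris_right
    if covered_iris is not None and not box.contains(covered_iris, margin_frac):
        return False
    if tested_iris is None or box.contains(tested_iris, margin_frac):
        return False
    return True


def classify_pose(obs: PoseObservation, margin_frac: float = 0.10) -> PoseClassification:
    """Full per-frame classification: marker mapping demoted to Invalid
    when the iris occlusion check fails."""
    label = classify_markers(obs.marker_ids)
    if label == PoseLabel.INVALID:
        return PoseClassification(label, iris_check_passed=False, source_ids=obs.marker_ids, reason="markers")
    if not iris_within_region(obs, label, margin_frac):
        reason = "NO_FACE" if obs.face_box is None else "iris"
        return PoseClassification(PoseLabel.INVALID, iris_check_passed=False, source_ids=obs.marker_ids, reason=reason)
    return PoseClassification(label, iris_check_passed=True, source_ids=obs.marker_ids)


def debounce(stream: Sequence[PoseClassification], k: int = 5) -> list[tuple[int, PoseLabel]]:
    """Stabilise a frame stream into (frame_index, label) emission events.

    A valid label is emitted only once its run reaches k consecutive
    identical frames; any Invalid frame emits Invalid immediately and
    resets the run (Invalid is absorbing until a fresh k-run establishes a
    pose). Frame indices are positions in the stream, starting at 1.
    """
    if k < 1:
        raise PoseError("debounce window k must be >= 1")
    events: list[tuple[int, PoseLabel]] = []
    run_label: Optional[PoseLabel] = None
    run_len = 0
    for idx, cls in enumerate(stream, start=1):
        label = cls.label if isinstance(cls, PoseClassification) else cls
        if label == PoseLabel.INVALID:
            events.append((idx, PoseLabel.INVALID))
            run_label, run_len = None, 0
            continue
        if label == run_label:
            run_len += 1
        else:
            run_label, run_len = label, 1
        if run_len == k:
            events.append((idx, label))
    return events


def moving_average_smooth(values: Sequence[float], window: int) -> np.ndarray:
    """Trailing moving average: element i is the mean of the last
    min(i+1, window) values; output length equals input length."""
    if window < 1:
        raise PoseError("window must be >= 1")
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        return x
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(1, x.size + 1)
    lo = np.maximum(0, idx - window)
    return (csum[idx] - csum[lo]) / (idx - lo)


@dataclass(frozen=True)
class FixtureGeometry:
    """Synthetic image geometry for pose fixtures (pixels, 640x480 frame).

    Eye positions are unmirrored subject coordinates: the subject's right
    eye on the image left. Purely a fixture convention -- the physical
    marker-to-corner layout of the real occluder is not modelled.
    """

    width: int = 640
    height: int = 480
    right_eye: tuple[float, float] = (220.0, 240.0)
    left_eye: tuple[float, float] = (420.0, 240.0)
    occluder_w: float = 140.0
    occluder_h: float = 100.0
    jitter_px: float = 4.0


def synth_pose_fixture(pose_id: int, geometry: Optional[FixtureGeometry] = None, seed: int = 0) -> PoseObservation:
    """Construct a synthetic observation realising one of the nine
    validation poses, with seeded sub-pixel jitter on all landmarks."""
    if not 1 <= pose_id <= 9:
        raise PoseError(f"pose_id must be in 1..9, got {pose_id}")
    g = geometry or FixtureGeometry()
    rng = np.random.default_rng(seed)

    def jit(p: tuple[float, float]) -> tuple[float, float]:
        return (p[0] + rng.uniform(-g.jitter_px, g.jitter_px), p[1] + rng.uniform(-g.jitter_px, g.jitter_px))

    face = Box.from_center((g.right_eye[0] + g.left_eye[0]) / 2, 260.0, 320.0, 360.0)

    def marker_box(center: tuple[float, float]) -> Box:
        cx, cy = jit(center)
        return Box.from_center(cx, cy, g.occluder_w, g.occluder_h)

    # Which physical eye the occluder sits over, per pose:
    over_right = g.right_eye  # testing left
    over_left = g.left_eye    # testing right

    if pose_id == 1:  # valid Left: cover right eye, its iris hidden
        boxes = {1: marker_box(over_right)}
        return PoseObservation(frozenset({1}), boxes, iris_left=jit(g.left_eye), iris_right=None, face_box=face)
    if pose_id == 2:  # valid Right: cover left eye
        boxes = {2: marker_box(over_left)}
        return PoseObservation(frozenset({2}), boxes, iris_left=None, iris_right=jit(g.right_eye), face_box=face)
    if pose_id == 3:  # valid Left pinhole: base + pinhole markers
        boxes = {1: marker_box(over_right), 3: marker_box(over_right)}
        return PoseObservation(frozenset({1, 3}), boxes, iris_left=jit(g.left_eye), iris_right=None, face_box=face)
    if pose_id == 4:  # valid Right pinhole
        boxes = {2: marker_box(over_left), 4: marker_box(over_left)}
        return PoseObservation(frozenset({2, 4}), boxes, iris_left=None, iris_right=jit(g.right_eye), face_box=face)
    if pose_id == 5:  # partial cover: covered iris peeks out below the occluder
        slipped = (over_right[0], over_right[1] - 120.0)
        boxes = {1: marker_box(slipped)}
        return PoseObservation(frozenset({1}), boxes, iris_left=jit(g.left_eye), iris_right=jit(g.right_eye), face_box=face)
    if pose_id == 6:
        slipped = (over_left[0], over_left[1] - 120.0)
        boxes = {2: marker_box(slipped)}
        return PoseObservation(frozenset({2}), boxes, iris_left=jit(g.left_eye), iris_right=jit(g.right_eye), face_box=face)
    if pose_id == 7:  # pinhole flap half-lowered hides marker 3; base pose reads valid
        boxes = {1: marker_box(over_right)}
        return PoseObservation(frozenset({1}), boxes, iris_left=jit(g.left_eye), iris_right=None, face_box=face)
    if pose_id == 8:  # flap hides the base marker instead; lone id 4 remains
        boxes = {4: marker_box(over_left)}
        return PoseObservation(frozenset({4}), boxes, iris_left=None, iris_right=jit(g.right_eye), face_box=face)
    # pose 9: occluder not raised at all
    return PoseObservation(frozenset(), {}, iris_left=jit(g.left_eye), iris_right=jit(g.right_eye), face_box=face)
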