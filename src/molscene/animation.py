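"""Keyframe animation: pose/color/grouping keyframes, splines, frame export.

Object state over time is defined by keyframes.  Between keyframes,
positions follow a centripetal Catmull-Rom spline (C1, interpolating — the
sampled path passes exactly through every keyframe, which live preview
requires), orientations follow piecewise spherical linear interpolation
with shortest-arc sign correction, and colors interpolate linearly in RGB.
Group membership and visibility are discrete: they switch at keyframe
times, holding the value of the latest keyframe at or before the sample
time.  Before the first and after the last keyframe the boundary state
holds.

:func:`export_frames` samples the timeline at a fixed frame rate into
neutral per-frame pose/color records (JSON-lines), the headless stand-in
for handing the scene to an external renderer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .scene import Scene
from .transforms import RigidTransform

__all__ = [
    "Keyframe",
    "KeyState",
    "Timeline",
    "set_keyframe",
    "sample",
    "export_frames",
    "write_frames_jsonl",
]

ColorT = "tuple[float, float, float] | str"


@dataclass(frozen=True)
class Keyframe:
    """Object state pinned at a time point (seconds >= 0).  ``color`` is an
    RGB triple in [0, 1] or a symbolic data-coloring label (e.g.
    ``"charge"``), which is held, not interpolated."""

    time: float
    pose: RigidTransform = field(default_factory=RigidTransform.identity)
    color: tuple | str = (0.5, 0.5, 0.5)
    group: str | None = None
    visible: bool = True

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"keyframe time must be >= 0, got {self.time}")
        if not isinstance(self.color, str):
            c = tuple(float(x) for x in self.color)
            if len(c) != 3 or any(not 0 <= x <= 1 for x in c):
                raise ValueError(f"RGB color must be 3 values in [0,1], got {self.color!r}")
            object.__setattr__(self, "color", c)


@dataclass(frozen=True)
class KeyState:
    """A sampled (interpolated) object state."""

    pose: RigidTransform
    color: tuple | str
    group: str | None
    visible: bool


class Timeline:
    """Per-object sorted keyframe lists."""

    def __init__(self, duration: float = 0.0) -> None:
        self.keyframes: dict[str, list[Keyframe]] = {}
        self.duration = float(duration)

    def times(self, object_id: str) -> list[float]:
        return [k.time for k in self.keyframes.get(object_id, [])]


def set_keyframe(timeline: Timeline, object_id: str, keyframe: Keyframe) -> Timeline:
    """Insert a keyframe keeping the list sorted; a keyframe at an identical
    time is replaced (at most one keyframe per object per time)."""
    frames = timeline.keyframes.setdefault(object_id, [])
    frames[:] = [k for k in frames if k.time != keyframe.time]
    frames.append(keyframe)
    frames.sort(key=lambda k: k.time)
    timeline.duration = max(timeline.duration, keyframe.time)
    return timeline


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------

def _catmull_rom(P0, P1, P2, P3, s: float) -> np.ndarray:
    """Centripetal Catmull-Rom (Barry-Goldman form) evaluated at fraction
    ``s`` in [0, 1] of the P1->P2 segment."""
    pts = [np.asarray(p, dtype=float) for p in (P0, P1, P2, P3)]
    knots = [0.0]
    for a, b in zip(pts, pts[1:]):
        knots.append(knots[-1] + max(np.linalg.norm(b - a) ** 0.5, 1e-9))
    t0, t1, t2, t3 = knots
    u = t1 + s * (t2 - t1)

    def lerp(pa, pb, ta, tb):
        if tb - ta < 1e-15:
            return pa
        w = (u - ta) / (tb - ta)
        return (1 - w) * pa + w * pb

    A1 = lerp(pts[0], pts[1], t0, t1)
    A2 = lerp(pts[1], pts[2], t1, t2)
    A3 = lerp(pts[2], pts[3], t2, t3)
    B1 = lerp(A1, A2, t0, t2)
    B2 = lerp(A2, A3, t1, t3)
    return lerp(B1, B2, t1, t2)


def _interp_position(frames: list[Keyframe], i: int, s: float) -> np.ndarray:
    """Position between frames[i] and frames[i+1]; endpoints duplicated at
    the boundaries (clamped spline); two keyframes degenerate to linear."""
    pos = [k.pose.translation for k in frames]
    if len(pos) == 2:
        return (1 - s) * pos[0] + s * pos[1]
    P0 = pos[i - 1] if i > 0 else pos[0]
    P1, P2 = pos[i], pos[i + 1]
    P3 = pos[i + 2] if i + 2 < len(pos) else pos[-1]
    return _catmull_rom(P0, P1, P2, P3, s)


def _interp_rotation(k1: Keyframe, k2: Keyframe, s: float) -> np.ndarray:
    rots = Rotation.from_matrix(np.stack([k1.pose.rotation, k2.pose.rotation]))
    return Slerp([0.0, 1.0], rots)(s).as_matrix()


def _interp_color(c1, c2, s: float):
    if isinstance(c1, str) or isinstance(c2, str):
        return c1  # symbolic coloring modes switch at keyframes, not between
    a, b = np.asarray(c1, dtype=float), np.asarray(c2, dtype=float)
    return tuple(float(x) for x in (1 - s) * a + s * b)


def sample(timeline: Timeline, object_id: str, t: float) -> KeyState:
    """Interpolated object state at time ``t``.

    Exactly reproduces keyframe states at keyframe times; outside the
    keyframed range the boundary keyframe's state holds.
    """
    frames = timeline.keyframes.get(object_id)
    if not frames:
        raise ValueError(f"object {object_id!r} has no keyframes")

    def state_of(k: Keyframe) -> KeyState:
        return KeyState(k.pose, k.color, k.group, k.visible)

    if t <= frames[0].time:
        return state_of(frames[0])
    if t >= frames[-1].time:
        return state_of(frames[-1])
    times = [k.time for k in frames]
    # bracketing segment i: times[i] <= t < times[i+1]
    i = int(np.searchsorted(times, t, side="right")) - 1
    if times[i] == t:
        return state_of(frames[i])
    k1, k2 = frames[i], frames[i + 1]
    s = (t - k1.time) / (k2.time - k1.time)
    pose = RigidTransform(_interp_rotation(k1, k2, s), _interp_position(frames, i, s))
    # discrete channels hold the latest keyframe at or before t
    return KeyState(pose, _interp_color(k1.color, k2.color, s), k1.group, k1.visible)


# ---------------------------------------------------------------------------
# Frame export
# ---------------------------------------------------------------------------

def export_frames(
    timeline: Timeline, scene: Scene, fps: float, t0: float, t1: float
) -> list[dict]:
    """Sample the timeline at ``fps`` into ``floor((t1-t0)*fps) + 1``
    per-frame records (frame k at ``t0 + k/fps``); deterministic.

    Objects without keyframes are exported with their static scene state.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if t1 < t0:
        raise ValueError("t1 must be >= t0")
    num_frames = int(np.floor((t1 - t0) * fps + 1e-9)) + 1
    records = []
    for k in range(num_frames):
        t = t0 + k / fps
        objects = {}
        for oid, obj in scene.objects.items():
            if timeline.keyframes.get(oid):
                st = sample(timeline, oid, t)
            else:
                st = KeyState(obj.pose, obj.color, obj.group, obj.visible)
            objects[oid] = {
                "matrix": [float(x) for x in st.pose.matrix().ravel()],  # row-major
                "color": list(st.color) if not isinstance(st.color, str) else st.color,
                "group": st.group,
                "visible": st.visible,
            }
        records.append({"frame": k, "time": t, "objects": objects})
    return records


def write_frames_jsonl(records: list[dict], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")
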