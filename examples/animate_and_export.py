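"""Keyframe animation: spline a molecule between poses and export frames.

Two pose keyframes one second apart; the path is sampled at 24 fps into
neutral frame records (what an external renderer would consume).  The
midpoint is exactly halfway in position and halfway along the rotation arc.
"""

import numpy as np

from molscene import (
    Keyframe,
    RigidTransform,
    Scene,
    SceneObject,
    Timeline,
    export_frames,
    make_fixture,
    sample,
    set_keyframe,
)

scene = Scene()
scene.add_object(SceneObject("mol", make_fixture("blob", {}, seed=3)))

timeline = Timeline()
set_keyframe(timeline, "mol", Keyframe(0.0, RigidTransform.identity(), color=(1, 0, 0)))
set_keyframe(timeline, "mol", Keyframe(
    1.0, RigidTransform.from_rotvec([0, 0, np.pi / 2], [10, 0, 0]), color=(0, 0, 1)))

mid = sample(timeline, "mol", 0.5)
angle = np.degrees(np.arccos((np.trace(mid.pose.rotation) - 1) / 2))
print(f"t=0.5 s: position {np.round(mid.pose.translation, 3)} A, "
      f"rotation {angle:.1f} degrees, color {tuple(round(c, 2) for c in mid.color)}")

frames = export_frames(timeline, scene, fps=24, t0=0.0, t1=1.0)
print(f"exported {len(frames)} frames (floor(1 s * 24 fps) + 1)")
xs = [f["objects"]["mol"]["matrix"][3] for f in frames]
print(f"x advances monotonically from {xs[0]:.1f} to {xs[-1]:.1f} A")
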