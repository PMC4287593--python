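"""Crystal-by-example: replicate one monomer into a helical filament.

Places two copies of a blob "monomer" related by a screw motion (twist
-166.7 degrees, rise 27.5 A about z — an actin-like repeat), derives the
inter-copy transform from the pair, and generates a 13-copy chain.
"""

import numpy as np

from molscene import (
    RigidTransform,
    chain_from_pair,
    compose,
    describe_helix,
    make_fixture,
)
from molscene.transforms import screw_transform

monomer = make_fixture("blob", {"radii": [12, 14, 18]}, seed=42)

T_A = RigidTransform.identity()
T_B = compose(T_A, screw_transform([0, 0, 1], np.radians(-166.7), 27.5))
chain = chain_from_pair(monomer, T_A, T_B, n=13)

helix = describe_helix(chain)
twist = np.degrees(helix.angle) * np.sign(helix.axis_direction[2])
rise = helix.rise * np.sign(helix.axis_direction[2])
print(f"repeat twist: {twist:8.2f} degrees about z")
print(f"repeat rise:  {rise:8.2f} A")
for i in (1, 2, 7, 13):
    x, y, z = chain.pose_of(i).translation
    print(f"copy {i:2d} center offset: ({x:7.2f}, {y:7.2f}, {z:7.2f}) A")

# Each copy climbs 27.5 A along the axis while rotating -166.7 degrees, so
# copy centers stay on the axis here (monomer origin on-axis) and 13 copies
# complete about 6 full turns of the genetic helix.
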