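"""Screw motions: a rotation about an off-origin axis combined with a slide
along it — the general rigid displacement — applied to a point and a line.
"""

import numpy as np

from dqkin import (
    ScrewSpec,
    decode_line,
    decode_point,
    encode_line,
    encode_point,
    make_screw,
    transform_line,
    transform_point,
)

# quarter turn about the vertical line through (1, 0, 0), sliding 2 cm up
spec = ScrewSpec(axis=[0, 0, 1], angle=np.pi / 2, point=[1, 0, 0], slide=2.0)
m = make_screw(spec)
print("screw dual quaternion:", np.round(m, 6))

p = decode_point(transform_point(m, encode_point([2.0, 0.0, 0.0]), "active"))
print(f"\npoint (2,0,0) -> {np.round(p, 6)}")
print("  (rotates 90° around the axis through (1,0,0): x-offset 1 becomes y-offset 1, then +2 cm in z)")

line = encode_line([1.0, 0.0, 0.0], [0.0, 0.0, 0.0])  # the x-axis
n, closest = decode_line(transform_line(m, line, "active"))
print(f"\nx-axis line -> direction {np.round(n, 6)}, closest point to origin {np.round(closest, 6)}")
print("  (the line turns to +y through the rotated foot point, lifted by the slide)")

# the screw is invariant to which point on its axis we name
m2 = make_screw(ScrewSpec(axis=[0, 0, 1], angle=np.pi / 2, point=[1, 0, 7.5], slide=2.0))
print(f"\naxis-point invariance: max |difference| = {np.max(np.abs(m - m2)):.2e}")
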