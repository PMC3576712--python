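"""Visuomotor reference-frame transformation: where does a moving target land
on the retina, and can the brain-side inverse recover its spatial motion?

A target moves in shoulder-fixed space while the eye and head are rotated and
offset; we project it onto the retina and then invert the whole chain using
the retinal signals plus depth.
"""

import numpy as np

from dqkin import (
    BodyGeometry,
    RotationSpec,
    TargetState,
    gaze_forward_velocity,
    gaze_inverse_velocity,
    retinal_project,
)

geometry = BodyGeometry(
    eye_in_head=RotationSpec(np.array([0.0, 0, 1]), np.deg2rad(15.0)),   # 15° horizontal eye rotation
    head_on_shoulder=RotationSpec(np.array([1.0, 0, 0]), np.deg2rad(-20.0)),  # 20° head roll
    t_he=np.array([0.0, 0.0, 2.0]),     # eye sits 2 cm from the head rotation center
    t_sh=np.array([0.0, -30.0, 0.0]),   # head center 30 cm above the shoulder
    omega_eh=np.array([0.0, 0.0, 0.5]),  # the eye is rotating at 0.5 rad/s
)

target = TargetState("SS", position=[10.0, 0.0, 50.0], velocity=[5.0, 0.0, 0.0])

ee = gaze_forward_velocity(geometry, target)
print(f"target in eye coordinates:   P^EE = {np.round(ee.position, 4)} cm")
print(f"target velocity in eye frame: {np.round(ee.velocity, 4)} cm/s")

retina = retinal_project(ee.position, ee.velocity)
print(f"\nretinal projection (unit sphere): {np.round(retina.proj, 6)}")
print(f"retinal drift:                   {np.round(retina.proj_rate, 6)} /s")
print(f"target depth d_P = {retina.distance:.4f} cm, depth rate = {retina.distance_rate:.4f} cm/s")

back = gaze_inverse_velocity(geometry, retina)
print(f"\ninverse transform recovers the spatial state (needs depth!):")
print(f"position error {np.max(np.abs(back.position - target.position)):.2e} cm, "
      f"velocity error {np.max(np.abs(back.velocity - target.velocity)):.2e} cm/s")
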