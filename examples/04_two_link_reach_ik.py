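"""Closed-loop inverse kinematics of the four-dof two-link arm tracking a
bell-profile straight-line reach (the packaged flagship simulation).

The solver inverts the 6×6 constrained Jacobian with the Moore–Penrose
pseudo-inverse each millisecond and corrects integration drift with a
position-error feedback gain of 1000 s⁻¹.
"""

import numpy as np

from dqkin import max_stable_gain
from dqkin.protocols import simulate_reach

result, trajectory = simulate_reach(duration=0.8, peak_speed=100.0, dt=1e-3, k1=1000.0)

speed = np.linalg.norm(trajectory.vel, axis=0)
print(f"commanded reach: {np.linalg.norm(trajectory.pos[:, -1] - trajectory.pos[:, 0]):.2f} cm "
      f"in {trajectory.t[-1]*1e3:.0f} ms, peak speed {speed.max():.1f} cm/s")
print(f"start {np.round(trajectory.pos[:, 0], 2)} cm -> end {np.round(trajectory.pos[:, -1], 2)} cm")

print(f"\nper-step task-Jacobian rank: {set(result.ranks.tolist())}  "
      "(rank 5 of 6: the arm can always spin about the shoulder-hand axis)")
print(f"maximum position error: {result.max_error:.6f} cm over {result.t.size} steps")
print(f"stability bound for dt=1 ms: gains above {max_stable_gain(1e-3):.0f} 1/s diverge")

# the elbow angle along the movement, from the integrated joint quaternions
theta = 2 * np.arccos(np.clip(result.r_lu[0], -1, 1))
print(f"elbow angle runs from {np.degrees(theta[0]):.1f}° to {np.degrees(theta[-1]):.1f}° "
      f"(stays near 90°, far from the aligned-arm singularity)")
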