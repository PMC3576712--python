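# Methods

This note records the model conventions, numerical choices and known limits
of `dqkin`, in the spirit of a package's methods appendix: what exactly is
computed, under which conventions, and what the tests do and do not
establish.

## Algebraic conventions

**Product.** The quaternion product is the geometric product of
scalar-plus-bivector elements,
`AB = (a0b0 − a⃗·b⃗) + i(a0b⃗ + b0a⃗ − a⃗×b⃗)`.
The negated cross term makes this the mirror image of the Hamilton
convention (`qmul(A, B)` equals the Hamilton product of B with A). Two
consequences are load-bearing and covered by tests:

- the *active* point sandwich `D̄* X D` acts like the standard rotation
  matrix of the real part (a +90° turn about z takes x to y), and
- composition maps to matrices contravariantly:
  `to_homogeneous(dqmul(D, E)) = H(E) @ H(D)`, i.e. the left factor of a
  product acts first.

Mixing routines from Hamilton-convention libraries into these chains would
silently flip sandwich directions; the only external rotation code used
(scipy's `Rotation`) is confined to the independent oracle path in
`dqkin.fixtures`.

**Conjugates and modes.** Points use the mixed conjugate, lines the
quaternion conjugate; `entities.transform` dispatches on the entity kind so
the choice lives in one place. Active and passive modes are mutually
inverse for rotations only: a translation equals its own mixed conjugate,
so both modes displace by +d·t and a translation is inverted by negating
d. This asymmetry is intentional (it is what makes chains of alternating
rotations and translations read identically in both directions) and is
pinned by tests.

**Storage.** Elements are plain float arrays `[q0, qx, qy, qz]` /
`[D0, D1]`; a batch is a 4×N or 8×N array whose columns are elements, and
every operation accepts a single element, a batch, or one of each
(broadcast). The batch contract is tested against per-column scalar calls
at N = 257.

**Tolerances.** Unitarity and equality default to 1e-9 absolute on
components (`DEFAULT_TOL`), configurable per call. Rotation/translation
axes must be unit to 1e-6 (renormalized with a warning beyond 1e-12
deviation, rejected beyond 1e-6); a zero axis with zero angle is the
identity, with nonzero angle an error. A dual quaternion with zero-norm
real part has no inverse; its norm's dual part is reported as NaN with an
`is_defined` predicate rather than raising, since the real-part norm is
still meaningful.

## Velocity calculus

Rotational velocity is the pure quaternion Ω with `Ṙ = ½ R Ω` (and
`Ω = 2 R* Ṙ`); it is *not* the coordinate derivative of R. Translational
velocity is `Ṫ = ε v/2`, `v = ḋ t + d ṫ`. The screw rate is the
three-term product rule (slide term `Ṫ R_T`, axis-offset term
`Ṫ_L* R + R Ṫ_L`, rotation term `½ T T_L* R Ω T_L`). Transformed-entity
rates are computed by the product rule on the full sandwich rather than by
pre-expanded special cases; the rotating-frame commutator
`½(PΩ − ΩP) = −ε(P⃗∧Ω⃗)` (the ω×r term) falls out of this and is what the
Jacobian assembly exploits. Every rate operator is validated against
central finite differences of its constructor with O(h²) convergence
checked across h = 1e-3…1e-5; these oracles share no code with the
operators they check.

## Visuomotor transformation

The forward chain nests four operators — eye-in-head rotation R_EH,
eye–head offset T_HE, head-on-shoulder rotation R_HS, head–shoulder offset
T_SH — as `P_EE = R_EH T_HE R_HS T_SH · P_SS · T_SH R_HS* T_HE R_EH*`,
with t_he the head position in eye-centered head-fixed coordinates and
t_sh the shoulder position in head-centered shoulder-fixed coordinates
(the round-trip test guards this sign convention). Velocity adds one
commutator term per rotating joint; with a static eye-head posture only
the rotated target velocity survives. Retinal projection divides by the
eye-centered distance d_P (sphere radius r_eye = 1 by default — a pure
scale). The inverse chain uses the conjugates of the same unit elements.

Depth policy: d_P (and ḋ_P for velocity) are *required inputs* to the
inverse path. Biological depth estimation (binocular or monocular) is a
separate inference problem outside this package's scope; silently guessing
depth would corrupt the round-trip guarantee, so absence raises. Setting
individual velocity signals to zero in the inverse (e.g. dropping the head
rotation signal) reproduces degraded-transformation predictions; the
resulting velocity error is exactly the dropped commutator term, which the
test-suite asserts.

## Arm models

**Two-link arm** (upper arm a, forearm b, default 30 cm each): shoulder is
a free 3-dof rotation R_UB, elbow a 1-dof rotation R_LU about
n_elbow = [0,0,1] in upper-arm coordinates; at zero angles the arm lies
extended along +x. FK is the nested sandwich
`P_BS = R_UB* T_ES R_LU* P_LE R_LU T_ES R_UB`. The elbow's velocity
contribution uses the lever arm about the elbow, `P_UE = R_LU* P_LE R_LU`
(elbow-centered, upper-arm-fixed): defining P_UE with the elbow–shoulder
offset included fails the finite-difference oracle by O(10 cm/s) on random
joint paths, so the offset-free form is the one implemented.

**Three-link arm** (a, b, c, default 30/30/15 cm) adds a 3-dof wrist; the
elbow and wrist rotations are realized as screw operators with axes offset
to [a,0,0] and [a+b,0,0]. The end-effector carries both a point and an
oriented tool line (direction [0,1,0] through [a+b+c,0,0] at reference);
the line transforms with the quaternion conjugate, the point with the
mixed conjugate, through the same total screw. The line determines
position only orthogonally to its own direction, which is why the point
transform runs in parallel.

## Inverse kinematics

The task Jacobian columns are the velocity dual quaternions at unit joint
rates. For the two-link arm this gives the closed form
`J = −(Ã_P_BS R_UB Ã_P_UE)` (3×6); the 1-dof elbow constraint
`n_elbow × Ω_LU = 0` is appended as rows (6×6, generic rank 5 — the kernel
is the arm's self-rotation about the shoulder–hand axis). The planar 2×2
Jacobian extracts in-plane components and is singular exactly at elbow
angle 0 or 180° (rank 1). For the three-link point + line-direction task
the nine columns are evaluated from the analytic rate formulas in one
batched pass (the task map is linear in the Ω's) and validated against
finite differences; rank is generically 7 of 9.

Solving uses the SVD pseudo-inverse with a relative singular-value cutoff
of 1e-10·σ_max; the Penrose conditions are asserted in tests. `J⁺ rhs` is
the minimal-norm joint velocity; `(I − J⁺J) w` adds self-motions. At
singularities the solution degrades gracefully to least squares (rank is
reported, never raised).

Integration: explicit Euler on the quaternion followed by renormalization
(default), or the exact exponential map `R ← R·ΔR`; the two agree to
O(Δt²) per step. Drift is cancelled by the closed loop
`J Ω = (Ṗ_des + k1 e; 0)` with `e = P_des − FK(joints)`. The scalar error
recursion `e⁺ = (1 − k1Δt) e` gives the stability bound `k1 < 2/Δt`
(2000 s⁻¹ at 1 ms); the loop warns and proceeds above it, and aborts with
a diagnostic when ‖e‖ exceeds the workspace radius. Orientation error for
the line task is the tangent-plane correction `(n × n_des) × n`, which is
the direction ṅ must take to close the angle.

## The reach protocol and the synthetic generator

The packaged simulation reaches along a straight line with a minimum-jerk
speed profile `s(τ) = D(10τ³ − 15τ⁴ + 6τ⁵)` — the standard bell-shaped
kinematic model of point-to-point human reaches; peak speed is 1.875·D/T,
so 800 ms at 100 cm/s peak implies D ≈ 42.7 cm. Defaults: Δt = 1 ms,
k1 = 1000 s⁻¹, a = b = 30 cm, direction (1,1,1)/√3. The start pose keeps
the elbow flexed near 90°: both endpoints of the chord sit at 45 cm from
the shoulder (elbow angle 83–97° along the path), comfortably inside the
[0, 60] cm workspace annulus and away from the aligned-arm singularity. A
42.7 cm chord launched from an arbitrary central posture would exit the
workspace, so the chord-symmetric placement is the deterministic choice
the protocol makes; the achieved maximum tracking error (~2·10⁻⁴ cm) is
insensitive to admissible start poses.

The random-element generator draws rotation axes uniformly on the sphere,
angles uniformly on [0, π], and translation components from a normal
distribution with 10 cm standard deviation — magnitudes on the scale of
eye/head/limb geometry. What the generator does *not* emulate: measurement
noise, sensor delays, biomechanical joint limits, or muscle dynamics. The
transformations are noise-free by design, so passing tests establish
algebraic and geometric correctness, not robustness to noisy signals.

Problem sizes in the tests and acceptance script (1000-element algebra
batches, 800-step reach, 150–250-step three-link tracking runs) were
chosen as the package's own defaults: large enough that drift, rank and
convergence pathologies would surface, small enough to run interactively.

## Known limitations

- No screw-motion interpolation (ScLERP) or blending.
- No joint limits, damped least squares or task-priority redundancy
  resolution — redundancy handling is exactly minimal-norm + nullspace.
- Depth estimation for the visuomotor inverse is out of scope (explicit
  input only).
- Lines are the only non-point entity (no planes or points at infinity).
- The CLI covers the two-link IK pipeline; the three-link tracking task is
  library-only.
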