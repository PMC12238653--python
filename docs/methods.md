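# Methods

`balancempc` simulates a standing human on a platform that oscillates
anterior-posteriorly with slowly increasing frequency, and analyses how the
postural control strategy reorganises as the perturbation speeds up.  The
model has three parts: a rigid-body plant, a receding-horizon controller
standing in for the neural command centre, and a coordination-analysis
stack that detects strategy transitions in the resulting trajectories.

## Plant

The body is reduced to four sagittal-plane segments — foot, shank, thigh
and HAT (head + arms + trunk), left and right limbs lumped — articulated at
ankle, knee and hip.  The foot is rigidly attached to the platform, whose
horizontal position x_p(t) is prescribed; the three links above the ankle
form a triple inverted pendulum under gravity, driven by joint torques.

With absolute segment angles from vertical α (joint deviations φ with
α = cumsum(φ); upright is φ = 0), the Euler–Lagrange equations are

    Σ_j M_ij(α) α̈_j + Σ_j b_ij sin(α_i − α_j) α̇_j² − g P_i sin α_i
        + P_i cos α_i ẍ_p = (Dᵀτ)_i

where M_ij = b_ij cos(α_i − α_j) + δ_ij I_i, P_i = m_i d_i + L_i Σ_{k>i} m_k
is the first-moment coefficient of link i, b_ii = m_i d_i² + L_i² Σ_{k>i} m_k,
b_ij = L_i P_j (i < j), and D maps absolute-angle variations to joint-angle
variations.  Platform motion enters only through the inertial coupling
P_i cos α_i ẍ_p (base excitation); with the platform frozen the model is an
ordinary fixed-base triple pendulum.  The hand-coded closed form is
validated in the test suite against an independent symbolic Euler–Lagrange
derivation (sympy) to 1e−8 relative on 1 000 random states, and the
analytic linearisation against central finite differences.

Anthropometry scales a Winter-style proportion table (masses, joint
heights, segment COM locations and radii of gyration as fractions of total
mass and stature) to the default subject, 68.4 kg / 1.68 m — the mean of
the young-adult cohort whose protocol the simulation emulates.  The mass
fractions (foot 0.029, shank 0.093, thigh 0.200, HAT 0.678) sum to exactly 1.

The centre of pressure comes from the foot free-body: the ankle reaction
force follows from Newton's law applied to the three supported links, and
the moment balance of the foot (ground reaction at the COP, foot weight,
ankle torque reaction, foot inertia under platform acceleration) yields
Fz, Fx and the COP x-coordinate.  In static equilibrium the COP reduces
exactly to the whole-body COM projection; the dynamic computation is
checked against a whole-body angular-momentum balance.  Heel lift
(Fz ≤ 0) and COP excursions beyond the heel–toe extent are flagged, not
clipped.  Whole-body COM is the mass-weighted mean over all four segments.

Integration is classical fixed-step RK4 at the 10 ms control period (one
step per period by default; sub-stepping available), torque held over the
step.  Passive energy drift is below 1e−6 relative over 10 s at dt = 0.1 ms.

No passive joint stiffness or damping is included: joint torques are
purely the controller's commands.

Recorded joint torques use the internal-moment, restoring-positive sign
convention (the negative of the torque conjugate to the CCW angle), so a
joint that resists its own deflection has positive quasi-stiffness.
Pairwise coordination measures are invariant to this choice.

## Controller

At every 10 ms step the controller minimises

    J = (Rs − Y)ᵀ Q̄ (Rs − Y) + ΔΓᵀ R̄ ΔΓ

over a move-blocked sequence of torque increments ΔΓ (control horizon
Nc = 2 moves of 3 torques), where Y stacks the predicted 6-state vectors
over the prediction horizon Np = 4 and Rs ≡ 0 is the upright target.
Per-step weights tile block-diagonally over the horizons.  Predictions
roll the nonlinear plant forward with the true platform-acceleration
preview (the chirp is deterministic; a no-preview mode holds the current
acceleration).  Torque, torque-increment, joint-angle and joint-velocity
bounds are enforced in the solve; at the 2 mm perturbation scale they
never bind, and the defaults (±0.6 rad, ±6 rad/s, ankle/knee ±150 N m,
hip ±200 N m, ±50 N m per step) are deliberately generous physiological
ranges.  The applied torque is the previous torque plus the first move;
warm starts shift the previous solution.

**Effort scaling.**  The state weights act on radians (Q̄ = 10·I₆ by
default); the increment weights act on *dimensionless effort*, i.e. torque
increments divided by a characteristic joint torque capacity
(`tau_scale`, default 150 N m — the same scale as the ankle/knee torque
bounds).  This scaling is load-bearing.  Weighting raw N·m increments
against radian-scale states makes the effort term so dominant that no
receding-horizon law with these short horizons stabilises the plant at
all (closed-loop spectral radius ≈ 1.07 at upright); conversely, making
the effort term negligible stabilises the loop but erases the
strategy-transition phenomenology, because the transition is precisely
the trade-off between posture error and effort re-balancing across
joints as the perturbation gets faster.  Expressing effort as a fraction
of torque capacity keeps both cost terms active, stabilises the loop
(spectral radius 0.9998), and leaves the printed weight *ratios* — ankle
10, knee 10, hip 80 — acting exactly as written.  A single shared scale
is used rather than per-joint capacities so those ratios are not
silently rescaled.

Two solver modes share the same problem definition:

* `sqp` (default): Gauss–Newton SQP specialised to this 6-variable
  problem — exact nonlinear nominal rollout, sensitivity matrix from the
  analytic Jacobians discretised RK4-consistently, direct solve of the
  regularised normal equations, two iterations.  ~2 ms per step.
* `nlp`: scipy SLSQP on the full nonlinear rollout with explicit bound
  and state constraints, objective rescaled to O(1) per solve.  Slower;
  agrees with `sqp` to ~1e−5 N m per step in closed loop and serves as
  the independent route in tests.

A `prediction="linear"` option replaces the rollout by the affine-exact
discretisation of the linearisation at the current state; it makes the
problem exactly quadratic and is used to check both solvers against a
closed-form least-squares solution.

Nothing in the controller is scheduled, switched or retuned during a run:
any change of coordination pattern over the sweep is an emergent property
of one fixed optimisation problem interacting with the plant.

## Platform

x(t) = A sin(2π(f₀t + kt²/2)), amplitude A = 2 mm, instantaneous frequency
f₀ + kt ramping linearly 0.4 → 6 Hz.  The sweep duration is not a
physiological constant; the default is 280 s (ramp 0.02 Hz/s) and the
acceptance/analysis runs use 120 s (0.047 Hz/s).  Transition estimates are
reported against instantaneous frequency and agree between the two
durations to within 0.01 Hz, so results are insensitive to the ramp rate
at this scale.  Velocity and acceleration are exact analytic derivatives.

## Coordination analysis

* **Vector coding.**  For a signal pair (x, y), the coupling angle
  γ_i = atan2(Δy_i, Δx_i) ∈ [0°, 360°) of each consecutive-sample
  displacement.  Exactly-zero displacement pairs are excluded.
* **Binary classification.**  In-phase when γ is nearer the 45°/225°
  diagonal, anti-phase when nearer 135°/315°; ties (0°, 90°, 180°, 270°)
  count as in-phase.  Equivalent to sign(Δx·Δy) ≥ 0, hence invariant to
  positive rescaling of either signal.
* **RPR.**  Proportions of in-/anti-phase samples per non-overlapping
  1-s window (100 samples), stamped with the window-centre instantaneous
  frequency.
* **Transition estimation.**  A four-parameter logistic
  p(f) = p₀ + (p₁ − p₀)/(1 + exp(−(f − f_t)/s)) is least-squares fitted to
  the anti-phase proportion versus frequency; f_t is the transition
  frequency.  Free plateaus matter here: the ankle–knee phase lag in this
  model saturates near 120° rather than 180°, so the anti-phase
  proportion plateaus near 0.7, and forcing asymptotes 0/1 would bias the
  midpoint upward by ~1 Hz.  "No transition" is declared when the fitted
  curve spans < 0.5 over the data or the fit fails.
* **Strategy labels.**  From the two adjacent torque pairs:
  (in, in) → ankle, (anti, in) → knee, (in, anti) → hip,
  (anti, anti) → combined.
* **COP–COM pair.**  Coded on support-frame displacements (COP and COM
  relative to the platform) — the quantities that platform-embedded force
  plates and platform-referenced kinematics provide.  In this frame the
  simulation reproduces the characteristic amplitude sequence: COP
  dominant at low frequency, COM briefly dominant just before the
  transition, COP dominance restored after it.  Lab-frame signals show no
  phase reorganisation at all.

**Quasi-stiffness.**  Ordinary least-squares slope of joint torque
against joint angle within each platform-period cycle (cycles delimited
by upward zero-crossings of platform position so every joint is segmented
identically).  Cycles with fewer than 5 samples or zero angle variance are
flagged.  A sign transition is reported at the first slope sign change
persisting ≥ 3 consecutive cycles.

## Synthetic fixtures

`generate_synthetic_pair` produces two chirp-locked unit sinusoids whose
mutual phase offset moves smoothly (logistically in instantaneous
frequency, width 0.1 Hz) from 0° to 180° around a programmed transition
frequency, plus additive white Gaussian noise.  It exercises the whole
analysis stack against known ground truth without the simulator.  The
default noise (σ = 0.01) is set by an explicit criterion: vector coding
differentiates the signals, so the per-sample noise step σ√2 must stay
below the smallest per-sample signal displacement (A·2πf₀/fs = 0.025 at
0.4 Hz) — noise well above that buries the low-frequency phase structure
rather than merely perturbing it.  What the fixture does *not* emulate:
amplitude growth with frequency, harmonic content, or the partial
(<180°) phase saturation of the real closed loop.

## What the defaults produce

With the default configuration the closed loop balances over the whole
0.4–6 Hz sweep and, with nothing scheduled, the coordination reorganises:
the ankle–knee torque pair flips from in-phase to anti-phase around
2.0 Hz (reported values 2.14 Hz for this protocol), the support-frame
COP–COM pair around 1.9 Hz (reported 2.24 Hz), and the knee–hip pair
stays in-phase throughout, so the strategy reads ankle below the
transition and knee above it.  Equalising the three increment weights
moves the ankle–knee transition to ≈ 3.5 Hz (reported 3.65 Hz),
reproducing the monotone effect of the hip penalty.

## Known limitations

* The plant equations were re-derived from the standard formulation; the
  original model's full parameterisation is not public.  Two emergent
  details differ from the reported behaviour and are left as-is rather
  than tuned away: the COP–COM transition here slightly *precedes* the
  joint-level one (reversed ordering, gap ≈ 0.09 Hz), and at high
  frequency the optimiser leans on ankle + hip torque rather than
  ankle + knee, so the knee quasi-stiffness slope never turns negative
  while the hip slope does (≈ 4 Hz).
* The marginal closed-loop mode (spectral radius 0.9998) implies slow,
  bounded drift dynamics near upright; with zero perturbation the loop is
  exactly quiescent.
* Full-state feedback, no sensory noise or delays, no state observer; no
  stepping; sagittal plane only; no muscle-level actuation.
* `compare_series` (Pearson r + RMSE) is machinery for comparing
  simulated and experimental traces; no experimental data ships with the
  package.
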