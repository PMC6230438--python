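# Methods

## Model

The single-limb CPG is a feedforward rate model: two half-centers with
states x1, x2 obeying

    dxi/dt = x0i + gi·u + r_leak·xi

with a hard reciprocity constraint — exactly one state is active and
integrates; the other is clamped at 0. When the active state reaches the
threshold 1 it resets to 0 and the antagonist starts. States are
normalised so that each phase spans max − min = 1; the threshold and
reset level are therefore fixed at 1 and 0 and not exposed as
parameters. The drive u is constant (or piecewise constant in the
simulator); all closed forms assume a constant drive within a phase.

Bilateral coupling across the midline is deliberately absent: the leak
matrix is diagonal, so limbs are independent and a two-limb behaviour
(steering) arises only through the shared descending speed command. This
confines the model to symmetric walking gaits — split-belt-style
asymmetries and running (stance shorter than swing) are out of scope.

## Closed forms and their numerical handling

For the active half-center with effective rate ρ = x0 + g·u and leak
r = r_leak ≤ 0:

* exact phase duration: τ = ln(1 + r/ρ)/r, implemented with `log1p` for
  accuracy at small r/ρ;
* small-leak (first-order Taylor) limit: τ = 1/ρ;
* the Taylor cycle duration τ1 + τ2 equals the rational form
  (a + b·u)/(ã + b̃·u + c̃·u²) with a = x01+x02, b = g1+g2, ã = x01·x02,
  b̃ = x01·g2 + x02·g1, c̃ = g1·g2 — asserted as an identity to 1e−12
  relative in the tests.

Admissibility: the exact form requires ρ > |r| (otherwise the state
saturates at ρ/|r| below threshold), the Taylor form ρ > 0. The two
failure modes are distinct error classes (`SaturationError`,
`NonPositiveRateError`), and each error carries the minimal admissible
drive when a positive gain makes one exist — with the optimised
parameters the flexor-like offset is negative (x01 = −0.0007), so low
drives are silently pathological without this report. r_leak = 0 is
accepted and routed to the Taylor formula so the API is continuous at
the singular parameter value.

Phase naming: the indices 1/2 are fixed by the parameter table, but the
mapping to flexor/extensor is ambiguous — with the optimised values the
weakly modulated ≈ 0.21–0.27 s phase (index 2) behaves like the
near-constant swing while index 1 modulates like stance. The package
exposes indices and treats the stance-like/swing-like naming as a
reporting label only.

## Simulator

Within a segment of constant drive the ODE is linear, so the simulator
advances the state with the exact exponential update and solves the
local closed form for the threshold-crossing time; a `dt` grid only
controls trajectory sampling (and piecewise-drive breakpoints split
segments exactly). Samples and crossings are computed from the segment
anchor, not by chaining per-dt updates, so event times carry no
dt-dependent rounding accumulation and refining dt never degrades the
agreement with the analytic solution (observed residuals are at float
precision, ~1e−12 relative). Default dt = 1e−4 s, well below the
shortest phase (~0.1 s) in the modelled speed range.

Both states start at 0 with state 1 active by default; for constant
drive the steady rhythm is independent of the start. A stalled
oscillator (non-positive derivative below threshold, or saturation with
no upcoming drive change) terminates with an error carrying the stall
time, rather than silently producing no events.

## Speed maps and validation

Three empirical constants tie the model to cat overground walking: the
affine regression u = (V + 0.1272)/0.2357 from speed to drive, the
power law Tc = 0.5445·V^(−0.5925) s for the cycle duration, and the
constant-swing approximation 0.25 s (stance = Tc − 0.25, valid only
while Tc > 0.25 s, i.e. walking speeds). They ship as a JSON fixture,
not literals in code.

`validate` evaluates the analytic Tc with the exact exponential form
(the rational form is retained for comparison; the choice moves R² by
< 1e−3) over a default grid of 0.1–2.0 m/s in 0.05 m/s steps
(39 points). The grid is a package choice: the source of the empirical
law states only "the full range of walking speeds", so the default
spans cat walking while avoiding the V → 0 divergence of the power law
and staying inside the constant-swing validity window; the grid used is
recorded in the output sidecar. Agreement is summarised as the squared
Pearson correlation between the analytic and empirical duration
vectors — the scale-free form of regressing one duration against the
other — with the coefficient of determination about the identity line
reported alongside (it is the stricter statement that the curves agree
in value, not just shape). On the default grid with the shipped
parameters R² = 0.9907 and the identity-line R² = 0.9889; both numbers
are computed, never stored.

## Steering

Heading change per cycle follows differential-drive kinematics,
γ = Tc·(V_R − V_L)/W with W = 0.15 m by default. Tc is evaluated at the
mean of the two limb speeds mapped through the regression — the only
symmetric choice, matching a surface parameterised by (mean speed,
differential); the rational (Taylor) form is the default here,
configurable to exact. Positive γ means a turn toward the slower left
limb (counterclockwise). Walk paths apply turn-then-translate per step
(heading updates by γ, then the position advances one stride,
mean speed × Tc, along the new heading); the order is configurable for
sensitivity checks and changes nothing qualitative. Angles are radians
internally; degrees exist only at the reporting layer.

The shipped demonstration schedules hold the mean speed fixed at 0.5, 1
or 2 m/s for five steps while the differential ramps linearly from 0 to
0.2 m/s. The ramp endpoint is a package choice (no numeric schedule is
published): 0.2 m/s produces clearly curved but non-degenerate paths at
all three speeds.

## Tunable parameters

| parameter | unit | default | meaning |
|---|---|---|---|
| x01, x02 | state/s | −0.0007, 2.4256 | background offset rate per half-center |
| g1, g2 | (state/s)/drive | 0.6203, 0.4882 | drive gain per half-center |
| r_leak | 1/s | −0.0094 | shared leak (≤ 0) |
| u_offset, u_scale | m/s | 0.1272, 0.2357 | speed→drive regression |
| emp_coeff, emp_exp | s, — | 0.5445, −0.5925 | empirical duration power law |
| swing_const | s | 0.25 | constant-swing approximation |
| W | m | 0.15 | interlimb step width |
| dt | s | 1e−4 | trajectory sampling interval |

The half-center defaults are an optimised fit to cat locomotor phase
data taken as given; the package does not re-fit them, nor the power
law.

## What the tests do and do not show

All validation targets printed reference relations, not raw data: a
passing suite shows the analytic model reproduces the phenomenological
cat-walking law and the structural properties of differential-drive
steering (zero turn at equal speeds, antisymmetry and linearity in the
differential, harder turning at slower speeds). It does not show
fidelity to individual-animal variability, to running gaits, to large
interlimb asymmetries (split-belt), or to swing-phase modulation in
flexor-dominant patterns — all outside the model. The independent
oracle for the simulator and the exact closed form is scipy's
event-detecting adaptive ODE solver at tight tolerance.

## Known limitations

* Valid for walking only (stance ≥ swing); the constant-swing split
  fails above ≈ 3.7 m/s where the empirical cycle drops below 0.25 s.
* Time-varying drive within a phase is handled only by the simulator,
  not the closed forms.
* Steering is the forward map (speeds → heading); the inverse map from
  a desired heading to limb-speed commands is not modelled, nor are
  trunk orientation, balance or spin turning.
* The heading-surface extents and units are configuration, not
  empirically fixed.
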