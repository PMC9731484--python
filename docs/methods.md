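# Methods

## Arm model

The arm is a planar two-link chain (shoulder at the origin, elbow, hand) with
rigid-body dynamics

```
M(q) q̈ + C(q, q̇) q̇ + g(q) = τ
```

where `q = (q1, q2)` are the shoulder and elbow angles, `M` is the 2×2
configuration-dependent inertia matrix, `C` collects Coriolis/centripetal
terms in Christoffel form (so that `dM/dt − 2C` is skew-symmetric, which the
test suite verifies), and `g = ∂U/∂q` is the gravity torque derived from the
potential energy of the two link masses. Default anthropometrics (SI units):

| parameter | value | meaning |
|---|---|---|
| `l1`, `l2` | 0.33, 0.32 m | link lengths |
| `m1`, `m2` | 2.10, 1.65 kg | link masses |
| `lc1`, `lc2` | 0.144, 0.218 m | center-of-mass offsets |
| `I1`, `I2` | 0.024, 0.037 kg·m² | link moments of inertia about the COM |
| `g` | 9.81 m/s², direction (0, −1) | gravity |

## Controller

Joint torque combines an endpoint impedance around a moving reference with a
joint-space elastic field at the elbow:

```
τ = Jᵀ Kx (xr − x) − Jᵀ Bx ẋ + Kq (qr − q)
```

with `Kx = diag(500, 500)` N/m, `Bx = diag(10, 10)` N·s/m,
`Kq = [[0, 0], [0, E]]` with elbow stiffness `E ∈ {0, 10, 20, 30, 40, 50}`
N·m/rad, and joint reference `qr = (π/4, π/4)` rad. The endpoint reference is
a circle of radius 0.1 m traversed at angular frequency `ω = 2π/3.33` rad/s
(one revolution per 3.33 s); `ω` is chosen so that the movement's nominal
cycle time equals the slowest constant-speed stimulus duration, making the
*original* and retimed conditions comparable in overall tempo. The circle
center defaults to (0.25, 0.25) m, a location in the flexed part of the
workspace where raising `E` monotonically lengthens and elongates the steady
path; centers near full arm extension instead shrink the path with `E` and do
not produce the intended stimulus family.

Because `Kq` is rank one, the elbow spring projects into endpoint space as a
rank-one stiffness of magnitude `E · ‖∇q2‖²`; it deforms the circular hand
path increasingly as `E` grows, which is the physical source of the stimulus
family.

## Steady-cycle extraction

The equations of motion are integrated with an adaptive Runge–Kutta method
(`scipy.integrate.solve_ivp`, RK45, `rtol = 1e-8`, `atol = 1e-10`), starting
at rest on the reference circle (elbow-up inverse kinematics). Successive
reference periods are compared; a cycle is accepted as steady when the
maximum endpoint distance to the previous cycle falls below 1e-4 m (at most
20 cycles, typically 2 with the defaults). The accepted cycle is resampled
from the dense ODE output onto a uniform 1 ms grid, including the closing
sample, giving 3331 samples per cycle.

## Path geometry and retiming

Arc length is the cumulative chord length of the sampled path. The radius of
curvature `R = |v|³ / |v × a|` is estimated with 4th-order periodic finite
differences after light circular smoothing (moving average, window 9), and
capped at 10 m to keep near-straight segments finite. A final sample that
revisits the start (gap below half the median chord) is treated as the
closing duplicate of the cycle.

Timing conditions re-assign time stamps to the fixed position samples:

- **original** — the dynamics' own uniform time grid.
- **constant** — `t(s) = s / v` with `v = 0.185` m/s, so every stimulus moves
  at the same tangential speed and duration is proportional to arc length
  (3.286 s at `E = 0` up to 3.716 s at `E = 50` with the defaults).
- **inverse** — the two-thirds power law, `v = K · R^(1/3)` in terms of the
  radius of curvature. `K` is set in closed form,
  `K = Σ ds · R^(1/3) / T`, so the duration `T` matches the constant
  condition on the same path exactly (no iteration needed because duration is
  `Σ ds / v` and `v` scales linearly with `K`).
- **variable** — the constant-condition time vector of the stiffest
  (`E = 50`) path transplanted by ordinal sample index, giving a speed
  profile uncorrelated with the receiving path's geometry. On the donor path
  itself this reduces to the constant condition.

Retiming never changes a position sample, so all geometric features are
identical across the four conditions of one path by construction (and tested).
Each stimulus carries the loop count needed to fill a 20 s display.

## Features

Path features use arc-length quadrature weights so they are invariant to
sampling density: centroid, oblongness (ratio of the larger to the smaller
eigenvalue of the 2×2 position covariance; 1 for a circle), shoelace enclosed
area, and mean curvature (arc-length average of `1/R`). Joint features are the
shoulder/elbow ranges of motion and the shoulder–elbow relative phase, found
as the peak lag of the circular cross-correlation of the mean-removed joint
waveforms resampled to a uniform grid; the sign convention is positive when
the elbow waveform trails the shoulder waveform, and the phase is reported
against the stimulus' own (possibly retimed) time base. Temporal features are
time-weighted RMS velocity, acceleration and jerk in joint and endpoint
coordinates, computed by second-order finite differences with periodic
wrap-around directly on the nonuniform retimed grids.

## Synthetic raters

Each simulated subject rates perceived stiffness on a 7-point scale. The
latent response is

```
latent = intercept + gain · z(feature) + penalty · [condition ≠ original] + ε
```

where `z(feature)` standardizes the driving feature over the subject's own
stimulus set (default driving feature: negated elbow range of motion, which
decreases monotonically with `E`), `ε` is Gaussian noise, and the optional
temporal penalty raises ratings for non-veridical velocity profiles. The
latent value is shrunk toward the scale midpoint by a central-tendency factor
and quantized to the nearest of `n` equally spaced scale levels. Trial
schedules are blocked and randomized within block: the stiffness-rating
experiment presents 6 stimuli × 5 blocks per subject with timing condition
varied between subjects; the timing-condition experiment presents the four
conditions of one path, 5 blocks, within subject.

This generator is a deliberately minimal linear-readout model. It is adequate
for testing the analysis chain (parameter recovery, condition contrasts,
quantization effects) but makes no claim to model human stiffness perception:
real raters need not be linear in any single feature, the noise need not be
Gaussian or homoscedastic, and near the scale edges clipping attenuates the
effective gain — which is why recovery checks are run in a regime where the
latent responses stay strictly on-scale.

## Statistics

Per subject, an ordinary least-squares line of rating against `E` gives the
slope, intercept, R² and Pearson r; a subject whose ratings never vary is
reported with slope 0 and R² 0 by convention. Between-subjects comparisons
use a one-way ANOVA over per-subject R² and slopes (requiring at least two
subjects per condition when two or more conditions are present); the
within-subject experiment is summarized by per-condition subject means and
all pairwise paired t-tests (a pair with identically zero differences is
reported as t = 0, p = 1). Written strategy reports are coded into four
binary features (path information, temporal information, joint motion,
endpoint motion) by case-insensitive whole-word keyword matching; "angle"
counts as both path information and joint motion.

## Numerical and design choices

- Integration tolerances (1e-8/1e-10) leave the one-cycle energy audit —
  change in stored energy versus boundary work minus damping dissipation —
  closed to well under 0.5 % of the dissipated energy.
- The curvature cap (10 m) bounds the inverse-condition speed on
  near-straight segments; power-law checks exclude capped samples.
- The closed-form `K` for the inverse condition avoids an iterative duration
  match; the residual mismatch with the constant condition is below 0.1 %.
- CSV products are written with `%.17g` and read with the round-trip float
  parser, so trajectory files reproduce the in-memory doubles exactly.
- All randomness flows from explicit seeds through `numpy` `SeedSequence`
  spawning (one stream per simulated subject), making every pipeline product
  bit-reproducible.

## Limitations

- The arm is planar and the hand is not modeled as a separate segment;
  results depend quantitatively on the assumed anthropometrics.
- Stimulus rendering (stick-figure animation) is out of scope; the toolkit
  stops at trajectories, features and synthetic ratings.
- The rater model is a measurement-chain stub, not a perceptual theory; group
  statistics produced from it characterize the pipeline, not human observers.
- Strategy coding handles text only; drawings or gestures cannot be coded.
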