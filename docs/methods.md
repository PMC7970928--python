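# Methods

## Motion model and arrival times

A player at position `x0` with velocity `v0` who commits to sprinting in a
fixed unit direction `n` follows

    x(t) = x0 + (1 − e^{−αt})/α · v0 + V_max (t − (1 − e^{−αt})/α) n.

The model has two parameters: the terminal sprint speed `V_max` (default
7.8 m/s) and the relaxation rate `α` (default 1.3 1/s, the inverse of the
time scale on which the initial velocity decays and the sprint speed is
reached). The same parameters are used for every player by default — sprint
characteristics vary little across professional outfield players — and
per-player overrides can be passed wherever a `MotionParams` is accepted.

Because the sprint term is isotropic in `n`, the set of reachable positions
at time `t` is a circle with centre `x0 + (1 − e^{−αt})/α · v0` (the drift of
the decaying initial velocity, which converges to `x0 + v0/α`) and radius
`V_max (t − (1 − e^{−αt})/α)` (zero at `t = 0`, asymptotically linear with
slope `V_max`). The minimum arrival time to a target is the first root of

    g(t) = ‖target − centre(t)‖ − radius(t).

`g` is not monotone in general — when `v0` points away from the target the
distance to the centre first grows — so a bracketing solver started on an
arbitrary interval could skip the first root. We therefore scan `g` on a
coarse grid (Δt = 0.01 s) and refine the first sign change by bisection to
1e-6 s. The scan range is bounded analytically: the centre never strays more
than `|v0|/α` from `x0` and the radius exceeds `V_max·t − V_max/α`, so the
first crossing occurs before `(d0 + |v0|/α)/V_max + 1/α`. A hard cap
(`t_max = 60 s`) turns pathological inputs into an explicit error. Targets
closer than 1e-6 m return exactly zero. Recorded speeds above 12 m/s are
accepted with a warning (tracking noise), above 15 m/s the I/O validators
reject the frame.

The grid evaluation is vectorised per player over all cells (distances to the
drift curve are computed on the shared time grid in memory-bounded chunks),
which keeps a full 211 × 137-cell, 22-player evaluation near 20 s on one CPU.

## z1, z2 and the four-way division

With `τ_of` and `τ_df` the team minima of the per-player arrival times
(offense = side in possession), the coordinates

    z1 = (τ_df − τ_of)/√2,   z2 = (τ_df + τ_of)/√2

are an exact 45° rotation, so `z1² + z2² = τ_of² + τ_df²` holds cell-wise to
rounding error, and `z2 ≥ |z1|` always. With all players at rest and equal
parameters, `τ` is a monotone function of distance, so the sign of `z1`
reproduces the Voronoi (nearest-team) partition; the moving-player field is
its natural generalisation.

Region labels use `z1 = 0` and `z2 = 2` (the sparsity value at which passes
empirically move outside the formation, i.e. where the mean `R̃` crosses 1).
The strict inequalities leave the boundaries undefined; we classify `z1 = 0`
as risky and `z2 = 2` as dense, so `(0, 2) → D`. This only affects a measure-
zero set of locations and keeps the partition exhaustive.

Goalkeepers are **included** in the team minima by default (they genuinely
contest balls near their area); `--exclude-gk-tau` / `include_goalkeepers=False`
is provided for sensitivity analysis. Goalkeepers are always excluded from
the formation centroid and spread, which are defined over the 20 outfield
players.

## Pass evaluation and outcome statistics

A pass `[t_o, x_o, t_e, x_e, q]` is evaluated at the state of its end point
at the moment the pass is made: `z1(x_e, t_o)`, `z2(x_e, t_o)` and
`R̃ = ‖x_e − x_c(t_o)‖/σ(t_o)`. The snapshot used is the nearest frame to
`t_o`, required to lie within one 25 Hz frame (0.04 s). The formation spread
`σ` is the RMS distance of the 20 outfield players from their centroid; a
zero spread is degenerate and rejected.

- **Class-conditional normals.** `z1 | q` is fitted per class by the sample
  mean and the ddof = 0 standard deviation (the maximum-likelihood normal
  fit). Classes need at least two samples and non-zero variance.
- **Empirical success curve.** Mean of `q` in `z1` bins (default width 0.1);
  bins with fewer than 30 passes are suppressed as noise. Both defaults are
  package choices, configurable.
- **Sigmoid.** `P(q=1|z1) = expit(a·z1 + b)` is fitted by logistic-regression
  maximum likelihood (Newton iteration via statsmodels, tolerance 1e-10) on
  the raw `(z1, q)` pairs. Whether such a curve should be fitted to raw pairs
  or to binned fractions is a genuinely open choice; MLE is the default and a
  weighted least-squares fit to the binned curve (`method="binned"`) is
  provided for comparison. Perfect separation is detected up front (a `z1`
  threshold splitting the classes) and reported as a numerical error since
  the MLE diverges.
- **Bayes identity.** When the class sigmas agree, Bayes' rule reduces the
  posterior exactly to the sigmoid with `a = (μ1−μ0)/σ²`,
  `b = −(μ1²−μ0²)/(2σ²) + log(p1/(1−p1))`; the default prior is the empirical
  success fraction. With unequal sigmas (as in the published fits, 0.54 vs
  0.38) the log-odds are quadratic in `z1`; the function then flags the
  reduction inapplicable and returns the exact quadratic-discriminant
  posterior instead — this asymmetry is why an empirical success curve can
  deviate from the best sigmoid in the `z1 < 0` tail. Equality is tested at
  relative 1e-6; estimated sigmas are essentially never exactly equal, so
  callers comparing against the closed form should pool the class sigmas
  first (as the tests do).
- **Pre-shot passes.** A boolean flag on pass events supports analysing
  passes immediately preceding shots separately; these tend to have lower
  `z1` (riskier) than passes at large.

## Synthetic data: what it emulates, and what it does not

The generators state one world and keep it fixed:

- **Snapshots**: mirrored 4-4-2 templates with isotropic Gaussian positional
  jitter (sd 3 m, reduced to 0.9 m for goalkeepers so they stay near their
  line), velocities with uniform random direction and speed ~ U(0, 8) m/s,
  possession assigned by fair coin.
- **Labelled z1 values**: `q ~ Bernoulli(prior1)`, `z1 | q` normal at the
  published class parameters (0.69, 0.54) / (−0.25, 0.38). The overall prior
  success probability is not published; the default 0.78 is a typical
  professional pass-completion rate.
- **Outcome passes**: `z1 ~ U(−2, 3)` (spanning the support observed in real
  pass data), `q ~ Bernoulli(expit(4.68·z1 + 0.48))`, `z2 = |z1| + U(0, 4)`
  (respecting `z2 ≥ |z1|`), and `R̃ = z2/2` plus Gaussian noise (sd 0.15,
  clipped at 0) so the mean-`R̃` curve crosses 1 near `z2 = 2` as observed.
- **Snapshot + pass pairs**: the origin is a possessing outfield player, the
  end point uniform on the pitch, and the outcome drawn from the sigmoid at
  the *true* `z1` of the end point computed from the emitted snapshot, so
  every derived quantity is recomputable.

All randomness flows from a single `numpy.random.Generator`; a fixed seed
reproduces every dataset bit for bit.

What green tests on this world establish: the solver matches brute-force
first-crossing scans, the algebraic identities hold on full grids, and the
estimators recover the parameters of data generated at the published values.
What they do not establish: that real match data follow these distributions —
real formations deform, velocities are autocorrelated, pass targets are
chosen tactically, and outcomes depend on more than `z1` (ball flight,
pressure on the passer, distance to goal are all outside the model).

## Tracking I/O and velocity estimation

Tracking files carry positions at 25 Hz; how velocities are derived from
positions is not standardised, so it is explicit configuration here. The
default is a central finite difference across a 5-frame window (exact for
affine motion, O(dt²) error otherwise, and mildly noise-averaging because the
step spans 2 frames each way); the first/last half-window frames use
one-sided differences, short tracks fall back to smaller windows, and an
isolated single frame gets zero velocity with a warning. Frames are validated
strictly: 22 players, 11 per side, exactly one goalkeeper per side, positions
within the pitch plus a 5 m pad, speeds below 15 m/s.

Analysis functions deliberately do not re-impose the 22-player invariant, so
reduced scenarios (e.g. the two-player Voronoi limit) can be constructed
programmatically; file readers always validate.

## Numerical choices

- Grid: 0.5 m default resolution over a 105 × 68 m pitch (211 × 137 cell
  centres including the boundary); the resolution must divide the pitch
  exactly. Contour displays cap τ at 2 s by default purely for legibility.
- Arrival solver: scan Δt = 0.01 s, bisection to 1e-6 s, position tolerance
  1e-6 m, `t_max` 60 s.
- Logistic MLE: Newton, convergence 1e-10, 200 iterations max; standard
  errors from the observed information.
- `R̃`-vs-`z2` curve: bin width 0.25 (no published value).

## Known limitations

- The motion model ignores reaction time, acceleration anisotropy, turning
  and fatigue; all players share parameters unless overridden.
- `z1`/`z2` evaluate the end location only — not ball flight time, passing
  lanes, or interception along the trajectory.
- The synthetic world is a statistical emulation, not an agent-based match
  simulation; headline numbers from proprietary match data can only be
  checked as parameter recovery, not reproduced.
- Snapshot selection for a pass is nearest-frame, not interpolated.
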