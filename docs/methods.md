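# Methods

## Model

Each cell is an isolated self-propelled particle in the plane. Its state is
a position `x` and a heading angle `theta`; the heading defines the unit
polarity vector `p = (cos theta, sin theta)`. Per timestep `dt` the model
updates, in order:

1. **Heading.** `theta <- theta + sqrt(2 Dr) dW_theta`, where `dW_theta` is
   an increment of an uncorrelated noise series (variance `dt`) and `Dr >= 0`
   is the rotational diffusion coefficient. Under guidance (below) an extra
   deterministic rotation is added after the stochastic increment.
2. **Position.** `x <- x + (Fm/gamma_s) p dt + (alpha/gamma_s) (dWx, dWy)`,
   using the heading just updated. `Fm` is the motile-force magnitude,
   `gamma_s` the substrate friction, and `(dWx, dWy)` are increments of two
   independent fractional-Brownian noise series with Hurst index `H`,
   scaled by the translational-noise amplitude `alpha`.

The heading is stored unwrapped so cumulative rotation is inspectable; all
trigonometry is wrap-invariant. The per-step update order (heading first,
then position) makes the scheme explicit; because the position update does
not depend on the position itself, an implicit update of `x` would give the
identical result.

Translational correlation is the model's proxy for intrinsic cellular
memory — the finite lifetime of lamellipodia, adhesions and polarity
machinery that stabilizes displacement over consecutive steps — while
angular diffusion models reorientation events that destabilize it.

### Guidance (taxis)

An organizing center at `x_org` adds a heading correction with rate
`f_tax * phi` toward the target, where `phi` is the angle between `p` and
the target direction `v_org = x_org - x`, recomputed each step, with
magnitude `arccos(v_org . p / ||v_org||)`. The arccos form is unsigned; the
turn direction is resolved by the planar cross/dot construction so the
correction always rotates toward the target. Two degenerate configurations
get a zero correction: the cell standing exactly on the center (no defined
direction) and exact anti-alignment, which is an unstable equilibrium —
injecting an arbitrary turn direction there would replace a symmetric
measure-zero configuration with an asymmetric artifact. Guidance enters the
angular equation only, so with `alpha = 0` the total distance traveled is
independent of `f_tax`.

A consequence worth stating because it shapes tests: the deterministic
heading-to-target angle obeys `dphi/dt = -f_tax phi + sin(phi)/r` (with `r`
the distance to the target; the second term is the bearing drift from the
cell's own motion), so the angle is guaranteed non-increasing only where
`f_tax * r > 1`. Weak guidance (`f_tax = 0.01`) at the default geometry is
in the marginal regime from the start, which is why some cells escape the
cue entirely.

## Noise synthesis

Fractional Brownian motion `W^H` is the centered Gaussian process with
`Cov(W^H(t), W^H(s)) = (t^{2H} + s^{2H} - |t-s|^{2H})/2`. Its increments on
the uniform grid (fractional Gaussian noise) are synthesized exactly by
Davies–Harte circulant embedding (`O(n log n)`), with a Hosking
(Durbin–Levinson) recursion as the exact fallback should the embedding ever
fail to be nonnegative definite; exactness makes the closed-form covariance
a true oracle in the tests rather than an asymptotic approximation. Only
`H >= 0.5` (uncorrelated to persistent) is used in the study presets;
anti-persistent `H < 0.5` is supported by the generator but flagged, as it
has no biological reading in this context.

**Increment scaling.** Per-step increments carry variance `dt^{2H}`: the
restriction of standard fBm to the grid. At `H = 0.5` this reduces exactly
to Wiener increments of variance `dt`.

**Initialization.** Every noise series (angular and both translational
components) starts from an explicit Gaussian seed value used as its first
increment, after which the series continues by exact conditional sampling
(a kriging correction on an unconditional Davies–Harte draw — exact for
Gaussian processes and `O(n)` after synthesis). The seed value is drawn
from the stationary marginal `N(0, dt^{2H})` — under the default protocol
that is `N(0, 0.1)` (variance 0.1) for the angular series and for
uncorrelated translational noise. The draw is deliberately *not* taken with
variance 0.1 at every `H`: for `H` near 1 the increment correlation is
close to 1, so a first increment an order of magnitude above the stationary
step scale would propagate down the whole series and hand every strongly
correlated cell a spurious ballistic drift that dominates the ensemble MSD
(it compresses the MSD separation between `Dr = 0` and `Dr = 10` at
`H = 0.99` from roughly tenfold to below twofold). The convention is
isolated in `dynamics.draw_initial_increment` so it can be switched in one
place.

**Seeding.** Each replicate's master seed spawns four independent
substreams (initial heading, noise-x, noise-y, angular) via numpy's
`SeedSequence`, so replicates are reproducible, mutually independent, and
pinning the initial heading by hand does not shift the noise streams. Grid
runs derive the replicate seed from `(base_seed, cell_index, replicate)`,
making results independent of execution order.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `Fm` | motile-force magnitude | 1 | arbitrary force unit; only `Fm/gamma_s` (speed) matters |
| `gamma_s` | substrate friction | 1 | sets speed 1 length-unit per time-unit |
| `alpha` | translational-noise amplitude | 0.25 | balances the noise scale against the advective step `Fm/gamma_s * dt = 0.1` |
| `Dr` | rotational diffusion coefficient | 0 | studied over {0, 0.1, 1, 10} |
| `H` | Hurst index, translational noise | 0.5 | studied over {0.5, 0.75, 0.99}; `alpha = 0` is the control |
| `Htheta` | Hurst index, angular noise | 0.5 | white angular noise; correlated reorientation is out of scope |
| `dt` | timestep | 0.1 | reference protocol |
| `n_steps` | steps per replicate | 1000 | 100 time units; the deterministic run spans exactly 100 length units |
| `f_tax` | guidance strength | 0 | studied over {0.01, 0.1, 1} |
| `x_org` | organizing center | `(-100/sqrt(2), -100/sqrt(2))` | 100 units from the origin, on the deterministic reference ring |

The organizing center's stated distance (100 units, on the reference ring)
is taken as authoritative over the ambiguous printed coordinate form
`(-100/2, -100/2)`, whose norm would be ~70.7; `--x-org` overrides it.

## Statistics

* **Persistence factor** `PF = ||x_f - x_0|| / sum_i ||x_{i+1} - x_i||`,
  in [0, 1]; defined as 0 (with a warning) for a path of zero total length,
  which cannot arise from the model but can from arbitrary CSV input.
* **Relative turning angle** `theta_R = pi - arccos((a^2 + b^2 - c^2)/2ab)`
  over consecutive position triples; degenerate triples (repeated points)
  are skipped and counted, never imputed. The arccos argument is clamped to
  [-1, 1] against rounding.
* **Increment** — per-step displacement magnitude; the closed-form
  expansion `sqrt(dt^2 + 2 alpha dt (cos theta dWx + sin theta dWy) +
  alpha^2 (dWx^2 + dWy^2))` is cross-validated against the step norm.
* **Initial alignment** — `alpha` times the cosine of the angle between the
  first translational-noise vector and the initial heading. Only its range
  `[-alpha, alpha]` and verbal definition are fixed externally; the cosine
  projection scaled by `alpha` is the minimal formula with exactly that
  range.
* **Ensemble MSD** — `MSD(t) = <||x(t) - x_0||^2>` over a seeded random
  subsample of N replicates (ensemble definition, origin-anchored; no time
  averaging). The power-law exponent is the least-squares slope of
  log MSD vs log t; the default fit window is the last decade of time
  points, excluding the early advective transient, and is configurable
  because no canonical window exists.

## Numerical choices

* Validation rejects `n_steps = 0`, non-positive `dt`, `Fm`, `gamma_s`, and
  `H` outside (0, 1).
* The circulant-embedding eigenvalues are clipped at zero below a relative
  tolerance of 1e-10 (rounding noise); a genuinely negative spectrum
  triggers the Hosking fallback.
* "Exact" contracts (deterministic displacement, increment constancy, CSV
  round-trip) are asserted at 1e-9 absolute or tighter; trajectory CSVs
  write floats at 17 significant digits and are parsed back with
  round-trip precision, so write/read is bit-exact.
* Division by `gamma_s` is kept everywhere even though the presets fix it
  to 1, so the force-balance form holds in full.

## What the ensembles do and do not emulate

The simulated ensembles reproduce the study conditions: isolated cells, a
homogeneous unbounded substrate, constant motile force, noise stationary in
time, and (for taxis) a single fixed target sensed with perfect accuracy at
any distance. Passing tests therefore demonstrate the stochastic model's
internal behavior — persistence scaling with `H`, diffusion regimes, the
guidance interplay — not agreement with tracked cell data. Real
trajectories add cell–cell interaction, finite domains, measurement noise
and sampling-rate effects, time-varying polarity, and gradient-strength
sensing, none of which are modeled. Problem sizes in the test suite (ending
at 200 replicates x 1000 steps for full presets, with trend checks at
50–100 replicates) were chosen as the smallest ensembles at which the
documented Monte-Carlo tolerances hold comfortably.

## Known limitations

* Exact fBm synthesis is whole-path: the horizon must be fixed up front, so
  the integrator cannot be extended online without regenerating noise.
* The guidance term uses the heading *after* the stochastic angular kick of
  the same step; schemes that evaluate it before the kick differ at
  `O(dt^{3/2})`.
* `H` very close to 1 (condition number of the increment covariance grows)
  is limited by double precision; `H = 0.99` is well within range.
* The CLI's `sweep` runs cells serially; replicates are embarrassingly
  parallel in principle, and seeds derive from indices so any future
  parallel scheduler reproduces identical results.
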