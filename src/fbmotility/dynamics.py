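"""Single-cell equations of motion and the trajectory integrator.

Each cell is a self-propelled particle in the plane.  Its motile force of
magnitude ``Fm`` acts along the heading ``p = (cos theta, sin theta)`` against
a substrate friction ``gamma_s``, and the displacement carries a correlated
translational noise of amplitude ``alpha`` whose x and y components are
independent fBm increment series with Hurst index ``H``:

    dx = (Fm / gamma_s) * p * dt + (alpha / gamma_s) * (dWx^H, dWy^H)

The heading undergoes angular diffusion with coefficient ``Dr`` driven by an
(uncorrelated, ``Htheta = 0.5``) noise:

    theta <- theta + sqrt(2 * Dr) * dW

Per step the heading is updated first and the fresh heading enters the
position update.  Noise series are pre-generated for the whole horizon with
exact fBm synthesis and consumed stepwise; the first increment of every
series is the model's initialization draw (see
:func:`draw_initial_increment`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .noise_fbm import condition_on_first, sample_fgn, validate_hurst

__all__ = [
    "MotilityParams",
    "CellState",
    "Trajectory",
    "draw_initial_increment",
    "step_orientation",
    "step_position",
    "increment_magnitude",
    "run_simulation",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

def draw_initial_increment(rng: np.random.Generator, H: float,
                           dt: float) -> float:
    """Draw the first increment of a noise series from its stationary
    marginal, ``N(0, dt**(2*H))``.

    Under the reference protocol (``dt = 0.1``) this is ``N(0, 0.1)`` —
    variance 0.1 — for the angular noise (``Htheta = 0.5``) and for
    uncorrelated translational noise (``H = 0.5``); for ``H > 0.5`` it is
    the correspondingly smaller stationary step variance.  Drawing the seed
    value with a larger variance than the stationary one would hand every
    strongly correlated cell a spurious persistent drift an order of
    magnitude above the noise scale, which distorts the ensemble MSD.
    Isolated here so the initialization convention can be switched in one
    place.
    """
    return float(rng.normal(0.0, dt**H))


@dataclass(frozen=True)
class MotilityParams:
    """Scalar parameters of the single-cell model.

    Defaults reproduce the reference protocol: unit motile force and
    friction, ``alpha = 0.25``, 1000 steps of ``dt = 0.1`` (100 time units).
    """

    Fm: float = 1.0
    gamma_s: float = 1.0
    alpha: float = 0.25
    Dr: float = 0.0
    H: float = 0.5
    Htheta: float = 0.5
    dt: float = 0.1
    n_steps: int = 1000

    def __post_init__(self):
        if self.Fm <= 0:
            raise ValueError("Fm must be positive")
        if self.gamma_s <= 0:
            raise ValueError("gamma_s must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.Dr < 0:
            raise ValueError("Dr must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        validate_hurst(self.H, warn_antipersistent=True)
        validate_hurst(self.Htheta)

    @property
    def speed(self) -> float:
        """Deterministic advection speed Fm / gamma_s."""
        return self.Fm / self.gamma_s


@dataclass
class CellState:
    """Instantaneous state of one cell."""

    position: np.ndarray
    theta: float
    t: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (2,):
            raise ValueError("position must be a 2-vector")

    @property
    def direction(self) -> np.ndarray:
        """Unit heading vector p = (cos theta, sin theta)."""
        return np.array([math.cos(self.theta), math.sin(self.theta)])


@dataclass
class Trajectory:
    """Per-timestep record of one simulated cell.

    ``theta`` is stored unwrapped so cumulative rotation is inspectable.
    ``noise_x``/``noise_y`` hold the translational fBm increments actually
    consumed (needed for the initial-alignment statistic); they are ``None``
    for trajectories read back from CSV.
    """

    times: np.ndarray
    positions: np.ndarray
    thetas: np.ndarray
    step_vectors: np.ndarray
    params: MotilityParams | None = None
    replicate_id: int = 0
    seed: int | None = None
    noise_x: np.ndarray | None = field(default=None, repr=False)
    noise_y: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.thetas = np.asarray(self.thetas, dtype=float)
        self.step_vectors = np.asarray(self.step_vectors, dtype=float)
        n = len(self.times) - 1
        if n < 1:
            raise ValueError("a trajectory needs at least one step")
        if self.positions.shape != (n + 1, 2):
            raise ValueError("positions must have shape (n_steps + 1, 2)")
        if self.thetas.shape != (n + 1,):
            raise ValueError("thetas must have shape (n_steps + 1,)")
        if self.step_vectors.shape != (n, 2):
            raise ValueError("step_vectors must have shape (n_steps, 2)")

    @property
    def n_steps(self) -> int:
        return len(self.times) - 1

    @property
    def final_position(self) -> np.ndarray:
        return self.positions[-1]


def step_orientation(theta: float, Dr: float, dt: float,
                     angular_increment: float) -> float:
    """One angular-diffusion update: ``theta + sqrt(2*Dr) * dW``.

    ``angular_increment`` must be a Wiener increment over ``dt``
    (variance ``dt``); ``Dr = 0`` returns ``theta`` unchanged.
    """
    if Dr < 0:
        raise ValueError("Dr must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return theta + math.sqrt(2.0 * Dr) * angular_increment


def step_position(state: CellState, params: MotilityParams,
                  dWx: float, dWy: float) -> np.ndarray:
    """One displacement step ``(Fm/gamma_s) p dt + (alpha/gamma_s) dW``.

    ``state.theta`` must already hold the heading for this step.
    """
    adv = params.speed * params.dt
    ns = params.alpha / params.gamma_s
    return np.array([
        adv * math.cos(state.theta) + ns * dWx,
        adv * math.sin(state.theta) + ns * dWy,
    ])


def increment_magnitude(theta: float, dWx: float, dWy: float,
                        alpha: float, dt: float) -> float:
    """Step length from the closed-form expansion (unit force and friction):

    ``|dx| = sqrt(dt^2 + 2 alpha dt (cos(theta) dWx + sin(theta) dWy)
    + alpha^2 (dWx^2 + dWy^2))``.

    Algebraically this is the norm of the displacement step, so the radicand
    is a perfect square sum and cannot be negative (asserted against
    rounding).
    """
    radicand = (dt * dt
                + 2.0 * alpha * dt * (math.cos(theta) * dWx
                                      + math.sin(theta) * dWy)
                + alpha * alpha * (dWx * dWx + dWy * dWy))
    assert radicand > -1e-12, "increment radicand must be non-negative"
    return math.sqrt(max(radicand, 0.0))


def _replicate_noise(params: MotilityParams, seed) -> tuple[float, np.ndarray,
                                                            np.ndarray,
                                                            np.ndarray]:
    """Build (theta0, dWx, dWy, dWtheta) for one replicate.

    A master seed spawns four independent substreams — initial heading,
    translational x, translational y, angular — so replicates are
    reproducible and mutually independent, and pinning ``theta0`` by hand
    does not shift the noise streams.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rng_theta0, rng_x, rng_y, rng_ang = map(np.random.default_rng,
                                            ss.spawn(4))
    theta0 = float(rng_theta0.uniform(0.0, 2.0 * math.pi))
    n, dt = params.n_steps, params.dt

    def series(rng, H):
        first = draw_initial_increment(rng, H, dt)
        if n == 1:
            return np.array([first])
        x = sample_fgn(n, H, dt, rng)
        return condition_on_first(x, H, dt, first)

    dwx = series(rng_x, params.H)
    dwy = series(rng_y, params.H)
    dwt = series(rng_ang, params.Htheta)
    return theta0, dwx, dwy, dwt


def _integrate(params: MotilityParams, theta0: float, dWx: np.ndarray,
               dWy: np.ndarray, dWtheta: np.ndarray, angular_bias=None,
               replicate_id: int = 0, seed: int | None = None) -> Trajectory:
    """Core explicit stepping loop shared by guided and unguided runs.

    ``angular_bias(x, y, theta) -> rate`` is an optional extra angular drift
    (radians per unit time) applied after the stochastic heading update; the
    taxis module supplies it.  Keeping one loop guarantees that a zero bias
    reduces bitwise to the unguided model under the same seed.
    """
    n, dt = params.n_steps, params.dt
    adv = params.speed * dt
    ns = params.alpha / params.gamma_s
    sq = math.sqrt(2.0 * params.Dr)

    xs = np.empty(n + 1)
    ys = np.empty(n + 1)
    thetas = np.empty(n + 1)
    x = y = 0.0
    theta = float(theta0)
    xs[0] = ys[0] = 0.0
    thetas[0] = theta
    lx, ly, lt = dWx.tolist(), dWy.tolist(), dWtheta.tolist()
    cos, sin = math.cos, math.sin
    for k in range(n):
        theta = theta + sq * lt[k]
        if angular_bias is not None:
            theta = theta + angular_bias(x, y, theta) * dt
        x += adv * cos(theta) + ns * lx[k]
        y += adv * sin(theta) + ns * ly[k]
        xs[k + 1] = x
        ys[k + 1] = y
        thetas[k + 1] = theta

    positions = np.column_stack([xs, ys])
    return Trajectory(
        times=np.arange(n + 1) * dt,
        positions=positions,
        thetas=thetas,
        step_vectors=np.diff(positions, axis=0),
        params=params,
        replicate_id=replicate_id,
        seed=seed if isinstance(seed, int) else None,
        noise_x=dWx,
        noise_y=dWy,
    )


def run_simulation(params: MotilityParams, seed,
                   theta0="random", replicate_id: int = 0) -> Trajectory:
    """Simulate one cell for ``params.n_steps`` steps from the origin.

    ``theta0="random"`` draws the initial heading uniformly on [0, 2*pi);
    a float pins it.  Identical arguments replay bit-identically.
    """
    t0, dwx, dwy, dwt = _replicate_noise(params, seed)
    if theta0 != "random":
        t0 = float(theta0)
    return _integrate(params, t0, dwx, dwy, dwt,
                      replicate_id=replicate_id, seed=seed)


# ---------------------------------------------------------------------------
# Trajectory interchange format: plain CSV + JSON sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def write_trajectory_csv(trajectories, path, extra_meta: dict | None = None):
    """Write trajectories to CSV (``replicate,step,t,x,y,theta``).

    Floats are written at 17 significant digits so a read-back round-trips
    bit-exactly.  A JSON sidecar ``<stem>.meta.json`` records the model
    parameters and seeds.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    path = Path(path)
    frames = []
    for traj in trajectories:
        n = traj.n_steps
        frames.append(pd.DataFrame({
            "replicate": np.full(n + 1, traj.replicate_id, dtype=int),
            "step": np.arange(n + 1),
            "t": traj.times,
            "x": traj.positions[:, 0],
            "y": traj.positions[:, 1],
            "theta": traj.thetas,
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g")

    meta: dict = {"n_trajectories": len(trajectories)}
    p0 = trajectories[0].params
    if p0 is not None:
        meta["params"] = asdict(p0)
    meta["seeds"] = {str(t.replicate_id): t.seed for t in trajectories}
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_trajectory_csv(path) -> list[Trajectory]:
    """Read trajectories back from the CSV schema written above.

    The JSON sidecar, when present, restores :class:`MotilityParams` and the
    per-replicate seeds.  Noise series are not part of the interchange
    format, so statistics that need them (initial alignment) are undefined
    on loaded trajectories.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"replicate", "step", "t", "x", "y", "theta"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")

    params = None
    seeds = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "params" in meta:
            params = MotilityParams(**meta["params"])
        seeds = meta.get("seeds", {})

    out = []
    for rep, grp in df.groupby("replicate", sort=True):
        grp = grp.sort_values("step")
        positions = grp[["x", "y"]].to_numpy()
        out.append(Trajectory(
            times=grp["t"].to_numpy(),
            positions=positions,
            thetas=grp["theta"].to_numpy(),
            step_vectors=np.diff(positions, axis=0),
            params=params,
            replicate_id=int(rep),
            seed=seeds.get(str(rep)),
        ))
    return out
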