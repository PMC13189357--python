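"""Directional guidance toward an organizing center.

Guidance enters exclusively through the angular equation: per unit time the
heading is corrected by ``f_tax`` times the angle between the heading and the
direction to the organizing center ``x_org``,

    dtheta/dt = sqrt(2 Dr) dW/dt + f_tax * phi_signed,

where ``|phi_signed| = arccos(v_org . p / ||v_org||)`` with
``v_org = x_org - x`` recomputed from the current position each step, and the
sign rotates the heading *toward* the target (the unsigned arccos alone
cannot distinguish left from right).  Exact anti-alignment is an unstable
equilibrium and is left uncorrected: a cell heading exactly away from the
center keeps going.  The position update is untouched, so with ``alpha = 0``
the total distance traveled is independent of the guidance strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import MotilityParams, Trajectory, _integrate, _replicate_noise

__all__ = ["TaxisParams", "taxis_angular_term", "run_taxis_simulation",
           "DEFAULT_X_ORG"]

#: Default organizing center: 100 length units from the origin along the
#: diagonal of the third quadrant, i.e. (-100/sqrt(2), -100/sqrt(2)).
DEFAULT_X_ORG = (-100.0 / math.sqrt(2.0), -100.0 / math.sqrt(2.0))


@dataclass(frozen=True)
class TaxisParams:
    """Guidance-cue strength and organizing-center location.

    The reference experiments use ``f_tax`` in {0.01, 0.1, 1}; any
    non-negative strength is accepted.
    """

    f_tax: float = 0.0
    x_org: np.ndarray = field(default=DEFAULT_X_ORG)

    def __post_init__(self):
        if self.f_tax < 0:
            raise ValueError("f_tax must be non-negative")
        x_org = np.asarray(self.x_org, dtype=float)
        if x_org.shape != (2,):
            raise ValueError("x_org must be a 2-vector")
        object.__setattr__(self, "x_org", x_org)


def _signed_angle_rate(x: float, y: float, theta: float, f_tax: float,
                       ox: float, oy: float) -> float:
    """Angular rate steering the heading toward (ox, oy); scalar core."""
    vx = ox - x
    vy = oy - y
    norm = math.hypot(vx, vy)
    if norm == 0.0:  # target reached: no defined direction
        return 0.0
    px = math.cos(theta)
    py = math.sin(theta)
    dot = (px * vx + py * vy) / norm
    if dot <= -1.0:
        # exact anti-alignment: an unstable equilibrium deliberately left
        # uncorrected rather than injecting an arbitrary turn direction
        return 0.0
    cross = (px * vy - py * vx) / norm
    # |phi| = arccos(dot), clamped against floating error
    phi = math.acos(min(1.0, dot))
    if cross > 0.0:
        return f_tax * phi
    if cross < 0.0:
        return -f_tax * phi
    # collinear: aligned needs no turn, anti-aligned left uncorrected
    return 0.0


def taxis_angular_term(position, theta: float, taxis: TaxisParams) -> float:
    """Guidance contribution to ``dtheta/dt`` at the given state.

    Returns a signed rate (radians per unit time) of magnitude
    ``f_tax * arccos(v_org . p / ||v_org||)`` whose sign rotates the heading
    toward the organizing center; 0 when already aligned, when the center is
    reached, or at exact anti-alignment.
    """
    position = np.asarray(position, dtype=float)
    if position.shape != (2,):
        raise ValueError("position must be a 2-vector")
    return _signed_angle_rate(float(position[0]), float(position[1]),
                              float(theta), taxis.f_tax,
                              float(taxis.x_org[0]), float(taxis.x_org[1]))


def run_taxis_simulation(params: MotilityParams, taxis: TaxisParams, seed,
                         theta0="random", replicate_id: int = 0) -> Trajectory:
    """Simulate one guided cell.

    Identical to the unguided simulator except that the guidance rate times
    ``dt`` is added to the heading each step, after the stochastic angular
    increment.  With ``f_tax = 0`` the result is bitwise identical to
    :func:`fbmotility.dynamics.run_simulation` under the same seed.
    """
    t0, dwx, dwy, dwt = _replicate_noise(params, seed)
    if theta0 != "random":
        t0 = float(theta0)
    bias = None
    if taxis.f_tax > 0.0:
        f_tax = taxis.f_tax
        ox, oy = float(taxis.x_org[0]), float(taxis.x_org[1])

        def bias(x, y, theta):
            return _signed_angle_rate(x, y, theta, f_tax, ox, oy)

    return _integrate(params, t0, dwx, dwy, dwt, angular_bias=bias,
                      replicate_id=replicate_id, seed=seed)
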