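"""Trajectory- and ensemble-level migration statistics.

Implements the statistics used throughout the study:

* persistence factor ``PF = ||x_f - x_0|| / sum_i ||x_{i+1} - x_i||``,
  bounded in [0, 1] (1 = perfectly straight path);
* relative turning angle between three consecutive positions via the law of
  cosines, ``theta_R = pi - arccos((a^2 + b^2 - c^2) / (2ab))`` in [0, pi];
* per-step increment magnitudes and their mean;
* initial alignment ``alpha * cos(angle)`` between the first translational
  noise vector and the initial heading, bounded in [-alpha, alpha];
* ensemble mean squared displacement ``MSD(t) = <||x(t) - x_0||^2>`` over a
  (possibly subsampled) set of replicates seeded at the origin, and the
  log–log power-law exponent that classifies the diffusion regime
  (ballistic = 2, diffusive = 1, super > 1, sub < 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryStats",
    "MSDCurve",
    "DegenerateGeometryError",
    "persistence_factor",
    "relative_turning_angle",
    "relative_turning_angles",
    "trajectory_stats",
    "initial_alignment",
    "ensemble_msd",
    "msd_scaling_exponent",
    "classify_diffusion",
    "summary_frame",
    "write_summary_csv",
    "write_msd_csv",
]


class DegenerateGeometryError(ValueError):
    """Raised when a turning angle is requested for a repeated point."""


def _positions(traj) -> np.ndarray:
    """Accept a Trajectory or a bare (m, 2) position array."""
    pos = getattr(traj, "positions", traj)
    pos = np.asarray(pos, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 2:
        raise ValueError("need an (m >= 2, 2) array of positions")
    return pos


def persistence_factor(traj) -> float:
    """Net displacement divided by total path length, in [0, 1].

    A path that never moves has no defined direction; its PF is returned
    as 0 with a warning (cannot occur under the model, where increments are
    strictly positive almost surely, but arbitrary CSV input must be
    handled).
    """
    pos = _positions(traj)
    steps = np.diff(pos, axis=0)
    total = float(np.linalg.norm(steps, axis=1).sum())
    if total == 0.0:
        warnings.warn("zero total distance; persistence factor set to 0",
                      UserWarning, stacklevel=2)
        return 0.0
    return float(np.linalg.norm(pos[-1] - pos[0]) / total)


def relative_turning_angle(x1, x2, x3) -> float:
    """Turning angle for three consecutive positions, in [0, pi].

    Law-of-cosines form with ``a = |x2 - x1|``, ``b = |x3 - x2|``,
    ``c = |x3 - x1|``; 0 for collinear forward motion, pi for a reversal.
    Raises :class:`DegenerateGeometryError` when a or b vanishes.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x3 = np.asarray(x3, dtype=float)
    a = float(np.linalg.norm(x2 - x1))
    b = float(np.linalg.norm(x3 - x2))
    if a == 0.0 or b == 0.0:
        raise DegenerateGeometryError(
            "turning angle undefined for repeated points")
    c = float(np.linalg.norm(x3 - x1))
    cosarg = (a * a + b * b - c * c) / (2.0 * a * b)
    return math.pi - math.acos(min(1.0, max(-1.0, cosarg)))


def relative_turning_angles(traj) -> tuple[np.ndarray, int]:
    """All turning angles along a trajectory (vectorized).

    Returns ``(angles, n_skipped)`` where degenerate triples (repeated
    points) are skipped and counted, not imputed.
    """
    pos = _positions(traj)
    if pos.shape[0] < 3:
        return np.empty(0), 0
    a = np.linalg.norm(pos[1:-1] - pos[:-2], axis=1)
    b = np.linalg.norm(pos[2:] - pos[1:-1], axis=1)
    c = np.linalg.norm(pos[2:] - pos[:-2], axis=1)
    ok = (a > 0) & (b > 0)
    cosarg = np.clip((a[ok] ** 2 + b[ok] ** 2 - c[ok] ** 2)
                     / (2.0 * a[ok] * b[ok]), -1.0, 1.0)
    return math.pi - np.arccos(cosarg), int((~ok).sum())


def initial_alignment(traj) -> float:
    """Alignment of the first translational-noise vector with the heading.

    ``alpha`` times the cosine of the angle between ``(dWx_0, dWy_0)`` and
    ``p(theta_0)``, bounded in [-alpha, alpha] by construction; 0 for a zero
    noise vector.  Requires the trajectory to carry its noise record.
    """
    if getattr(traj, "noise_x", None) is None or traj.params is None:
        raise ValueError(
            "initial alignment needs the trajectory's noise record "
            "(not available for CSV-loaded trajectories)")
    vx, vy = float(traj.noise_x[0]), float(traj.noise_y[0])
    norm = math.hypot(vx, vy)
    if norm == 0.0:
        return 0.0
    theta0 = float(traj.thetas[0])
    cosang = (vx * math.cos(theta0) + vy * math.sin(theta0)) / norm
    return traj.params.alpha * cosang


@dataclass(frozen=True)
class TrajectoryStats:
    """Per-replicate summary statistics."""

    total_distance: float
    displacement: float
    persistence_factor: float
    mean_increment: float
    mean_relative_angle: float
    initial_alignment: float  # NaN when the noise record is unavailable
    final_position: np.ndarray
    n_skipped_angles: int = 0
    replicate_id: int = 0


def trajectory_stats(traj) -> TrajectoryStats:
    """Aggregate all per-trajectory statistics in one pass."""
    pos = _positions(traj)
    steps = np.diff(pos, axis=0)
    lengths = np.linalg.norm(steps, axis=1)
    total = float(lengths.sum())
    displacement = float(np.linalg.norm(pos[-1] - pos[0]))
    angles, skipped = relative_turning_angles(pos)
    try:
        align = initial_alignment(traj)
    except ValueError:
        align = float("nan")
    return TrajectoryStats(
        total_distance=total,
        displacement=displacement,
        persistence_factor=persistence_factor(pos) if total > 0 else 0.0,
        mean_increment=float(lengths.mean()),
        mean_relative_angle=float(angles.mean()) if angles.size else 0.0,
        initial_alignment=align,
        final_position=pos[-1].copy(),
        n_skipped_angles=skipped,
        replicate_id=getattr(traj, "replicate_id", 0),
    )


@dataclass(frozen=True)
class MSDCurve:
    """Ensemble MSD over a seeded subsample of replicates."""

    times: np.ndarray
    values: np.ndarray
    sample_size: int
    replicate_ids: tuple

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must align")
        if np.any(self.values < 0):
            raise ValueError("MSD values must be non-negative")


def ensemble_msd(trajectories, sample_size: int | None = None,
                 seed: int | None = None) -> MSDCurve:
    """Ensemble mean squared displacement from the origin.

    ``MSD(t) = (1/N) sum_i ||x_i(t) - x_i(0)||^2`` over a random subsample
    of ``sample_size`` trajectories (all of them when omitted), drawn
    without replacement with the given seed.  All trajectories must share
    one time grid.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("need at least one trajectory")
    times = np.asarray(trajectories[0].times, dtype=float)
    for t in trajectories[1:]:
        if len(t.times) != len(times) or not np.allclose(t.times, times):
            raise ValueError("all trajectories must share the same time grid")

    n = len(trajectories)
    if sample_size is None:
        sample_size = n
    if not 1 <= sample_size <= n:
        raise ValueError(f"sample_size must be in [1, {n}]")
    if sample_size < n:
        idx = np.sort(np.random.default_rng(seed).choice(
            n, size=sample_size, replace=False))
    else:
        idx = np.arange(n)

    chosen = [trajectories[i] for i in idx]
    sq = np.stack([
        ((t.positions - t.positions[0]) ** 2).sum(axis=1) for t in chosen])
    return MSDCurve(
        times=times,
        values=sq.mean(axis=0),
        sample_size=int(sample_size),
        replicate_ids=tuple(getattr(t, "replicate_id", i)
                            for i, t in zip(idx, chosen)),
    )


def msd_scaling_exponent(curve: MSDCurve,
                         fit_window: tuple[float, float] | None = None
                         ) -> float:
    """Power-law exponent of the MSD by least squares in log–log space.

    The default window is the last decade of time points (``t >= t_max/10``),
    excluding the early advective transient and the ``t = 0`` point.  At
    least three strictly positive points are required.
    """
    t = curve.times
    v = curve.values
    if fit_window is None:
        fit_window = (t.max() / 10.0, t.max())
    lo, hi = fit_window
    mask = (t >= lo) & (t <= hi) & (t > 0)
    if mask.sum() < 3:
        raise ValueError("fit window must contain at least 3 points")
    if np.any(v[mask] <= 0):
        raise ValueError("MSD must be positive throughout the fit window")
    slope, _ = np.polyfit(np.log(t[mask]), np.log(v[mask]), 1)
    return float(slope)


def classify_diffusion(exponent: float, tol: float = 0.1) -> str:
    """Name the regime: 'subdiffusive' (<1), 'diffusive' (~1), else super."""
    if exponent < 1.0 - tol:
        return "subdiffusive"
    if exponent > 1.0 + tol:
        return "superdiffusive"
    return "diffusive"


# ---------------------------------------------------------------------------
# Tabular output


def summary_frame(stats_list, x_org=None) -> pd.DataFrame:
    """Per-replicate summary table; adds ``final_distance_to_target`` when an
    organizing center is given."""
    rows = []
    for s in stats_list:
        row = {
            "replicate": s.replicate_id,
            "total_distance": s.total_distance,
            "displacement": s.displacement,
            "pf": s.persistence_factor,
            "mean_increment": s.mean_increment,
            "mean_rel_angle": s.mean_relative_angle,
            "initial_alignment": s.initial_alignment,
            "final_x": s.final_position[0],
            "final_y": s.final_position[1],
        }
        if x_org is not None:
            row["final_distance_to_target"] = float(
                np.linalg.norm(s.final_position - np.asarray(x_org, float)))
        rows.append(row)
    return pd.DataFrame(rows)


def write_summary_csv(stats_list, path, x_org=None):
    summary_frame(stats_list, x_org=x_org).to_csv(
        Path(path), index=False, float_format="%.17g")


def write_msd_csv(curve: MSDCurve, path):
    pd.DataFrame({
        "t": curve.times,
        "msd": curve.values,
        "N": curve.sample_size,
    }).to_csv(Path(path), index=False, float_format="%.17g")
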