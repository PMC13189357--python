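"""Exact synthesis of fractional Brownian motion (fBm) increments.

Fractional Brownian motion :math:`W^H(t)` is the centered Gaussian process
with stationary increments and covariance

.. math::

    \\operatorname{Cov}(W^H(t), W^H(s))
        = \\tfrac{1}{2}\\left(t^{2H} + s^{2H} - |t-s|^{2H}\\right),

where the Hurst index :math:`H \\in (0, 1)` sets the sign and strength of the
increment correlation: ``H = 0.5`` recovers ordinary Brownian motion
(independent increments), ``H > 0.5`` gives positively correlated
("persistent") increments.  In the migration model the per-step translational
noise of each cell is the increment process of an fBm, so the whole package
rests on sampling these increments exactly.

Synthesis uses the Davies–Harte / Wood–Chan circulant embedding, which is
exact (the sample covariance converges to the closed form above, not to an
approximation of it) and costs ``O(n log n)`` per path.  When the circulant
embedding is not nonnegative definite — which does not occur for fractional
Gaussian noise on the grids used here, but is checked — a Hosking
(Durbin–Levinson) recursion is used instead, exact at ``O(n^2)``.

Increments on a uniform grid with step ``dt`` carry marginal variance
``dt**(2*H)``: the restriction of standard fBm to the grid, so that
``H = 0.5`` reduces exactly to Wiener increments of variance ``dt``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FBMIncrementSeries",
    "fbm_covariance",
    "fgn_autocovariance",
    "generate_fbm_increments",
    "sample_fgn",
    "condition_on_first",
    "validate_hurst",
]

#: Relative tolerance below which a negative circulant eigenvalue is treated
#: as rounding noise and clipped rather than triggering the Hosking fallback.
_EIGENVALUE_RTOL = 1e-10


def validate_hurst(H: float, *, warn_antipersistent: bool = False) -> float:
    """Validate a Hurst index, returning it as a float.

    Raises ``ValueError`` outside the open interval (0, 1).  With
    ``warn_antipersistent=True`` a warning is issued for ``H < 0.5``:
    anti-persistent noise is outside the migration model's scope, although
    the generator itself supports it.
    """
    H = float(H)
    if not 0.0 < H < 1.0:
        raise ValueError(f"Hurst index must lie in (0, 1); got {H}")
    if warn_antipersistent and H < 0.5:
        warnings.warn(
            f"H={H} < 0.5 (anti-persistent noise) is outside the model's "
            "intended regime; proceeding anyway",
            UserWarning,
            stacklevel=2,
        )
    return H


def fbm_covariance(t, s, H: float):
    """Closed-form fBm covariance ``0.5*(t^2H + s^2H - |t-s|^2H)``.

    Accepts scalars or arrays (broadcast).  This is the analytic oracle the
    generator is tested against.  Negative times are rejected.
    """
    H = validate_hurst(H)
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(t < 0) or np.any(s < 0):
        raise ValueError("fBm covariance is defined for t, s >= 0 only")
    h2 = 2.0 * H
    out = 0.5 * (t**h2 + s**h2 - np.abs(t - s) ** h2)
    if out.ndim == 0:
        return float(out)
    return out


def fgn_autocovariance(lags, H: float, dt: float = 1.0):
    """Autocovariance of fractional Gaussian noise at integer ``lags``.

    fGn is the increment process ``X_k = W^H((k+1) dt) - W^H(k dt)``; its
    autocovariance is

    ``gamma(k) = dt^2H / 2 * (|k+1|^2H - 2|k|^2H + |k-1|^2H)``,

    with ``gamma(0) = dt^2H`` the marginal step variance.
    """
    H = validate_hurst(H)
    if dt <= 0:
        raise ValueError("dt must be positive")
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * H
    gamma = 0.5 * dt**h2 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)
    return gamma


def _davies_harte(n: int, gamma: np.ndarray, rng: np.random.Generator,
                  size: int | None):
    """Sample fGn via circulant embedding; returns None if not PSD."""
    m = 2 * n
    # first row of the circulant extension: gamma(0..n), gamma(n-1..1)
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    if lam.min() < -_EIGENVALUE_RTOL * lam.max():
        return None
    lam = np.clip(lam, 0.0, None)

    nsamp = 1 if size is None else size
    # Hermitian complex Gaussian with E[Z_j conj(Z_j)] = lam_j
    z = np.empty((nsamp, m), dtype=complex)
    z[:, 0] = np.sqrt(lam[0]) * rng.standard_normal(nsamp)
    z[:, n] = np.sqrt(lam[n]) * rng.standard_normal(nsamp)
    if n > 1:
        a = rng.standard_normal((nsamp, n - 1))
        b = rng.standard_normal((nsamp, n - 1))
        half = np.sqrt(lam[1:n] / 2.0) * (a + 1j * b)
        z[:, 1:n] = half
        z[:, n + 1:] = np.conj(half[:, ::-1])
    x = np.fft.fft(z, axis=1)[:, :n].real / np.sqrt(m)
    return x[0] if size is None else x


def _hosking(n: int, gamma: np.ndarray, rng: np.random.Generator,
             size: int | None):
    """Sample fGn by the Hosking/Durbin–Levinson recursion (exact, O(n^2))."""
    nsamp = 1 if size is None else size
    x = np.empty((nsamp, n))
    phi = np.zeros(n)
    x[:, 0] = np.sqrt(gamma[0]) * rng.standard_normal(nsamp)
    v = gamma[0]
    for k in range(1, n):
        # partial correlation of lag k given lags 1..k-1
        pk = (gamma[k] - phi[:k - 1] @ gamma[k - 1:0:-1]) / v
        phi_new = phi[:k - 1] - pk * phi[:k - 1][::-1]
        phi[:k - 1] = phi_new
        phi[k - 1] = pk
        v *= 1.0 - pk * pk
        mean = x[:, :k] @ phi[:k][::-1]
        x[:, k] = mean + np.sqrt(v) * rng.standard_normal(nsamp)
    return x[0] if size is None else x


def sample_fgn(n: int, H: float, dt: float = 1.0,
               rng: np.random.Generator | None = None,
               size: int | None = None) -> np.ndarray:
    """Draw fractional Gaussian noise (fBm increments) of length ``n``.

    Parameters
    ----------
    n : number of increments (>= 1).
    H : Hurst index in (0, 1).
    dt : grid step; each increment has variance ``dt**(2*H)``.
    rng : numpy Generator (a fresh default Generator if omitted).
    size : if given, return ``(size, n)`` independent paths.

    Davies–Harte is attempted first; the Hosking recursion is the exact
    fallback when the circulant embedding fails to be nonnegative definite.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    H = validate_hurst(H)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if rng is None:
        rng = np.random.default_rng()
    if n == 1:
        out = dt**H * rng.standard_normal(1 if size is None else (size, 1))
        return out if size is None else out
    gamma = fgn_autocovariance(np.arange(n + 1), H, dt)
    x = _davies_harte(n, gamma, rng, size)
    if x is None:  # pragma: no cover - fGn embeddings are PSD in practice
        x = _hosking(n, gamma[:n], rng, size)
    return x


def condition_on_first(increments: np.ndarray, H: float, dt: float,
                       first: float) -> np.ndarray:
    """Exact conditional fGn sample given a prescribed first increment.

    Given an unconditional fGn draw ``X``, the kriging residual

    ``Y_k = X_k + gamma(k)/gamma(0) * (first - X_0)``

    is an exact sample from the law of the fGn conditioned on its first
    increment equalling ``first`` (Gaussian conditioning; the correction
    coefficients are the regression of ``X_k`` on ``X_0``).  Used to thread
    the model's initialization draw through the correlated series.
    """
    increments = np.asarray(increments, dtype=float)
    n = increments.shape[-1]
    gamma = fgn_autocovariance(np.arange(n), H, dt)
    r = gamma / gamma[0]
    x0 = increments[..., :1]
    return increments + r * (float(first) - x0)


@dataclass(frozen=True)
class FBMIncrementSeries:
    """A length-``n`` sequence of fBm increments on a uniform time grid."""

    H: float
    dt: float
    n: int
    values: np.ndarray = field(repr=False)
    seed: int | None = None

    def __post_init__(self):
        validate_hurst(self.H)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.n,):
            raise ValueError(
                f"values must have shape ({self.n},); got {values.shape}")
        object.__setattr__(self, "values", values)

    def times(self) -> np.ndarray:
        """Grid times ``0, dt, ..., n*dt`` of the implied path."""
        return np.arange(self.n + 1) * self.dt

    def path(self) -> np.ndarray:
        """Cumulative path ``W(t_k)``, starting from ``W(0) = 0``."""
        return np.concatenate([[0.0], np.cumsum(self.values)])


def generate_fbm_increments(n: int, H: float, dt: float = 1.0,
                            seed: int | None = None,
                            rng: np.random.Generator | None = None,
                            first_increment: float | None = None,
                            ) -> FBMIncrementSeries:
    """Generate an :class:`FBMIncrementSeries` of ``n`` increments.

    Identical ``(n, H, dt, seed)`` give bit-identical output.  When
    ``first_increment`` is supplied, the series is an exact sample of the
    fGn law conditioned on that first value (see :func:`condition_on_first`).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    values = sample_fgn(n, H, dt, rng)
    if first_increment is not None:
        values = condition_on_first(values, H, dt, first_increment)
    return FBMIncrementSeries(H=float(H), dt=float(dt), n=int(n),
                              values=values, seed=seed)
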