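"""Time-averaged MSD estimation and propulsive-regime fitting.

The per-trajectory estimator is the overlapping time average

    MSD(k*dt) = (1/(N-k)) * sum_t [ (x(t+k*dt)-x(t))^2 + (y(t+k*dt)-y(t))^2 ]

over all N-k start frames, for integer lags k >= 1. Ensemble curves are the
unweighted mean across particles with the s.e.m. as dispersion. Speed v and
translational diffusion D_t come from an ordinary least-squares fit of the
propulsive-regime parabola

    MSD(t) = 4 D_t t + v^2 t^2       (valid for t << tau_r)

restricted to lags at most ``window_frac * tau_r``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "MSDCurve",
    "MotionEstimate",
    "compute_msd",
    "ensemble_msd",
    "fit_propulsive",
    "speed_summary",
]


@dataclass
class MSDCurve:
    """Lag times vs mean-squared displacement.

    ``n_pairs`` counts displacement pairs per lag (N-k for a single
    trajectory; the number of particles for an ensemble curve). ``sem`` is
    populated only for ensemble curves (NaN when undefined, i.e. a single
    particle).
    """

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    is_ensemble: bool = False
    sem: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs)
        if self.lags.ndim != 1 or self.lags.size == 0:
            raise ValueError("lags must be a non-empty 1-D array")
        if np.any(np.diff(self.lags) <= 0) or self.lags[0] <= 0:
            raise ValueError("lags must be strictly increasing and > 0")
        if self.msd.size != self.lags.size or self.n_pairs.size != self.lags.size:
            raise ValueError("msd and n_pairs must match lags in length")
        if np.any(self.msd < 0):
            raise ValueError("msd values must be >= 0")
        if np.any(self.n_pairs < 1):
            raise ValueError("n_pairs must be >= 1")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)


@dataclass
class MotionEstimate:
    """Result of the propulsive-regime fit.

    ``v_squared`` is the raw fitted quadratic coefficient; it may be
    negative for sub-diffusive / purely Brownian data, in which case ``v``
    is reported as 0 with ``propulsive=False`` and ``v_se`` undefined (NaN).
    ``d_t`` is the raw linear coefficient (not clipped). ``r_squared`` is
    the uncentered coefficient of determination of the no-intercept fit.
    """

    v: float
    d_t: float
    v_se: float
    d_t_se: float
    v_squared: float
    v_squared_se: float
    fit_window_s: float
    n_lags_used: int
    r_squared: float
    propulsive: bool
    particle_id: int | str | None = None


def compute_msd(traj: Trajectory, max_lag: float | None = None) -> MSDCurve:
    """Overlapping time-averaged MSD of one trajectory.

    Parameters
    ----------
    traj : Trajectory
        Uniformly sampled path (validated on construction).
    max_lag : float, optional
        Largest lag time to evaluate, s. Defaults to the largest available
        lag (duration minus one frame). Must not exceed it.
    """
    n = len(traj)
    dt = traj.dt
    max_available = (n - 1) * dt
    if max_lag is None:
        max_lag = max_available
    if max_lag <= 0:
        raise ValueError("max_lag must be > 0")
    if max_lag > max_available * (1 + 1e-9):
        raise ValueError(
            f"max_lag {max_lag:g} s exceeds available range {max_available:g} s"
        )
    k_max = min(int(math.floor(max_lag / dt + 1e-9)), n - 1)
    x, y = traj.x, traj.y
    lags = np.arange(1, k_max + 1) * dt
    msd = np.empty(k_max)
    n_pairs = np.empty(k_max, dtype=int)
    for k in range(1, k_max + 1):
        dx = x[k:] - x[:-k]
        dy = y[k:] - y[:-k]
        msd[k - 1] = np.mean(dx * dx + dy * dy)
        n_pairs[k - 1] = n - k
    return MSDCurve(lags=lags, msd=msd, n_pairs=n_pairs, is_ensemble=False)


def ensemble_msd(curves: list[MSDCurve]) -> MSDCurve:
    """Unweighted per-lag mean across particles, with s.e.m. dispersion.

    Curves of different lengths are intersected to the common (shortest)
    lag grid; the grids must agree on the shared lags. A single input curve
    is returned as an ensemble of one with undefined (NaN) s.e.m.
    """
    if not curves:
        raise ValueError("need at least one MSD curve")
    n_lags = min(c.lags.size for c in curves)
    lags = curves[0].lags[:n_lags]
    for c in curves[1:]:
        if not np.allclose(c.lags[:n_lags], lags, rtol=1e-9, atol=1e-12):
            raise ValueError("curves must share a common lag grid")
    stack = np.vstack([c.msd[:n_lags] for c in curves])
    mean = stack.mean(axis=0)
    n = len(curves)
    if n >= 2:
        sem = stack.std(axis=0, ddof=1) / math.sqrt(n)
    else:
        sem = np.full(n_lags, np.nan)
    return MSDCurve(
        lags=lags,
        msd=mean,
        n_pairs=np.full(n_lags, n, dtype=int),
        is_ensemble=True,
        sem=sem,
    )


def fit_propulsive(
    msd: MSDCurve,
    tau_r: float,
    window_frac: float = 0.2,
    weight_by_pairs: bool = False,
    particle_id: int | str | None = None,
) -> MotionEstimate:
    """Fit MSD(t) = 4 D_t t + v^2 t^2 over lags <= window_frac * tau_r.

    Ordinary least squares on the design {4t, t^2} with no intercept; the
    coefficients are D_t and v^2. ``v = sqrt(max(v^2, 0))``; a negative
    fitted v^2 yields v = 0 flagged non-propulsive rather than an error,
    since Brownian controls must produce speeds. Standard errors come from
    the linear fit, propagated to v by the delta method
    (se_v = se_{v^2} / (2 v)) when v^2 > 0.

    ``weight_by_pairs`` switches to inverse-variance-style weighting with
    weights proportional to the pair count at each lag.
    """
    if tau_r <= 0:
        raise ValueError("tau_r must be > 0")
    if not 0 < window_frac:
        raise ValueError("window_frac must be > 0")
    t_max = window_frac * tau_r
    mask = msd.lags <= t_max * (1 + 1e-9)
    t = msd.lags[mask]
    y = msd.msd[mask]
    if t.size < 3:
        raise ValueError(
            f"need >= 3 lags within (0, {t_max:g} s]; got {t.size}"
        )
    a = np.column_stack([4.0 * t, t * t])
    if weight_by_pairs:
        w = np.sqrt(np.asarray(msd.n_pairs, dtype=float)[mask])
        aw = a * w[:, None]
        yw = y * w
    else:
        aw, yw = a, y
    coef, _, _, _ = np.linalg.lstsq(aw, yw, rcond=None)
    d_t, v2 = float(coef[0]), float(coef[1])
    resid = yw - aw @ coef
    dof = t.size - 2
    s2 = float(resid @ resid) / dof if dof > 0 else np.nan
    cov = s2 * np.linalg.inv(aw.T @ aw)
    d_t_se = float(np.sqrt(cov[0, 0]))
    v2_se = float(np.sqrt(cov[1, 1]))
    ss_tot = float(yw @ yw)
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else np.nan
    propulsive = v2 > 0
    v = math.sqrt(v2) if propulsive else 0.0
    v_se = v2_se / (2.0 * v) if propulsive else float("nan")
    return MotionEstimate(
        v=v,
        d_t=d_t,
        v_se=v_se,
        d_t_se=d_t_se,
        v_squared=v2,
        v_squared_se=v2_se,
        fit_window_s=float(t[-1]),
        n_lags_used=int(t.size),
        r_squared=r2,
        propulsive=propulsive,
        particle_id=particle_id,
    )


def speed_summary(estimates: list[MotionEstimate]) -> tuple[float, float]:
    """Unweighted mean and s.e.m. of per-particle speeds.

    With a single estimate the s.e.m. is NaN (undefined).
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    speeds = np.array([e.v for e in estimates], dtype=float)
    mean = float(speeds.mean())
    if speeds.size >= 2:
        sem = float(speeds.std(ddof=1) / math.sqrt(speeds.size))
    else:
        sem = float("nan")
    return mean, sem
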