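"""Active-Brownian-particle (ABP) trajectory generator.

The ABP model: a particle self-propels at constant speed ``v`` along a
heading ``theta`` that diffuses rotationally with coefficient ``D_r``, on
top of translational diffusion ``D_t``:

    dtheta = sqrt(2 D_r) dW_theta
    dx     = v cos(theta) dt + sqrt(2 D_t) dW_x
    dy     = v sin(theta) dt + sqrt(2 D_t) dW_y

Integration is Euler-Maruyama with ``substeps`` internal steps per recorded
frame (internal step delta = 1/(fps*substeps)); recorded positions emulate a
camera sampling at ``fps``. Initial headings are uniform on [0, 2pi) so the
ensemble is isotropic, as assumed by the MSD model. Identical seeds give
bit-identical trajectories.
"""

from __future__ import annotations

import numpy as np

from .trajectory import Trajectory

__all__ = ["simulate_abp", "simulate_ensemble", "add_localization_noise"]


def _validate(v: float, d_t: float, d_r: float, fps: float, duration: float, substeps: int) -> None:
    if v < 0:
        raise ValueError("v must be >= 0")
    if d_t < 0 or d_r < 0:
        raise ValueError("D_t and D_r must be >= 0")
    if fps <= 0 or duration <= 0:
        raise ValueError("fps and duration must be > 0")
    if substeps < 1:
        raise ValueError("substeps must be >= 1")


def _simulate_batch(
    n: int,
    v: float,
    d_t: float,
    d_r: float,
    fps: float,
    duration: float,
    rng: np.random.Generator,
    substeps: int,
    drift: tuple[float, float] = (0.0, 0.0),
):
    """Vectorized Euler-Maruyama for ``n`` independent particles.

    Returns (times, x, y, heading) with x, y, heading of shape (n, n_frames).
    """
    n_frames = int(round(duration * fps)) + 1
    if n_frames < 2:
        raise ValueError("duration must cover at least one frame interval")
    delta = 1.0 / (fps * substeps)
    n_steps = (n_frames - 1) * substeps

    theta0 = rng.uniform(0.0, 2.0 * np.pi, size=n)
    dtheta = np.sqrt(2.0 * d_r * delta) * rng.standard_normal((n, n_steps))
    # heading at the START of each internal step (Euler-Maruyama drift uses it)
    theta_start = np.empty((n, n_steps))
    theta_start[:, 0] = theta0
    np.cumsum(dtheta[:, :-1], axis=1, out=theta_start[:, 1:])
    theta_start[:, 1:] += theta0[:, None]

    step_x = (v * np.cos(theta_start) + drift[0]) * delta
    step_y = (v * np.sin(theta_start) + drift[1]) * delta
    if d_t > 0:
        sigma = np.sqrt(2.0 * d_t * delta)
        step_x = step_x + sigma * rng.standard_normal((n, n_steps))
        step_y = step_y + sigma * rng.standard_normal((n, n_steps))

    x = np.zeros((n, n_steps + 1))
    y = np.zeros((n, n_steps + 1))
    np.cumsum(step_x, axis=1, out=x[:, 1:])
    np.cumsum(step_y, axis=1, out=y[:, 1:])

    theta_full = np.empty((n, n_steps + 1))
    theta_full[:, 0] = theta0
    np.cumsum(dtheta, axis=1, out=theta_full[:, 1:])
    theta_full[:, 1:] += theta0[:, None]

    times = np.arange(n_frames) / fps
    return times, x[:, ::substeps], y[:, ::substeps], theta_full[:, ::substeps]


def simulate_abp(
    v: float,
    d_t: float,
    d_r: float,
    fps: float = 25.0,
    duration: float = 30.0,
    seed: int | np.random.Generator | None = None,
    substeps: int = 10,
    particle_id: int | str = 0,
    drift: tuple[float, float] = (0.0, 0.0),
) -> Trajectory:
    """Simulate one ABP trajectory.

    Parameters
    ----------
    v : float
        Propulsion speed, um s^-1.
    d_t, d_r : float
        Translational (um^2 s^-1) and rotational (s^-1) diffusion
        coefficients. Either may be zero to switch the term off.
    fps : float
        Recording rate, frames per second.
    duration : float
        Recorded length, s. The trajectory has ``round(duration*fps)+1``
        samples starting at t = 0.
    seed : int, Generator or None
        Seed (or generator) for reproducibility.
    substeps : int
        Internal integration steps per frame.
    drift : (float, float)
        Constant drift velocity (x, y) in um s^-1, off by default; exposed
        for testing drift-robustness of downstream analysis.
    """
    _validate(v, d_t, d_r, fps, duration, substeps)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    times, x, y, heading = _simulate_batch(1, v, d_t, d_r, fps, duration, rng, substeps, drift)
    return Trajectory(particle_id=particle_id, times=times, x=x[0], y=y[0], heading=heading[0])


def simulate_ensemble(
    n_particles: int,
    v: float,
    d_t: float,
    d_r: float,
    fps: float = 25.0,
    duration: float = 30.0,
    seed: int | np.random.Generator | None = None,
    substeps: int = 10,
    drift: tuple[float, float] = (0.0, 0.0),
) -> list[Trajectory]:
    """Simulate ``n_particles`` independent ABP trajectories in one batch."""
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    _validate(v, d_t, d_r, fps, duration, substeps)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    times, x, y, heading = _simulate_batch(
        n_particles, v, d_t, d_r, fps, duration, rng, substeps, drift
    )
    return [
        Trajectory(particle_id=i, times=times, x=x[i], y=y[i], heading=heading[i])
        for i in range(n_particles)
    ]


def add_localization_noise(
    traj: Trajectory, sigma_um: float, seed: int | np.random.Generator | None = None
) -> Trajectory:
    """Add i.i.d. Gaussian localization error of s.d. ``sigma_um`` to x and y.

    Models the sub-pixel centroiding error of the tracking stage. On a
    stationary particle this inflates the MSD by a constant 4 sigma^2
    plateau. ``sigma_um == 0`` returns the input unchanged.
    """
    if sigma_um < 0:
        raise ValueError("sigma_um must be >= 0")
    if sigma_um == 0:
        return traj
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(traj)
    return Trajectory(
        particle_id=traj.particle_id,
        times=traj.times.copy(),
        x=traj.x + sigma_um * rng.standard_normal(n),
        y=traj.y + sigma_um * rng.standard_normal(n),
        heading=None if traj.heading is None else traj.heading.copy(),
    )
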