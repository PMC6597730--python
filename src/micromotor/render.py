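"""Render trajectories into microscopy-like grayscale frame stacks.

Each particle is drawn as an isotropic 2-D Gaussian intensity spot (a
diffraction-limited point-spread-function stand-in) on a constant
background, with optional Poisson shot noise and Gaussian read noise.
Micrometre coordinates map to pixels via ``pixel_size_um`` with the origin
at the centre of pixel (0, 0); frames are 16-bit grayscale, matching the
multi-page TIFF interchange format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .trajectory import Trajectory

__all__ = ["FrameStack", "render_frames"]

logger = logging.getLogger(__name__)


@dataclass
class FrameStack:
    """A stack of same-shape grayscale frames plus acquisition metadata."""

    frames: np.ndarray  # (n_frames, height, width), uint16
    pixel_size_um: float
    fps: float
    psf_sigma_um: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if self.pixel_size_um <= 0 or self.fps <= 0 or self.psf_sigma_um <= 0:
            raise ValueError("pixel_size_um, fps and psf_sigma_um must be > 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape_px(self) -> tuple[int, int]:
        return (int(self.frames.shape[1]), int(self.frames.shape[2]))


def render_frames(
    trajs: list[Trajectory],
    shape_px: tuple[int, int] = (512, 512),
    pixel_size_um: float = 0.1,
    psf_sigma_um: float = 0.2,
    amplitude: float = 8000.0,
    background: float = 500.0,
    poisson_noise: bool = False,
    read_noise: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> FrameStack:
    """Draw every trajectory frame-by-frame into a 16-bit image stack.

    All trajectories must share the frame grid (same length and dt); frame
    ``f`` shows every particle at its position at time ``f/fps``. Particles
    whose spot centre falls outside the field of view are clipped (only the
    in-frame part of the spot is drawn) and a warning is logged.

    Parameters
    ----------
    shape_px : (height, width)
        Frame shape in pixels.
    amplitude : float
        Peak intensity of one spot above background, camera counts.
    background : float
        Constant background level, counts.
    poisson_noise : bool
        Apply Poisson shot noise to the noiseless image.
    read_noise : float
        Gaussian read noise s.d., counts (0 disables).
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    n_frames = len(trajs[0])
    dt = trajs[0].dt
    for tr in trajs[1:]:
        if len(tr) != n_frames or abs(tr.dt - dt) > 1e-9:
            raise ValueError("all trajectories must share the same frame grid")
    h, w = shape_px
    fps = 1.0 / dt
    sigma_px = psf_sigma_um / pixel_size_um
    half = max(int(np.ceil(4.0 * sigma_px)), 2)

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    stack = np.full((n_frames, h, w), float(background))
    clipped: set[int | str] = set()

    for f in range(n_frames):
        img = stack[f]
        for tr in trajs:
            cx = tr.x[f] / pixel_size_um  # column, px
            cy = tr.y[f] / pixel_size_um  # row, px
            if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1) and tr.particle_id not in clipped:
                clipped.add(tr.particle_id)
                logger.warning(
                    "particle %r outside field of view at frame %d; spot clipped",
                    tr.particle_id,
                    f,
                )
            x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
            y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
            x0c, x1c = max(x0, 0), min(x1, w)
            y0c, y1c = max(y0, 0), min(y1, h)
            if x0c >= x1c or y0c >= y1c:
                continue
            xs = np.arange(x0c, x1c)
            ys = np.arange(y0c, y1c)
            gx = np.exp(-((xs - cx) ** 2) / (2.0 * sigma_px**2))
            gy = np.exp(-((ys - cy) ** 2) / (2.0 * sigma_px**2))
            img[y0c:y1c, x0c:x1c] += amplitude * np.outer(gy, gx)

    if poisson_noise:
        stack = rng.poisson(np.clip(stack, 0, None)).astype(float)
    if read_noise > 0:
        stack = stack + read_noise * rng.standard_normal(stack.shape)
    frames = np.clip(np.rint(stack), 0, 65535).astype(np.uint16)
    return FrameStack(
        frames=frames, pixel_size_um=pixel_size_um, fps=fps, psf_sigma_um=psf_sigma_um
    )
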