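"""Plain-text and TIFF interchange.

Trajectories travel as CSV with header ``particle_id,frame,t_s,x_um,y_um``;
frame stacks as multi-page 16-bit grayscale TIFF with acquisition metadata
(fps, pixel size, PSF width) in a JSON sidecar next to the TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .render import FrameStack
from .trajectory import Trajectory

__all__ = [
    "trajectories_to_frame",
    "write_trajectories_csv",
    "read_trajectories_csv",
    "write_stack",
    "read_stack",
]

TRAJECTORY_COLUMNS = ["particle_id", "frame", "t_s", "x_um", "y_um"]


def trajectories_to_frame(trajs: list[Trajectory]) -> pd.DataFrame:
    """Long-format table of a trajectory list (one row per particle-frame)."""
    parts = []
    for tr in trajs:
        n = len(tr)
        parts.append(
            pd.DataFrame(
                {
                    "particle_id": [tr.particle_id] * n,
                    "frame": np.arange(n),
                    "t_s": tr.times,
                    "x_um": tr.x,
                    "y_um": tr.y,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_trajectories_csv(trajs: list[Trajectory], path: str | Path, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        trajectories_to_frame(trajs).to_csv(fh, index=False)


def read_trajectories_csv(path: str | Path) -> list[Trajectory]:
    df = pd.read_csv(path, comment="#")
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns {sorted(missing)}")
    out = []
    for pid, group in df.groupby("particle_id", sort=True):
        group = group.sort_values("frame")
        times = group["t_s"].to_numpy(dtype=float)
        out.append(
            Trajectory(
                particle_id=pid,
                times=times - times[0],
                x=group["x_um"].to_numpy(dtype=float),
                y=group["y_um"].to_numpy(dtype=float),
            )
        )
    return out


def _sidecar_path(tif_path: Path) -> Path:
    return tif_path.with_suffix(".json")


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a multi-page TIFF plus JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    meta = {
        "fps": stack.fps,
        "pixel_size_um": stack.pixel_size_um,
        "psf_sigma_um": stack.psf_sigma_um,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_stack(path: str | Path) -> FrameStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    meta = json.loads(_sidecar_path(path).read_text())
    return FrameStack(
        frames=frames,
        pixel_size_um=float(meta["pixel_size_um"]),
        fps=float(meta["fps"]),
        psf_sigma_um=float(meta["psf_sigma_um"]),
    )
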