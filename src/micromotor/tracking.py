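"""Spot detection and frame-to-frame linking of particle trajectories.

Detection finds per-frame local intensity maxima above a threshold and
refines them to sub-pixel precision with a background-subtracted
intensity-weighted centroid. Linking assigns detections to open tracks
frame by frame with a globally optimal (minimum total displacement)
bipartite matching under a maximum-displacement gate, bridging short
detection gaps by persisting the last known position.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max

from .render import FrameStack
from .trajectory import Trajectory

__all__ = ["LinkingConfig", "detect_spots", "detect_stack", "link_tracks", "track_stack"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LinkingConfig:
    """Linking parameters.

    ``max_disp_um`` is the largest allowed displacement per frame interval
    (scaled by the gap length when bridging missed detections);
    ``min_track_length`` drops short fragments; ``memory`` is the number of
    consecutive frames a particle may go undetected without terminating its
    track.
    """

    max_disp_um: float = 0.7
    min_track_length: int = 250
    memory: int = 0

    def __post_init__(self) -> None:
        if self.max_disp_um <= 0:
            raise ValueError("max_disp_um must be > 0")
        if self.min_track_length < 2:
            raise ValueError("min_track_length must be >= 2")
        if self.memory < 0:
            raise ValueError("memory must be >= 0")


def detect_spots(
    frame: np.ndarray,
    pixel_size_um: float,
    threshold: float | None = None,
    min_sep_um: float = 1.0,
    psf_sigma_um: float = 0.2,
) -> pd.DataFrame:
    """Detect bright spots in one frame; sub-pixel positions in micrometres.

    Local maxima above ``threshold`` (``None`` = automatic: halfway between
    the frame median and maximum) separated by at least ``min_sep_um`` are
    kept (closer maxima are merged to the brighter one). Each is refined by
    an intensity-weighted centroid over a window of radius 3 * psf_sigma,
    after subtracting the frame median as background estimate.

    Returns a DataFrame with columns ``x_um, y_um, intensity`` (possibly
    empty; an empty frame is not an error).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("frame must be non-empty")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    background = float(np.median(frame))
    if threshold is None:
        threshold = background + 0.5 * (float(frame.max()) - background)
    if threshold <= background:
        logger.warning("threshold %.3g at or below background %.3g", threshold, background)

    min_dist_px = max(int(round(min_sep_um / pixel_size_um)), 1)
    peaks = peak_local_max(
        frame, min_distance=min_dist_px, threshold_abs=threshold, exclude_border=False
    )
    if peaks.size == 0:
        logger.info("no detections above threshold %.3g", threshold)
        return pd.DataFrame(columns=["x_um", "y_um", "intensity"])

    half = max(int(math.ceil(3.0 * psf_sigma_um / pixel_size_um)), 1)
    h, w = frame.shape
    rows = []
    for r, c in peaks:
        r0, r1 = max(r - half, 0), min(r + half + 1, h)
        c0, c1 = max(c - half, 0), min(c + half + 1, w)
        window = np.clip(frame[r0:r1, c0:c1] - background, 0.0, None)
        total = window.sum()
        if total <= 0:
            continue
        ys, xs = np.mgrid[r0:r1, c0:c1]
        cy = float((window * ys).sum() / total)
        cx = float((window * xs).sum() / total)
        rows.append(
            {
                "x_um": cx * pixel_size_um,
                "y_um": cy * pixel_size_um,
                "intensity": float(frame[r, c] - background),
            }
        )
    return pd.DataFrame(rows)


def detect_stack(
    stack: FrameStack,
    threshold: float | None = None,
    min_sep_um: float = 1.0,
) -> pd.DataFrame:
    """Run :func:`detect_spots` over every frame of a stack.

    Returns the detection table with columns ``frame, x_um, y_um,
    intensity`` sorted by frame.
    """
    tables = []
    for f in range(stack.n_frames):
        det = detect_spots(
            stack.frames[f],
            pixel_size_um=stack.pixel_size_um,
            threshold=threshold,
            min_sep_um=min_sep_um,
            psf_sigma_um=stack.psf_sigma_um,
        )
        det.insert(0, "frame", f)
        tables.append(det)
    out = pd.concat(tables, ignore_index=True)
    return out


class _Track:
    __slots__ = ("track_id", "frames", "xs", "ys", "last_frame")

    def __init__(self, track_id: int, frame: int, x: float, y: float):
        self.track_id = track_id
        self.frames = [frame]
        self.xs = [x]
        self.ys = [y]
        self.last_frame = frame

    def extend(self, frame: int, x: float, y: float) -> None:
        # bridge any skipped frames by persisting the last known position
        gap = frame - self.last_frame
        for g in range(1, gap):
            self.frames.append(self.last_frame + g)
            self.xs.append(self.xs[-1])
            self.ys.append(self.ys[-1])
        self.frames.append(frame)
        self.xs.append(x)
        self.ys.append(y)
        self.last_frame = frame


def link_tracks(
    detections: pd.DataFrame,
    cfg: LinkingConfig,
    fps: float,
) -> list[Trajectory]:
    """Link a detection table into trajectories.

    Per frame pair the assignment of open tracks to new detections is the
    minimum-total-displacement bipartite matching restricted to candidate
    pairs within ``max_disp_um`` (scaled by the gap when a track was missed
    for up to ``memory`` frames). Unmatched detections open new tracks;
    tracks missing longer than ``memory`` frames are closed; fragments
    shorter than ``min_track_length`` frames are dropped. Detections are
    canonically ordered before linking, so the result is invariant to the
    input row order; cost ties are resolved toward the lowest track id.
    """
    if fps <= 0:
        raise ValueError("fps must be > 0")
    required = {"frame", "x_um", "y_um"}
    if not required.issubset(detections.columns):
        raise ValueError(f"detection table must have columns {sorted(required)}")
    if len(detections) == 0:
        return []
    dets = detections.sort_values(
        ["frame", "x_um", "y_um"], kind="mergesort"
    ).reset_index(drop=True)

    open_tracks: list[_Track] = []
    closed: list[_Track] = []
    next_id = 0
    for frame, group in dets.groupby("frame", sort=True):
        frame = int(frame)
        # retire tracks that have been dark for longer than memory
        still_open = []
        for tr in open_tracks:
            if frame - tr.last_frame > cfg.memory + 1:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        xs = group["x_um"].to_numpy()
        ys = group["y_um"].to_numpy()
        n_det = xs.size
        assigned_det = np.zeros(n_det, dtype=bool)
        if open_tracks:
            tx = np.array([tr.xs[-1] for tr in open_tracks])
            ty = np.array([tr.ys[-1] for tr in open_tracks])
            gaps = np.array([frame - tr.last_frame for tr in open_tracks])
            dist = np.hypot(tx[:, None] - xs[None, :], ty[:, None] - ys[None, :])
            allowed = dist <= cfg.max_disp_um * gaps[:, None]
            big = dist.max() + cfg.max_disp_um * gaps.max() + 1.0
            cost = np.where(allowed, dist, big)
            row_ind, col_ind = linear_sum_assignment(cost)
            for i, j in zip(row_ind, col_ind):
                if allowed[i, j]:
                    open_tracks[i].extend(frame, float(xs[j]), float(ys[j]))
                    assigned_det[j] = True
        for j in range(n_det):
            if not assigned_det[j]:
                open_tracks.append(_Track(next_id, frame, float(xs[j]), float(ys[j])))
                next_id += 1

    closed.extend(open_tracks)
    closed.sort(key=lambda tr: tr.track_id)
    out = []
    for tr in closed:
        if len(tr.frames) < cfg.min_track_length:
            continue
        times = (np.array(tr.frames) - tr.frames[0]) / fps
        out.append(
            Trajectory(particle_id=tr.track_id, times=times, x=np.array(tr.xs), y=np.array(tr.ys))
        )
    return out


def track_stack(
    stack: FrameStack,
    cfg: LinkingConfig | None = None,
    threshold: float | None = None,
    min_sep_um: float = 1.0,
) -> list[Trajectory]:
    """Convenience: detect every frame then link (detect_stack + link_tracks)."""
    cfg = cfg or LinkingConfig()
    dets = detect_stack(stack, threshold=threshold, min_sep_um=min_sep_um)
    return link_tracks(dets, cfg, fps=stack.fps)
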