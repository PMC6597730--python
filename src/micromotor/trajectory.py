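"""The Trajectory container: one particle's uniformly sampled 2-D path."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory"]

_UNIFORMITY_TOL_S = 1e-9


@dataclass
class Trajectory:
    """A single particle's timestamped 2-D path in micrometres.

    Samples must be uniformly spaced in time with ``times[0] == 0``; the
    frame interval is ``1/fps`` of the acquisition. ``heading`` (radians) is
    carried only for simulator ground truth and is never produced by
    tracking.
    """

    particle_id: int | str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.times.size
        if n < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if self.x.size != n or self.y.size != n:
            raise ValueError("times, x and y must have equal length")
        if abs(self.times[0]) > _UNIFORMITY_TOL_S:
            raise ValueError("times must start at 0")
        dt = np.diff(self.times)
        bad = np.nonzero(np.abs(dt - dt[0]) > _UNIFORMITY_TOL_S)[0]
        if dt[0] <= 0:
            raise ValueError("times must be strictly increasing")
        if bad.size:
            i = int(bad[0]) + 1
            raise ValueError(
                f"non-uniform sampling at index {i}: gap {dt[bad[0]]:.3e} s "
                f"vs frame interval {dt[0]:.3e} s"
            )
        if self.heading is not None:
            self.heading = np.asarray(self.heading, dtype=float)
            if self.heading.size != n:
                raise ValueError("heading must match times in length")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def dt(self) -> float:
        """Frame interval, s."""
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1])
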