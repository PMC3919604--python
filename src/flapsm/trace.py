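"""Per-frame donor/acceptor intensity traces.

The :class:`IntensityTrace` is the raw unit of all single-molecule
analysis: two aligned photon-count channels sampled on a uniform frame
grid, as produced by a TIRF camera (or by the simulator emulating one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["IntensityTrace"]


@dataclass
class IntensityTrace:
    """Donor/acceptor photon counts on a uniform frame grid.

    Parameters
    ----------
    times:
        Frame start times in seconds, strictly increasing, uniform spacing.
    donor_counts, acceptor_counts:
        Detected counts per frame in each channel; same length as `times`.
    frame_time:
        Camera integration time per frame in seconds.
    metadata:
        Free-form condition labels and simulator ground truth.
    """

    times: np.ndarray
    donor_counts: np.ndarray
    acceptor_counts: np.ndarray
    frame_time: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.donor_counts = np.asarray(self.donor_counts, dtype=float)
        self.acceptor_counts = np.asarray(self.acceptor_counts, dtype=float)
        n = len(self.times)
        if len(self.donor_counts) != n or len(self.acceptor_counts) != n:
            raise ValueError("channel lengths differ from time axis")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be > 0")
        if n > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("frame times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                bad = int(np.argmax(np.abs(dt - dt[0]) > 1e-6 * dt[0] + 1e-9))
                raise ValueError(f"non-uniform frame spacing at frame {bad + 1}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def total_counts(self) -> np.ndarray:
        return self.donor_counts + self.acceptor_counts

    def efficiency(self, gamma: float = 1.0) -> np.ndarray:
        """Apparent FRET efficiency E_app = I_A / (I_A + gamma * I_D) per frame.

        Frames with non-positive total signal yield NaN.
        """
        denom = self.acceptor_counts + gamma * self.donor_counts
        with np.errstate(divide="ignore", invalid="ignore"):
            e = np.where(denom > 0, self.acceptor_counts / denom, np.nan)
        return e

    def slice(self, start: int, stop: int | None = None) -> "IntensityTrace":
        """Return a frame-index slice as a new trace (metadata shared)."""
        sl = np.s_[start:stop]
        return IntensityTrace(
            times=self.times[sl],
            donor_counts=self.donor_counts[sl],
            acceptor_counts=self.acceptor_counts[sl],
            frame_time=self.frame_time,
            metadata=dict(self.metadata),
        )
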