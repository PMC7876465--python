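"""Spacetime movie container shared by every pipeline stage.

A recording is a stack of 2-D fluorescence frames along time.  The canonical
mapping geometry is a 16x16 photodiode grid; other sizes are accepted with a
warning so the analysis can be exercised on simulated fields of any size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

CANONICAL_GRID = 16


@dataclass
class SpacetimeCube:
    """One channel's movie: ``values[frame, row, col]`` plus acquisition metadata.

    Parameters
    ----------
    values
        Fluorescence, shape ``(frames, rows, cols)``.  Arbitrary units before
        normalization, per-trace ``[0, 1]`` (the dF range) afterwards.
    frame_interval
        Milliseconds per frame.
    channel
        ``"Vm"`` (voltage dye) or ``"Cai"`` (calcium indicator).
    normalized
        True once per-trace min-max scaling has been applied.
    mask
        Boolean ``(rows, cols)`` grid of retained pixels.  Pixels outside the
        mask are ignored by all downstream stages.
    """

    values: np.ndarray
    frame_interval: float
    channel: str = "Vm"
    normalized: bool = False
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"values must be (frames, rows, cols); got shape {self.values.shape}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive (ms)")
        if self.channel not in ("Vm", "Cai"):
            raise ValueError(f"channel must be 'Vm' or 'Cai', got {self.channel!r}")
        rows, cols = self.values.shape[1:]
        if (rows, cols) != (CANONICAL_GRID, CANONICAL_GRID):
            warnings.warn(
                f"non-canonical grid {rows}x{cols} (mapping arrays are "
                f"{CANONICAL_GRID}x{CANONICAL_GRID}); proceeding anyway",
                stacklevel=2,
            )
        if self.mask is None:
            self.mask = np.ones((rows, cols), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (rows, cols):
                raise ValueError("mask shape must match the frame shape")

    # -- geometry ---------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def duration_ms(self) -> float:
        return self.n_frames * self.frame_interval

    def times_ms(self) -> np.ndarray:
        """Sample times of each frame (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval

    def copy(self, **changes) -> "SpacetimeCube":
        """Deep copy, optionally replacing fields (``values`` always copied)."""
        out = replace(self, **changes)
        if "values" not in changes:
            out.values = self.values.copy()
        if "mask" not in changes:
            out.mask = self.mask.copy()
        return out

    def frame_of(self, time_ms: float) -> int:
        """Nearest frame index for a time in ms."""
        return int(round(time_ms / self.frame_interval))
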