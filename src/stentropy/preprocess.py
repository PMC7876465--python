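"""Trace conditioning: smoothing, normalization, edge discard, activity threshold.

The conditioning chain mirrors standard dual-dye optical-mapping practice:
a short moving-average filter on every trace, per-trace min-max scaling so
fluorescence lies in [0, 1], removal of traces near the edge of the imaging
field, and a binary activity threshold at a fixed fraction of the per-trace
maximum dF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cubes import SpacetimeCube

DEFAULT_FILTER_WIDTH_MS = 13.0
DEFAULT_THRESHOLD_FRACTION = 0.65
DEFAULT_EDGE_RADIUS_PX = 8.0

_DEAD_RANGE = 1e-12


@dataclass
class ActivityMask:
    """Boolean supra-threshold volume derived from a normalized cube.

    ``active[frame, row, col]`` is True where the normalized fluorescence is at
    or above ``threshold_fraction`` of the per-trace maximum dF.  Everything
    outside the cube's retained-pixel mask is forced inactive.
    """

    active: np.ndarray
    threshold_fraction: float
    source_channel: str
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return self.active.shape[0]


def moving_average(cube: SpacetimeCube, width_ms: float = DEFAULT_FILTER_WIDTH_MS) -> SpacetimeCube:
    """Boxcar-smooth every pixel trace.

    The boxcar has ``round(width_ms / frame_interval)`` taps.  At the ends of
    the record the window shrinks to the available samples rather than padding
    with fabricated values, so a constant trace stays exactly constant.
    """
    if width_ms < cube.frame_interval:
        raise ValueError(
            f"filter width {width_ms} ms is shorter than one frame "
            f"({cube.frame_interval} ms)"
        )
    taps = int(round(width_ms / cube.frame_interval))
    if taps <= 1:
        return cube.copy()
    # sum over the window / count of in-bounds samples == shrinking-window mean
    sums = ndimage.uniform_filter1d(
        cube.values.astype(float), taps, axis=0, mode="constant", cval=0.0
    ) * taps
    ones = np.ones(cube.n_frames)
    counts = ndimage.uniform_filter1d(ones, taps, mode="constant", cval=0.0) * taps
    smoothed = sums / counts[:, None, None]
    return cube.copy(values=smoothed)


def normalize(cube: SpacetimeCube) -> SpacetimeCube:
    """Per-trace min-max scaling so every retained trace spans [0, 1].

    A trace with zero range carries no signal (a dead photodiode); it is
    dropped from the retained-pixel mask instead of being divided by zero.
    """
    vals = cube.values.astype(float)
    lo = vals.min(axis=0)
    hi = vals.max(axis=0)
    rng = hi - lo
    dead = rng <= _DEAD_RANGE
    safe = np.where(dead, 1.0, rng)
    out = (vals - lo[None]) / safe[None]
    out[:, dead] = 0.0
    mask = cube.mask & ~dead
    return cube.copy(values=out, mask=mask, normalized=True)


def edge_mask(rows: int = 16, cols: int = 16, radius: float = DEFAULT_EDGE_RADIUS_PX) -> np.ndarray:
    """Retained-pixel grid: keep pixels within ``radius`` of the field center.

    The center of an even grid sits between pixels, at ((rows-1)/2, (cols-1)/2);
    a pixel is retained iff its Euclidean distance from that point is <= radius.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    r = np.arange(rows)[:, None] - (rows - 1) / 2.0
    c = np.arange(cols)[None, :] - (cols - 1) / 2.0
    return np.hypot(r, c) <= radius


def apply_edge_mask(cube: SpacetimeCube, radius: float = DEFAULT_EDGE_RADIUS_PX) -> SpacetimeCube:
    """Intersect the cube's retained-pixel mask with the edge-discard disc."""
    rows, cols = cube.shape[1:]
    return cube.copy(mask=cube.mask & edge_mask(rows, cols, radius))


def activity_mask(
    cube: SpacetimeCube,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    global_max: bool = False,
) -> ActivityMask:
    """Threshold a normalized cube into a binary activity volume.

    A voxel is active iff its value is >= ``threshold_fraction`` (inclusive
    boundary).  After per-trace normalization the per-trace maximum dF is 1,
    so the default 0.65 threshold is applied directly in normalized units.
    ``global_max=True`` instead thresholds against the field-wide maximum
    (sensitivity-analysis mode).
    """
    if not cube.normalized:
        raise ValueError("activity_mask requires a normalized cube")
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    ref = cube.values[:, cube.mask].max() if global_max else 1.0
    active = cube.values >= threshold_fraction * ref
    active &= cube.mask[None, :, :]
    return ActivityMask(
        active=active,
        threshold_fraction=threshold_fraction,
        source_channel=cube.channel,
        frame_interval=cube.frame_interval,
    )


def condition(
    cube: SpacetimeCube,
    filter_width_ms: float = DEFAULT_FILTER_WIDTH_MS,
    edge_radius_px: float = DEFAULT_EDGE_RADIUS_PX,
) -> SpacetimeCube:
    """Full conditioning chain: smooth -> normalize -> edge discard."""
    return apply_edge_mask(normalize(moving_average(cube, filter_width_ms)), edge_radius_px)
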