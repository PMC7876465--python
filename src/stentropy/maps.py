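"""Activation maps, interpolation, false-color rendering, wave-break detection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import LinearSegmentedColormap
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .cubes import SpacetimeCube
from .preprocess import ActivityMask

#: blue -> green -> red, low -> intermediate -> high fluorescence
FALSE_COLOR_CMAP = LinearSegmentedColormap.from_list(
    "optical_mapping", [(0.0, 0.0, 1.0), (0.0, 1.0, 0.0), (1.0, 0.0, 0.0)]
)

INTERP_SIZE = 256


@dataclass
class ActivationMap:
    """Per-pixel activation time (ms) for one beat; NaN marks silent pixels."""

    activation_time: np.ndarray  # (rows, cols), ms, NaN for silent/discarded
    beat_window: tuple[int, int]
    channel: str


@dataclass
class WaveBreakSet:
    """Wave-break points: sites where activation and repolarization fronts meet."""

    points: np.ndarray  # (n, 3) of (frame, row, col)

    def __len__(self) -> int:
        return int(self.points.shape[0])


def activation_times(
    cube: SpacetimeCube,
    beat_window: tuple[int, int],
    criterion: str = "half_amplitude",
    sustain_ms: float = 0.0,
) -> ActivationMap:
    """Per-pixel activation time within one beat window.

    ``half_amplitude`` (default): first upward crossing of 0.5 normalized
    amplitude, confirmed by the trace staying elevated shortly after (so a
    noise flicker on a repolarizing tail is not an activation).  ``dvdt_max``:
    frame of steepest upstroke.  ``sustain_ms > 0`` additionally requires the
    trace to remain at or above half amplitude for that long after the
    crossing (evaluated on the full trace, so beats cut by the window edge
    still qualify) — the per-pixel analog of the cluster persistence filter,
    which rejects short-lived detector-noise blobs.  Pixels without a
    qualifying upstroke anywhere in the window are silent (NaN); if *no*
    pixel activates the window does not contain a beat and an error is
    raised.
    """
    if not cube.normalized:
        raise ValueError("activation_times requires a normalized cube")
    start, end = beat_window
    if not (0 <= start < end <= cube.n_frames):
        raise ValueError(f"beat window {beat_window} outside recording")
    sub = cube.values[start:end]
    rows, cols = sub.shape[1:]
    out = np.full((rows, cols), np.nan)
    confirm = min(3, sub.shape[0] - 1)
    sustain = int(round(sustain_ms / cube.frame_interval))
    for r in range(rows):
        for cc in range(cols):
            if not cube.mask[r, cc]:
                continue
            tr = sub[:, r, cc]
            if criterion == "dvdt_max":
                if tr.max() < 0.5:
                    continue
                k = int(np.argmax(np.diff(tr))) + 1
                out[r, cc] = (start + k) * cube.frame_interval
                continue
            up = np.flatnonzero((tr[1:] >= 0.5) & (tr[:-1] < 0.5)) + 1
            full = cube.values[:, r, cc]
            for k in up:
                j = min(k + confirm, len(tr) - 1)
                if tr[j] < 0.55 and j != k:  # flicker, not a rise
                    continue
                if sustain:
                    seg = full[start + k : start + k + sustain]
                    if seg.size and seg.min() < 0.5:
                        continue
                out[r, cc] = (start + k) * cube.frame_interval
                break
    if np.all(np.isnan(out)):
        raise ValueError("no pixel activates in the requested beat window")
    return ActivationMap(activation_time=out, beat_window=beat_window, channel=cube.channel)


def interpolate_map(map16: np.ndarray) -> np.ndarray:
    """Expand a coarse activation/fluorescence map to 256x256 by bilinear
    interpolation.

    Coarse-grid node values are preserved exactly.  NaN entries (silent
    pixels) are excluded by nearest-neighbor infill before interpolating.
    """
    m = np.asarray(map16, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D map")
    nr, nc = m.shape
    nan = np.isnan(m)
    filled = m
    if nan.any():
        if nan.all():
            raise ValueError("map contains no finite values")
        idx = ndimage.distance_transform_edt(nan, return_distances=False, return_indices=True)
        filled = m[tuple(idx)]
    interp = RegularGridInterpolator(
        (np.arange(nr), np.arange(nc)), filled, method="linear"
    )
    rr = np.linspace(0, nr - 1, INTERP_SIZE)
    cc = np.linspace(0, nc - 1, INTERP_SIZE)
    grid = np.stack(np.meshgrid(rr, cc, indexing="ij"), axis=-1)
    fine = interp(grid)
    # pin coarse nodes exactly (256 = 16 + 15*16, so nodes land on the fine grid
    # only for the canonical 16x16 geometry)
    stride_r = (INTERP_SIZE - 1) // (nr - 1) if (INTERP_SIZE - 1) % (nr - 1) == 0 else 0
    stride_c = (INTERP_SIZE - 1) // (nc - 1) if (INTERP_SIZE - 1) % (nc - 1) == 0 else 0
    if stride_r and stride_c:
        fine[::stride_r, ::stride_c] = filled
    return fine


def false_color(frame: np.ndarray) -> np.ndarray:
    """Map a normalized frame to RGB: blue = low, green = intermediate, red = high."""
    f = np.clip(np.asarray(frame, dtype=float), 0.0, 1.0)
    return FALSE_COLOR_CMAP(f)[..., :3]


def _dilate4(a: np.ndarray) -> np.ndarray:
    return ndimage.binary_dilation(a, structure=ndimage.generate_binary_structure(2, 1))


def _dilate8(a: np.ndarray) -> np.ndarray:
    return ndimage.binary_dilation(a, structure=np.ones((3, 3), dtype=bool))


def detect_wave_break(
    activity_mask: ActivityMask, frame: int, lookahead_ms: float = 3.0
) -> WaveBreakSet:
    """Wave-break points in one frame.

    Operationalization of "the point where the activation wave front and the
    repolarization wave front join together": the activation front is the set
    of active pixels with a 4-neighbor that is inactive now but activates
    within the next ``lookahead_ms``; the repolarization front is the set of
    active pixels with a 4-neighbor that deactivated within the previous
    ``lookahead_ms``.  A break point is an activation-front pixel 8-adjacent
    to (or coincident with) a repolarization-front pixel.  The lookahead
    (default 3 ms, about one pixel of conduction at mapping speeds; always at
    least one frame) makes the front definition independent of the frame
    rate.  For an unbroken planar wave the two fronts are separated by the
    wave's plateau and never meet.
    """
    a = activity_mask.active
    n = a.shape[0]
    if not 0 <= frame < n:
        raise ValueError(f"frame {frame} outside recording of {n} frames")
    look = max(1, int(round(lookahead_ms / activity_mask.frame_interval)))
    now = a[frame]
    act_front = np.zeros_like(now)
    rep_front = np.zeros_like(now)
    if frame + 1 < n:
        soon_on = a[frame + 1 : frame + 1 + look].any(axis=0)
        act_front = now & _dilate4(~now & soon_on)
    if frame - 1 >= 0:
        was_on = a[max(0, frame - look) : frame].any(axis=0)
        rep_front = now & _dilate4(was_on & ~now)
    brk = act_front & _dilate8(rep_front)
    pts = np.argwhere(brk)
    if pts.size:
        pts = np.column_stack((np.full(len(pts), frame), pts))
    else:
        pts = np.empty((0, 3), dtype=int)
    return WaveBreakSet(points=pts)


def wave_break_fraction(activity_mask: ActivityMask, frames: range) -> float:
    """Fraction of the given frames (restricted to frames with any activity)
    containing at least one wave-break point."""
    hits = 0
    total = 0
    for f in frames:
        if not activity_mask.active[f].any():
            continue
        total += 1
        if len(detect_wave_break(activity_mask, f)):
            hits += 1
    return hits / total if total else 0.0
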