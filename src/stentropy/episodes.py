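"""VT episode segmentation, onset localization, cycle-length estimation.

The published workflow located episodes by visual inspection; here an explicit
prematurity rule replaces the human: an episode starts at the first beat whose
coupling interval falls below ``prematurity_fraction`` (default 0.75) of the
pacing cycle length, and ends when the inter-beat interval recovers above that
bound (self-terminating, ST) or at the end of the record (non-self-terminating,
NST).  The onset is anchored to the earliest-activating retained pixel of the
premature beat, matching the convention of starting the analysis window at the
site of earliest activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .cubes import SpacetimeCube
from .maps import activation_times

DEFAULT_PREMATURITY_FRACTION = 0.75
DEFAULT_PEAK_PROMINENCE = 0.2
DEFAULT_MIN_PEAK_DISTANCE_MS = 60.0


@dataclass
class Episode:
    """One VT episode (or a ground-truth record of one, when generated)."""

    onset_frame: int
    onset_pixel: tuple[int, int]
    duration: float  # ms
    label: str  # "ST" | "NST" | "baseline"
    cycle_length_mean: float
    cycle_length_sd: float
    e_d: float | None = None
    e_vm: float | None = None
    e_ca: float | None = None

    def __post_init__(self) -> None:
        if self.label not in ("ST", "NST", "baseline"):
            raise ValueError(f"bad episode label {self.label!r}")
        if self.duration <= 0:
            raise ValueError("episode duration must be positive")


def composite_trace(cube: SpacetimeCube) -> np.ndarray:
    """Mean normalized trace over retained pixels (the composite electrogram
    surrogate used for beat timing)."""
    if not cube.normalized:
        raise ValueError("composite_trace requires a normalized cube")
    if not cube.mask.any():
        raise ValueError("no retained pixels")
    return cube.values[:, cube.mask].mean(axis=1)


def detect_beats(
    cube: SpacetimeCube,
    prominence: float = DEFAULT_PEAK_PROMINENCE,
    min_distance_ms: float = DEFAULT_MIN_PEAK_DISTANCE_MS,
) -> np.ndarray:
    """Beat times (ms) from prominence-based peaks of the composite trace."""
    comp = composite_trace(cube)
    dist = max(1, int(round(min_distance_ms / cube.frame_interval)))
    peaks, _ = find_peaks(comp, prominence=prominence, distance=dist)
    return peaks * cube.frame_interval


def estimate_cycle_length(
    cube: SpacetimeCube,
    window: tuple[float, float] | None = None,
    prominence: float = DEFAULT_PEAK_PROMINENCE,
) -> tuple[float, float]:
    """Mean and SD of the beat-to-beat interval (ms) inside a time window.

    Peak-to-peak intervals of the composite trace; at least two beats are
    required.
    """
    beats = detect_beats(cube, prominence=prominence)
    if window is not None:
        lo, hi = window
        beats = beats[(beats >= lo) & (beats < hi)]
    if beats.size < 2:
        raise ValueError(
            f"need >= 2 beats to estimate a cycle length; found {beats.size}"
        )
    intervals = np.diff(beats)
    return float(intervals.mean()), float(intervals.std(ddof=1) if intervals.size > 1 else 0.0)


def _onset_of_beat(
    cube: SpacetimeCube, search_start_ms: float, peak_ms: float
) -> tuple[int, tuple[int, int]]:
    """Earliest half-amplitude upstroke (frame, pixel) of the beat peaking at
    ``peak_ms``, searched after ``search_start_ms``.

    Requires the upstroke to stay above half amplitude for 45 ms so that
    short-lived detector-noise blobs in the diastolic interval cannot
    masquerade as the earliest activation site."""
    fi = cube.frame_interval
    lo = max(0, int(np.ceil(search_start_ms / fi)))
    hi = min(cube.n_frames, int(round(peak_ms / fi)) + 1)
    amap = activation_times(cube, (lo, hi), sustain_ms=45.0)
    t = amap.activation_time
    idx = np.unravel_index(np.nanargmin(t), t.shape)
    onset_frame = int(round(t[idx] / fi))
    return onset_frame, (int(idx[0]), int(idx[1]))


def detect_episodes(
    vm_cube: SpacetimeCube,
    pacing_cl: float,
    prematurity_fraction: float = DEFAULT_PREMATURITY_FRACTION,
    prominence: float = DEFAULT_PEAK_PROMINENCE,
) -> list[Episode]:
    """Segment VT episodes from a conditioned Vm cube.

    A beat is premature when its coupling interval is below
    ``prematurity_fraction * pacing_cl``.  The episode runs while intervals
    stay premature; it is ST if a later beat (or quiescence of at least the
    prematurity bound) restores the slow rhythm before the record ends, NST
    otherwise.
    """
    beats = detect_beats(vm_cube, prominence=prominence)
    if beats.size < 2:
        raise ValueError("no baseline beats found — cannot reference a coupling interval")
    bound = prematurity_fraction * pacing_cl
    intervals = np.diff(beats)
    episodes: list[Episode] = []
    i = 1
    n = beats.size
    record_end = vm_cube.duration_ms
    while i < n:
        if intervals[i - 1] >= bound:
            i += 1
            continue
        # beat i is premature: episode spans beats i..j
        j = i
        while j + 1 < n and intervals[j] < bound:
            j += 1
        onset_frame, onset_pixel = _onset_of_beat(vm_cube, beats[i - 1], beats[i])
        # intervals *within* the episode (the coupling interval itself is not a VT CL)
        vt_intervals = intervals[i:j] if j > i else np.array([])
        if vt_intervals.size:
            cl_mean = float(vt_intervals.mean())
            cl_sd = float(vt_intervals.std(ddof=1)) if vt_intervals.size > 1 else 0.0
        else:
            cl_mean, cl_sd = float("nan"), float("nan")
        tail = record_end - beats[j]
        if j + 1 < n:  # a slow beat follows: terminated
            label = "ST"
            duration = beats[j] - onset_frame * vm_cube.frame_interval + (
                cl_mean if np.isfinite(cl_mean) else 0.0
            )
        elif tail >= bound:  # quiescence long enough to count as termination
            label = "ST"
            duration = beats[j] - onset_frame * vm_cube.frame_interval + (
                cl_mean if np.isfinite(cl_mean) else 0.0
            )
        else:
            label = "NST"
            duration = record_end - onset_frame * vm_cube.frame_interval
        episodes.append(
            Episode(
                onset_frame=onset_frame,
                onset_pixel=onset_pixel,
                duration=max(duration, vm_cube.frame_interval),
                label=label,
                cycle_length_mean=cl_mean,
                cycle_length_sd=cl_sd,
            )
        )
        i = j + 2  # skip the recovery interval
    return episodes
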