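"""Seeded dual-channel synthetic recordings for every regime of the analysis.

The generator emulates what the analysis pipeline assumes about real dual-dye
mapping data, without pretending to be an ionic model:

* paced rhythm at a fixed cycle length (600-1000 ms range; 750 ms default)
  with a planar conduction gradient, action-potential-shaped Vm pulses and
  calcium transients whose upstrokes lag Vm by 10-15 ms and decay more slowly;
* an "AP-A-like" variant with ~40-50% prolonged Vm/Cai durations and
  beat-to-beat Cai amplitude/duration alternans coupled to a smaller Vm
  duration alternans;
* premature-beat-initiated VT at a mean CL near 160 ms, either *coupled*
  (the Cai wavefront is a lag-shifted copy of the Vm wavefront) or
  *uncoupled* (the Cai activity fragments into independently timed wavelets —
  the observable signature of Vm/Cai uncoupling and wave break);
* additive detector noise plus short-lived supra-threshold noise blobs sized
  to be removed by the published cluster filters.

Everything is driven by one integer seed: identical spec + seed reproduces the
recording bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .cubes import SpacetimeCube
from .episodes import Episode
from .preprocess import edge_mask

REGIMES = ("paced", "paced_apa", "vt_coupled", "vt_uncoupled")

# -- fixed shape parameters of the kinematic templates (ms) -----------------
RISE_MS = 16.0          # linear upstroke; 50% crossing at RISE_MS / 2
PACED_APD50_VM = 220.0
PACED_FALL_VM = 80.0
PACED_APD50_CAI = 280.0
PACED_FALL_CAI = 140.0
VT_FALL = 40.0
VT_APD50_FLOOR = 60.0   # restitution floor: APD50 = max(0.5 * CL, floor)
VT_CL_FLOOR = 70.0      # truncation of the per-beat CL draws
PACED_COL_DELAY = 2.0   # ms per column, planar conduction
PACED_ROW_TILT = 0.3    # ms per row
VT_SPEED_PX_PER_MS = 0.4
PREMATURE_FRACTION = 0.5  # coupling interval of the initiating beat, x pacing CL
BASELINE_F = 0.2        # diastolic fluorescence offset
FIRST_BEAT_MS = 100.0

# uncoupled-Cai fragmentation
FRAG_REGIONS = (3, 6)       # inclusive range of Voronoi regions per beat
FRAG_OFFSET_MAX_MS = 40.0   # per-region activation delay (desynchronization)
FRAG_DROPOUT_P = 0.15       # chance a region stays silent for a beat

# detector-noise blobs
BLOB_AMP_FRACTION = 0.8
BLOB_DURATION_MS = (20.0, 40.0)


@dataclass
class SyntheticSpec:
    """Full parameterization of one generated recording.

    ``regime`` selects the rhythm; ``episode_duration`` of ``None`` means the
    VT persists to the end of the record (NST-like), a finite value means the
    episode self-terminates (ST-like) and pacing resumes.
    """

    regime: str
    grid: int = 16
    frame_interval: float = 1.0     # ms / frame
    duration: float = 4000.0        # ms
    pacing_cl: float = 750.0        # ms; 600-1000 is the physiological band
    vt_cl_mean: float = 160.0       # ms
    vt_cl_sd: float = 37.0          # ms
    cai_lag: float = 12.0           # ms; 10-15 is the physiological band
    apd_scale: float = 1.0          # AP-A-like prolongation factor
    alternans_depth: float = 0.0    # fractional Cai amplitude alternation
    episode_duration: float | None = 2000.0
    noise_sigma: float = 0.02       # fluorescence units
    noise_blob_rate: float = 1.0    # blobs / s / channel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if not 0 <= self.alternans_depth <= 1:
            raise ValueError("alternans_depth must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class LabeledRecording:
    """Generated recording plus its ground truth."""

    vm_cube: SpacetimeCube
    cai_cube: SpacetimeCube
    truth_episodes: list[Episode]
    spec: SyntheticSpec

    def __post_init__(self) -> None:
        if self.vm_cube.shape != self.cai_cube.shape:
            raise ValueError("Vm and Cai cubes must share shape")
        if self.vm_cube.frame_interval != self.cai_cube.frame_interval:
            raise ValueError("Vm and Cai cubes must share frame interval")


# ---------------------------------------------------------------------------
# templates and field assembly
# ---------------------------------------------------------------------------

def _pulse(tau: np.ndarray, apd50: float, fall: float, amp: float = 1.0) -> np.ndarray:
    """Piecewise-linear pulse: 16 ms upstroke, plateau, linear repolarization.

    ``tau`` is time since activation onset (ms).  The plateau length is set so
    the width at 50% amplitude (from 50% upstroke to 50% repolarization)
    equals ``apd50``.
    """
    plateau_end = apd50 - fall / 2.0 + RISE_MS / 2.0
    plateau_end = max(plateau_end, RISE_MS)
    rising = np.clip(tau / RISE_MS, 0.0, 1.0)
    falling = np.clip(1.0 - (tau - plateau_end) / fall, 0.0, 1.0)
    return amp * rising * falling


def _overlay(field3d: np.ndarray, times: np.ndarray, t_act: np.ndarray,
             apd50, fall: float, amp=1.0) -> None:
    """Max-compose one beat's pulse into the excitation field.

    ``t_act`` is the per-pixel activation-onset time (NaN = pixel silent this
    beat); ``apd50``/``amp`` may be scalars or per-pixel arrays.
    """
    silent = np.isnan(t_act)
    tau = times[:, None, None] - np.where(silent, 0.0, t_act)[None]
    apd = np.broadcast_to(np.asarray(apd50, dtype=float), t_act.shape)
    plateau_end = np.maximum(apd - fall / 2.0 + RISE_MS / 2.0, RISE_MS)
    rising = np.clip(tau / RISE_MS, 0.0, 1.0)
    falling = np.clip(1.0 - (tau - plateau_end[None]) / fall, 0.0, 1.0)
    beat = np.asarray(amp) * rising * falling
    beat[:, silent] = 0.0
    np.maximum(field3d, beat, out=field3d)


def _paced_delay(grid: int) -> np.ndarray:
    r = np.arange(grid)[:, None]
    c = np.arange(grid)[None, :]
    return c * PACED_COL_DELAY + r * PACED_ROW_TILT


def _radial_delay(grid: int, origin: tuple[int, int]) -> np.ndarray:
    r = np.arange(grid)[:, None] - origin[0]
    c = np.arange(grid)[None, :] - origin[1]
    return np.hypot(r, c) / VT_SPEED_PX_PER_MS


def _finish(spec: SyntheticSpec, rng: np.random.Generator,
            vm: np.ndarray, cai: np.ndarray,
            truth: list[Episode]) -> LabeledRecording:
    """Apply per-pixel gain, baseline offset, then detector noise."""
    amp = rng.uniform(0.85, 1.15, size=(spec.grid, spec.grid))
    vm_vals = BASELINE_F + amp[None] * vm
    cai_vals = BASELINE_F + amp[None] * cai
    rec = LabeledRecording(
        vm_cube=SpacetimeCube(vm_vals, spec.frame_interval, "Vm"),
        cai_cube=SpacetimeCube(cai_vals, spec.frame_interval, "Cai"),
        truth_episodes=truth,
        spec=spec,
    )
    if spec.noise_sigma > 0 or spec.noise_blob_rate > 0:
        noise_seed = int(rng.integers(0, 2**31 - 1))
        rec = add_detector_noise(rec, spec.noise_sigma, spec.noise_blob_rate, noise_seed)
    return rec


# ---------------------------------------------------------------------------
# paced rhythm
# ---------------------------------------------------------------------------

def generate_paced(spec: SyntheticSpec) -> LabeledRecording:
    """Paced rhythm: a planar wavefront sweeps the grid once per beat.

    ``paced_apa`` uses the same machinery; its physiology enters through
    ``apd_scale`` (duration prolongation) and ``alternans_depth`` (Cai
    amplitude/duration alternans with a smaller coupled Vm-duration
    alternans).
    """
    if spec.regime not in ("paced", "paced_apa"):
        raise ValueError(f"generate_paced expects a paced regime, got {spec.regime!r}")
    if spec.duration < 2 * spec.pacing_cl:
        raise ValueError(
            f"duration {spec.duration} ms too short: need >= 2 pacing cycles "
            f"({2 * spec.pacing_cl:.0f} ms)"
        )
    rng = np.random.default_rng(spec.seed)
    fi = spec.frame_interval
    n = int(round(spec.duration / fi))
    times = np.arange(n) * fi
    delay = _paced_delay(spec.grid)
    vm = np.zeros((n, spec.grid, spec.grid))
    cai = np.zeros_like(vm)

    beat_times = np.arange(FIRST_BEAT_MS, spec.duration, spec.pacing_cl)
    d = spec.alternans_depth
    for k, t0 in enumerate(beat_times):
        parity = 1.0 if k % 2 == 0 else -1.0
        vm_apd = PACED_APD50_VM * spec.apd_scale * (1.0 + parity * d / 8.0)
        cai_apd = PACED_APD50_CAI * spec.apd_scale * (1.0 + parity * d / 4.0)
        cai_amp = 1.0 + parity * d / 2.0
        _overlay(vm, times, t0 + delay, vm_apd, PACED_FALL_VM)
        _overlay(cai, times, t0 + delay + spec.cai_lag, cai_apd, PACED_FALL_CAI, cai_amp)
    return _finish(spec, rng, vm, cai, truth=[])


# ---------------------------------------------------------------------------
# VT regimes
# ---------------------------------------------------------------------------

def _draw_cl(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    for _ in range(100):
        cl = rng.normal(mean, sd)
        if cl >= VT_CL_FLOOR:
            return float(cl)
    return VT_CL_FLOOR


def _fragmented_cai_beat(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    retained: np.ndarray,
    t_beat: float,
) -> np.ndarray:
    """Per-pixel Cai activation times for one uncoupled VT beat.

    The retained field is split into 3-6 Voronoi regions around random seed
    pixels; each region fires as its own wavelet with an independent delay,
    regions occasionally drop out, and a silent boundary band between regions
    keeps the wavelets spatially distinct, so each beat's Cai activity breaks
    into separate spacetime clusters of diverse sizes while the Vm wavefront
    stays whole.
    """
    grid = spec.grid
    k = int(rng.integers(FRAG_REGIONS[0], FRAG_REGIONS[1] + 1))
    idx = np.argwhere(retained)
    seeds = idx[rng.choice(len(idx), size=k, replace=False)]
    rr = np.arange(grid)[:, None, None]
    cc = np.arange(grid)[None, :, None]
    dist = np.hypot(rr - seeds[:, 0][None, None, :], cc - seeds[:, 1][None, None, :])
    assign = np.argmin(dist, axis=2)
    # silence the 4-neighbor boundary band between regions
    boundary = np.zeros((grid, grid), dtype=bool)
    boundary[:-1] |= assign[:-1] != assign[1:]
    boundary[1:] |= assign[1:] != assign[:-1]
    boundary[:, :-1] |= assign[:, :-1] != assign[:, 1:]
    boundary[:, 1:] |= assign[:, 1:] != assign[:, :-1]
    offsets = rng.uniform(0.0, FRAG_OFFSET_MAX_MS, size=k)
    dropped = rng.random(k) < FRAG_DROPOUT_P
    if dropped.all():
        dropped[0] = False
    t_act = np.full((grid, grid), np.nan)
    for region in range(k):
        if dropped[region]:
            continue
        members = (assign == region) & ~boundary
        d = np.hypot(
            np.arange(grid)[:, None] - seeds[region, 0],
            np.arange(grid)[None, :] - seeds[region, 1],
        ) / VT_SPEED_PX_PER_MS
        t_act[members] = t_beat + spec.cai_lag + offsets[region] + d[members]
    return t_act


def generate_vt(spec: SyntheticSpec) -> LabeledRecording:
    """Premature-beat-initiated VT: coupled or uncoupled Cai dynamics.

    Two paced baseline beats establish the reference rhythm; a premature beat
    at half the pacing interval initiates the episode at a random retained
    origin pixel.  Per-beat cycle lengths are truncated-normal draws around
    ``vt_cl_mean``; every VT beat is a radial wavefront from a fresh origin
    (reentrant-like meander).  In the coupled regime the Cai field is the Vm
    field delayed by ``cai_lag``; in the uncoupled regime each Cai beat is an
    independently fragmented set of wavelets while Vm keeps propagating as
    whole wavefronts, so the two channels' cluster-size distributions diverge.
    """
    if spec.regime not in ("vt_coupled", "vt_uncoupled"):
        raise ValueError(f"generate_vt expects a VT regime, got {spec.regime!r}")
    if spec.vt_cl_mean <= spec.frame_interval:
        raise ValueError(
            f"vt_cl_mean {spec.vt_cl_mean} ms must exceed the frame interval"
        )
    rng = np.random.default_rng(spec.seed)
    fi = spec.frame_interval
    n = int(round(spec.duration / fi))
    times = np.arange(n) * fi
    grid = spec.grid
    retained = edge_mask(grid, grid)
    delay = _paced_delay(grid)
    vm = np.zeros((n, grid, grid))
    cai = np.zeros_like(vm)

    # --- paced baseline (both regimes stay coupled before the VT) ---------
    baseline_beats = [FIRST_BEAT_MS, FIRST_BEAT_MS + spec.pacing_cl]
    for t0 in baseline_beats:
        _overlay(vm, times, t0 + delay, PACED_APD50_VM, PACED_FALL_VM)
        _overlay(cai, times, t0 + delay + spec.cai_lag, PACED_APD50_CAI, PACED_FALL_CAI)

    # --- episode skeleton -------------------------------------------------
    t_on_beat = baseline_beats[-1] + PREMATURE_FRACTION * spec.pacing_cl
    vt_end = (
        spec.duration if spec.episode_duration is None
        else min(t_on_beat + spec.episode_duration, spec.duration)
    )
    # an episode that runs into the record end is operationally NST, even if a
    # finite episode_duration was requested but does not fit
    terminates = vt_end < spec.duration
    idx_retained = np.argwhere(retained)
    origin0 = tuple(idx_retained[rng.integers(len(idx_retained))])
    beat_times: list[float] = []
    cls: list[float] = []
    t = t_on_beat
    while t < vt_end:
        beat_times.append(t)
        cl = _draw_cl(rng, spec.vt_cl_mean, spec.vt_cl_sd)
        cls.append(cl)
        t += cl

    # --- render VT beats --------------------------------------------------
    for m, t0 in enumerate(beat_times):
        origin = origin0 if m == 0 else tuple(idx_retained[rng.integers(len(idx_retained))])
        rad = _radial_delay(grid, origin)
        apd = max(0.5 * cls[m], VT_APD50_FLOOR)
        t_act = t0 + rad
        _overlay(vm, times, t_act, apd, VT_FALL)
        if spec.regime == "vt_coupled":
            _overlay(cai, times, t_act + spec.cai_lag, apd, VT_FALL)
        else:
            frag = _fragmented_cai_beat(rng, spec, retained, t0)
            _overlay(cai, times, frag, apd, VT_FALL)

    # --- resumed pacing after a self-terminating episode ------------------
    label = "ST" if terminates else "NST"
    if label == "ST":
        t0 = vt_end + 0.9 * spec.pacing_cl
        while t0 < spec.duration:
            _overlay(vm, times, t0 + delay, PACED_APD50_VM, PACED_FALL_VM)
            _overlay(cai, times, t0 + delay + spec.cai_lag, PACED_APD50_CAI, PACED_FALL_CAI)
            t0 += spec.pacing_cl

    onset_ms = t_on_beat + RISE_MS / 2.0  # 50% upstroke of the earliest pixel
    cls_arr = np.asarray(cls)
    truth = [
        Episode(
            onset_frame=int(round(onset_ms / fi)),
            onset_pixel=(int(origin0[0]), int(origin0[1])),
            duration=float(vt_end - t_on_beat),
            label=label,
            cycle_length_mean=float(cls_arr.mean()),
            cycle_length_sd=float(cls_arr.std(ddof=1)) if cls_arr.size > 1 else 0.0,
        )
    ]
    return _finish(spec, rng, vm, cai, truth)


def generate(spec: SyntheticSpec) -> LabeledRecording:
    """Dispatch on regime."""
    if spec.regime in ("paced", "paced_apa"):
        return generate_paced(spec)
    return generate_vt(spec)


# ---------------------------------------------------------------------------
# detector noise
# ---------------------------------------------------------------------------

def _add_channel_noise(
    cube: SpacetimeCube,
    sigma: float,
    blob_rate: float,
    rng: np.random.Generator,
) -> SpacetimeCube:
    vals = cube.values.astype(float).copy()
    n, grid = cube.n_frames, cube.shape[1]
    fi = cube.frame_interval

    if blob_rate > 0:
        # approximate clean activity (pre-noise) so blobs land in quiescent
        # spacetime, away from real wavefronts even after dilation
        lo = vals.min(axis=0)
        rngmax = vals.max(axis=0) - lo
        safe = np.where(rngmax <= 0, 1.0, rngmax)
        norm = (vals - lo[None]) / safe[None]
        busy = ndimage.binary_dilation(norm >= 0.5, np.ones((5, 5, 5), dtype=bool))
        n_blobs = rng.poisson(blob_rate * cube.duration_ms / 1000.0)
        plus = np.array([[0, 0], [-1, 0], [1, 0], [0, -1], [0, 1]])
        for _ in range(n_blobs):
            for _attempt in range(50):
                r = int(rng.integers(1, grid - 1))
                c = int(rng.integers(1, grid - 1))
                dur = int(round(rng.uniform(*BLOB_DURATION_MS) / fi))
                f0 = int(rng.integers(0, max(1, n - dur)))
                pix = plus + (r, c)
                if busy[f0 : f0 + dur, pix[:, 0], pix[:, 1]].any():
                    continue
                level = lo[pix[:, 0], pix[:, 1]] + BLOB_AMP_FRACTION * rngmax[pix[:, 0], pix[:, 1]]
                seg = vals[f0 : f0 + dur, pix[:, 0], pix[:, 1]]
                vals[f0 : f0 + dur, pix[:, 0], pix[:, 1]] = np.maximum(seg, level[None])
                break

    if sigma > 0:
        vals += rng.normal(0.0, sigma, size=vals.shape)
    return cube.copy(values=vals)


def add_detector_noise(
    recording: LabeledRecording,
    noise_sigma: float,
    noise_blob_rate: float,
    seed: int,
) -> LabeledRecording:
    """Additive Gaussian detector noise plus sparse supra-threshold blobs.

    Blobs are 5-pixel plus-shapes lasting 20-40 ms at 80% of the local trace
    range: bright enough to cross the 65% activity threshold, but below both
    the 50 ms persistence and the >5 px area bounds, so the published cluster
    filters remove them.  Blobs are placed only in quiescent spacetime so they
    never merge with genuine wavefront clusters.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    vm = _add_channel_noise(recording.vm_cube, noise_sigma, noise_blob_rate, rng)
    cai = _add_channel_noise(recording.cai_cube, noise_sigma, noise_blob_rate, rng)
    return LabeledRecording(
        vm_cube=vm,
        cai_cube=cai,
        truth_episodes=recording.truth_episodes,
        spec=recording.spec,
    )
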