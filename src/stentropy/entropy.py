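"""Spatiotemporal entropy E, the entropy difference E_d, and running traces.

E is a Shannon entropy over cluster-*size classes*: with n_s clusters of size
s and total cluster volume V = sum(s * n_s),

    v_s = s * n_s / V          (fractional volume of size class s)
    E   = -sum_s v_s ln v_s    (natural log; nats)

E is computed separately for the voltage and calcium channels of the same
window; their absolute difference E_d = |E_Vm - E_Ca| quantifies how far the
two channels' wavefront complexity has diverged (Vm/Cai uncoupling).  A
quiescent window (no surviving clusters) is assigned E = 0: no wavefronts,
zero complexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import (
    ClusterSet,
    filter_clusters,
    label_clusters,
)

DEFAULT_WINDOW_MS = 500.0
DEFAULT_STEP_MS = 160.0


@dataclass
class ClusterParams:
    """Cluster labeling/filter settings threaded through entropy windows."""

    connectivity: int = 26
    min_duration_ms: float = 50.0
    min_peak_area_px: int = 5
    max_area_at_start_px: int = 10


@dataclass
class EntropyResult:
    """Entropy of one analysis window, both channels."""

    e_vm: float
    e_ca: float
    e_d: float
    window_ms: tuple[float, float]
    v_s_vm: dict[int, float] = field(default_factory=dict)
    v_s_ca: dict[int, float] = field(default_factory=dict)


@dataclass
class EntropyTrace:
    """Running entropy: one E per channel per window start."""

    times_ms: np.ndarray  # window start times
    e_vm_series: np.ndarray
    e_ca_series: np.ndarray
    e_d_series: np.ndarray
    window_ms: float
    step_ms: float


def _v_s_table(cluster_set: ClusterSet) -> dict[int, float]:
    sizes = cluster_set.sizes()
    if sizes.size == 0:
        return {}
    uniq, counts = np.unique(sizes, return_counts=True)
    v = uniq * counts / sizes.sum()
    return {int(s): float(x) for s, x in zip(uniq, v)}


def entropy(cluster_set: ClusterSet) -> float:
    """E = -sum_s v_s ln v_s over the filtered cluster set (nats).

    Clusters of equal size share one term: v_s aggregates their volume.  An
    empty set returns 0 by convention.
    """
    sizes = cluster_set.sizes()
    if sizes.size == 0:
        return 0.0
    uniq, counts = np.unique(sizes, return_counts=True)
    v = uniq * counts / sizes.sum()
    return float(-(v * np.log(v)).sum())


def entropy_difference(e_vm: float, e_ca: float) -> float:
    """E_d = |E_Vm - E_Ca|; symmetric and non-negative."""
    return abs(e_vm - e_ca)


def _window_entropy(mask, start: int, end: int, params: ClusterParams) -> tuple[float, ClusterSet]:
    cs = label_clusters(mask, (start, end), connectivity=params.connectivity)
    cs = filter_clusters(
        cs,
        min_duration_ms=params.min_duration_ms,
        min_peak_area_px=params.min_peak_area_px,
        max_area_at_start_px=params.max_area_at_start_px,
    )
    return entropy(cs), cs


def episode_ed(
    vm_mask,
    cai_mask,
    onset_frame: int,
    window_ms: float = DEFAULT_WINDOW_MS,
    params: ClusterParams | None = None,
) -> EntropyResult:
    """Entropy of the single onset-anchored analysis window of one episode.

    The window covers ``[onset_frame, onset_frame + window)``; its first frame
    is "time zero" for the 10-pixel start-area filter, so wavefronts already
    in flight at the onset are excluded.
    """
    params = params or ClusterParams()
    fi = vm_mask.frame_interval
    w = int(round(window_ms / fi))
    n = vm_mask.n_frames
    if onset_frame < 0 or onset_frame + w > n:
        remaining = (n - onset_frame) * fi
        raise ValueError(
            f"window of {window_ms} ms does not fit at onset frame {onset_frame}: "
            f"only {remaining:.0f} ms of recording remain"
        )
    e_vm, cs_vm = _window_entropy(vm_mask, onset_frame, onset_frame + w, params)
    e_ca, cs_ca = _window_entropy(cai_mask, onset_frame, onset_frame + w, params)
    return EntropyResult(
        e_vm=e_vm,
        e_ca=e_ca,
        e_d=entropy_difference(e_vm, e_ca),
        window_ms=(onset_frame * fi, (onset_frame + w) * fi),
        v_s_vm=_v_s_table(cs_vm),
        v_s_ca=_v_s_table(cs_ca),
    )


def running_entropy(
    vm_mask,
    cai_mask,
    window_ms: float = DEFAULT_WINDOW_MS,
    step_ms: float = DEFAULT_STEP_MS,
    params: ClusterParams | None = None,
    mode: str = "sliding",
) -> EntropyTrace:
    """Continuous E: one value per channel every ``step_ms``, each over a
    ``window_ms`` segment.

    ``mode="sliding"`` (default) advances overlapping windows by the step;
    ``mode="tiled"`` forces non-overlapping windows (step = window).  Each
    window's first frame is its own time zero for the start-area filter.
    """
    if mode not in ("sliding", "tiled"):
        raise ValueError("mode must be 'sliding' or 'tiled'")
    if mode == "tiled":
        step_ms = window_ms
    params = params or ClusterParams()
    fi = vm_mask.frame_interval
    if vm_mask.active.shape != cai_mask.active.shape:
        raise ValueError("Vm and Cai masks must share shape")
    w = int(round(window_ms / fi))
    s = int(round(step_ms / fi))
    if s < 1:
        raise ValueError("step shorter than one frame")
    n = vm_mask.n_frames
    if n < w:
        raise ValueError(
            f"recording ({n * fi:.0f} ms) shorter than one window ({window_ms} ms)"
        )
    starts = np.arange(0, n - w + 1, s)
    e_vm = np.empty(starts.size)
    e_ca = np.empty(starts.size)
    for i, st in enumerate(starts):
        e_vm[i], _ = _window_entropy(vm_mask, int(st), int(st) + w, params)
        e_ca[i], _ = _window_entropy(cai_mask, int(st), int(st) + w, params)
    return EntropyTrace(
        times_ms=starts * fi,
        e_vm_series=e_vm,
        e_ca_series=e_ca,
        e_d_series=np.abs(e_vm - e_ca),
        window_ms=window_ms,
        step_ms=step_ms,
    )
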