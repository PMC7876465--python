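"""Spacetime coherent clusters: labeling, the published filters, size histogram.

Successive activity frames stacked along time form a 3-D binary volume; a
coherent cluster is a connected component of active voxels in that volume.
Clusters are the substrate of the spatiotemporal entropy statistic, so the
filter rules that decide which clusters count are applied here, exactly as
published for this analysis:

* persistence: a cluster must last at least 50 ms (inclusive);
* instantaneous area: it must exceed 5 pixels in at least one frame;
* time zero: a cluster occupying more than 10 pixels in the analysis
  window's first frame began before the window and is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

DEFAULT_CONNECTIVITY = 26
DEFAULT_MIN_DURATION_MS = 50.0
DEFAULT_MIN_PEAK_AREA_PX = 5
DEFAULT_MAX_AREA_AT_START_PX = 10


@dataclass
class Cluster:
    """One spacetime connected component.

    ``voxels`` is an (n, 3) array of (frame, row, col) with absolute frame
    indices; ``size`` is the voxel count (the s of the entropy statistic).
    """

    voxels: np.ndarray
    birth_frame: int
    death_frame: int
    area_by_frame: np.ndarray  # pixels per frame, birth..death inclusive
    area_at_window_start: int

    @property
    def size(self) -> int:
        return int(self.voxels.shape[0])

    @property
    def duration_frames(self) -> int:
        return self.death_frame - self.birth_frame + 1

    @property
    def peak_area(self) -> int:
        return int(self.area_by_frame.max())


@dataclass
class ClusterSet:
    """All clusters of one channel within one analysis window."""

    clusters: list[Cluster]
    window: tuple[int, int]  # [start_frame, end_frame) — absolute indices
    connectivity: int
    frame_interval: float
    filter_counts: dict = field(default_factory=dict)

    @property
    def total_volume(self) -> int:
        return int(sum(c.size for c in self.clusters))

    def sizes(self) -> np.ndarray:
        return np.array([c.size for c in self.clusters], dtype=np.int64)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def label_clusters(
    activity_mask,
    window: tuple[int, int] | None = None,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> ClusterSet:
    """Label connected components of active voxels within ``window``.

    ``window`` is ``(start_frame, end_frame)`` with the end exclusive; ``None``
    means the whole recording.  Components are maximal and pairwise disjoint
    under the chosen 3-D connectivity (26 joins space and time diagonals, 6 is
    face-adjacency only).
    """
    active = activity_mask.active
    if window is None:
        window = (0, active.shape[0])
    start, end = window
    if not (0 <= start < end <= active.shape[0]):
        raise ValueError(f"empty or out-of-range window {window}")
    sub = active[start:end]
    labels, n = ndimage.label(sub, structure=_structure(connectivity))

    clusters: list[Cluster] = []
    if n:
        flat = labels.ravel()
        nz = np.flatnonzero(flat)
        labs = flat[nz]
        order = np.argsort(labs, kind="stable")
        nz, labs = nz[order], labs[order]
        bounds = np.searchsorted(labs, np.arange(1, n + 2))
        f, r, c = np.unravel_index(nz, sub.shape)
        f = f + start
        for i in range(n):
            lo, hi = bounds[i], bounds[i + 1]
            vox = np.column_stack((f[lo:hi], r[lo:hi], c[lo:hi]))
            birth = int(vox[:, 0].min())
            death = int(vox[:, 0].max())
            area = np.bincount(vox[:, 0] - birth, minlength=death - birth + 1)
            clusters.append(
                Cluster(
                    voxels=vox,
                    birth_frame=birth,
                    death_frame=death,
                    area_by_frame=area,
                    area_at_window_start=int(np.count_nonzero(vox[:, 0] == start)),
                )
            )
    return ClusterSet(
        clusters=clusters,
        window=(start, end),
        connectivity=connectivity,
        frame_interval=activity_mask.frame_interval,
    )


def filter_clusters(
    cluster_set: ClusterSet,
    min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
    min_peak_area_px: int = DEFAULT_MIN_PEAK_AREA_PX,
    max_area_at_start_px: int = DEFAULT_MAX_AREA_AT_START_PX,
) -> ClusterSet:
    """Apply the three published cluster filters.

    Kept iff duration >= ``min_duration_ms`` (inclusive) AND peak instantaneous
    area strictly exceeds ``min_peak_area_px`` AND area in the window's first
    frame is <= ``max_area_at_start_px`` (strictly larger is removed, because
    such a cluster began before the analysis window).  Survivors' voxel sets
    are untouched; per-criterion counts are recorded for audit logging.
    """
    fi = cluster_set.frame_interval
    counts = {"input": len(cluster_set.clusters)}
    stage = [
        c for c in cluster_set.clusters if c.duration_frames * fi >= min_duration_ms
    ]
    counts["after_duration"] = len(stage)
    stage = [c for c in stage if c.peak_area > min_peak_area_px]
    counts["after_peak_area"] = len(stage)
    stage = [c for c in stage if c.area_at_window_start <= max_area_at_start_px]
    counts["after_start_area"] = len(stage)
    return ClusterSet(
        clusters=stage,
        window=cluster_set.window,
        connectivity=cluster_set.connectivity,
        frame_interval=fi,
        filter_counts=counts,
    )


def size_histogram(cluster_set: ClusterSet) -> dict[int, int]:
    """Map cluster size s -> number of clusters n_s of that size."""
    sizes = cluster_set.sizes()
    if sizes.size == 0:
        return {}
    uniq, counts = np.unique(sizes, return_counts=True)
    return {int(s): int(n) for s, n in zip(uniq, counts)}
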