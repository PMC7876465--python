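"""Spacetime cluster labeling (vs a flood-fill oracle) and the published filters."""

from collections import deque

import numpy as np
import pytest

import stentropy as st
from stentropy.preprocess import ActivityMask


def mask_of(active, fi=1.0):
    return ActivityMask(np.asarray(active, bool), 0.65, "Vm", fi)


def flood_fill_components(active, connectivity):
    """Independent BFS labeling oracle over a binary 3-D volume."""
    if connectivity == 26:
        neigh = [
            (df, dr, dc)
            for df in (-1, 0, 1)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (df, dr, dc) != (0, 0, 0)
        ]
    else:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    shape = active.shape
    seen = np.zeros(shape, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(active)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            f, r, c = q.popleft()
            comp.add((f, r, c))
            for df, dr, dc in neigh:
                nf, nr, nc = f + df, r + dr, c + dc
                if (
                    0 <= nf < shape[0]
                    and 0 <= nr < shape[1]
                    and 0 <= nc < shape[2]
                    and active[nf, nr, nc]
                    and not seen[nf, nr, nc]
                ):
                    seen[nf, nr, nc] = True
                    q.append((nf, nr, nc))
        comps.append(frozenset(comp))
    return set(comps)


class TestLabeling:
    def test_single_voxel(self):
        a = np.zeros((4, 16, 16), bool)
        a[2, 3, 3] = True
        cs = st.label_clusters(mask_of(a))
        assert len(cs.clusters) == 1 and cs.clusters[0].size == 1

    def test_spatial_diagonal_connectivity_rule(self):
        a = np.zeros((1, 16, 16), bool)
        a[0, 5, 5] = a[0, 6, 6] = True
        assert len(st.label_clusters(mask_of(a), connectivity=26).clusters) == 1
        assert len(st.label_clusters(mask_of(a), connectivity=6).clusters) == 2

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a = rng.random((10, 16, 16)) < 0.3
            cs = st.label_clusters(mask_of(a), connectivity=connectivity)
            got = {
                frozenset(map(tuple, c.voxels.tolist())) for c in cs.clusters
            }
            assert got == flood_fill_components(a, connectivity)

    def test_empty_window_rejected(self):
        a = np.zeros((5, 16, 16), bool)
        with pytest.raises(ValueError, match="window"):
            st.label_clusters(mask_of(a), window=(3, 3))

    def test_permutation_invariant_size_multiset(self):
        rng = np.random.default_rng(7)
        a = rng.random((8, 16, 16)) < 0.25
        sizes = sorted(c.size for c in st.label_clusters(mask_of(a)).clusters)
        # transposing rows/cols relabels pixel order but preserves adjacency
        b = np.transpose(a, (0, 2, 1))
        sizes_t = sorted(c.size for c in st.label_clusters(mask_of(b)).clusters)
        assert sizes == sizes_t


class TestFilters:
    @staticmethod
    def block_mask(n_frames, area, start_frame, duration):
        """One rectangular cluster of `area` pixels lasting `duration` frames."""
        a = np.zeros((n_frames, 16, 16), bool)
        pix = [(r, c) for r in range(16) for c in range(16)][:area]
        for f in range(start_frame, start_frame + duration):
            for r, c in pix:
                a[f, r, c] = True
        return a

    def test_persistence_bound_inclusive_at_50ms(self):
        kept = st.label_clusters(mask_of(self.block_mask(80, 8, 10, 50)))
        gone = st.label_clusters(mask_of(self.block_mask(80, 8, 10, 49)))
        assert len(st.filter_clusters(kept).clusters) == 1
        assert len(st.filter_clusters(gone).clusters) == 0

    def test_peak_area_must_strictly_exceed_5(self):
        kept = st.label_clusters(mask_of(self.block_mask(80, 6, 10, 60)))
        gone = st.label_clusters(mask_of(self.block_mask(80, 5, 10, 60)))
        assert len(st.filter_clusters(kept).clusters) == 1
        assert len(st.filter_clusters(gone).clusters) == 0

    def test_time_zero_area_above_10_removed(self):
        # cluster present in the window's first frame with 11 px: began earlier
        gone = st.label_clusters(mask_of(self.block_mask(80, 11, 0, 60)))
        kept = st.label_clusters(mask_of(self.block_mask(80, 10, 0, 60)))
        assert len(st.filter_clusters(gone).clusters) == 0
        assert len(st.filter_clusters(kept).clusters) == 1

    def test_filtering_is_pure_subset(self):
        rng = np.random.default_rng(5)
        a = rng.random((70, 16, 16)) < 0.35
        cs = st.label_clusters(mask_of(a))
        before = {
            frozenset(map(tuple, c.voxels.tolist())): c.size for c in cs.clusters
        }
        for c in st.filter_clusters(cs).clusters:
            key = frozenset(map(tuple, c.voxels.tolist()))
            assert before[key] == c.size  # survivors' voxel sets unchanged

    def test_filter_counts_recorded(self):
        cs = st.label_clusters(mask_of(self.block_mask(80, 8, 10, 50)))
        out = st.filter_clusters(cs)
        assert out.filter_counts["input"] == 1
        assert out.filter_counts["after_start_area"] == 1


class TestSizeHistogram:
    def test_small_example(self, ):
        from conftest import cluster_set_of_sizes

        cs = cluster_set_of_sizes([3, 3, 7])
        assert st.size_histogram(cs) == {3: 2, 7: 1}
        assert cs.total_volume == 13

    def test_empty(self):
        from conftest import cluster_set_of_sizes

        assert st.size_histogram(cluster_set_of_sizes([])) == {}

    def test_totals_match_recount_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            a = rng.random((6, 16, 16)) < 0.3
            cs = st.label_clusters(mask_of(a))
            hist = st.size_histogram(cs)
            assert sum(s * n for s, n in hist.items()) == int(a.sum())
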