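import numpy as np
import pytest

import stentropy as st


def conditioned(rec):
    """Condition both channels and return (vm_cube, cai_cube, vm_mask, cai_mask)."""
    vm = st.condition(rec.vm_cube)
    cai = st.condition(rec.cai_cube)
    return vm, cai, st.activity_mask(vm), st.activity_mask(cai)


@pytest.fixture(scope="session")
def paced_clean():
    """Noise-free paced recording: planar wavefront every 750 ms."""
    spec = st.SyntheticSpec(
        regime="paced", duration=2500.0, noise_sigma=0.0, noise_blob_rate=0.0, seed=3
    )
    return st.generate(spec)


@pytest.fixture(scope="session")
def coupled_rec():
    spec = st.SyntheticSpec(regime="vt_coupled", duration=3000.0, seed=11)
    return st.generate(spec)


@pytest.fixture(scope="session")
def uncoupled_rec():
    spec = st.SyntheticSpec(
        regime="vt_uncoupled", duration=3000.0, episode_duration=None, seed=11
    )
    return st.generate(spec)


def cluster_set_of_sizes(sizes):
    """Minimal ClusterSet carrying a given size multiset (entropy only reads sizes)."""
    clusters = []
    for s in sizes:
        vox = np.zeros((int(s), 3), dtype=int)
        vox[:, 0] = np.arange(int(s))
        clusters.append(
            st.Cluster(
                voxels=vox,
                birth_frame=0,
                death_frame=int(s) - 1,
                area_by_frame=np.ones(int(s), dtype=int),
                area_at_window_start=1,
            )
        )
    return st.ClusterSet(clusters=clusters, window=(0, 1), connectivity=26, frame_interval=1.0)
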