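"""Synthetic dual-channel generator: determinism, physiology, noise model."""

import numpy as np
import pytest

import stentropy as st
from conftest import conditioned


def upstroke_times(trace, fi, frac=0.5):
    """50%-crossing times (ms) of each upstroke in a normalized trace."""
    up = np.flatnonzero((trace[1:] >= frac) & (trace[:-1] < frac)) + 1
    # keep only crossings that stay up a while (genuine beats)
    keep = [k for k in up if trace[min(k + 20, len(trace) - 1)] > frac]
    return np.asarray(keep, float) * fi


def apd50s(trace, fi):
    """Durations (ms) above half amplitude, per beat."""
    above = trace >= 0.5
    edges = np.diff(above.astype(int))
    ups = np.flatnonzero(edges == 1) + 1
    downs = np.flatnonzero(edges == -1) + 1
    durs = []
    for u in ups:
        later = downs[downs > u]
        if later.size:
            durs.append((later[0] - u) * fi)
    return np.asarray(durs)


class TestDeterminism:
    @pytest.mark.parametrize("regime", ["paced", "vt_coupled", "vt_uncoupled"])
    def test_same_spec_same_seed_bit_identical(self, regime):
        spec = st.SyntheticSpec(regime=regime, duration=2000.0, seed=5)
        a = st.generate(spec)
        b = st.generate(spec)
        np.testing.assert_array_equal(a.vm_cube.values, b.vm_cube.values)
        np.testing.assert_array_equal(a.cai_cube.values, b.cai_cube.values)

    def test_different_seed_differs(self):
        a = st.generate(st.SyntheticSpec(regime="paced", duration=2000.0, seed=1))
        b = st.generate(st.SyntheticSpec(regime="paced", duration=2000.0, seed=2))
        assert not np.array_equal(a.vm_cube.values, b.vm_cube.values)


class TestPacedPhysiology:
    def test_cai_upstroke_lags_vm_by_the_spec_lag(self):
        spec = st.SyntheticSpec(
            regime="paced", pacing_cl=750.0, cai_lag=12.0, duration=2500.0,
            noise_sigma=0.0, noise_blob_rate=0.0, seed=1,
        )
        rec = st.generate(spec)
        vm, cai, _, _ = conditioned(rec)
        for r, c in [(7, 7), (4, 10), (10, 4)]:
            tv = upstroke_times(vm.values[:, r, c], vm.frame_interval)
            tc = upstroke_times(cai.values[:, r, c], cai.frame_interval)
            lags = tc[: len(tv)] - tv[: len(tc)]
            assert np.all(np.abs(lags - 12.0) <= 1.0 + 1e-9)

    def test_apa_prolongs_durations_by_apd_scale(self):
        base = st.SyntheticSpec(regime="paced", duration=2500.0,
                                noise_sigma=0.0, noise_blob_rate=0.0, seed=2)
        apa = st.SyntheticSpec(regime="paced_apa", apd_scale=1.45, duration=2500.0,
                               noise_sigma=0.0, noise_blob_rate=0.0, seed=2)
        vm0 = st.condition(st.generate(base).vm_cube)
        vm1 = st.condition(st.generate(apa).vm_cube)
        d0 = apd50s(vm0.values[:, 8, 8], 1.0).mean()
        d1 = apd50s(vm1.values[:, 8, 8], 1.0).mean()
        assert d1 / d0 == pytest.approx(1.45, abs=0.05)

    def test_alternans_alternates_cai_amplitude_and_vm_duration(self):
        spec = st.SyntheticSpec(
            regime="paced_apa", apd_scale=1.45, alternans_depth=0.3,
            duration=4000.0, noise_sigma=0.0, noise_blob_rate=0.0, seed=3,
        )
        rec = st.generate(spec)
        cai = rec.cai_cube.values[:, 8, 8]
        # per-beat Cai peaks alternate in amplitude
        beats = np.array_split(cai, np.arange(1, 6) * 750)
        peaks = np.array([b.max() for b in beats[:5]])
        big, small = peaks[::2].mean(), peaks[1::2].mean()
        assert (big - small) / ((big + small) / 2) == pytest.approx(0.3, abs=0.08)
        # Vm duration alternates too, but less than Cai duration
        vm = st.condition(rec.vm_cube).values[:, 8, 8]
        ca = st.condition(rec.cai_cube).values[:, 8, 8]
        dv = apd50s(vm, 1.0)[:4]
        dc = apd50s(ca, 1.0)[:4]
        vm_swing = abs(np.diff(dv)).mean() / dv.mean()
        cai_swing = abs(np.diff(dc)).mean() / dc.mean()
        assert 0 < vm_swing < cai_swing

    def test_short_duration_rejected(self):
        spec = st.SyntheticSpec(regime="paced", duration=1000.0, pacing_cl=750.0)
        with pytest.raises(ValueError, match="too short"):
            st.generate_paced(spec)


class TestVtGeneration:
    def test_st_truth_carries_generator_inputs(self):
        spec = st.SyntheticSpec(regime="vt_coupled", vt_cl_mean=160.0,
                                episode_duration=2000.0, seed=4)
        ep = st.generate(spec).truth_episodes[0]
        assert ep.label == "ST"
        assert ep.duration == 2000.0

    def test_nst_truth_label(self):
        spec = st.SyntheticSpec(regime="vt_uncoupled", episode_duration=None,
                                duration=3000.0, seed=4)
        ep = st.generate(spec).truth_episodes[0]
        assert ep.label == "NST"

    def test_cl_mean_below_frame_interval_rejected(self):
        spec = st.SyntheticSpec(regime="vt_coupled", vt_cl_mean=0.5)
        with pytest.raises(ValueError, match="frame interval"):
            st.generate_vt(spec)

    def test_regime_dispatch_guards(self):
        with pytest.raises(ValueError, match="paced regime"):
            st.generate_paced(st.SyntheticSpec(regime="vt_coupled"))
        with pytest.raises(ValueError, match="VT regime"):
            st.generate_vt(st.SyntheticSpec(regime="paced"))

    def test_uncoupled_overlap_below_coupled_on_matched_seeds(self):
        """Lag-aligned voxel overlap (Jaccard) of Vm vs Cai activity is lower
        when the Cai field fragments."""
        def jaccard(rec):
            vm, cai, va, ca = conditioned(rec)
            lag = int(round(rec.spec.cai_lag / vm.frame_interval))
            a = va.active[:-lag]
            b = ca.active[lag:]
            return (a & b).sum() / max((a | b).sum(), 1)

        for seed in range(10):
            c = st.generate(st.SyntheticSpec(
                regime="vt_coupled", episode_duration=None, duration=2500.0, seed=seed))
            u = st.generate(st.SyntheticSpec(
                regime="vt_uncoupled", episode_duration=None, duration=2500.0, seed=seed))
            assert jaccard(u) < jaccard(c)


class TestDetectorNoise:
    def test_zero_noise_is_identity(self):
        spec = st.SyntheticSpec(regime="paced", duration=2000.0,
                                noise_sigma=0.0, noise_blob_rate=0.0, seed=6)
        rec = st.generate(spec)
        out = st.add_detector_noise(rec, 0.0, 0.0, seed=99)
        np.testing.assert_array_equal(out.vm_cube.values, rec.vm_cube.values)

    def test_same_seed_same_noise(self):
        spec = st.SyntheticSpec(regime="paced", duration=2000.0,
                                noise_sigma=0.0, noise_blob_rate=0.0, seed=6)
        rec = st.generate(spec)
        a = st.add_detector_noise(rec, 0.05, 1.0, seed=7)
        b = st.add_detector_noise(rec, 0.05, 1.0, seed=7)
        np.testing.assert_array_equal(a.vm_cube.values, b.vm_cube.values)

    def test_blobs_removed_by_cluster_filters(self):
        """Noise blobs alone never change the filtered cluster inventory."""
        for seed in range(5):
            clean = st.generate(st.SyntheticSpec(
                regime="paced", duration=2500.0,
                noise_sigma=0.0, noise_blob_rate=0.0, seed=seed))
            noisy = st.add_detector_noise(clean, 0.0, 3.0, seed=seed + 100)

            def filtered_voxels(rec):
                _, _, va, _ = conditioned(rec)
                cs = st.filter_clusters(st.label_clusters(va))
                return {frozenset(map(tuple, c.voxels.tolist())) for c in cs.clusters}

            assert filtered_voxels(noisy) == filtered_voxels(clean)

    def test_blob_rate_with_default_sigma_keeps_cluster_counts(self):
        for seed in range(3):
            clean = st.generate(st.SyntheticSpec(
                regime="paced", duration=2500.0,
                noise_sigma=0.0, noise_blob_rate=0.0, seed=seed))
            noisy = st.add_detector_noise(clean, 0.02, 2.0, seed=seed + 50)

            def n_filtered(rec):
                _, _, va, _ = conditioned(rec)
                return len(st.filter_clusters(st.label_clusters(va)).clusters)

            assert n_filtered(noisy) == n_filtered(clean)

    def test_negative_sigma_rejected(self):
        spec = st.SyntheticSpec(regime="paced", duration=2000.0, seed=0)
        rec = st.generate(spec)
        with pytest.raises(ValueError):
            st.add_detector_noise(rec, -0.1, 0.0, seed=0)


class TestSpecValidation:
    def test_bad_regime(self):
        with pytest.raises(ValueError, match="regime"):
            st.SyntheticSpec(regime="sinus")

    def test_bad_alternans_depth(self):
        with pytest.raises(ValueError, match="alternans"):
            st.SyntheticSpec(regime="paced", alternans_depth=1.5)
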