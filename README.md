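# stentropy

Spatiotemporal entropy analysis of dual-channel cardiac optical-mapping
movies — for electrophysiology labs quantifying voltage/calcium (Vm/Cai)
uncoupling during ventricular tachyarrhythmia (VT).

Simultaneous voltage-dye and calcium-dye movies of the same tissue show, beat
by beat, whether calcium release still follows the electrical wavefront.
During polymorphic VT the two can dissociate ("uncoupling"), and the degree
of early dissociation relates to whether an episode self-terminates (ST) or
persists (NST).  `stentropy` measures this with a cluster-entropy statistic:
each channel's movie is thresholded into a binary spacetime volume, active
voxels are joined into coherent wavefront clusters (filtered by persistence
≥ 50 ms, instantaneous area > 5 px, and a ≤ 10 px footprint at the analysis
window's start), and each 500 ms window is summarized by

    E = − Σ_s v_s ln v_s ,   v_s = s · n_s / V_Total

where n_s counts clusters of size s voxels and V_Total is the total cluster
volume.  The uncoupling measure is the entropy difference between channels,

    E_d = | E_Vm − E_Ca |   (nats).

Coherent rhythm gives E_d ≈ 0; fragmented, discordant calcium dynamics raise
E_Ca away from E_Vm.  The package implements the full chain — trace
conditioning (13 ms moving average, per-trace [0, 1] normalization, edge
discard), spacetime clustering, entropy windows, automatic VT-episode
segmentation with cycle-length estimation, and group statistics (ANOVA,
Welch tests at the Bonferroni-corrected 0.0125 level, Monte-Carlo
Lilliefors) — plus a seeded synthetic generator of paced, coupled-VT and
uncoupled-VT recordings, and a two-variable excitable-medium simulator for
wave-break phenomenology.  See `docs/methods.md` for the model and every
default.

## Worked example

Generate an uncoupled (non-self-terminating) VT recording and analyze it:

```sh
stentropy simulate --regime vt_uncoupled --episode-duration 0 \
    --out-dir demo_rec --seed 8
stentropy analyze --vm demo_rec/vm.tif --cai demo_rec/cai.tif \
    --sidecar demo_rec/sidecar.yaml --out-dir demo_out
```

which prints the episode table:

```
 onset_ms  onset_row  onset_col  duration_ms label  cycle_length_mean_ms  cycle_length_sd_ms     e_vm     e_ca      e_d
   1233.0         10         13       2767.0   NST              159.9375           36.909744 1.598814 2.383949 0.785135
```

Reading it: a premature beat at 1233 ms arising at pixel (10, 13) starts a
VT that persists to the record end (NST) at a mean cycle length of ~160 ms.
Over the 500 ms onset window the voltage channel forms a few large coherent
clusters (E_Vm = 1.60 nats) while the calcium channel fragments into many
cluster sizes (E_Ca = 2.38 nats); the entropy difference E_d = 0.79 nats
flags strong Vm/Cai uncoupling.  A matched *coupled* recording gives
E_d ≈ 0.  `demo_out/` also receives the running-entropy trace
(E every 160 ms) as CSV + PNG and a resolved `config.yaml`.

The same analysis is three calls in Python:

```python
import stentropy as st

rec = st.generate(st.SyntheticSpec(regime="vt_uncoupled",
                                   episode_duration=None, seed=8))
vm, cai = st.condition(rec.vm_cube), st.condition(rec.cai_cube)
ep = st.detect_episodes(vm, rec.spec.pacing_cl)[0]
res = st.episode_ed(st.activity_mask(vm), st.activity_mask(cai), ep.onset_frame)
print(res.e_vm, res.e_ca, res.e_d)
```

`stentropy demo --out-dir batch/` writes a labeled 23 + 12 batch of
coupled/uncoupled recordings, and `stentropy stats` runs the group
comparison over episode tables.

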