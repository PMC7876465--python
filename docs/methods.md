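# Methods

## The statistic

`stentropy` analyzes simultaneous voltage (Vm) and intracellular calcium
(Cai) optical-mapping movies of cardiac tissue — two spacetime cubes of
fluorescence, one per dye channel, on a 16×16 photodiode grid.  The question
it answers is whether, during a ventricular tachyarrhythmia (VT) episode, the
calcium wavefronts still track the voltage wavefronts (coupled) or have
broken away into independent dynamics (uncoupled).

Each channel is reduced to a binary activity volume and summarized by a
Shannon entropy over *coherent cluster* sizes:

1. every pixel trace is smoothed with a 13 ms moving average and min–max
   scaled to [0, 1] (the scaled value is dF relative to that trace's range);
2. pixels farther than 8 px from the field center are discarded;
3. a voxel is *active* when its normalized value is ≥ 0.65 (65% of the
   per-trace maximum dF; inclusive boundary);
4. active voxels are joined into spacetime connected components
   (26-connectivity by default; 6 available);
5. clusters are filtered: persistence ≥ 50 ms (inclusive), instantaneous
   area > 5 px in at least one frame, area ≤ 10 px in the analysis window's
   first frame (a larger footprint at "time zero" means the cluster began
   before the window);
6. with n_s clusters of size s (voxels) and V = Σ s·n_s, the fractional
   volume per size class is v_s = s·n_s / V and

       E = − Σ_s v_s ln v_s        (natural log, nats).

E is computed per channel over the same window; the *entropy difference*
E_d = |E_Vm − E_Ca| is the uncoupling measure.  E_d is a relative statistic:
neither channel's E is treated as an absolute entropy of the tissue.

Windows: each VT episode is summarized by a single 500 ms window anchored at
the episode onset (the earliest half-amplitude activation of the premature
beat).  A running trace computes E every 160 ms, each value over a 500 ms
segment; windows slide (overlap) by default, a tiled mode exists behind
config.  A window with no surviving clusters has E = 0 (quiescence carries no
wavefront complexity).  The entropy of an empty or single-size-class cluster
set is exactly 0, and E ≤ ln(#distinct sizes) always.

## Episode machinery

Episodes are segmented automatically (replacing visual inspection) by a
prematurity rule: a beat whose coupling interval is below 0.75× the pacing
cycle length starts an episode; the episode ends when the inter-beat interval
recovers above that bound (self-terminating, ST) or at the record end
(non-self-terminating, NST).  Beat times come from prominence-based peaks of
the composite trace (mean over retained pixels).  The onset pixel is the
earliest half-amplitude upstroke of the premature beat, required to stay
above half amplitude for 45 ms — the per-pixel analog of the 50 ms cluster
persistence rule, which prevents short detector-noise blobs in diastole from
posing as the earliest activation site.  Cycle length is mean ± SD of
peak-to-peak intervals of the composite trace.

Group statistics follow the standard protocol for this design: one-way ANOVA
across rhythm groups, post-hoc two-tailed Welch t-tests (unequal variance)
significant below the Bonferroni-corrected critical value 0.0125 (α = 0.05),
and a Lilliefors normality check per group.  The Lilliefors p-value is
obtained by seeded Monte-Carlo simulation of the null (default 10⁴
replicates) rather than truncated lookup tables; the statistic matches the
table-based implementation in statsmodels to machine precision.

## Synthetic data: what it emulates

No recordings ship with the package; a seeded generator produces recordings
with the statistical and wavefront structure the analysis assumes.  Defaults
are fixed at the study's operating points:

| parameter | default | meaning |
|---|---|---|
| grid | 16×16 | photodiode array geometry |
| frame_interval | 1 ms | sampling (not dictated by the method; all ms rules round to frames) |
| pacing_cl | 750 ms | paced rhythm, physiological band 600–1000 ms |
| cai_lag | 12 ms | Cai upstroke lag behind Vm, band 10–15 ms |
| apd_scale | 1.0 (1.45 typical) | pharmacological AP/Cai prolongation (~40–50%) |
| alternans_depth | 0 | fractional beat-to-beat Cai amplitude alternation; Cai duration alternates at half, Vm duration at a quarter of the depth (the Vm alternation is the smaller, coupled echo) |
| vt_cl_mean ± sd | 160 ± 37 ms | per-beat VT cycle length, truncated-normal (floor 70 ms) |
| episode_duration | 2000 ms / None | finite → ST-like; None → activity persists to record end (NST-like) |
| noise_sigma | 0.02 | additive Gaussian detector noise (fluorescence units) |
| noise_blob_rate | 1 /s/channel | supra-threshold noise blobs sized to be removed by the cluster filters |

Action potentials are piecewise-linear templates (16 ms linear upstroke,
plateau, linear repolarization) parameterized by their width at 50%
amplitude: paced APD50 is 220 ms (Vm) and 280 ms (Cai, slower decay); during
VT, APD50 = max(0.5·CL, 60) ms.  Paced conduction is planar (2 ms/column
with a 0.3 ms/row tilt); each VT beat is a radial wavefront from a fresh
random origin at 0.4 px/ms, the first one from the episode's ground-truth
onset pixel, coupled at half the pacing interval after the last paced beat.
Per-pixel gain varies ±15% and a diastolic offset of 0.2 is added, so
normalization has real work to do.

*Coupled* VT derives the Cai field from the same activation times plus the
lag — concordant wavefronts, so E_Ca ≈ E_Vm and E_d ≈ 0.  *Uncoupled* VT
fragments each Cai beat into 3–6 Voronoi wavelets around random seeds, each
with an independent 0–40 ms delay, 15% region dropout, and a silent boundary
band that keeps wavelets in separate clusters; the Vm wavefront stays whole.
The Cai cluster-size distribution therefore diversifies while Vm's stays
concentrated, driving E_d up — the observable the uncoupling statistic is
built to detect.  Identical spec + seed reproduces a recording bit for bit.

Noise blobs are 5-px plus-shapes lasting 20–40 ms at 80% of the local trace
range: bright enough to cross the 0.65 threshold, but below both the 50 ms
persistence and the >5 px area bounds, and placed only in quiescent
spacetime, so the published filters remove them without touching genuine
clusters.

What the generator does **not** emulate: ionic/calcium-cycling biophysics,
EAD/DAD mechanisms, motion artifacts, photobleaching, 3-D tissue, or real
reentrant circuit geometry.  Passing tests therefore demonstrate that the
*pipeline* recovers the regime structure it is specified to detect, not that
the generator's physiology is quantitatively realistic.

A separate two-variable excitable-medium simulator (Barkley kinetics,
explicit Euler, no-flux boundaries) provides wavefront phenomenology the
kinematic generator cannot: expanding target waves, and — after a premature
cross-field S2 inside the vulnerable window — a broken wavefront with
sustained reentry.  It validates the wave-break detector: the activation
front (active pixels with an inactive 4-neighbor that activates within the
next ~3 ms) and the repolarization front (active pixels with a 4-neighbor
that just deactivated) meet, 8-adjacent, at the break; for planar waves the
fronts never meet.  The VT generator itself remains kinematic because the
validation targets need exact control of per-beat cycle length and
ground-truth onsets, which a PDE model cannot guarantee.

One geometric caveat, discovered during design: a detected front junction is
by construction a 26-connected bridge between two wavelets, so a Cai field
whose wavelets stay in distinct clusters (the basis of the E_d contrast)
cannot simultaneously show front junctions in most frames.  Wave-break
detection is therefore validated on the excitable-medium protocol, where
break points appear within 1–2 px of the S2 boundary, rather than on the
fragmented synthetic Cai field.

## Numerical choices

- Moving-average edges shrink the window to in-bounds samples; no padding
  values are fabricated.  Constant (dead) traces are dropped from the
  retained-pixel mask rather than divided by zero.
- The 0.65 threshold is applied per trace (consistent with per-trace
  normalization); a field-wide-maximum mode exists behind a flag for
  sensitivity analysis.
- Filter boundary semantics are literal: duration ≥ 50 ms kept, peak area
  must strictly exceed 5 px, area strictly above 10 px at time zero removed.
- Bilinear 16×16 → 256×256 interpolation pins coarse-grid nodes exactly;
  silent (NaN) pixels are nearest-neighbor infilled first.
- All randomness descends from one integer seed via `SeedSequence` fan-out,
  so batch membership never perturbs individual recordings.

## Validation sizes

The shipped validation uses problem sizes chosen to exercise the method at
its published operating points while staying cheap: 4 s recordings at
1 ms/frame; 20 paced seeds for baseline coherence (per-seed mean running
E_d ≤ 0.08 nats); 23 coupled + 12 uncoupled VT episodes for the regime
contrast (uncoupled mean onset E_d > 0.33 nats; Welch p < 0.001); 10 seeds
at a fixed 160 ms VT cycle length for the estimator check (±5 ms); 40
recordings for episode ground-truth recovery (≥95%); 4000-replicate null
simulations for the 1.25% per-pair type-I error of the corrected test.

## Known limitations

- The sliding-window E_d of a *paced* recording can spike in the rare window
  whose start frame falls inside the ~12 ms interval between the Vm
  wavefront exceeding the 10 px time-zero bound and the lagged Cai wavefront
  birth: the filter then removes the Vm cluster but keeps the Cai cluster.
  This is a property of the published filter rules combined with the
  physiological lag; baseline coherence is therefore a statement about the
  mean over windows, not each window.
- The prematurity rule (0.75× pacing CL, configurable) is an explicit
  stand-in for visual episode identification and is reported as such.
- ST vs NST is operational: an episode reaching the record end is NST, with
  no fixed duration cutoff.
- Wave-break detection implements a testable reading of a verbal definition;
  it is not a phase-singularity tracker.
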