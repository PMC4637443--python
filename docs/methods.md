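# Methods

This note documents the models, parameters, and numerical choices behind the
`ischemia_ecg` package: a fully synthetic pipeline from voxel ventricles to
body-surface ST-deviation features and detection-rate statistics.

Units are fixed throughout the interface: millimetres (lengths), milliseconds
(times), millivolts (transmembrane voltage), microvolts (surface signals),
metres per second (conduction velocity).

## 1. Synthetic anatomy (`anatomy.py`)

The left ventricle is the shell between two confocal half-ellipsoids truncated
by a base plane at `z = 0.45 · lv_long_axis`; the wall thickness tapers
linearly from `wall_thickness_base` at the base to `wall_thickness_apex` at the
apex. A crescent right ventricle of constant `rv_wall_thickness` is attached on
the septal side down to 60 % of the long axis. The heart is voxelized on a
regular grid (`voxel_size ≤ 2 mm`), tilted by two rotation angles, and placed
inside a cylindrical torso.

Three default subjects vary wall thickness and torso size:

| subject | LV long/short axis | wall base/apex | torso radius/height |
| --- | --- | --- | --- |
| VM-like | 82 / 35 mm | 12 / 9 mm | 172 / 680 mm |
| K-like  | 75 / 32 mm | 10 / 7 mm | 165 / 640 mm |
| D-like  | 70 / 30 mm |  9 / 6 mm | 158 / 610 mm |

Per voxel the package stores chamber label, AHA 17-segment label (apex cap
below the cavity, long-axis thirds, 6/6/4 circumferential sectors with the
anterior wall at +y), and a transmural depth `d ∈ [0, 1]` computed from
Euclidean distance transforms to the endocardial and epicardial surface voxel
sets, `d = d_endo / (d_endo + d_epi)` (exactly 0 on the endocardium, 1 on the
epicardium).

Ten early-activation sites are chosen by farthest-point sampling on the
endocardium (deterministic per subject seed) with stimulus delays spread
uniformly over 10–30 ms. The 10 ms offset keeps the first frames of the beat
at rest so they can serve as the baseline window, and places the R peak near
40 ms.

Electrodes: the standard limb and precordial electrodes plus right-sided
V3R–V6R (precordial positions mirrored across the sagittal plane), and a
body-surface map of ~600 electrodes on a Fibonacci lattice over the torso
cylinder (mean nearest-neighbor spacing ≈ 4 cm). Unipolar leads are referenced
to the Wilson central terminal (mean of RA, LA, LL); bipolar limb and
augmented leads follow the Einthoven/Goldberger definitions.

## 2. Ischemia geometry (`ischemia.py`)

An ischemic region is a hemisphere of total radius `r` grown from an
endocardial center voxel in a chosen AHA segment. The zone factor of a voxel
at distance `d` from the center is

```
ZF(d) = 1                      d ≤ r − bz      (central ischemic zone, CIZ)
      = (r − d) / bz           r − bz < d < r  (linear border zone)
      = 0                      d ≥ r
```

with border-zone width `bz ∈ {2.8, 4.8, 9.6}` mm by default. When `r ≤ bz`
the CIZ is empty and the peak zone factor is `r / bz < 1`; such setups are
valid members of the study grid (small radii with the widest border zone). A
setup is classified *transmural* when a fully ischemic (CIZ) voxel lies on or
26-adjacent to the epicardial surface, otherwise *subendocardial*.

The default study grid is the Cartesian product of 17 segments × 3 border
zones × per-subject radii (5–25 mm in 5 mm steps; up to 30 mm for the
thick-walled VM-like subject), i.e. 765 setups.

## 3. Action-potential model (`ap.py`)

Each voxel carries a phenomenological transmembrane-voltage template
parameterized by resting voltage, amplitude, APD90, and conduction velocity:
rest until activation, a 2 ms linear upstroke, a plateau until
`t_act + 0.5 · APD90`, then a half-cosine repolarization whose span is chosen
so the voltage at `t_act + APD90` is exactly `rest + 0.1 · amplitude`
(the APD90 definition).

Parameters interpolate linearly in ZF between healthy and acutely ischemic
endpoints, per wall layer (endo/mid/epi by transmural depth thirds):

| parameter | healthy (endo/mid/epi) | CIZ (≈10 min of ischemia) | rationale |
| --- | --- | --- | --- |
| resting voltage | −85 mV | −70 mV | extracellular K⁺ accumulation depolarizes the resting membrane, driving diastolic injury currents |
| amplitude | 125 mV | 95 mV | reduced upstroke in depolarized tissue |
| APD90 | 320 / 340 / 300 ms | −25 % | ATP-sensitive K⁺ channel activation shortens the plateau |
| conduction velocity | 0.6 m/s | −40 % | depressed excitability slows propagation |

The transmural APD90 gradient (epi < endo < mid) yields a concordant T wave.
All endpoints are configurable in the study YAML.

## 4. Activation propagation (`propagation.py`)

Activation is a first-arrival process: edge traversal time between adjacent
voxels (26-neighborhood) is the Euclidean edge length divided by the harmonic
mean of the two voxels' conduction velocities. First arrivals from all
stimulus sites (with their delays) are computed with Dijkstra's algorithm on a
sparse graph with a virtual source node, and rounded to a 0.1 ms clock — a
cellular-automaton view of wavefront spread that ignores curvature and
anisotropy. Beats are 500 ms long, sampled every 2 ms (251 frames).

## 5. Forward model (`forward.py`)

Each voxel contributes an equivalent current dipole
`p = −σ_i ∇V_m · voxel³` with intracellular conductivity `σ_i = 0.17 S/m`.
The gradient is taken over myocardial tissue only: central differences where
both axis neighbors are tissue, one-sided at the boundary, zero across
non-tissue. This masked gradient reproduces the open-double-layer (solid
angle) physics of injury currents — the mechanism behind ST depression over
subendocardial and ST elevation over transmural ischemia — and makes a
spatially uniform voltage exactly electrically silent.

Electrode potentials are infinite-medium dipole sums,
`φ(e) = Σ_v p_v · (r_e − r_v) / (4π σ_b |r_e − r_v|³)` with bulk conductivity
`σ_b = 0.2 S/m`; no torso boundary correction is applied. Per subject, one
physiological (ZF ≡ 0) simulation fixes a calibration factor so the largest
absolute 12-lead QRS amplitude is 1500 µV, making microvolt thresholds
meaningful. Every record is baseline-corrected by subtracting each lead's mean
over the first five frames (0–8 ms, before the earliest stimulus).

## 6. Features (`features.py`)

* **STSD** — for each lead, the mean over the 25 samples at 110–158 ms; STSD
  is the largest absolute window mean across leads. It mimics classical
  fixed-latency ST measurement and is blind to deviations that cancel within
  the window or across time.
* **K point / KPD** — the K point is the time in 40–320 ms (R peak to T peak)
  where the across-lead envelope `max_e |b_e(t)|` is minimal (earliest sample
  on ties); KPD is the envelope value there. It is a surrogate for J-point ST
  measurement that needs no QRS delineation: at the quietest instant of the
  beat, whatever amplitude remains in *some* lead is deviation.
* **K-point elevation** — same construction with negative amplitudes clipped
  to zero before the envelope, an ST-elevation-only criterion (STEMI-like).

Lead scenarios: `3-channel` (the six limb-derived leads), `12-lead`, `12+R`
(plus V3R–V6R), `12+1` (plus one optimized unipolar electrode), and `BSPM`
(all unipolar electrodes plus the limb-derived leads). Each scenario's lead
set is a superset of the previous one, so per-setup feature values — and hence
detection rates at every threshold — are monotone in electrode coverage by
construction.

## 7. Study engine (`study.py`)

Detection rate at threshold τ is the fraction of ischemic setups with feature
value ≥ τ. Threshold-free comparisons average the rate over fixed grids: 54
steps on 24–240 µV (STSD) and 36 steps on 9–150 µV (KPD and elevation). The
additional 10th electrode of the `12+1` scenario is chosen once (common across
all setups, or per subject) to maximize the grid-averaged rate of the
augmented 12-lead set; ties resolve to the lowest electrode index. Per-segment
sensitivity is summarized by the largest threshold that still detects ≥ 80 %
of a segment's setups — attained at an observed feature value because the rate
is a step function. Subgroup reports slice rates by radius, border zone,
transmurality, subject, segment, or single lead (at the K point shared across
the 12-lead set).

The entire pipeline is deterministic — anatomy, electrode placement,
activation, and forward model contain no run-time randomness beyond the
per-subject seeds stored in the configuration — so re-running a study with
the same configuration reproduces the feature table bit-identically.

## 8. Numerical choices

* Activation uses `scipy.sparse.csgraph.dijkstra` on a COO adjacency built
  vectorially from the 26 neighbor offsets; times are rounded to a 0.1 ms
  clock, which bounds the discrepancy with any exact shortest-path solver by
  one clock tick.
* The forward solve is a single dense GEMM per beat: gain matrix
  (electrodes × voxels × 3) contracted against the per-frame dipole field.
* Threshold-grid averaging uses `searchsorted` counting, exactly equal to the
  mean of per-threshold rates.
* Serialization: voxel hearts and movies as compressed `.npz` with a JSON
  metadata sidecar; ECG records and study tables as CSV (read back with
  pandas' `round_trip` float parser so round-trips are bit-exact).

## 9. What the synthetic data does and does not emulate

Emulated: the geometry-dependent magnitude and sign of ST deviation (depression
over subendocardial, elevation over transmural regions), its growth with
ischemic radius, the information gain from denser electrode coverage, limb vs
precordial sensitivity to anterior ischemia, and a concordant T wave.

Not emulated:

* **Physiological ST noise.** Healthy voxels share identical per-layer
  templates, so the physiological beat has an almost perfectly flat,
  near-zero ST segment (maximum physiological KPD ≈ 0 µV). Real
  physiological ST levels are tens of microvolts; absolute detection rates
  here are therefore optimistic, and the physiological-threshold operating
  points degenerate to ~0. Comparisons *between* lead systems, features, and
  setup subgroups are the meaningful outputs.
* **Torso inhomogeneity.** The infinite-medium dipole sum omits the bounded
  torso, lungs, and cavity blood, which scale and smear surface potentials;
  the per-subject QRS calibration absorbs the overall scale but not the
  spatial distortion.
* **Realistic conduction.** No His–Purkinje tree, fiber anisotropy, or
  wavefront curvature; activation is isotropic first-arrival from ten
  endocardial sites.
* **Beat-to-beat variability, noise, respiration, electrode misplacement** —
  all records are noise-free single beats.
* **Anatomical realism.** Parametric ellipsoid ventricles and a cylindrical
  torso stand in for subject-specific imaging; absolute rates are not
  comparable to rates obtained on segmented human anatomies.

## 10. Open design decisions

* Stimulus delays span 10–30 ms so the 0–8 ms baseline window is strictly
  diastolic.
* The BSPM scenario includes the six limb-derived leads alongside all
  unipolar electrodes, making the lead-coverage monotonicity exact rather
  than approximate.
* Study-grid setups with `r ≤ bz` (no CIZ) are retained; their peak zone
  factor is `r / bz`.
* The hemisphere is grown from an endocardial voxel nearest the segment
  centroid; at 2 mm resolution the transmurality classifier is generous
  (26-adjacency to the epicardium), so mid-sized radii on thin walls may
  already classify as transmural.
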