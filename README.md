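# ischemia-ecg

In-silico study of how detectable **early (≈10 min) myocardial ischemia** is in
the surface ECG, and how much detection improves when more electrodes are
available. In the first minutes of an occlusion the ECG change is often a
subtle shift of the ST segment — frequently ST *depression* for subendocardial
ischemia — which standard 12-lead criteria miss in a large fraction of cases.
This package simulates thousands of ischemic beats on parametric voxel
ventricles, computes the resulting body-surface signals, extracts ST-deviation
features, and tabulates detection rates per lead system.

## What is simulated

1. **Synthetic anatomy** — a truncated-ellipsoid left ventricle plus a
   crescent right ventricle on a regular voxel grid (1–2 mm), inside a
   cylindrical torso carrying the standard 12-lead electrodes, right-sided
   V3R–V6R, and a ~600-electrode body-surface map (BSPM) at ≈4 cm spacing.
2. **Ischemia geometry** — a hemispherical ischemic region grown from an
   endocardial point in one of the 17 AHA segments, with a central ischemic
   zone (CIZ) and a linear border zone (BZ); every voxel gets a zone factor
   ZF ∈ [0, 1].
3. **Electrophysiology** — a phenomenological action-potential template per
   voxel (resting voltage, amplitude, APD90, conduction velocity), linearly
   interpolated between healthy and acutely ischemic endpoints by ZF and
   transmural depth. Activation spreads as a shortest-path (first-arrival)
   process on the 26-neighbor voxel graph.
4. **Forward model** — each voxel contributes a current dipole proportional
   to the spatial transmembrane-voltage gradient (taken over tissue only);
   electrode potentials are infinite-medium dipole sums, calibrated so the
   physiological 12-lead QRS peaks at 1.5 mV.
5. **Features and study** — ST-segment deviation (STSD: largest absolute
   window-mean over 25 samples at 110–158 ms) and K-point deviation (KPD:
   the minimum over 40–320 ms of the across-lead envelope of absolute
   amplitudes, evaluated at that minimum), plus an elevation-only variant.
   Detection rate = fraction of ischemic setups whose feature clears a
   threshold; threshold-free comparisons average the rate over fixed grids
   (54 steps on 24–240 µV for STSD, 36 steps on 9–150 µV for KPD).

The default study grid enumerates **765 ischemic setups**: 17 segments × 3
border-zone radii (2.8 / 4.8 / 9.6 mm) × 15 subject-radius combinations
(three subjects, ischemia radii 5–25 mm, up to 30 mm for the thick-walled
subject).

## Worked example

Simulate one anterior (segment 7) ischemic setup, 15 mm radius with a 4.8 mm
border zone, on the thin-walled default subject at 2 mm voxels:

```bash
$ ischemia-ecg simulate --subject D-like --segment 7 --radius 15 --bz 4.8 --out sim_demo
3-channel: STSD 5.9 uV (II), KPD 5.9 uV at 162 ms, K-elevation 5.9 uV
12-lead: STSD 40.2 uV (V4), KPD 40.2 uV at 100 ms, K-elevation 6.2 uV
12+R: STSD 43.4 uV (V3R), KPD 42.8 uV at 178 ms, K-elevation 6.2 uV
BSPM: STSD 44.3 uV (U:B406), KPD 43.8 uV at 178 ms, K-elevation 25.1 uV
transmural: True
```

The limb leads barely see this anterior ischemia (≈6 µV) while the precordial
and right-sided leads show a ~40 µV ST shift, and the best BSPM electrode a
little more — the electrode-coverage effect the study quantifies. Per-scenario
ECGs are written as CSV (`sim_demo/ecg_12-lead.csv`, …) together with the
electrode positions and lead definitions.

The same pipeline from Python:

```python
from ischemia_ecg import (IschemiaSetup, default_endpoints, prepare_subject,
                          simulate_setup, subject_by_name)
from ischemia_ecg.features import evaluate
from ischemia_ecg.forward import extract_scenario

endpoints = default_endpoints()
ctx = prepare_subject(subject_by_name("D-like", voxel_size=2.0), 600, endpoints)
record, zf = simulate_setup(ctx, IschemiaSetup("D-like", 7, 15.0, 4.8), endpoints)
print(evaluate(extract_scenario(record, "12-lead")))
# FeatureResult(stsd=40.2…, kpd=40.2…, k_elevation=6.2…, k_point_time=100.0, …)
```

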