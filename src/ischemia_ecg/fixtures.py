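"""Small deterministic fixtures for tests and demonstrations."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .anatomy import SubjectSpec, assign_aha_segments, build_ventricles
from .forward import ECGRecord, LIMB_LEADS, PRECORDIAL
from .io import save_heart, save_record


def toy_heart_spec() -> SubjectSpec:
    """A small but fully formed biventricular geometry (2 mm voxels)."""
    return SubjectSpec(name="toy", lv_long_axis=40.0, lv_short_axis=20.0,
                       wall_thickness_base=7.0, wall_thickness_apex=5.0,
                       rv_wall_thickness=3.5, torso_radius=100.0,
                       torso_height=400.0, voxel_size=2.0, rng_seed=1)


def make_toy_heart():
    return assign_aha_segments(build_ventricles(toy_heart_spec()))


def make_toy_ecg() -> ECGRecord:
    """A 12-lead record with a stylized beat on every lead."""
    t = np.arange(0.0, 501.0, 2.0)
    leads = LIMB_LEADS + PRECORDIAL
    signals = np.zeros((len(leads), t.size))
    qrs = 800.0 * np.exp(-((t - 40.0) / 8.0) ** 2)
    twave = 250.0 * np.exp(-((t - 300.0) / 35.0) ** 2)
    for i in range(len(leads)):
        signals[i] = (0.5 + i / len(leads)) * (qrs + twave)
    return ECGRecord(signals=signals, lead_names=leads, frame_interval=2.0,
                     scenario_tag="12-lead", baseline_corrected=True)


def make_alternating_st_record(c: float = 100.0) -> ECGRecord:
    """Alternating ST deviation: zero 25-sample window mean, envelope >= c.

    Lead A carries +c over the first half of the ST window and -c over the
    second half (window mean exactly zero); lead B patches the two frames
    where A would leave the envelope short, itself with zero window mean.
    STSD vanishes on this record while the KPD equals c — the constructed
    case where the envelope-minimum feature outperforms the window mean.
    """
    t = np.arange(0.0, 501.0, 2.0)
    a = np.zeros(t.size)
    b = np.zeros(t.size)
    in_k = (t >= 40.0) & (t <= 320.0)
    a[in_k] = c
    a[(t >= 134.0) & (t <= 156.0)] = -c
    a[np.isclose(t, 158.0)] = 0.0
    b[np.isclose(t, 158.0)] = c
    b[np.isclose(t, 156.0)] = -c
    return ECGRecord(signals=np.vstack([a, b]), lead_names=["A", "B"],
                     frame_interval=2.0, scenario_tag="fixture",
                     baseline_corrected=True)


def make_fixtures(kind: str, out_dir: str | Path) -> list[Path]:
    """Write a named fixture to ``out_dir``; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "toy_heart":
        p = out_dir / "toy_heart.npz"
        save_heart(make_toy_heart(), p)
        return [p, p.with_suffix(".npz.json")]
    if kind == "toy_ecg":
        p = out_dir / "toy_ecg.csv"
        save_record(make_toy_ecg(), p)
        return [p, p.with_suffix(".csv.json")]
    if kind == "alternating_st":
        p = out_dir / "alternating_st.csv"
        save_record(make_alternating_st_record(), p)
        return [p, p.with_suffix(".csv.json")]
    raise ValueError(f"unknown fixture kind {kind!r}")
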