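"""Forward ECG: infinite-medium dipole sum from the transmembrane voltage movie.

Each myocardial voxel contributes an equivalent current dipole
``p = -sigma_i * grad(V_m) * voxel_volume``; the potential at an electrode in
an infinite homogeneous medium of conductivity sigma is
``phi = p . (r_e - r_v) / (4 pi sigma |r_e - r_v|^3)``. Gradients are taken
only over myocardial tissue (one-sided at the boundary), which reproduces the
open-double-layer behavior responsible for ST depression over subendocardial
and ST elevation over transmural injury. Amplitudes are calibrated per
subject so the physiological 12-lead maximum |QRS| is 1.5 mV, making
microvolt threshold grids meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .anatomy import ElectrodeSet, VoxelHeart
from .ap import FRAME_INTERVAL_MS
from .propagation import TMVMovie

SIGMA_BULK = 0.2      # S/m, bulk torso conductivity
SIGMA_INTRA = 0.17    # S/m, intracellular conductivity scale
CALIBRATION_MAX_QRS_UV = 1500.0
BASELINE_FRAMES = 5   # pre-stimulus diastolic frames used as baseline

SCENARIOS = ("3-channel", "12-lead", "12+R", "12+1", "BSPM")
LIMB_LEADS = ["I", "II", "III", "aVR", "aVL", "aVF"]
PRECORDIAL = ["V1", "V2", "V3", "V4", "V5", "V6"]
RIGHT_SIDED = ["V3R", "V4R", "V5R", "V6R"]


@dataclass
class ECGRecord:
    """Multichannel body-surface signals in microvolts, one row per lead."""

    signals: np.ndarray            # (n_leads, n_frames) uV
    lead_names: list[str]
    frame_interval: float = FRAME_INTERVAL_MS
    scenario_tag: str = "BSPM"
    baseline_corrected: bool = False

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.signals.shape[1]) * self.frame_interval

    def lead(self, name: str) -> np.ndarray:
        return self.signals[self.lead_names.index(name)]

    def subset(self, names: list[str], scenario_tag: str) -> "ECGRecord":
        rows = [self.lead_names.index(n) for n in names]
        return replace(self, signals=self.signals[rows], lead_names=list(names),
                       scenario_tag=scenario_tag)


def lead_field(heart: VoxelHeart, electrodes: ElectrodeSet) -> np.ndarray:
    """Dipole gain matrix, shape (n_electrodes, n_voxels, 3).

    Entry (e, v, :) maps a dipole at voxel v (components in the heart's local
    frame) to the potential at electrode e. The point-dipole kernel
    (r_e - r_v)/(4 pi sigma |r_e - r_v|^3) is evaluated in global coordinates
    and rotated into the local frame.
    """
    r_v = heart.global_voxel_centers()                 # (n_vox, 3) mm
    r_e = electrodes.positions                         # (n_el, 3) mm
    diff = r_e[:, None, :] - r_v[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    if np.any(dist < heart.voxel_size):
        raise ValueError("electrode coincides with a myocardial voxel")
    gain = diff / (4.0 * np.pi * SIGMA_BULK * dist[..., None] ** 3)
    rot = heart.subject.rotation_matrix() if heart.subject is not None else np.eye(3)
    return gain @ rot   # local dipole components -> electrode potentials


def masked_gradient(movie_tmv: np.ndarray, heart: VoxelHeart) -> np.ndarray:
    """Spatial TMV gradient per myocardial voxel, (n_vox, 3, n_frames) mV/mm.

    Central differences where both axis neighbors are myocardium, one-sided
    at the tissue boundary, zero where the voxel has no myocardial neighbor
    along an axis. Gradients never reach across non-tissue, so a spatially
    uniform movie yields exactly zero.
    """
    idx = np.argwhere(heart.occupancy)
    n = idx.shape[0]
    flat_of = -np.ones(heart.shape, np.int64)
    flat_of[tuple(idx.T)] = np.arange(n)
    h = heart.voxel_size
    grad = np.zeros((n, 3, movie_tmv.shape[1]))
    shape = np.array(heart.shape)
    for axis in range(3):
        off = np.zeros(3, np.int64)
        off[axis] = 1
        for sign, store in ((1, 0), (-1, 1)):
            nb = idx + sign * off
            ok = np.all((nb >= 0) & (nb < shape), axis=1)
            j = np.full(n, -1, np.int64)
            j[ok] = flat_of[tuple(nb[ok].T)]
            if store == 0:
                j_plus = j
            else:
                j_minus = j
        has_p, has_m = j_plus >= 0, j_minus >= 0
        v_p = np.where(has_p[:, None], movie_tmv[np.where(has_p, j_plus, 0)], movie_tmv)
        v_m = np.where(has_m[:, None], movie_tmv[np.where(has_m, j_minus, 0)], movie_tmv)
        span = (has_p.astype(float) + has_m.astype(float)) * h
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(span[:, None] > 0, (v_p - v_m) / np.where(span, span, 1.0)[:, None], 0.0)
        grad[:, axis, :] = g
    return grad


def compute_bspm(movie: TMVMovie, gain: np.ndarray, heart: VoxelHeart,
                 electrodes: ElectrodeSet) -> ECGRecord:
    """Raw (uncalibrated) lead signals from the TMV movie.

    Returns the full lead set (limb, precordial, right-sided, all unipolars)
    in arbitrary units; apply :func:`finalize_record` with a subject
    calibration scale to obtain baseline-corrected microvolt signals.
    """
    n_vox = gain.shape[1]
    if movie.tmv.shape[0] != n_vox:
        raise ValueError("movie and gain voxel counts differ")
    grad = masked_gradient(movie.tmv, heart)           # (n_vox, 3, n_frames)
    dipoles = -SIGMA_INTRA * grad * heart.voxel_size ** 3
    pot = gain.reshape(gain.shape[0], -1) @ dipoles.reshape(-1, movie.n_frames)
    signals = electrodes.lead_matrix @ pot
    return ECGRecord(signals=signals, lead_names=list(electrodes.lead_names),
                     frame_interval=movie.frame_interval, scenario_tag="full",
                     baseline_corrected=False)


def calibration_scale(raw: ECGRecord) -> float:
    """Scale mapping the physiological 12-lead max |QRS| to 1.5 mV."""
    rows = [raw.lead_names.index(n) for n in LIMB_LEADS + PRECORDIAL]
    peak = np.abs(raw.signals[rows]).max()
    if peak == 0:
        raise ValueError("flat physiological record; cannot calibrate")
    return CALIBRATION_MAX_QRS_UV / peak


def finalize_record(raw: ECGRecord, scale: float) -> ECGRecord:
    """Apply amplitude calibration and per-lead diastolic baseline subtraction."""
    sig = raw.signals * scale
    baseline = sig[:, :BASELINE_FRAMES].mean(axis=1, keepdims=True)
    return replace(raw, signals=sig - baseline, baseline_corrected=True)


def extract_scenario(record: ECGRecord, scenario: str,
                     extra_electrode: int | None = None,
                     electrodes: ElectrodeSet | None = None) -> ECGRecord:
    """Select the lead subset of a clinical scenario.

    3-channel: limb leads I, II, III, aVR, aVL, aVF. 12-lead adds V1-V6.
    12+R adds the right-sided V3R-V6R. 12+1 adds one unipolar electrode lead
    (``extra_electrode`` index into the electrode set). BSPM comprises every
    unipolar lead vs WCT together with the limb-derived leads.
    """
    if scenario == "3-channel":
        return record.subset(LIMB_LEADS, scenario)
    if scenario == "12-lead":
        return record.subset(LIMB_LEADS + PRECORDIAL, scenario)
    if scenario == "12+R":
        return record.subset(LIMB_LEADS + PRECORDIAL + RIGHT_SIDED, scenario)
    if scenario == "12+1":
        if extra_electrode is None or electrodes is None:
            raise ValueError("12+1 requires extra_electrode and electrodes")
        extra = electrodes.unipolar_lead_name(extra_electrode)
        return record.subset(LIMB_LEADS + PRECORDIAL + [extra], scenario)
    if scenario == "BSPM":
        names = LIMB_LEADS + [n for n in record.lead_names if n.startswith("U:")]
        return record.subset(names, scenario)
    raise ValueError(f"unknown scenario {scenario!r}")
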