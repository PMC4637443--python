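"""Serialization: array containers with JSON sidecars, diff-able CSV tables.

Voxel hearts and TMV movies go to compressed .npz containers with a JSON
metadata sidecar; ECG records and study tables are CSV with unit-annotated
headers plus a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import ElectrodeSet, SubjectSpec, VoxelHeart
from .forward import ECGRecord
from .propagation import TMVMovie
from .study import StudyTable


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


# -- VoxelHeart --------------------------------------------------------------


def save_heart(heart: VoxelHeart, path: str | Path) -> None:
    path = Path(path)
    np.savez_compressed(
        path, occupancy=heart.occupancy, chamber_label=heart.chamber_label,
        aha_segment=heart.aha_segment, transmural_depth=heart.transmural_depth,
        endo_surface=heart.endo_surface, epi_surface=heart.epi_surface,
        lv_cavity=heart.lv_cavity, origin=heart.origin,
        apex_base_axis=heart.apex_base_axis)
    meta = {
        "voxel_size_mm": heart.voxel_size,
        "lv_center_xy": list(heart.lv_center_xy),
        "base_z": heart.base_z,
        "stimulus_sites": [[list(s), d] for s, d in heart.stimulus_sites],
        "subject": asdict(heart.subject) if heart.subject else None,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_heart(path: str | Path) -> VoxelHeart:
    path = Path(path)
    arr = np.load(path)
    meta = json.loads(_sidecar(path).read_text())
    subject = None
    if meta["subject"] is not None:
        sub = dict(meta["subject"])
        sub["heart_center_offset"] = tuple(sub["heart_center_offset"])
        sub["heart_orientation"] = tuple(sub["heart_orientation"])
        subject = SubjectSpec(**sub)
    return VoxelHeart(
        voxel_size=meta["voxel_size_mm"], origin=arr["origin"],
        occupancy=arr["occupancy"], chamber_label=arr["chamber_label"],
        aha_segment=arr["aha_segment"], transmural_depth=arr["transmural_depth"],
        endo_surface=arr["endo_surface"], epi_surface=arr["epi_surface"],
        lv_cavity=arr["lv_cavity"], apex_base_axis=arr["apex_base_axis"],
        stimulus_sites=[(tuple(s), float(d)) for s, d in meta["stimulus_sites"]],
        lv_center_xy=tuple(meta["lv_center_xy"]), base_z=meta["base_z"],
        subject=subject)


def heart_equal(a: VoxelHeart, b: VoxelHeart) -> bool:
    return (a.voxel_size == b.voxel_size
            and np.array_equal(a.origin, b.origin)
            and np.array_equal(a.occupancy, b.occupancy)
            and np.array_equal(a.chamber_label, b.chamber_label)
            and np.array_equal(a.aha_segment, b.aha_segment)
            and np.array_equal(a.transmural_depth, b.transmural_depth)
            and a.stimulus_sites == b.stimulus_sites)


# -- TMV movie ---------------------------------------------------------------


def save_movie(movie: TMVMovie, path: str | Path) -> None:
    path = Path(path)
    np.savez_compressed(path, tmv=movie.tmv)
    _sidecar(path).write_text(json.dumps(
        {"frame_interval_ms": movie.frame_interval, "duration_ms": movie.duration}))


def load_movie(path: str | Path) -> TMVMovie:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    return TMVMovie(tmv=np.load(path)["tmv"],
                    frame_interval=meta["frame_interval_ms"],
                    duration=meta["duration_ms"])


# -- ECGRecord ---------------------------------------------------------------


def save_record(record: ECGRecord, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(record.signals.T, columns=record.lead_names)
    df.insert(0, "time_ms", record.times)
    df.to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps({
        "units": "uV", "frame_interval_ms": record.frame_interval,
        "scenario_tag": record.scenario_tag,
        "baseline_corrected": record.baseline_corrected}))


def load_record(path: str | Path, frame_interval: float | None = None) -> ECGRecord:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    side = _sidecar(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    leads = [c for c in df.columns if c != "time_ms"]
    if frame_interval is None:
        if "frame_interval_ms" in meta:
            frame_interval = meta["frame_interval_ms"]
        elif "time_ms" in df.columns and len(df) > 1:
            frame_interval = float(df.time_ms.iloc[1] - df.time_ms.iloc[0])
        else:
            raise ValueError("frame interval unknown; pass frame_interval")
    return ECGRecord(signals=df[leads].to_numpy().T, lead_names=leads,
                     frame_interval=frame_interval,
                     scenario_tag=meta.get("scenario_tag", "imported"),
                     baseline_corrected=meta.get("baseline_corrected", True))


# -- electrodes --------------------------------------------------------------


def save_electrodes(electrodes: ElectrodeSet, positions_path: str | Path,
                    leads_path: str | Path) -> None:
    pos = pd.DataFrame(electrodes.positions, columns=["x_mm", "y_mm", "z_mm"])
    pos.insert(0, "name", electrodes.names)
    pos.to_csv(positions_path, index=False)
    rows = []
    for lead, coefs in zip(electrodes.lead_names, electrodes.lead_matrix):
        for e in np.nonzero(coefs)[0]:
            rows.append({"lead": lead, "electrode": electrodes.names[e],
                         "coefficient": coefs[e]})
    pd.DataFrame(rows).to_csv(leads_path, index=False)


# -- study table -------------------------------------------------------------


def save_study_table(table: StudyTable, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(directory / "study_table.csv", index=False)
    if not table.aug.empty:
        table.aug.to_csv(directory / "augmented_features.csv", index=False)
    if not table.per_lead.empty:
        table.per_lead.to_csv(directory / "per_lead_features.csv", index=False)
    (directory / "study_table.meta.json").write_text(json.dumps(
        {"value_units": "uV", "rows": int(len(table.df))}))


def load_study_table(directory: str | Path) -> StudyTable:
    directory = Path(directory)
    df = pd.read_csv(directory / "study_table.csv", float_precision="round_trip")
    aug_p = directory / "augmented_features.csv"
    lead_p = directory / "per_lead_features.csv"
    rt = {"float_precision": "round_trip"}
    return StudyTable(df=df,
                      aug=pd.read_csv(aug_p, **rt) if aug_p.exists() else pd.DataFrame(),
                      per_lead=pd.read_csv(lead_p, **rt) if lead_p.exists() else pd.DataFrame())
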