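"""Detection-rate study over the full ischemia grid.

For every subject one physiological (zone factor 0) simulation fixes the
amplitude calibration and the specificity anchor; every ischemic setup is
then simulated and the ST-deviation features are computed for each lead
scenario. Detection rate at a threshold is the fraction of ischemic setups
whose feature meets the threshold (>= rule); threshold-free statistics
average the rate over fixed grids (54 steps on 24-240 uV for STSD, 36 steps
on 9-150 uV for KPD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as feat
from .anatomy import ElectrodeSet, VoxelHeart, assign_aha_segments, build_ventricles, place_electrodes
from .ap import IschemiaEndpoints
from .forward import (ECGRecord, LIMB_LEADS, PRECORDIAL, calibration_scale,
                      compute_bspm, extract_scenario, finalize_record, lead_field)
from .ischemia import IschemiaSetup, enumerate_study_grid, ischemic_fraction, place_ischemia
from .propagation import build_tmv_movie, compute_activation, ischemic_cv_field

STSD_GRID = np.linspace(24.0, 240.0, 54)
KPD_GRID = np.linspace(9.0, 150.0, 36)
BASE_SCENARIOS = ("3-channel", "12-lead", "12+R", "BSPM")
FEATURES = ("stsd", "kpd", "k_elevation")
PHYSIO_ID = "physio"


def grid_for(feature: str, grid=None) -> np.ndarray:
    """Resolve the averaging threshold grid for a feature."""
    if grid is not None:
        if isinstance(grid, str):
            return {"stsd_grid": STSD_GRID, "kpd_grid": KPD_GRID}[grid]
        g = np.asarray(grid, float)
        if g.size == 0:
            raise ValueError("empty threshold grid")
        return g
    return STSD_GRID if feature == "stsd" else KPD_GRID


@dataclass
class StudyTable:
    """Long-format study results.

    ``df`` holds one row per (setup, scenario, feature); physiological
    reference rows use setup_id 'physio'. ``aug`` holds, per setup and
    candidate electrode, the feature value of the 12-lead set augmented by
    that electrode's unipolar lead. ``per_lead`` holds single-lead values at
    the K point shared across the 12-lead set.
    """

    df: pd.DataFrame
    aug: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_lead: pd.DataFrame = field(default_factory=pd.DataFrame)

    def ischemic(self) -> pd.DataFrame:
        return self.df[self.df.setup_id != PHYSIO_ID]

    def values(self, scenario: str, feature: str) -> np.ndarray:
        d = self.ischemic()
        sel = d[(d.scenario == scenario) & (d.feature == feature)]
        if sel.empty:
            raise KeyError(f"no rows for scenario={scenario!r}, feature={feature!r}")
        return sel.value.to_numpy()

    def equals(self, other: "StudyTable") -> bool:
        return (self.df.equals(other.df) and self.aug.equals(other.aug)
                and self.per_lead.equals(other.per_lead))


@dataclass
class DetectionReport:
    scenario: str
    feature: str
    by: str
    rates: dict
    sizes: dict
    overall: float


# ---------------------------------------------------------------------------
# simulation pipeline
# ---------------------------------------------------------------------------


@dataclass
class SubjectContext:
    """Cached per-subject anatomy, gain matrix and calibration."""

    heart: VoxelHeart
    electrodes: ElectrodeSet
    gain: np.ndarray
    scale: float
    physio_record: ECGRecord


def prepare_subject(spec, n_bspm: int, endpoints: IschemiaEndpoints) -> SubjectContext:
    heart = assign_aha_segments(build_ventricles(spec))
    electrodes = place_electrodes(spec, n_bspm)
    gain = lead_field(heart, electrodes)
    cv = ischemic_cv_field(heart, np.zeros(heart.shape), endpoints)
    act = compute_activation(heart, cv)
    movie = build_tmv_movie(act, None, endpoints, heart)
    raw = compute_bspm(movie, gain, heart, electrodes)
    scale = calibration_scale(raw)
    physio = finalize_record(raw, scale)
    return SubjectContext(heart=heart, electrodes=electrodes, gain=gain,
                          scale=scale, physio_record=physio)


def simulate_setup(ctx: SubjectContext, setup: IschemiaSetup,
                   endpoints: IschemiaEndpoints) -> tuple[ECGRecord, object]:
    """One ischemic beat: zone factors -> activation -> TMV -> surface ECG."""
    zf_field = place_ischemia(ctx.heart, setup)
    cv = ischemic_cv_field(ctx.heart, zf_field.zf, endpoints)
    act = compute_activation(ctx.heart, cv)
    movie = build_tmv_movie(act, zf_field.zf, endpoints, ctx.heart)
    raw = compute_bspm(movie, ctx.gain, ctx.heart, ctx.electrodes)
    return finalize_record(raw, ctx.scale), zf_field


def _scenario_features(record: ECGRecord, electrodes: ElectrodeSet) -> dict[str, dict[str, float]]:
    out = {}
    for scenario in BASE_SCENARIOS:
        sub = extract_scenario(record, scenario, electrodes=electrodes)
        res = feat.evaluate(sub)
        out[scenario] = {"stsd": res.stsd, "kpd": res.kpd,
                         "k_elevation": res.k_elevation,
                         "k_point_time": res.k_point_time}
    return out


def _augmented_features(record: ECGRecord, electrodes: ElectrodeSet) -> pd.DataFrame:
    """12-lead features augmented by each candidate unipolar electrode lead."""
    rec12 = extract_scenario(record, "12-lead")
    kcols = feat._window_columns(record, *feat.K_WINDOW_MS)
    scols = feat._window_columns(record, *feat.ST_WINDOW_MS)
    w12 = rec12.signals[:, kcols]
    env12 = np.abs(w12).max(axis=0)
    env12_elev = np.maximum(w12, 0.0).max(axis=0)
    stsd12, _ = feat.stsd(rec12)

    u_rows = [i for i, n in enumerate(record.lead_names) if n.startswith("U:")]
    U = record.signals[u_rows]
    uk = U[:, kcols]
    kpd_aug = np.minimum.reduce(np.maximum(np.abs(uk), env12[None, :]), axis=1)
    kelev_aug = np.minimum.reduce(np.maximum(np.maximum(uk, 0.0), env12_elev[None, :]), axis=1)
    stsd_aug = np.maximum(np.abs(U[:, scols].mean(axis=1)), stsd12)
    return pd.DataFrame({"electrode": np.arange(len(u_rows)),
                         "stsd": stsd_aug, "kpd": kpd_aug, "k_elevation": kelev_aug})


def _per_lead_rows(record: ECGRecord) -> pd.DataFrame:
    rec12 = extract_scenario(record, "12-lead")
    t_dev, _ = feat.k_point(rec12, "deviation")
    t_elev, _ = feat.k_point(rec12, "elevation")
    rows = []
    for lead in LIMB_LEADS + PRECORDIAL:
        rows.append({"lead": lead,
                     "kpd": feat.per_lead_feature(rec12, lead, t_dev, "deviation"),
                     "k_elevation": feat.per_lead_feature(rec12, lead, t_elev, "elevation")})
    return pd.DataFrame(rows)


def run_study(config) -> StudyTable:
    """Simulate the whole setup grid and tabulate features per scenario.

    Deterministic for a given configuration: anatomy, electrode placement,
    activation and forward model contain no stochastic elements.
    """
    endpoints = config.ap_endpoints()
    rows, aug_rows, lead_rows = [], [], []
    setups = enumerate_study_grid(config.subjects, config.segments,
                                  config.radii_map(), tuple(config.bz_radii))
    for spec in config.subject_specs():
        ctx = prepare_subject(spec, config.n_bspm, endpoints)
        physio_feats = _scenario_features(ctx.physio_record, ctx.electrodes)
        for scenario, vals in physio_feats.items():
            for f in FEATURES:
                rows.append(dict(setup_id=PHYSIO_ID, subject=spec.name, segment=0,
                                 total_radius=np.nan, bz_radius=np.nan,
                                 transmural=False, ischemic_fraction=0.0,
                                 scenario=scenario, feature=f, value=vals[f]))
        for setup in [s for s in setups if s.subject == spec.name]:
            record, zf_field = simulate_setup(ctx, setup, endpoints)
            frac = ischemic_fraction(zf_field, ctx.heart)
            svals = _scenario_features(record, ctx.electrodes)
            for scenario, vals in svals.items():
                for f in FEATURES:
                    rows.append(dict(setup_id=setup.setup_id, subject=spec.name,
                                     segment=setup.segment,
                                     total_radius=setup.total_radius,
                                     bz_radius=setup.bz_radius,
                                     transmural=zf_field.transmural_flag,
                                     ischemic_fraction=frac,
                                     scenario=scenario, feature=f, value=vals[f]))
            a = _augmented_features(record, ctx.electrodes)
            a.insert(0, "setup_id", setup.setup_id)
            a.insert(1, "subject", spec.name)
            aug_rows.append(a)
            pl = _per_lead_rows(record)
            pl.insert(0, "setup_id", setup.setup_id)
            pl.insert(1, "subject", spec.name)
            pl.insert(2, "segment", setup.segment)
            lead_rows.append(pl)
    return StudyTable(df=pd.DataFrame(rows),
                      aug=pd.concat(aug_rows, ignore_index=True) if aug_rows else pd.DataFrame(),
                      per_lead=pd.concat(lead_rows, ignore_index=True) if lead_rows else pd.DataFrame())


# ---------------------------------------------------------------------------
# detection statistics
# ---------------------------------------------------------------------------


def detection_rate(table: StudyTable, scenario: str, feature: str,
                   threshold: float) -> float:
    """Fraction of ischemic setups whose feature value meets the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    v = table.values(scenario, feature)
    return float(np.mean(v >= threshold))


def averaged_rate(table: StudyTable, scenario: str, feature: str,
                  grid=None) -> float:
    """Detection rate averaged over a threshold grid (mean of per-step rates)."""
    g = grid_for(feature, grid)
    v = table.values(scenario, feature)
    return float(np.mean([np.mean(v >= thr) for thr in g]))


def _averaged_rate_values(values: np.ndarray, g: np.ndarray) -> float:
    g = np.sort(g)
    counts = np.searchsorted(g, values, side="right")   # thresholds <= value
    return float(counts.mean() / g.size)


def physiological_threshold(table: StudyTable, scenario: str, feature: str,
                            pooling: str = "across_subjects"):
    """Greatest feature value seen in the nonischemic reference simulations.

    ``per_subject`` returns a dict subject -> max; ``across_subjects`` the
    max over subjects. Thresholds at 1x and 1.5x this value anchor the
    sensitivity/specificity comparison.
    """
    d = table.df
    sel = d[(d.setup_id == PHYSIO_ID) & (d.scenario == scenario) & (d.feature == feature)]
    if sel.empty:
        raise KeyError("no physiological rows for this scenario/feature")
    per = sel.groupby("subject").value.max().to_dict()
    if pooling == "per_subject":
        return per
    if pooling == "across_subjects":
        return float(max(per.values()))
    raise ValueError(f"unknown pooling {pooling!r}")


def threshold_multiples(base: float) -> tuple[float, float]:
    """The 1x and 1.5x physiological-threshold operating points."""
    return base, 1.5 * base


def optimize_additional_electrode(table: StudyTable, subject_scope: str = "common",
                                  subject: str | None = None, feature: str = "kpd",
                                  grid=None) -> int:
    """Best 10th electrode: maximizes the grid-averaged 12+1 detection rate.

    ``individual`` scope optimizes over one subject's setups, ``common`` over
    all subjects pooled; the chosen position is fixed across all radii,
    locations and border-zone extents. Ties go to the lowest electrode index.
    """
    if table.aug.empty:
        raise ValueError("study table lacks per-electrode augmented features")
    a = table.aug
    if subject_scope == "individual":
        if subject is None:
            raise ValueError("individual scope requires a subject")
        a = a[a.subject == subject]
        if a.empty:
            raise ValueError(f"no setups for subject {subject!r}")
    elif subject_scope != "common":
        raise ValueError(f"unknown subject_scope {subject_scope!r}")
    g = grid_for(feature, grid if grid is not None else "kpd_grid" if feature != "stsd" else "stsd_grid")
    pivot = a.pivot_table(index="setup_id", columns="electrode", values=feature)
    scores = np.array([_averaged_rate_values(pivot[e].to_numpy(), g)
                       for e in pivot.columns])
    return int(pivot.columns[int(np.argmax(scores))])


def add_optimized_scenario(table: StudyTable, electrode: int) -> StudyTable:
    """Materialize '12+1' rows for a fixed additional electrode."""
    a = table.aug[table.aug.electrode == electrode]
    if a.empty:
        raise ValueError(f"electrode {electrode} not in augmented table")
    meta = (table.ischemic()[["setup_id", "subject", "segment", "total_radius",
                              "bz_radius", "transmural", "ischemic_fraction"]]
            .drop_duplicates("setup_id"))
    rows = a.melt(id_vars=["setup_id", "subject", "electrode"],
                  value_vars=list(FEATURES), var_name="feature", value_name="value")
    rows = rows.merge(meta.drop(columns="subject"), on="setup_id")
    rows["scenario"] = "12+1"
    rows = rows.drop(columns="electrode")
    df = pd.concat([table.df, rows[table.df.columns]], ignore_index=True)
    return StudyTable(df=df, aug=table.aug, per_lead=table.per_lead)


def segment_threshold_80(table: StudyTable, scenario: str, feature: str,
                         segment: int, subject: str | None = None) -> float:
    """Largest threshold detecting >= 80% of a segment's ischemic setups.

    The detection rate is a step function of the threshold, so the maximum is
    attained at an observed feature value (the lower 20th-percentile value).
    """
    d = table.ischemic()
    sel = d[(d.scenario == scenario) & (d.feature == feature) & (d.segment == segment)]
    if subject is not None:
        sel = sel[sel.subject == subject]
    if sel.empty:
        raise ValueError(f"no setups for segment {segment}")
    v = np.sort(sel.value.to_numpy())
    n = v.size
    best = 0.0
    for tau in v:
        if np.mean(v >= tau) >= 0.8:
            best = max(best, float(tau))
    return best


def subgroup_report(table: StudyTable, by: str, scenario: str = "12-lead",
                    feature: str = "kpd", grid=None) -> DetectionReport:
    """Grid-averaged detection rates per subgroup level.

    ``by`` is one of radius, bz, transmurality, subject, segment, or lead
    (single-lead mode using the shared 12-lead K point).
    """
    g = grid_for(feature, grid)
    if by == "lead":
        if table.per_lead.empty:
            raise ValueError("study table lacks per-lead features")
        rates = {lead: _averaged_rate_values(sub[feature].to_numpy(), g)
                 for lead, sub in table.per_lead.groupby("lead", sort=False)}
        sizes = table.per_lead.groupby("lead", sort=False).size().to_dict()
        overall = _averaged_rate_values(table.per_lead[feature].to_numpy(), g)
        return DetectionReport(scenario="12-lead", feature=feature, by=by,
                               rates=rates, sizes=sizes, overall=overall)
    key = {"radius": "total_radius", "bz": "bz_radius",
           "transmurality": "transmural", "subject": "subject",
           "segment": "segment"}[by]
    d = table.ischemic()
    sel = d[(d.scenario == scenario) & (d.feature == feature)]
    rates = {level: _averaged_rate_values(sub.value.to_numpy(), g)
             for level, sub in sel.groupby(key)}
    sizes = sel.groupby(key).size().to_dict()
    overall = _averaged_rate_values(sel.value.to_numpy(), g)
    return DetectionReport(scenario=scenario, feature=feature, by=by,
                           rates=rates, sizes=sizes, overall=overall)
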