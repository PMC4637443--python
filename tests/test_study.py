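"""Detection statistics against brute-force oracles on constructed tables."""

import numpy as np
import pandas as pd
import pytest

from ischemia_ecg.study import (KPD_GRID, STSD_GRID, StudyTable, _averaged_rate_values,
                                add_optimized_scenario, averaged_rate, detection_rate,
                                grid_for, optimize_additional_electrode,
                                physiological_threshold, segment_threshold_80,
                                subgroup_report, threshold_multiples)

COLUMNS = ["setup_id", "subject", "segment", "total_radius", "bz_radius",
           "transmural", "ischemic_fraction", "scenario", "feature", "value"]


def make_table(values, scenario="12-lead", feature="kpd", physio=None,
               segments=None, radii=None):
    """StudyTable with one ischemic row per value (plus optional physio rows)."""
    rows = []
    for i, v in enumerate(values):
        rows.append(["s%03d" % i, "A", segments[i] if segments else 1,
                     radii[i] if radii else 10.0, 2.8, False, 0.01,
                     scenario, feature, float(v)])
    if physio is not None:
        for subj, v in physio.items():
            rows.append(["physio", subj, 0, np.nan, np.nan, False, 0.0,
                         scenario, feature, float(v)])
    return StudyTable(df=pd.DataFrame(rows, columns=COLUMNS))


def test_detection_rate_counts_fractions():
    t = make_table([10, 20, 30, 40])
    assert detection_rate(t, "12-lead", "kpd", 25.0) == 0.5
    assert detection_rate(t, "12-lead", "kpd", 0.0) == 1.0
    assert detection_rate(t, "12-lead", "kpd", 40.0) == 0.25   # >= rule
    assert detection_rate(t, "12-lead", "kpd", 41.0) == 0.0
    with pytest.raises(ValueError):
        detection_rate(t, "12-lead", "kpd", -1.0)
    with pytest.raises(KeyError):
        detection_rate(t, "BSPM", "kpd", 10.0)


def test_averaged_rate_single_value_on_stsd_grid():
    """One setup at 132 uV clears exactly half of the 54-step STSD grid."""
    t = make_table([132.0], feature="stsd")
    assert averaged_rate(t, "12-lead", "stsd") == pytest.approx(27 / 54)


def test_averaged_rate_matches_bruteforce():
    rng = np.random.default_rng(3)
    for grid in (STSD_GRID, KPD_GRID):
        vals = rng.uniform(0, 300, 40)
        expected = np.mean([np.mean(vals >= thr) for thr in grid])
        t = make_table(vals)
        assert averaged_rate(t, "12-lead", "kpd", grid) == pytest.approx(expected)
        assert _averaged_rate_values(vals, grid) == pytest.approx(expected)


def test_averaged_rate_value_on_grid_point_counts_as_detected():
    vals = np.array([KPD_GRID[0]])
    assert _averaged_rate_values(vals, KPD_GRID) == pytest.approx(1 / KPD_GRID.size)


def test_grid_for_resolution():
    assert grid_for("stsd") is STSD_GRID
    assert grid_for("kpd") is KPD_GRID
    assert grid_for("k_elevation") is KPD_GRID
    np.testing.assert_array_equal(grid_for("kpd", [1.0, 2.0]), [1.0, 2.0])
    with pytest.raises(ValueError):
        grid_for("kpd", [])


def test_physiological_threshold_pooling():
    t = make_table([10.0], physio={"A": 3.0, "B": 7.0})
    assert physiological_threshold(t, "12-lead", "kpd") == 7.0
    per = physiological_threshold(t, "12-lead", "kpd", pooling="per_subject")
    assert per == {"A": 3.0, "B": 7.0}
    with pytest.raises(ValueError):
        physiological_threshold(t, "12-lead", "kpd", pooling="median")
    with pytest.raises(KeyError):
        physiological_threshold(make_table([1.0]), "12-lead", "kpd")
    assert threshold_multiples(10.0) == (10.0, 15.0)


def test_segment_threshold_80_examples():
    t = make_table([10, 20, 30, 40, 50], segments=[4] * 5)
    # rate >= 0.8 needs at least 4 of 5 detected: largest such threshold is 20
    assert segment_threshold_80(t, "12-lead", "kpd", 4) == 20.0
    t2 = make_table([7.0] * 4, segments=[9] * 4)
    assert segment_threshold_80(t2, "12-lead", "kpd", 9) == 7.0
    t3 = make_table([42.0], segments=[2])
    assert segment_threshold_80(t3, "12-lead", "kpd", 2) == 42.0
    with pytest.raises(ValueError):
        segment_threshold_80(t3, "12-lead", "kpd", 5)


def test_segment_threshold_80_matches_bruteforce():
    rng = np.random.default_rng(5)
    vals = rng.uniform(0, 200, 12)
    t = make_table(vals, segments=[7] * 12)
    got = segment_threshold_80(t, "12-lead", "kpd", 7)
    cands = [tau for tau in vals if np.mean(vals >= tau) >= 0.8]
    assert got == pytest.approx(max(cands))


def make_aug_table(values):
    """values: dict electrode -> list of per-setup kpd values (equal lengths)."""
    rows = []
    n = len(next(iter(values.values())))
    meta = []
    for i in range(n):
        sid = "s%03d" % i
        meta.append([sid, "A", 1, 10.0, 2.8, False, 0.01, "12-lead", "kpd", 1.0])
        for e, vals in values.items():
            rows.append({"setup_id": sid, "subject": "A", "electrode": e,
                         "stsd": float(vals[i]), "kpd": float(vals[i]),
                         "k_elevation": float(vals[i])})
    return StudyTable(df=pd.DataFrame(meta, columns=COLUMNS),
                      aug=pd.DataFrame(rows))


def test_optimizer_picks_highest_grid_averaged_electrode():
    values = {0: [30.0, 30.0], 1: [150.0, 150.0], 2: [60.0, 10.0]}
    t = make_aug_table(values)
    assert optimize_additional_electrode(t) == 1
    scores = {e: _averaged_rate_values(np.array(v), KPD_GRID)
              for e, v in values.items()}
    assert max(scores, key=scores.get) == 1


def test_optimizer_tie_breaks_to_lowest_index():
    t = make_aug_table({2: [80.0, 80.0], 5: [80.0, 80.0], 7: [20.0, 20.0]})
    assert optimize_additional_electrode(t) == 2


def test_optimizer_scopes_and_errors():
    t = make_aug_table({0: [10.0], 1: [90.0]})
    assert optimize_additional_electrode(t, subject_scope="individual", subject="A") == 1
    with pytest.raises(ValueError):
        optimize_additional_electrode(t, subject_scope="individual")
    with pytest.raises(ValueError):
        optimize_additional_electrode(t, subject_scope="individual", subject="Z")
    with pytest.raises(ValueError):
        optimize_additional_electrode(t, subject_scope="regional")
    with pytest.raises(ValueError):
        optimize_additional_electrode(StudyTable(df=t.df))


def test_add_optimized_scenario_materializes_rows():
    t = make_aug_table({0: [30.0, 50.0], 1: [70.0, 90.0]})
    out = add_optimized_scenario(t, 1)
    vals = out.values("12+1", "kpd")
    assert sorted(vals) == [70.0, 90.0]
    assert list(out.df.columns) == list(t.df.columns)
    # original rows untouched, 2 setups x 3 features added
    assert len(out.df) == len(t.df) + 6
    with pytest.raises(ValueError):
        add_optimized_scenario(t, 9)


def test_subgroup_report_weighted_mean_identity():
    rng = np.random.default_rng(9)
    vals = rng.uniform(0, 200, 30)
    radii = list(rng.choice([5.0, 15.0, 25.0], 30))
    t = make_table(vals, radii=radii)
    rep = subgroup_report(t, by="radius")
    total = sum(rep.rates[k] * rep.sizes[k] for k in rep.rates)
    assert total / sum(rep.sizes.values()) == pytest.approx(rep.overall)
    assert rep.overall == pytest.approx(_averaged_rate_values(vals, KPD_GRID))


def test_subgroup_report_by_lead():
    per_lead = pd.DataFrame({
        "setup_id": ["s0", "s0"], "subject": ["A", "A"], "segment": [1, 1],
        "lead": ["I", "V2"], "kpd": [5.0, 120.0], "k_elevation": [0.0, 120.0]})
    t = StudyTable(df=make_table([1.0]).df, per_lead=per_lead)
    rep = subgroup_report(t, by="lead")
    assert rep.rates["V2"] > rep.rates["I"]
    assert rep.sizes == {"I": 1, "V2": 1}
    with pytest.raises(ValueError):
        subgroup_report(make_table([1.0]), by="lead")


def test_fast_study_table_shape_and_positivity(fast_study):
    """17 segments x 2 radii on one subject: 34 setups, physio references."""
    isch = fast_study.ischemic()
    assert isch.setup_id.nunique() == 34
    assert set(isch.scenario) == {"3-channel", "12-lead", "12+R", "BSPM"}
    assert (isch.value >= 0).all()
    physio = fast_study.df[fast_study.df.setup_id == "physio"]
    assert len(physio) == 4 * 3  # scenarios x features
    assert not fast_study.aug.empty and not fast_study.per_lead.empty
    assert fast_study.per_lead.lead.nunique() == 12


def test_fast_study_setupwise_lead_superset_order(fast_study):
    """Per setup: BSPM >= 12+R >= 12-lead >= 3-channel feature values."""
    isch = fast_study.ischemic()
    for f in ("stsd", "kpd", "k_elevation"):
        p = isch[isch.feature == f].pivot(index="setup_id", columns="scenario",
                                          values="value")
        assert (p["BSPM"] >= p["12+R"] - 1e-9).all()
        assert (p["12+R"] >= p["12-lead"] - 1e-9).all()
        assert (p["12-lead"] >= p["3-channel"] - 1e-9).all()
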