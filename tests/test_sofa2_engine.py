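"""Scoring-engine unit and property tests.

All numeric thresholds referenced here come from the explicit fixture rule
set in conftest (stated band-by-band), not from the shipped default file.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sofa2audit import sofa2_engine as eng
from sofa2audit.sofa2_engine import Band, Sofa2Config

from conftest import (
    make_events,
    make_fixture_config,
    make_infusions,
    make_stays,
    make_supports,
)


def score_one(config, events=(), infusions=(), supports=(), los_hours=48.0):
    stays = make_stays(1, los_hours=los_hours)
    return eng.score_cohort(stays, make_events(list(events)),
                            make_infusions(list(infusions)),
                            make_supports(list(supports)), config).iloc[0]


# --------------------------------------------------------------------------
# Worst-value extraction
# --------------------------------------------------------------------------

class TestWorstValues:
    def test_worst_is_min_for_gcs(self, fixture_config):
        ev = make_events([(1, 1, "GCS_total", 15), (1, 5, "GCS_total", 9),
                          (1, 9, "GCS_total", 13)])
        w = eng.extract_worst_values(make_stays(1), ev, fixture_config)
        assert w.loc[1, "gcs_total_min"] == 9

    def test_sf_uses_only_readings_below_cap(self, fixture_config):
        # SpO2 99 >= 98 is excluded from the fallback; 96/0.5 = 192
        ev = make_events([(1, 1, "FiO2", 0.5), (1, 2, "SpO2", 99), (1, 3, "SpO2", 96)])
        w = eng.extract_worst_values(make_stays(1), ev, fixture_config)
        assert w.loc[1, "sf_min"] == pytest.approx(192.0)

    def test_events_past_window_are_missing(self, fixture_config):
        ev = make_events([(1, 25, "bilirubin", 9.9)])
        w = eng.extract_worst_values(make_stays(1), ev, fixture_config)
        assert np.isnan(w.loc[1, "bilirubin_max"])

    def test_fio2_zero_pairing_skipped_with_note(self, fixture_config):
        ev = make_events([(1, 1, "FiO2", 0.0), (1, 2, "PaO2", 80)])
        w = eng.extract_worst_values(make_stays(1), ev, fixture_config)
        assert np.isnan(w.loc[1, "pf_min"])
        assert any("FiO2 = 0" in n for n in w.attrs["notes"])

    def test_fio2_carried_forward_within_staleness_cap(self, fixture_config):
        # FiO2 at h1 pairs with PaO2 at h3 (2 h gap) but not at h7 (6 h gap)
        ev = make_events([(1, 1, "FiO2", 0.4), (1, 3, "PaO2", 60), (1, 7, "PaO2", 40)])
        w = eng.extract_worst_values(make_stays(1), ev, fixture_config)
        assert w.loc[1, "pf_min"] == pytest.approx(150.0)

    def test_urine_output_totalled(self, fixture_config):
        ev = make_events([(1, h, "urine_output", 120) for h in (2, 8, 14, 20)])
        w = eng.extract_worst_values(make_stays(1), ev, fixture_config)
        assert w.loc[1, "urine_total"] == pytest.approx(480.0)


# --------------------------------------------------------------------------
# Organ subscores
# --------------------------------------------------------------------------

class TestRespiratory:
    def test_no_data_no_support_scores_zero_and_missing(self, fixture_config):
        r = score_one(fixture_config)
        assert r["respiratory"] == 0 and r["respiratory_missing"]

    def test_pf_governs_when_both_streams_present(self, fixture_config):
        # P/F 320 -> band 1 even though S/F 150 would score worse
        ev = [(1, 1, "FiO2", 0.5), (1, 2, "PaO2", 160), (1, 3, "SpO2", 75)]
        r = score_one(fixture_config, events=ev)
        assert r["respiratory"] == 1

    def test_top_band_requires_support(self, fixture_config):
        ev = [(1, 1, "FiO2", 1.0), (1, 2, "PaO2", 80)]  # P/F 80: top band
        no_sup = score_one(fixture_config, events=ev)
        with_sup = score_one(fixture_config, events=ev, supports=[(1, "IMV", 0, 10)])
        assert no_sup["respiratory"] == 2          # capped without support
        assert with_sup["respiratory"] == 4

    def test_sf_fallback_with_support(self, fixture_config):
        ev = [(1, 1, "FiO2", 0.8), (1, 2, "SpO2", 88)]  # S/F 110 -> band 4
        r = score_one(fixture_config, events=ev, supports=[(1, "HFNC", 0, 8)])
        assert r["respiratory"] == 4
        assert "S/F fallback" in r["respiratory_rule"]


class TestCardiovascular:
    def test_sub_60_minute_infusion_does_not_qualify(self, fixture_config):
        ev = [(1, 1, "MAP", 80)]
        inf = [(1, "norepinephrine", 1.0, 1.983, "vasopressor")]  # 59 min
        r = score_one(fixture_config, events=ev, infusions=inf)
        assert r["cardiovascular"] == 0  # MAP 80 band

    def test_qualifying_single_agent_tier(self, fixture_config):
        ev = [(1, 1, "MAP", 80)]
        inf = [(1, "norepinephrine", 1, 3, "vasopressor")]
        r = score_one(fixture_config, events=ev, infusions=inf)
        assert r["cardiovascular"] == 2

    def test_three_agents_reach_maximum(self, fixture_config):
        inf = [(1, d, 1, 5, "vasopressor")
               for d in ("norepinephrine", "vasopressin", "phenylephrine")]
        r = score_one(fixture_config, infusions=inf)
        assert r["cardiovascular"] == 4

    def test_split_episodes_merge_within_gap(self, fixture_config):
        # two 35-min segments 10 min apart merge into one 80-min episode
        inf = [(1, "norepinephrine", 1.0, 1.583, "vasopressor"),
               (1, "norepinephrine", 1.75, 2.333, "vasopressor")]
        r = score_one(fixture_config, infusions=inf)
        assert r["cardiovascular"] == 2

    def test_mcs_overrides_map(self, fixture_config):
        ev = [(1, 1, "MAP", 90)]
        r = score_one(fixture_config, events=ev, supports=[(1, "MCS", 0, 20)])
        assert r["cardiovascular"] == 4

    def test_map_bands(self, fixture_config):
        for mapv, expect in [(80, 0), (65, 1), (55, 2), (45, 3), (35, 4), (70, 0), (60, 1)]:
            r = score_one(fixture_config, events=[(1, 1, "MAP", mapv)])
            assert r["cardiovascular"] == expect, mapv

    def test_missing_map_no_treatment_is_missing(self, fixture_config):
        r = score_one(fixture_config)
        assert r["cardiovascular"] == 0 and r["cardiovascular_missing"]


class TestNeurologic:
    def test_delirium_treatment_floors_score(self, fixture_config):
        ev = [(1, 1, "GCS_total", 15)]
        inf = [(1, "haloperidol", 2, 3, "delirium_agent")]
        r = score_one(fixture_config, events=ev, infusions=inf)
        assert r["neurological"] == 1

    def test_motor_fallback(self, fixture_config):
        r = score_one(fixture_config, events=[(1, 1, "GCS_motor", 4)])
        assert r["neurological"] == 2
        assert "motor fallback" in r["neurological_rule"]

    def test_gcs_total_preferred_over_motor(self, fixture_config):
        ev = [(1, 1, "GCS_total", 15), (1, 2, "GCS_motor", 1)]
        r = score_one(fixture_config, events=ev)
        assert r["neurological"] == 0

    def test_floor_applies_with_no_gcs_at_all(self, fixture_config):
        inf = [(1, "dexmedetomidine", 1, 6, "delirium_agent")]
        r = score_one(fixture_config, infusions=inf)
        assert r["neurological"] == 1
        assert not r["neurological_missing"]

    def test_both_absent_scores_zero(self, fixture_config):
        r = score_one(fixture_config)
        assert r["neurological"] == 0 and r["neurological_missing"]


class TestRenal:
    def test_rrt_forces_maximum(self, fixture_config):
        ev = [(1, 1, "creatinine", 0.8)]
        r = score_one(fixture_config, events=ev, supports=[(1, "RRT", 2, 8)])
        assert r["renal"] == 4

    def test_worse_of_creatinine_and_urine(self, fixture_config):
        # creatinine 2.5 -> band 2; urine 300 mL -> band 3; worse-of = 3
        ev = [(1, 1, "creatinine", 2.5), (1, 2, "urine_output", 300)]
        r = score_one(fixture_config, events=ev)
        assert r["renal"] == 3

    def test_both_absent_scores_zero(self, fixture_config):
        r = score_one(fixture_config)
        assert r["renal"] == 0 and r["renal_missing"]


class TestHepaticCoagulation:
    def test_missing_bilirubin_scores_zero(self, fixture_config):
        r = score_one(fixture_config)
        assert r["hepatic"] == 0 and r["hepatic_missing"]

    def test_platelet_band_edges_are_explicit(self, fixture_config):
        # fixture bands close on the left: 150 -> 0, 149.9 -> 1, 20 -> 3, 19.9 -> 4
        for v, expect in [(150, 0), (149.9, 1), (20, 3), (19.9, 4)]:
            r = score_one(fixture_config, events=[(1, 1, "platelets", v)])
            assert r["coagulation"] == expect, v

    def test_platelets_below_lowest_edge_scores_four(self, fixture_config):
        r = score_one(fixture_config, events=[(1, 1, "platelets", 3)])
        assert r["coagulation"] == 4

    def test_bilirubin_bands(self, fixture_config):
        for v, expect in [(0.5, 0), (1.5, 1), (4.0, 2), (8.0, 3), (20.0, 4)]:
            r = score_one(fixture_config, events=[(1, 1, "bilirubin", v)])
            assert r["hepatic"] == expect, v


# --------------------------------------------------------------------------
# Totals
# --------------------------------------------------------------------------

class TestTotal:
    def _components(self, scores):
        idx = pd.Index([1], name="stay_id")
        return {name: pd.DataFrame({"score": [s], "missing": [False], "rule": ["r"]},
                                   index=idx)
                for name, s in zip(eng.COMPONENTS, scores)}

    def test_all_fours_total_24(self):
        out = eng.total_score(self._components([4] * 6))
        assert out["total"].iloc[0] == 24

    def test_all_zero_total_0(self):
        assert eng.total_score(self._components([0] * 6))["total"].iloc[0] == 0

    def test_mixed_sum(self):
        assert eng.total_score(self._components([1, 2, 0, 3, 0, 4]))["total"].iloc[0] == 10

    def test_out_of_range_subscore_rejected(self):
        with pytest.raises(eng.ScoreConsistencyError):
            eng.total_score(self._components([5, 0, 0, 0, 0, 0]))

    def test_worst_case_stay_scores_24(self, fixture_config):
        ev = [(1, 1, "GCS_total", 3), (1, 1, "MAP", 30), (1, 1, "FiO2", 1.0),
              (1, 2, "PaO2", 50), (1, 1, "bilirubin", 20), (1, 1, "creatinine", 9),
              (1, 1, "urine_output", 50), (1, 1, "platelets", 5)]
        sup = [(1, "IMV", 0, 20), (1, "MCS", 0, 20), (1, "RRT", 0, 20)]
        r = score_one(fixture_config, events=ev, supports=sup)
        assert r["total"] == 24


# --------------------------------------------------------------------------
# Invariants
# --------------------------------------------------------------------------

ANALYTE_CASES = [
    ("MAP", "cardiovascular", 10, 130, -1),        # lower is worse
    ("GCS_total", "neurological", 3, 15, -1),
    ("bilirubin", "hepatic", 0.1, 40, +1),         # higher is worse
    ("creatinine", "renal", 0.2, 20, +1),
    ("platelets", "coagulation", 2, 400, -1),
]


@pytest.mark.parametrize("var,comp,lo,hi,_dir", ANALYTE_CASES)
@given(data=st.data())
@settings(max_examples=40, deadline=None, derandomize=True)
def test_monotone_in_worst_value(var, comp, lo, hi, _dir, data):
    """Making a worst value strictly worse never decreases the subscore."""
    config = make_fixture_config()
    a = data.draw(st.floats(lo, hi, allow_nan=False))
    b = data.draw(st.floats(lo, hi, allow_nan=False))
    worse, better = (min(a, b), max(a, b)) if _dir < 0 else (max(a, b), min(a, b))
    r_better = score_one(config, events=[(1, 1, var, better)])
    r_worse = score_one(config, events=[(1, 1, var, worse)])
    assert r_worse[comp] >= r_better[comp]


@given(seed=st.integers(0, 10_000))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_removing_a_stream_never_increases_scores(seed):
    """Missing-as-normal: dropping a component's entire event stream can
    only lower (or keep) every subscore."""
    from sofa2audit.synthetic_cohort import GeneratorConfig, generate_cohort
    config = make_fixture_config()
    cohort = generate_cohort(GeneratorConfig(n_stays=5, seed=seed))
    base = eng.score_cohort(cohort.stays, cohort.events, cohort.infusions,
                            cohort.supports, config)
    for comp, variables in {
        "hepatic": ("bilirubin",), "coagulation": ("platelets",),
        "renal": ("creatinine", "urine_output"),
        "respiratory": ("PaO2", "FiO2", "SpO2"),
    }.items():
        ev = cohort.events.loc[~cohort.events["variable"].isin(variables)]
        red = eng.score_cohort(cohort.stays, ev, cohort.infusions,
                               cohort.supports, config)
        assert (red[comp] <= base[comp]).all()


def test_window_locality(fixture_config):
    """Events outside [intime, intime + window] never affect any score."""
    inside = [(1, 1, "MAP", 45), (1, 2, "platelets", 80)]
    outside = [(1, -2, "MAP", 20), (1, 30, "platelets", 5), (1, 25, "bilirubin", 30)]
    r1 = score_one(fixture_config, events=inside)
    r2 = score_one(fixture_config, events=inside + outside)
    for comp in eng.COMPONENTS:
        assert r1[comp] == r2[comp]


def test_every_nonzero_subscore_names_its_rule(fixture_config):
    from sofa2audit.synthetic_cohort import GeneratorConfig, generate_cohort
    cohort = generate_cohort(GeneratorConfig(n_stays=60, seed=9))
    res = eng.score_cohort(cohort.stays, cohort.events, cohort.infusions,
                           cohort.supports, fixture_config)
    for comp in eng.COMPONENTS:
        nz = res.loc[res[comp] > 0, f"{comp}_rule"]
        assert nz.notna().all() and (nz.astype(str).str.len() > 0).all()


def test_score_ranges_always_hold(fixture_config):
    from sofa2audit.synthetic_cohort import GeneratorConfig, generate_cohort
    cohort = generate_cohort(GeneratorConfig(n_stays=300, seed=4))
    res = eng.score_cohort(cohort.stays, cohort.events, cohort.infusions,
                           cohort.supports, fixture_config)
    for comp in eng.COMPONENTS:
        assert res[comp].between(0, 4).all()
    assert res["total"].between(0, 24).all()
    assert (res["total"] == res[list(eng.COMPONENTS)].sum(axis=1)).all()


# --------------------------------------------------------------------------
# Configuration round-trip
# --------------------------------------------------------------------------

def test_config_yaml_round_trip(tmp_path, fixture_config):
    path = tmp_path / "cfg.yaml"
    fixture_config.to_yaml(path)
    back = Sofa2Config.from_yaml(path)
    assert back == fixture_config


def test_config_rejects_out_of_range_subscore():
    with pytest.raises(eng.Sofa2ConfigError):
        make_fixture_config(map_bands=(Band(5, lower=0),))


def test_default_config_loads_and_is_complete():
    cfg = Sofa2Config.default()
    assert cfg.window_hours == 24
    assert cfg.sf_fallback_spo2_max == 98
    assert {"milrinone", "vasopressin", "phenylephrine"} <= set(cfg.vasopressor_drugs)
    assert {"dexmedetomidine", "haloperidol", "quetiapine", "ziprasidone",
            "olanzapine"} <= set(cfg.delirium_agents)
    for bands in (cfg.respiratory_pf_bands, cfg.map_bands, cfg.gcs_bands,
                  cfg.bilirubin_bands, cfg.creatinine_bands, cfg.platelet_bands):
        assert max(b.score for b in bands) == 4
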