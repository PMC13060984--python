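"""Shared fixtures: a fully explicit scoring rule set and tiny cohort
builders, so every test states the bands it relies on."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sofa2audit.sofa2_engine import Band, Sofa2Config

T0 = pd.Timestamp("2021-06-01 08:00:00")


def make_fixture_config(**overrides) -> Sofa2Config:
    """A compact rule set with bands stated explicitly (not the shipped
    default): thresholds are round numbers chosen for testability."""
    kw = dict(
        window_hours=24,
        sf_fallback_spo2_max=98,
        pf_staleness_hours=4,
        vasopressor_min_minutes=60,
        infusion_merge_gap_minutes=15,
        vasopressor_drugs=("norepinephrine", "vasopressin", "phenylephrine", "milrinone"),
        delirium_agents=("haloperidol", "dexmedetomidine", "quetiapine"),
        delirium_floor=1,
        rrt_max_score=4,
        mcs_max_score=4,
        missing_component_score=0,
        advanced_resp_modalities=("IMV", "NIV", "CPAP", "BiPAP", "HFNC", "ECMO"),
        respiratory_unsupported_cap=2,
        respiratory_pf_bands=(
            Band(0, lower=400), Band(1, 300, 400), Band(2, 200, 300),
            Band(3, 100, 200, requires_support=True),
            Band(4, upper=100, requires_support=True)),
        respiratory_sf_bands=(
            Band(0, lower=370), Band(1, 300, 370), Band(2, 200, 300),
            Band(3, 120, 200, requires_support=True),
            Band(4, upper=120, requires_support=True)),
        map_bands=(Band(0, lower=70), Band(1, 60, 70), Band(2, 50, 60),
                   Band(3, 40, 50), Band(4, upper=40)),
        vasopressor_tiers={1: 2, 2: 3, 3: 4},
        gcs_bands=(Band(0, lower=15), Band(1, 13, 15), Band(2, 10, 13),
                   Band(3, 6, 10), Band(4, upper=6)),
        gcs_motor_bands=(Band(0, lower=6), Band(1, 5, 6), Band(2, 4, 5),
                         Band(3, 2, 4), Band(4, upper=2)),
        bilirubin_bands=(Band(0, upper=1.2), Band(1, 1.2, 2.0), Band(2, 2.0, 6.0),
                         Band(3, 6.0, 12.0), Band(4, lower=12.0)),
        creatinine_bands=(Band(0, upper=1.2), Band(1, 1.2, 2.0), Band(2, 2.0, 3.5),
                          Band(3, 3.5, 5.0), Band(4, lower=5.0)),
        urine_bands=(Band(0, lower=500), Band(3, 200, 500), Band(4, upper=200)),
        platelet_bands=(Band(0, lower=150), Band(1, 100, 150), Band(2, 50, 100),
                        Band(3, 20, 50), Band(4, upper=20)),
    )
    kw.update(overrides)
    return Sofa2Config(**kw)


@pytest.fixture(scope="session")
def fixture_config() -> Sofa2Config:
    return make_fixture_config()


def make_stays(n: int = 1, los_hours: float = 48.0, **overrides) -> pd.DataFrame:
    """n simple adult stays starting at T0."""
    df = pd.DataFrame({
        "stay_id": np.arange(1, n + 1),
        "subject_id": np.arange(101, 101 + n),
        "hadm_id": np.arange(501, 501 + n),
        "admittime": T0 - pd.Timedelta(hours=6),
        "intime": T0,
        "outtime": T0 + pd.Timedelta(hours=los_hours),
        "age_years": 50.0,
        "sex": "Male",
        "race_ethnicity_raw": "WHITE",
        "language_raw": "ENGLISH",
        "insurance_raw": "PRIVATE",
        "death_time": pd.NaT,
    })
    for k, v in overrides.items():
        df[k] = v
    return df


def make_events(rows: list[tuple]) -> pd.DataFrame:
    """rows: (stay_id, hours_after_intime, variable, value)."""
    if not rows:
        return pd.DataFrame(columns=["stay_id", "time", "variable", "value"])
    return pd.DataFrame(
        [(sid, T0 + pd.Timedelta(hours=h), var, val) for sid, h, var, val in rows],
        columns=["stay_id", "time", "variable", "value"])


def make_infusions(rows: list[tuple]) -> pd.DataFrame:
    """rows: (stay_id, drug, start_h, end_h, category)."""
    cols = ["stay_id", "drug", "start", "end", "category"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(
        [(sid, drug, T0 + pd.Timedelta(hours=s), T0 + pd.Timedelta(hours=e), cat)
         for sid, drug, s, e, cat in rows], columns=cols)


def make_supports(rows: list[tuple]) -> pd.DataFrame:
    """rows: (stay_id, modality, start_h, end_h)."""
    cols = ["stay_id", "modality", "start", "end"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(
        [(sid, mod, T0 + pd.Timedelta(hours=s), T0 + pd.Timedelta(hours=e))
         for sid, mod, s, e in rows], columns=cols)
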