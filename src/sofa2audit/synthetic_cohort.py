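"""Seeded synthetic ICU cohorts with MIMIC-like relational shape.

The generator emulates the statistical structure of an event-level ICU
cohort -- per-stay demographics, severity-driven physiology, treatment and
organ-support episodes, and an ICU-mortality outcome -- so the whole
scoring and audit pipeline is testable without access to credentialed
data.  It is an artifact model, not a physiologic simulator:

* each stay draws a latent severity ``s ~ Beta`` (mean/concentration
  configurable); each organ's worst value interpolates between a healthy
  and a maximally deranged anchor at a jittered copy of ``s``, so every
  scoring band is exercised at all severity levels;
* treatments (vasopressors, advanced ventilation, RRT, MCS, delirium
  agents) are drawn with probabilities that rise with the relevant organ
  derangement;
* the *true* first-day score is obtained by running the scoring engine on
  the full emitted event streams, so generator and engine cannot drift
  apart;
* mortality is Bernoulli with
  ``logit(p) = alpha0 + beta * true_score + shift(subgroups) + eps``,
  ``eps ~ N(0, sd(subgroups))``: additive logit shifts model subgroup
  mis-calibration and score-independent noise models discrimination loss,
  while the recorded score stays integer-valued;
* deaths are placed inside the stay or within the 6 h post-discharge grace
  window (configurable split), and a small fraction of survivors die later
  than the grace window, so both branches of the outcome rule are
  exercised;
* measurement streams are then dropped per component at configurable
  missingness rates (treatments are never dropped).

Every table draws from its own random stream derived from the master seed,
so adding one table never perturbs the others, and a fixed config + seed
reproduces the cohort exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import sofa2_engine
from .sofa2_engine import Sofa2Config
from .subgroup_defs import DIMENSIONS

__all__ = ["GeneratorConfig", "SyntheticCohort", "generate_cohort", "write_cohort"]


class GeneratorConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


# Default demographic marginals follow the published MIMIC-IV validation
# cohort's baseline table.
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "sex": {"Male": 0.561, "Female": 0.439},
    "race_ethnicity": {"White": 0.661, "Black": 0.091, "Hispanic": 0.036,
                       "Asian": 0.030, "Other": 0.039, "Unknown": 0.143},
    "language": {"English": 0.905, "Non-English": 0.090, "Unknown": 0.005},
    "insurance": {"Medicare": 0.528, "Private": 0.282, "Medicaid": 0.143,
                  "Other": 0.047},
}

DEFAULT_AGE_BANDS: tuple[tuple[float, float], ...] = ((18, 45), (45, 65), (65, 75), (75, 95))
DEFAULT_AGE_WEIGHTS: tuple[float, ...] = (0.132, 0.324, 0.230, 0.314)

#: Per-component probability that the measurement stream is absent.
#: Hepatic (0.58) and cardiovascular (0.0) follow the published rates; the
#: other four are artifact choices.
DEFAULT_MISSINGNESS: dict[str, float] = {
    "neurological": 0.05,
    "cardiovascular": 0.0,
    "respiratory": 0.30,
    "hepatic": 0.58,
    "renal": 0.03,
    "coagulation": 0.08,
}

_STREAMS = ("demographics", "timing", "severity", "physiology",
            "interventions", "outcome", "missingness")

_COMPONENT_VARIABLES = {
    "neurological": ("GCS_total", "GCS_motor"),
    "cardiovascular": ("MAP",),
    "respiratory": ("PaO2", "FiO2", "SpO2"),
    "hepatic": ("bilirubin",),
    "renal": ("creatinine", "urine_output"),
    "coagulation": ("platelets",),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort generator (all defaults are the study
    conditions; see the package methods note)."""

    n_stays: int = 1000
    seed: int = 0
    demographic_marginals: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()})
    age_bands: tuple[tuple[float, float], ...] = DEFAULT_AGE_BANDS
    age_band_weights: tuple[float, ...] = DEFAULT_AGE_WEIGHTS
    severity_mean: float = 0.23          # latent severity Beta mean
    severity_concentration: float = 5.0  # Beta concentration (a+b)
    outcome_alpha0: float = -4.1         # mortality logit at score 0
    outcome_beta: float = 0.24           # logit increase per score point
    subgroup_intercept_shifts: Mapping[str, float] = field(default_factory=dict)
    subgroup_noise_sd: Mapping[str, float] = field(default_factory=dict)
    missingness_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    los_median_hours: float = 46.0       # lognormal LOS, median ~1.9 days
    los_sigma: float = 0.85
    los_min_hours: float = 2.0
    icu_death_fraction: float = 0.85     # deaths inside the stay vs grace window
    post_discharge_death_rate: float = 0.03  # survivors dying past the grace window
    sofa2_config: Sofa2Config | None = None

    def __post_init__(self) -> None:
        if self.n_stays < 1:
            raise GeneratorConfigError("n_stays: must be >= 1")
        for dim, probs in dict(self.demographic_marginals).items():
            if dim not in DIMENSIONS[1:]:
                raise GeneratorConfigError(f"demographic_marginals: unknown dimension {dim!r}")
            total = float(sum(probs.values()))
            if abs(total - 1.0) > 1e-9:
                raise GeneratorConfigError(
                    f"demographic_marginals[{dim!r}]: probabilities sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise GeneratorConfigError(f"demographic_marginals[{dim!r}]: negative probability")
        if len(self.age_bands) != len(self.age_band_weights):
            raise GeneratorConfigError("age_band_weights: length mismatch with age_bands")
        if abs(sum(self.age_band_weights) - 1.0) > 1e-9:
            raise GeneratorConfigError("age_band_weights: must sum to 1")
        for k, v in dict(self.subgroup_noise_sd).items():
            if v < 0:
                raise GeneratorConfigError(f"subgroup_noise_sd[{k!r}]: must be >= 0")
        for k, v in dict(self.missingness_rates).items():
            if k not in _COMPONENT_VARIABLES:
                raise GeneratorConfigError(f"missingness_rates: unknown component {k!r}")
            if not 0 <= v <= 1:
                raise GeneratorConfigError(f"missingness_rates[{k!r}]: must be in [0, 1]")
        for k in list(self.subgroup_intercept_shifts) + list(self.subgroup_noise_sd):
            if ":" not in k or k.split(":", 1)[0] not in DIMENSIONS:
                raise GeneratorConfigError(
                    f"subgroup key {k!r} must be 'dimension:category' with a known dimension")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SyntheticCohort:
    """Generated tables plus the per-stay ground truth (never read by the
    analysis pipeline)."""

    stays: pd.DataFrame
    events: pd.DataFrame
    infusions: pd.DataFrame
    supports: pd.DataFrame
    truth: pd.DataFrame


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

def _uniform_times(rng, intime: pd.Series, span_hours: np.ndarray, k: int) -> np.ndarray:
    """k random in-window offsets per stay, floored to whole seconds."""
    u = rng.random((k, len(intime)))
    secs = np.floor(u * span_hours * 3600.0).astype("int64")
    return intime.to_numpy()[None, :] + secs * np.timedelta64(1, "s")


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate a complete synthetic cohort under *config* (deterministic
    for a fixed config + seed)."""
    config = config or GeneratorConfig()
    n = config.n_stays
    ss = np.random.SeedSequence(config.seed)
    rngs = dict(zip(_STREAMS, map(np.random.default_rng, ss.spawn(len(_STREAMS)))))
    sofa_cfg = config.sofa2_config or Sofa2Config.default()

    # ---- demographics ----------------------------------------------------
    rng = rngs["demographics"]
    demo: dict[str, np.ndarray] = {}
    for dim in ("sex", "race_ethnicity", "language", "insurance"):
        probs = dict(config.demographic_marginals[dim])
        demo[dim] = rng.choice(list(probs), p=list(probs.values()), size=n)
    band_idx = rng.choice(len(config.age_bands), p=list(config.age_band_weights), size=n)
    lo = np.array([b[0] for b in config.age_bands])[band_idx]
    hi = np.array([b[1] for b in config.age_bands])[band_idx]
    age = np.round(lo + rng.random(n) * (hi - lo), 1)

    # ---- timing ----------------------------------------------------------
    rng = rngs["timing"]
    base = pd.Timestamp("2019-01-01")
    intime = base + pd.to_timedelta(
        np.floor(rng.random(n) * 730 * 24 * 3600).astype("int64"), unit="s")
    los_h = np.maximum(config.los_min_hours,
                       config.los_median_hours * np.exp(rng.normal(0, config.los_sigma, n)))
    outtime = intime + pd.to_timedelta(np.floor(los_h * 3600).astype("int64"), unit="s")
    admittime = intime - pd.to_timedelta(
        np.floor(rng.random(n) * 48 * 3600).astype("int64"), unit="s")
    window_h = np.minimum(sofa_cfg.window_hours, los_h) * 0.999  # events stay inside the stay

    stay_id = np.arange(3_000_000, 3_000_000 + n)
    stays = pd.DataFrame({
        "stay_id": stay_id,
        "subject_id": np.arange(1, n + 1),
        "hadm_id": np.arange(1_000_000, 1_000_000 + n),
        "admittime": admittime,
        "intime": intime,
        "outtime": outtime,
        "age_years": age,
        "sex": demo["sex"],
        "race_ethnicity_raw": demo["race_ethnicity"],
        "language_raw": demo["language"],
        "insurance_raw": demo["insurance"],
    })

    # ---- latent severity and organ weights -------------------------------
    rng = rngs["severity"]
    m, k = config.severity_mean, config.severity_concentration
    sev = rng.beta(m * k, (1 - m) * k, size=n)
    organ_w = {organ: np.clip(sev + rng.normal(0, 0.10, n), 0, 1)
               for organ in sofa2_engine.COMPONENTS}

    # ---- physiology ------------------------------------------------------
    rng = rngs["physiology"]
    ev_stay: list[np.ndarray] = []
    ev_time: list[np.ndarray] = []
    ev_var: list[np.ndarray] = []
    ev_val: list[np.ndarray] = []

    def emit(sid, times, var, values):
        ev_stay.append(np.asarray(sid))
        ev_time.append(np.asarray(times))
        ev_var.append(np.full(len(values), var, dtype=object))
        ev_val.append(np.asarray(values, dtype=float))

    # cardiovascular: worst MAP + two better readings
    w = organ_w["cardiovascular"]
    map_worst = np.clip(88 - 58 * w + rng.normal(0, 3, n), 16, 130)
    t = _uniform_times(rng, stays["intime"], window_h, 3)
    emit(stay_id, t[0], "MAP", np.round(map_worst, 1))
    for j in (1, 2):
        better = map_worst + (90 - map_worst) * rng.uniform(0.15, 0.8, n)
        emit(stay_id, t[j], "MAP", np.round(better, 1))

    # neurological: GCS total (or motor-only fallback for ~5% of stays)
    w = organ_w["neurological"]
    gcs_worst = np.clip(np.round(15 - 12 * w + rng.normal(0, 1.0, n)), 3, 15)
    motor_worst = np.clip(np.round(6 - 5 * w + rng.normal(0, 0.5, n)), 1, 6)
    motor_only = rng.random(n) < 0.05
    t = _uniform_times(rng, stays["intime"], window_h, 2)
    emit(stay_id[~motor_only], t[0][~motor_only], "GCS_total", gcs_worst[~motor_only])
    better = np.minimum(15, gcs_worst + rng.integers(0, 4, n))
    emit(stay_id[~motor_only], t[1][~motor_only], "GCS_total", better[~motor_only])
    emit(stay_id[motor_only], t[0][motor_only], "GCS_motor", motor_worst[motor_only])

    # respiratory: PaO2/FiO2 pairs, or SpO2-only fallback for ~15% of stays
    w = organ_w["respiratory"]
    pf_worst = np.clip(430 - 370 * w + rng.normal(0, 15, n), 45, 520)
    fio2 = np.round(np.clip(0.25 + 0.65 * w + rng.normal(0, 0.05, n), 0.21, 1.0), 2)
    sf_only = rng.random(n) < 0.15
    t = _uniform_times(rng, stays["intime"], window_h, 2)
    pao2 = np.round(np.clip(pf_worst * fio2, 30, 500), 1)
    emit(stay_id, t[0], "FiO2", fio2)
    emit(stay_id[~sf_only], t[0][~sf_only], "PaO2", pao2[~sf_only])
    spo2 = np.round(np.clip(pf_worst * 0.92 * fio2, 55, 97.5), 1)
    emit(stay_id[sf_only], t[0][sf_only], "SpO2", spo2[sf_only])
    # occasional saturated reading exercises the S/F 98% cap
    saturated = rng.random(n) < 0.25
    emit(stay_id[saturated], t[1][saturated], "SpO2",
         np.round(rng.uniform(98, 100, int(saturated.sum())), 1))

    # hepatic / coagulation / renal labs
    bili = np.round(np.clip(0.5 * np.exp(3.5 * organ_w["hepatic"])
                            * np.exp(rng.normal(0, 0.25, n)), 0.1, 60), 2)
    t = _uniform_times(rng, stays["intime"], window_h, 1)
    emit(stay_id, t[0], "bilirubin", bili)

    plt_worst = np.round(np.clip(260 - 250 * organ_w["coagulation"]
                                 + rng.normal(0, 20, n), 5, 900), 0)
    t = _uniform_times(rng, stays["intime"], window_h, 1)
    emit(stay_id, t[0], "platelets", plt_worst)

    w = organ_w["renal"]
    creat = np.round(np.clip(0.7 * np.exp(2.2 * w) * np.exp(rng.normal(0, 0.15, n)),
                             0.2, 30), 2)
    t = _uniform_times(rng, stays["intime"], window_h, 2)
    emit(stay_id, t[0], "creatinine", creat)
    emit(stay_id, t[1], "creatinine", np.round(np.maximum(0.2, creat * rng.uniform(0.7, 1.0, n)), 2))
    urine_total = np.clip(2400 - 2300 * w + rng.normal(0, 150, n), 30, 5000)
    t = _uniform_times(rng, stays["intime"], window_h, 4)
    for j in range(4):
        emit(stay_id, t[j], "urine_output", np.round(urine_total / 4, 0))

    events = pd.DataFrame({
        "stay_id": np.concatenate(ev_stay),
        "time": np.concatenate(ev_time),
        "variable": np.concatenate(ev_var),
        "value": np.concatenate(ev_val),
    }).sort_values(["stay_id", "time", "variable"], kind="mergesort").reset_index(drop=True)

    # ---- interventions ---------------------------------------------------
    rng = rngs["interventions"]
    inf_rows: list[pd.DataFrame] = []
    sup_rows: list[pd.DataFrame] = []

    def episodes(mask, start_frac, dur_hours, col_value, table, category=None):
        """Emit one interval per selected stay, inside [intime, outtime]."""
        if not mask.any():
            return
        sid = stay_id[mask]
        t0 = stays.loc[mask, "intime"].to_numpy() + (
            np.floor(start_frac[mask] * window_h[mask] * 3600).astype("int64")
            * np.timedelta64(1, "s"))
        t1 = t0 + (np.floor(dur_hours[mask] * 3600).astype("int64")
                   * np.timedelta64(1, "s"))
        t1 = np.minimum(t1, stays.loc[mask, "outtime"].to_numpy())
        ok = t1 > t0
        frame = pd.DataFrame({"stay_id": sid[ok], "start": t0[ok], "end": t1[ok]})
        value = col_value if np.isscalar(col_value) else np.asarray(col_value)[mask][ok]
        if table is inf_rows:
            frame["drug"] = value
            frame["category"] = category
            table.append(frame[["stay_id", "drug", "start", "end", "category"]])
        else:
            frame["modality"] = value
            table.append(frame[["stay_id", "modality", "start", "end"]])

    # advanced ventilatory support, driven by respiratory derangement
    p_support = np.clip((220 - pf_worst) / 180, 0, 1) * 0.9
    on_support = rng.random(n) < p_support
    modality = rng.choice(["IMV", "NIV", "HFNC", "CPAP", "BiPAP", "ECMO"],
                          p=[0.50, 0.20, 0.18, 0.06, 0.05, 0.01], size=n)
    episodes(on_support, rng.uniform(0, 0.3, n), rng.uniform(6, 20, n), modality, sup_rows)

    # vasopressors, driven by hypotension; a few sub-60-minute infusions
    # exercise the qualification rule
    p_vaso = np.clip((75 - map_worst) / 30, 0, 1) * 0.85
    on_vaso = rng.random(n) < p_vaso
    n_agents = 1 + rng.binomial(2, np.clip((65 - map_worst) / 40, 0, 1))
    short_only = rng.random(n) < 0.08
    agent_pool = [d for d in sofa_cfg.vasopressor_drugs]
    for a_i in range(3):
        sel = on_vaso & (n_agents > a_i)
        drug = np.asarray(agent_pool, object)[
            (band_idx + a_i + np.arange(n)) % len(agent_pool)]  # deterministic spread
        dur = np.where(short_only & (a_i == 0), 45 / 60.0, rng.uniform(2, 18, n))
        episodes(sel, rng.uniform(0, 0.4, n), dur, drug, inf_rows, "vasopressor")

    # delirium treatment, mechanical circulatory support, RRT
    on_deli = rng.random(n) < 0.08
    agent = rng.choice(list(sofa_cfg.delirium_agents), size=n)
    episodes(on_deli, rng.uniform(0, 0.6, n), rng.uniform(1, 10, n), agent,
             inf_rows, "delirium_agent")
    on_mcs = (organ_w["cardiovascular"] > 0.85) & (rng.random(n) < 0.25)
    episodes(on_mcs, rng.uniform(0, 0.3, n), rng.uniform(10, 30, n), "MCS", sup_rows)
    p_rrt = 0.6 * np.clip((organ_w["renal"] - 0.75) / 0.25, 0, 1)
    on_rrt = rng.random(n) < p_rrt
    episodes(on_rrt, rng.uniform(0, 0.4, n), rng.uniform(4, 12, n), "RRT", sup_rows)

    inf_cols = ["stay_id", "drug", "start", "end", "category"]
    sup_cols = ["stay_id", "modality", "start", "end"]
    infusions = (pd.concat(inf_rows, ignore_index=True)[inf_cols]
                 .sort_values(["stay_id", "drug", "start"], kind="mergesort")
                 .reset_index(drop=True)
                 if inf_rows else pd.DataFrame(columns=inf_cols))
    supports = (pd.concat(sup_rows, ignore_index=True)[sup_cols]
                .sort_values(["stay_id", "modality", "start"], kind="mergesort")
                .reset_index(drop=True)
                if sup_rows else pd.DataFrame(columns=sup_cols))

    # ---- ground-truth score (engine on the full streams) ------------------
    scored = sofa2_engine.score_cohort(stays, events, infusions, supports, sofa_cfg)
    true_score = scored["total"].reindex(stay_id).to_numpy()

    # ---- outcome ----------------------------------------------------------
    rng = rngs["outcome"]
    shift = np.zeros(n)
    noise_var = np.zeros(n)
    cats = {"age_group": _age_band_labels(config)[band_idx],
            "sex": demo["sex"], "race_ethnicity": demo["race_ethnicity"],
            "language": demo["language"], "insurance": demo["insurance"]}
    for key, val in dict(config.subgroup_intercept_shifts).items():
        dim, cat = key.split(":", 1)
        shift += np.where(cats[dim] == cat, float(val), 0.0)
    for key, val in dict(config.subgroup_noise_sd).items():
        dim, cat = key.split(":", 1)
        noise_var += np.where(cats[dim] == cat, float(val) ** 2, 0.0)
    eps = rng.normal(0, 1, n) * np.sqrt(noise_var)
    lin = config.outcome_alpha0 + config.outcome_beta * true_score + shift
    true_p = 1.0 / (1.0 + np.exp(-lin))
    died = rng.random(n) < 1.0 / (1.0 + np.exp(-(lin + eps)))

    death_time = np.full(n, np.datetime64("NaT"), dtype="datetime64[s]")
    in_icu = rng.random(n) < config.icu_death_fraction
    frac = rng.uniform(0.3, 1.0, n)
    t_in = intime.to_numpy().astype("datetime64[s]") + \
        (np.floor(frac * los_h * 3600).astype("int64") * np.timedelta64(1, "s"))
    t_post = outtime.to_numpy().astype("datetime64[s]") + \
        (np.floor(rng.uniform(0.25, 5.75, n) * 3600).astype("int64") * np.timedelta64(1, "s"))
    death_time[died & in_icu] = t_in[died & in_icu]
    death_time[died & ~in_icu] = t_post[died & ~in_icu]
    late = ~died & (rng.random(n) < config.post_discharge_death_rate)
    t_late = outtime.to_numpy().astype("datetime64[s]") + \
        (np.floor(rng.uniform(7, 720, n) * 3600).astype("int64") * np.timedelta64(1, "s"))
    death_time[late] = t_late[late]
    stays["death_time"] = pd.Series(death_time, index=stays.index).astype("datetime64[ns]")

    # ---- missingness -------------------------------------------------------
    rng = rngs["missingness"]
    drop_vars_per_stay: dict[int, set[str]] = {}
    for comp, rate in dict(config.missingness_rates).items():
        if rate <= 0:
            continue
        dropped = rng.random(n) < rate
        for sid in stay_id[dropped]:
            drop_vars_per_stay.setdefault(int(sid), set()).update(
                _COMPONENT_VARIABLES[comp])
    if drop_vars_per_stay:
        key = events["stay_id"].map(lambda s: drop_vars_per_stay.get(int(s)))
        drop_mask = [
            (vars_ is not None and var in vars_)
            for vars_, var in zip(key.tolist(), events["variable"].tolist())]
        events = events.loc[~np.asarray(drop_mask)].reset_index(drop=True)

    truth = pd.DataFrame({
        "stay_id": stay_id,
        "latent_severity": sev,
        "true_score": true_score.astype(int),
        "true_p": true_p,
    })
    return SyntheticCohort(stays=stays, events=events, infusions=infusions,
                           supports=supports, truth=truth)


def _age_band_labels(config: GeneratorConfig) -> np.ndarray:
    labels = []
    for i, (lo, hi) in enumerate(config.age_bands):
        if i == len(config.age_bands) - 1:
            labels.append(f"{int(lo)}+")
        else:
            labels.append(f"{int(lo)}-{int(hi) - 1}")
    return np.asarray(labels, dtype=object)


# --------------------------------------------------------------------------
# Flat-file output
# --------------------------------------------------------------------------

_TIME_COLS = {
    "stays.csv": ["admittime", "intime", "outtime", "death_time"],
    "events.csv": ["time"],
    "infusions.csv": ["start", "end"],
    "supports.csv": ["start", "end"],
}


def write_cohort(cohort: SyntheticCohort, directory,
                 include_truth: bool = True) -> list[Path]:
    """Write the flat-file layout the cohort builder reads (ISO-8601 times).

    ``truth.csv`` is a testing sidecar and is never read by the pipeline.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {"stays.csv": cohort.stays, "events.csv": cohort.events,
              "infusions.csv": cohort.infusions, "supports.csv": cohort.supports}
    for fname, df in tables.items():
        out = df.copy()
        for c in _TIME_COLS[fname]:
            if c in out.columns:
                out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        path = directory / fname
        out.to_csv(path, index=False)
        written.append(path)
    if include_truth:
        path = directory / "truth.csv"
        cohort.truth.to_csv(path, index=False)
        written.append(path)
    return written
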