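"""First-day SOFA-2 scoring from event-level ICU data.

The engine turns raw measurement events, infusion intervals and
organ-support episodes into the six SOFA-2 organ subscores (0-4 each) and
the total score (0-24) for the first ``window_hours`` (default 24 h) of an
ICU stay.  Every numeric cut-point, drug list and constant lives in a
:class:`Sofa2Config`, normally loaded from a YAML file, so the rule set is
data rather than code.

Scoring conventions implemented here:

* the *worst* value in the window governs each component (lowest MAP, GCS,
  P/F, S/F and platelets; highest bilirubin and creatinine; total urine
  output);
* SpO2/FiO2 is a fallback used only when no PaO2/FiO2 ratio can be formed,
  and only SpO2 readings strictly below ``sf_fallback_spo2_max`` (default
  98%) enter the ratio;
* FiO2 is carried forward to each PaO2/SpO2 time (last observation carried
  forward, capped at ``pf_staleness_hours``);
* advanced ventilatory support (IMV, NIV, CPAP, BiPAP, HFNC, ECMO) is
  required for the top respiratory bands; without it the band is capped;
* mechanical circulatory support and renal replacement therapy force the
  configured maximum cardiovascular / renal subscore;
* vasopressor infusions qualify only with >= ``vasopressor_min_minutes``
  (default 60) of in-window exposure per merged episode; when any agent
  qualifies the vasopressor tier rules replace the MAP bands;
* pharmacologic delirium treatment floors the neurologic subscore at
  ``delirium_floor`` (default 1), even when no GCS was charted;
* a component with no usable data is *missing* and scored
  ``missing_component_score`` (default 0, i.e. presumed normal).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EVENT_VARIABLES",
    "SUPPORT_MODALITIES",
    "COMPONENTS",
    "Band",
    "Sofa2Config",
    "extract_worst_values",
    "compute_support_flags",
    "compute_vasopressor_exposure",
    "compute_delirium_exposure",
    "respiratory_subscore",
    "cardiovascular_subscore",
    "neurologic_subscore",
    "renal_subscore",
    "hepatic_subscore",
    "coagulation_subscore",
    "total_score",
    "score_cohort",
]

#: Closed vocabulary of measurement event names (long-format events table).
EVENT_VARIABLES = (
    "MAP",            # mean arterial pressure, mmHg
    "GCS_total",      # Glasgow Coma Scale total, 3-15
    "GCS_motor",      # GCS motor component, 1-6
    "PaO2",           # arterial O2 tension, mmHg
    "FiO2",           # inspired O2 fraction, 0.21-1.0
    "SpO2",           # pulse oximetry, %
    "bilirubin",      # mg/dL
    "creatinine",     # mg/dL
    "urine_output",   # mL per event (summed over the window)
    "platelets",      # x10^3 / uL
)

#: Closed vocabulary of organ-support modalities.
SUPPORT_MODALITIES = ("IMV", "NIV", "CPAP", "BiPAP", "HFNC", "ECMO", "RRT", "MCS")

#: The six organ components in reporting order.
COMPONENTS = (
    "neurological",
    "cardiovascular",
    "respiratory",
    "hepatic",
    "renal",
    "coagulation",
)


class Sofa2ConfigError(ValueError):
    """Raised when a scoring configuration violates its invariants."""


class ScoreConsistencyError(ValueError):
    """Raised when a subscore outside 0-4 reaches the totaliser."""


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Band:
    """One threshold rule: a half-open/closed value interval mapping to a
    subscore.  Each band declares its own edge inclusivity explicitly; there
    is no global open/closed convention."""

    score: int
    lower: float | None = None
    upper: float | None = None
    lower_inclusive: bool = True
    upper_inclusive: bool = False
    requires_support: bool = False
    label: str = ""

    def contains(self, values: np.ndarray) -> np.ndarray:
        """Vectorised membership test; NaN never matches."""
        v = np.asarray(values, dtype=float)
        ok = ~np.isnan(v)
        if self.lower is not None:
            ok &= (v >= self.lower) if self.lower_inclusive else (v > self.lower)
        if self.upper is not None:
            ok &= (v <= self.upper) if self.upper_inclusive else (v < self.upper)
        return ok

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: v for k, v in d.items() if v not in (None, "") or k == "score"}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Band":
        return cls(**{k: d[k] for k in d if k in {f.name for f in dataclasses.fields(cls)}})


def _bands(raw: Sequence[Mapping]) -> tuple[Band, ...]:
    return tuple(Band.from_dict(r) for r in raw)


@dataclass(frozen=True)
class Sofa2Config:
    """Complete SOFA-2 rule set: threshold tables, qualifying drug lists and
    window/duration constants.

    The shipped default (``Sofa2Config.default()``) is an editable
    transcription of the published SOFA-2 structure; sites holding the
    authoritative threshold supplement should override the YAML file.
    """

    window_hours: float = 24.0
    sf_fallback_spo2_max: float = 98.0           # strict '<' per-reading cap
    pf_staleness_hours: float = 4.0              # FiO2 LOCF cap for pairing
    vasopressor_min_minutes: float = 60.0
    infusion_merge_gap_minutes: float = 15.0
    vasopressor_drugs: tuple[str, ...] = ()
    delirium_agents: tuple[str, ...] = ()
    delirium_floor: int = 1
    rrt_max_score: int = 4
    mcs_max_score: int = 4
    missing_component_score: int = 0
    advanced_resp_modalities: tuple[str, ...] = ("IMV", "NIV", "CPAP", "BiPAP", "HFNC", "ECMO")
    respiratory_pf_bands: tuple[Band, ...] = ()
    respiratory_sf_bands: tuple[Band, ...] = ()
    respiratory_unsupported_cap: int = 2
    map_bands: tuple[Band, ...] = ()
    vasopressor_tiers: Mapping[int, int] = field(default_factory=dict)  # n agents -> score
    gcs_bands: tuple[Band, ...] = ()
    gcs_motor_bands: tuple[Band, ...] = ()
    bilirubin_bands: tuple[Band, ...] = ()
    creatinine_bands: tuple[Band, ...] = ()
    urine_bands: tuple[Band, ...] = ()
    platelet_bands: tuple[Band, ...] = ()

    # -- validation --------------------------------------------------------
    def __post_init__(self) -> None:
        for name in (
            "respiratory_pf_bands", "respiratory_sf_bands", "map_bands",
            "gcs_bands", "gcs_motor_bands", "bilirubin_bands",
            "creatinine_bands", "urine_bands", "platelet_bands",
        ):
            for band in getattr(self, name):
                if not 0 <= band.score <= 4:
                    raise Sofa2ConfigError(
                        f"{name}: subscore {band.score} outside 0-4 in band {band.label!r}"
                    )
        for n, s in dict(self.vasopressor_tiers).items():
            if not 0 <= int(s) <= 4:
                raise Sofa2ConfigError(f"vasopressor_tiers[{n}]: subscore {s} outside 0-4")
        for name in ("delirium_floor", "rrt_max_score", "mcs_max_score",
                     "missing_component_score", "respiratory_unsupported_cap"):
            if not 0 <= getattr(self, name) <= 4:
                raise Sofa2ConfigError(f"{name} outside 0-4")
        if self.window_hours <= 0:
            raise Sofa2ConfigError("window_hours must be positive")

    @property
    def window(self) -> pd.Timedelta:
        return pd.Timedelta(hours=self.window_hours)

    # -- (de)serialisation -------------------------------------------------
    _BAND_FIELDS = (
        "respiratory_pf_bands", "respiratory_sf_bands", "map_bands",
        "gcs_bands", "gcs_motor_bands", "bilirubin_bands",
        "creatinine_bands", "urine_bands", "platelet_bands",
    )

    def to_dict(self) -> dict:
        out: dict = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name in self._BAND_FIELDS:
                out[f.name] = [b.to_dict() for b in v]
            elif f.name == "vasopressor_tiers":
                out[f.name] = {int(k): int(s) for k, s in dict(v).items()}
            elif isinstance(v, tuple):
                out[f.name] = list(v)
            else:
                out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "Sofa2Config":
        kw: dict = {}
        names = {f.name for f in dataclasses.fields(cls)}
        for k, v in d.items():
            if k not in names:
                raise Sofa2ConfigError(f"unknown configuration key: {k!r}")
            if k in cls._BAND_FIELDS:
                kw[k] = _bands(v)
            elif k == "vasopressor_tiers":
                kw[k] = {int(n): int(s) for n, s in v.items()}
            elif k in ("vasopressor_drugs", "delirium_agents", "advanced_resp_modalities"):
                kw[k] = tuple(v)
            else:
                kw[k] = v
        return cls(**kw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Sofa2Config":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "Sofa2Config":
        """The packaged default rule set (``data/sofa2_default.yaml``)."""
        text = resources.files("sofa2audit.data").joinpath("sofa2_default.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


# --------------------------------------------------------------------------
# Worst-value extraction
# --------------------------------------------------------------------------

def _in_window(events: pd.DataFrame, stays: pd.DataFrame, window: pd.Timedelta) -> pd.DataFrame:
    ev = events.merge(stays[["stay_id", "intime"]], on="stay_id", how="inner")
    keep = (ev["time"] >= ev["intime"]) & (ev["time"] <= ev["intime"] + window)
    return ev.loc[keep]


def _pair_with_fio2(numerator: pd.DataFrame, fio2: pd.DataFrame,
                    staleness: pd.Timedelta, notes: list[str], what: str) -> pd.Series:
    """Pair each numerator reading (PaO2 or SpO2) with the most recent FiO2
    at-or-before its time (LOCF within the window, capped at *staleness*).
    Returns per-stay minimum ratio."""
    if numerator.empty or fio2.empty:
        return pd.Series(dtype=float)
    left = numerator[["stay_id", "time", "value"]].sort_values("time").reset_index(drop=True)
    right = (fio2[["stay_id", "time", "value"]]
             .rename(columns={"value": "fio2"}).sort_values("time").reset_index(drop=True))
    pairs = pd.merge_asof(left, right, on="time", by="stay_id",
                          direction="backward", tolerance=staleness)
    bad = pairs["fio2"] == 0
    if bad.any():
        notes.append(f"{what}: skipped {int(bad.sum())} pairing(s) with FiO2 = 0")
        pairs = pairs.loc[~bad]
    pairs = pairs.dropna(subset=["fio2"])
    if pairs.empty:
        return pd.Series(dtype=float)
    ratio = pairs["value"] / pairs["fio2"]
    return ratio.groupby(pairs["stay_id"]).min()


def extract_worst_values(stays: pd.DataFrame, events: pd.DataFrame,
                         config: Sofa2Config | None = None) -> pd.DataFrame:
    """Reduce in-window events to per-stay worst values.

    Returns a frame indexed by ``stay_id`` with columns ``map_min,
    gcs_total_min, gcs_motor_min, pf_min, sf_min, bilirubin_max,
    creatinine_max, urine_total, platelets_min`` (NaN = stream absent).
    Pairing diagnostics are collected in ``result.attrs['notes']``.
    """
    config = config or Sofa2Config.default()
    notes: list[str] = []
    ev = _in_window(events, stays, config.window)

    def agg(var: str, how: str) -> pd.Series:
        sub = ev.loc[ev["variable"] == var]
        if sub.empty:
            return pd.Series(dtype=float)
        return getattr(sub.groupby("stay_id")["value"], how)()

    out = pd.DataFrame(index=pd.Index(stays["stay_id"], name="stay_id"))
    out["map_min"] = agg("MAP", "min")
    out["gcs_total_min"] = agg("GCS_total", "min")
    out["gcs_motor_min"] = agg("GCS_motor", "min")

    staleness = pd.Timedelta(hours=config.pf_staleness_hours)
    fio2 = ev.loc[ev["variable"] == "FiO2"]
    out["pf_min"] = _pair_with_fio2(ev.loc[ev["variable"] == "PaO2"], fio2,
                                    staleness, notes, "PaO2/FiO2")
    spo2 = ev.loc[(ev["variable"] == "SpO2") & (ev["value"] < config.sf_fallback_spo2_max)]
    out["sf_min"] = _pair_with_fio2(spo2, fio2, staleness, notes, "SpO2/FiO2")

    out["bilirubin_max"] = agg("bilirubin", "max")
    out["creatinine_max"] = agg("creatinine", "max")
    out["urine_total"] = agg("urine_output", "sum")
    out["platelets_min"] = agg("platelets", "min")
    out.attrs["notes"] = notes
    return out


# --------------------------------------------------------------------------
# Treatment / support exposure
# --------------------------------------------------------------------------

def _overlap_minutes(start: pd.Series, end: pd.Series,
                     win_start: pd.Series, win_end: pd.Series) -> pd.Series:
    lo = np.maximum(start.to_numpy(), win_start.to_numpy())
    hi = np.minimum(end.to_numpy(), win_end.to_numpy())
    mins = (hi - lo) / np.timedelta64(60, "s")
    return pd.Series(np.maximum(mins.astype(float), 0.0), index=start.index)


def _merge_episodes(iv: pd.DataFrame, gap: pd.Timedelta) -> pd.DataFrame:
    """Merge intervals of the same (stay, drug) separated by less than *gap*."""
    iv = iv.sort_values(["stay_id", "drug", "start"]).reset_index(drop=True)
    key = iv["stay_id"].astype(str) + "\x00" + iv["drug"]
    new_key = key != key.shift()
    prev_end = iv["end"].shift()
    gap_break = iv["start"] - prev_end >= gap
    episode = (new_key | gap_break).cumsum()
    return iv.groupby(episode).agg(
        stay_id=("stay_id", "first"), drug=("drug", "first"),
        start=("start", "min"), end=("end", "max"))


def compute_vasopressor_exposure(infusions: pd.DataFrame, stays: pd.DataFrame,
                                 config: Sofa2Config) -> pd.Series:
    """Number of distinct qualifying vasopressor agents per stay.

    An agent qualifies when some merged infusion episode overlaps the scoring
    window by at least ``vasopressor_min_minutes``.
    """
    idx = pd.Index(stays["stay_id"], name="stay_id")
    counts = pd.Series(0, index=idx, dtype=int)
    if infusions.empty:
        return counts
    drugs = {d.lower() for d in config.vasopressor_drugs}
    iv = infusions.loc[infusions["drug"].str.lower().isin(drugs)]
    if iv.empty:
        return counts
    iv = _merge_episodes(iv, pd.Timedelta(minutes=config.infusion_merge_gap_minutes))
    iv = iv.merge(stays[["stay_id", "intime"]], on="stay_id")
    mins = _overlap_minutes(iv["start"], iv["end"], iv["intime"], iv["intime"] + config.window)
    qual = iv.loc[mins.to_numpy() >= config.vasopressor_min_minutes]
    got = qual.groupby("stay_id")["drug"].nunique()
    counts.loc[got.index] = got
    return counts


def compute_delirium_exposure(infusions: pd.DataFrame, stays: pd.DataFrame,
                              config: Sofa2Config) -> pd.Series:
    """Boolean per stay: any in-window infusion of a qualifying delirium agent."""
    idx = pd.Index(stays["stay_id"], name="stay_id")
    flag = pd.Series(False, index=idx)
    if infusions.empty:
        return flag
    agents = {d.lower() for d in config.delirium_agents}
    iv = infusions.loc[infusions["drug"].str.lower().isin(agents)]
    if iv.empty:
        return flag
    iv = iv.merge(stays[["stay_id", "intime"]], on="stay_id")
    mins = _overlap_minutes(iv["start"], iv["end"], iv["intime"], iv["intime"] + config.window)
    hit = iv.loc[mins.to_numpy() > 0, "stay_id"].unique()
    flag.loc[hit] = True
    return flag


def compute_support_flags(supports: pd.DataFrame, stays: pd.DataFrame,
                          config: Sofa2Config) -> pd.DataFrame:
    """Per-stay booleans: ``resp_support`` (any advanced ventilatory modality),
    ``mcs`` and ``rrt``, each requiring positive in-window overlap."""
    idx = pd.Index(stays["stay_id"], name="stay_id")
    out = pd.DataFrame({"resp_support": False, "mcs": False, "rrt": False}, index=idx)
    if supports.empty:
        return out
    sp = supports.merge(stays[["stay_id", "intime"]], on="stay_id")
    mins = _overlap_minutes(sp["start"], sp["end"], sp["intime"], sp["intime"] + config.window)
    sp = sp.loc[mins.to_numpy() > 0]
    resp = set(config.advanced_resp_modalities)
    out.loc[sp.loc[sp["modality"].isin(resp), "stay_id"].unique(), "resp_support"] = True
    out.loc[sp.loc[sp["modality"] == "MCS", "stay_id"].unique(), "mcs"] = True
    out.loc[sp.loc[sp["modality"] == "RRT", "stay_id"].unique(), "rrt"] = True
    return out


# --------------------------------------------------------------------------
# Organ subscores
# --------------------------------------------------------------------------

def _band_scores(values: np.ndarray, bands: Sequence[Band],
                 support: np.ndarray | None = None,
                 unsupported_cap: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """First-match band lookup.  Returns (score, rule-label); unmatched
    (including NaN) entries get score -1 / label None.  Bands flagged
    ``requires_support`` are capped at *unsupported_cap* when unsupported."""
    n = len(values)
    score = np.full(n, -1, dtype=int)
    rule = np.full(n, None, dtype=object)
    unmatched = np.ones(n, dtype=bool)
    for b in bands:
        hit = b.contains(values) & unmatched
        if not hit.any():
            continue
        lbl = b.label or f"score {b.score}"
        if b.requires_support and support is not None:
            ok = hit & support
            capped = hit & ~support
            score[ok] = b.score
            rule[ok] = lbl
            cap = b.score if unsupported_cap is None else min(unsupported_cap, b.score)
            score[capped] = cap
            rule[capped] = f"{lbl} [no advanced support: capped at {cap}]"
        else:
            score[hit] = b.score
            rule[hit] = lbl
        unmatched &= ~hit
    return score, rule


def _component_frame(index: pd.Index, score: np.ndarray, missing: np.ndarray,
                     rule: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"score": score.astype(int), "missing": missing, "rule": rule},
                        index=index)


def respiratory_subscore(worst: pd.DataFrame, support_flags: pd.DataFrame,
                         config: Sofa2Config) -> pd.DataFrame:
    """P/F governs when available; S/F is the fallback; the top bands need
    an advanced ventilatory modality, otherwise they are capped."""
    pf = worst["pf_min"].to_numpy(float)
    sf = worst["sf_min"].to_numpy(float)
    sup = support_flags["resp_support"].reindex(worst.index).fillna(False).to_numpy(bool)
    s_pf, r_pf = _band_scores(pf, config.respiratory_pf_bands, sup,
                              config.respiratory_unsupported_cap)
    s_sf, r_sf = _band_scores(sf, config.respiratory_sf_bands, sup,
                              config.respiratory_unsupported_cap)
    use_pf = ~np.isnan(pf)
    use_sf = np.isnan(pf) & ~np.isnan(sf)
    missing = ~use_pf & ~use_sf
    score = np.where(use_pf, s_pf, np.where(use_sf, s_sf, config.missing_component_score))
    rule = np.where(use_pf, r_pf,
                    np.where(use_sf, np.char.add("S/F fallback: ", r_sf.astype(str)),
                             "missing oxygenation: scored as normal"))
    return _component_frame(worst.index, score, missing, rule)


def cardiovascular_subscore(worst: pd.DataFrame, vaso_agents: pd.Series,
                            support_flags: pd.DataFrame, config: Sofa2Config) -> pd.DataFrame:
    """MCS forces the configured maximum; qualifying vasopressors select the
    agent-count tier rules; otherwise graduated MAP bands apply."""
    idx = worst.index
    mcs = support_flags["mcs"].reindex(idx).fillna(False).to_numpy(bool)
    n_agents = vaso_agents.reindex(idx).fillna(0).to_numpy(int)
    mapv = worst["map_min"].to_numpy(float)
    s_map, r_map = _band_scores(mapv, config.map_bands)

    tiers = dict(config.vasopressor_tiers)
    tier_keys = sorted(tiers)
    score = np.full(len(idx), config.missing_component_score, dtype=int)
    rule = np.full(len(idx), "missing MAP, no drugs/devices: scored as normal", dtype=object)
    missing = np.ones(len(idx), dtype=bool)

    has_map = ~np.isnan(mapv) & (s_map >= 0)
    score[has_map] = s_map[has_map]
    rule[has_map] = r_map[has_map]
    missing[has_map] = False

    on_vaso = n_agents > 0
    if tier_keys:
        capped = np.minimum(n_agents, tier_keys[-1])
        tier_score = np.array([tiers.get(int(c), 0) for c in capped])
        score[on_vaso] = tier_score[on_vaso]
        rule[on_vaso] = [f"vasopressor tier: {int(k)} agent(s)" for k in n_agents[on_vaso]]
        missing[on_vaso] = False

    score[mcs] = config.mcs_max_score
    rule[mcs] = "mechanical circulatory support"
    missing[mcs] = False
    return _component_frame(idx, score, missing, rule)


def neurologic_subscore(worst: pd.DataFrame, delirium: pd.Series,
                        config: Sofa2Config) -> pd.DataFrame:
    """Worst GCS total governs; the motor component is the fallback; any
    qualifying delirium treatment floors the result at ``delirium_floor``
    (unconditionally, even with no GCS charted)."""
    idx = worst.index
    total = worst["gcs_total_min"].to_numpy(float)
    motor = worst["gcs_motor_min"].to_numpy(float)
    deli = delirium.reindex(idx).fillna(False).to_numpy(bool)
    s_t, r_t = _band_scores(total, config.gcs_bands)
    s_m, r_m = _band_scores(motor, config.gcs_motor_bands)
    use_t = ~np.isnan(total)
    use_m = np.isnan(total) & ~np.isnan(motor)
    missing = ~use_t & ~use_m & ~deli
    score = np.where(use_t, s_t, np.where(use_m, s_m, config.missing_component_score))
    rule = np.where(use_t, r_t,
                    np.where(use_m, np.char.add("GCS motor fallback: ", r_m.astype(str)),
                             "missing GCS: scored as normal"))
    floored = deli & (score < config.delirium_floor)
    score = np.where(floored, config.delirium_floor, score)
    rule = np.where(floored, f"delirium treatment floor ({config.delirium_floor})", rule)
    return _component_frame(idx, score, missing, rule)


def renal_subscore(worst: pd.DataFrame, support_flags: pd.DataFrame,
                   config: Sofa2Config) -> pd.DataFrame:
    """RRT forces the configured maximum; otherwise the worse of the
    creatinine band and the 24-h urine-output band."""
    idx = worst.index
    rrt = support_flags["rrt"].reindex(idx).fillna(False).to_numpy(bool)
    cr = worst["creatinine_max"].to_numpy(float)
    uo = worst["urine_total"].to_numpy(float)
    s_cr, r_cr = _band_scores(cr, config.creatinine_bands)
    s_uo, r_uo = _band_scores(uo, config.urine_bands)
    have_cr = ~np.isnan(cr) & (s_cr >= 0)
    have_uo = ~np.isnan(uo) & (s_uo >= 0)
    missing = ~have_cr & ~have_uo & ~rrt
    score = np.full(len(idx), config.missing_component_score, dtype=int)
    rule = np.full(len(idx), "missing creatinine and urine output: scored as normal",
                   dtype=object)
    only_cr = have_cr & ~have_uo
    only_uo = have_uo & ~have_cr
    both = have_cr & have_uo
    score[only_cr] = s_cr[only_cr]
    rule[only_cr] = r_cr[only_cr]
    score[only_uo] = s_uo[only_uo]
    rule[only_uo] = r_uo[only_uo]
    cr_wins = both & (s_cr >= s_uo)
    uo_wins = both & (s_uo > s_cr)
    score[cr_wins] = s_cr[cr_wins]
    rule[cr_wins] = r_cr[cr_wins]
    score[uo_wins] = s_uo[uo_wins]
    rule[uo_wins] = r_uo[uo_wins]
    score[rrt] = config.rrt_max_score
    rule[rrt] = "renal replacement therapy"
    missing[rrt] = False
    return _component_frame(idx, score, missing, rule)


def hepatic_subscore(worst: pd.DataFrame, config: Sofa2Config) -> pd.DataFrame:
    """Worst (maximum) bilirubin band; absent stream scores as normal."""
    v = worst["bilirubin_max"].to_numpy(float)
    s, r = _band_scores(v, config.bilirubin_bands)
    missing = np.isnan(v)
    score = np.where(missing, config.missing_component_score, s)
    rule = np.where(missing, "missing bilirubin: scored as normal", r)
    return _component_frame(worst.index, score, missing, rule)


def coagulation_subscore(worst: pd.DataFrame, config: Sofa2Config) -> pd.DataFrame:
    """Worst (minimum) platelet-count band; absent stream scores as normal."""
    v = worst["platelets_min"].to_numpy(float)
    s, r = _band_scores(v, config.platelet_bands)
    missing = np.isnan(v)
    score = np.where(missing, config.missing_component_score, s)
    rule = np.where(missing, "missing platelets: scored as normal", r)
    return _component_frame(worst.index, score, missing, rule)


# --------------------------------------------------------------------------
# Totals
# --------------------------------------------------------------------------

def total_score(components: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Combine the six per-component frames into a Sofa2Result table.

    Columns: ``<component>`` subscores, ``<component>_missing`` flags,
    ``<component>_rule`` audit notes and ``total``.
    """
    missing_keys = set(COMPONENTS) - set(components)
    if missing_keys:
        raise ScoreConsistencyError(f"missing components: {sorted(missing_keys)}")
    idx = components[COMPONENTS[0]].index
    out = pd.DataFrame(index=idx)
    for name in COMPONENTS:
        comp = components[name]
        sc = comp["score"].to_numpy(int)
        if ((sc < 0) | (sc > 4)).any():
            raise ScoreConsistencyError(f"{name}: subscore outside 0-4")
        out[name] = sc
        out[f"{name}_missing"] = comp["missing"].to_numpy(bool)
        out[f"{name}_rule"] = comp["rule"].to_numpy(object)
    out["total"] = out[list(COMPONENTS)].sum(axis=1)
    return out


def score_cohort(stays: pd.DataFrame, events: pd.DataFrame,
                 infusions: pd.DataFrame, supports: pd.DataFrame,
                 config: Sofa2Config | None = None) -> pd.DataFrame:
    """End-to-end first-day SOFA-2 scoring for a cohort.

    Returns the :func:`total_score` table indexed by ``stay_id``, with the
    worst-value columns appended (prefixed ``wv_``).
    """
    config = config or Sofa2Config.default()
    worst = extract_worst_values(stays, events, config)
    flags = compute_support_flags(supports, stays, config)
    vaso = compute_vasopressor_exposure(infusions, stays, config)
    deli = compute_delirium_exposure(infusions, stays, config)
    comps = {
        "neurological": neurologic_subscore(worst, deli, config),
        "cardiovascular": cardiovascular_subscore(worst, vaso, flags, config),
        "respiratory": respiratory_subscore(worst, flags, config),
        "hepatic": hepatic_subscore(worst, config),
        "renal": renal_subscore(worst, flags, config),
        "coagulation": coagulation_subscore(worst, config),
    }
    result = total_score(comps)
    for col in worst.columns:
        result[f"wv_{col}"] = worst[col]
    result.attrs["notes"] = worst.attrs.get("notes", [])
    return result
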