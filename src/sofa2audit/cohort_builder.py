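"""Analytic-cohort construction from event-level flat files.

Reads the delimited layout (``stays.csv``, ``events.csv``,
``infusions.csv``, ``supports.csv``), applies the inclusion/exclusion
cascade -- adults, one index ICU stay per patient, length-of-stay >= 6 h,
physiologically plausible worst values -- defines the ICU-mortality
outcome (death during the stay or within a 6 h grace window after
discharge), and keeps an attrition log with demographic summaries and
standardized mean differences (SMDs) against the initial population at
every step.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .sofa2_engine import EVENT_VARIABLES, SUPPORT_MODALITIES

__all__ = [
    "RawCohort",
    "PlausibilityRanges",
    "AttritionLog",
    "CohortReadError",
    "read_cohort",
    "select_index_stays",
    "apply_exclusions",
    "define_outcome",
    "compute_smd",
]

STAY_COLUMNS = (
    "stay_id", "subject_id", "hadm_id", "admittime", "intime", "outtime",
    "age_years", "sex", "race_ethnicity_raw", "language_raw",
    "insurance_raw", "death_time",
)

INFUSION_CATEGORIES = ("vasopressor", "delirium_agent", "other")


class CohortReadError(ValueError):
    """Malformed or missing input file; message carries row numbers."""


# --------------------------------------------------------------------------
# Reading
# --------------------------------------------------------------------------

def _parse_times(df: pd.DataFrame, cols: list[str], fname: str,
                 optional: tuple[str, ...] = ("death_time", "admittime")) -> list[str]:
    problems = []
    for c in cols:
        parsed = pd.to_datetime(df[c], errors="coerce", format="ISO8601")
        bad = parsed.isna()
        if c in optional:
            bad &= df[c].notna()  # blank is allowed for optional columns
        for i in df.index[bad][:5]:
            problems.append(f"{fname} row {i + 2}: unparseable timestamp in {c!r}")
        df[c] = parsed
    return problems


def read_cohort(directory) -> "RawCohort":
    """Read and validate the four flat files of an event-level cohort.

    Raises :class:`CohortReadError` naming the file and (1-based, header
    included) row of the first few offending records.
    """
    directory = Path(directory)
    problems: list[str] = []
    frames = {}
    spec = {
        "stays.csv": list(STAY_COLUMNS),
        "events.csv": ["stay_id", "time", "variable", "value"],
        "infusions.csv": ["stay_id", "drug", "start", "end", "category"],
        "supports.csv": ["stay_id", "modality", "start", "end"],
    }
    for fname, cols in spec.items():
        path = directory / fname
        if not path.exists():
            raise CohortReadError(f"missing required file: {path}")
        df = pd.read_csv(path)
        missing = set(cols) - set(df.columns)
        if missing:
            raise CohortReadError(f"{fname}: missing columns {sorted(missing)}")
        frames[fname] = df

    stays = frames["stays.csv"]
    problems += _parse_times(stays, ["admittime", "intime", "outtime", "death_time"],
                             "stays.csv")
    events = frames["events.csv"]
    problems += _parse_times(events, ["time"], "events.csv")
    bad_var = ~events["variable"].isin(EVENT_VARIABLES)
    for i in events.index[bad_var][:5]:
        problems.append(
            f"events.csv row {i + 2}: unknown variable {events.at[i, 'variable']!r}")
    bad_val = ~np.isfinite(pd.to_numeric(events["value"], errors="coerce"))
    for i in events.index[bad_val][:5]:
        problems.append(f"events.csv row {i + 2}: non-finite value")

    infusions = frames["infusions.csv"]
    problems += _parse_times(infusions, ["start", "end"], "infusions.csv")
    bad_cat = ~infusions["category"].isin(INFUSION_CATEGORIES)
    for i in infusions.index[bad_cat][:5]:
        problems.append(
            f"infusions.csv row {i + 2}: unknown category {infusions.at[i, 'category']!r}")

    supports = frames["supports.csv"]
    problems += _parse_times(supports, ["start", "end"], "supports.csv")
    bad_mod = ~supports["modality"].isin(SUPPORT_MODALITIES)
    for i in supports.index[bad_mod][:5]:
        problems.append(
            f"supports.csv row {i + 2}: unknown modality {supports.at[i, 'modality']!r}")

    for name, df in (("infusions.csv", infusions), ("supports.csv", supports)):
        bad = ~(df["end"] > df["start"])
        for i in df.index[bad][:5]:
            problems.append(f"{name} row {i + 2}: end not after start")
    bad = ~(stays["outtime"] > stays["intime"])
    for i in stays.index[bad][:5]:
        problems.append(f"stays.csv row {i + 2}: outtime not after intime")

    if problems:
        raise CohortReadError("; ".join(problems))
    return RawCohort(stays=stays, events=events, infusions=infusions, supports=supports)


@dataclass
class RawCohort:
    stays: pd.DataFrame
    events: pd.DataFrame
    infusions: pd.DataFrame
    supports: pd.DataFrame


# --------------------------------------------------------------------------
# Index-stay selection
# --------------------------------------------------------------------------

def select_index_stays(stays: pd.DataFrame, order_by: str = "admittime") -> pd.DataFrame:
    """One index ICU stay per patient: adults only (age >= 18), the first
    hospitalization with an ICU visit per subject, and within it the
    earliest-``intime`` ICU stay.

    ``order_by`` picks how hospitalizations are ordered when hospital
    admission time and ICU in-time disagree: ``"admittime"`` (default) or
    ``"intime"`` (earliest ICU intime within each hospitalization).
    """
    adults = stays.loc[stays["age_years"] >= 18].copy()
    if adults.empty:
        return adults
    if order_by == "admittime" and adults["admittime"].notna().all():
        hadm_key = adults["admittime"]
    else:
        hadm_key = adults.groupby("hadm_id")["intime"].transform("min")
    adults = adults.assign(_hadm_key=hadm_key)
    adults = adults.sort_values(["subject_id", "_hadm_key", "intime"], kind="mergesort")
    first_hadm = adults.groupby("subject_id", sort=False)["hadm_id"].transform("first")
    adults = adults.loc[adults["hadm_id"] == first_hadm]
    idx = adults.groupby("subject_id", sort=False)["intime"].idxmin()
    return stays.loc[sorted(idx)].copy()


# --------------------------------------------------------------------------
# SMD and attrition logging
# --------------------------------------------------------------------------

def compute_smd(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """Absolute standardized mean difference:
    ``|mean_a - mean_b| / sqrt((sd_a^2 + sd_b^2) / 2)``.

    For proportions pass ``sd = sqrt(p (1 - p))``.  Returns 0 when the
    pooled SD is 0 and the means agree, NaN (undefined) when the pooled SD
    is 0 but the means differ.
    """
    pooled = np.sqrt((sd_a ** 2 + sd_b ** 2) / 2.0)
    diff = abs(mean_a - mean_b)
    if pooled == 0:
        return 0.0 if diff == 0 else float("nan")
    return float(diff / pooled)


def _summarise(stays: pd.DataFrame) -> dict:
    """Demographic summary: age mean/SD plus category proportions of the
    raw sex/race/language/insurance fields."""
    out: dict = {"n": int(len(stays))}
    if len(stays):
        out["age_mean"] = float(stays["age_years"].mean())
        out["age_sd"] = float(stays["age_years"].std(ddof=0))
    else:
        out["age_mean"] = out["age_sd"] = float("nan")
    for col in ("sex", "race_ethnicity_raw", "language_raw", "insurance_raw"):
        props = (stays[col].fillna("Unknown").value_counts(normalize=True)
                 if len(stays) else pd.Series(dtype=float))
        out[col] = {str(k): float(v) for k, v in props.items()}
    return out


def _smds_vs(summary: dict, baseline: dict) -> dict:
    smds = {"age": compute_smd(summary["age_mean"], summary["age_sd"],
                               baseline["age_mean"], baseline["age_sd"])}
    for col in ("sex", "race_ethnicity_raw", "language_raw", "insurance_raw"):
        cats = set(summary[col]) | set(baseline[col])
        for c in sorted(cats):
            p, q = summary[col].get(c, 0.0), baseline[col].get(c, 0.0)
            smds[f"{col}:{c}"] = compute_smd(p, np.sqrt(p * (1 - p)),
                                             q, np.sqrt(q * (1 - q)))
    return smds


@dataclass
class AttritionLog:
    """Ordered record of the exclusion cascade with per-step demographic
    summaries and SMDs against the initial population."""

    baseline: dict = field(default_factory=dict)
    steps: list[dict] = field(default_factory=list)

    @classmethod
    def start(cls, stays: pd.DataFrame) -> "AttritionLog":
        return cls(baseline=_summarise(stays))

    def add_step(self, label: str, before: pd.DataFrame, after: pd.DataFrame) -> None:
        if len(after) > len(before):
            raise ValueError("attrition step cannot gain stays")
        summary = _summarise(after)
        self.steps.append({
            "label": label,
            "n_before": int(len(before)),
            "n_after": int(len(after)),
            "n_excluded": int(len(before) - len(after)),
            "summary": summary,
            "smd_vs_initial": _smds_vs(summary, self.baseline),
        })

    @property
    def total_excluded(self) -> int:
        return sum(s["n_excluded"] for s in self.steps)

    def to_dict(self) -> dict:
        return {"baseline": self.baseline, "steps": self.steps}

    def to_json(self, path) -> None:
        def _clean(o):
            if isinstance(o, float) and np.isnan(o):
                return None
            if isinstance(o, dict):
                return {k: _clean(v) for k, v in o.items()}
            if isinstance(o, list):
                return [_clean(v) for v in o]
            return o
        Path(path).write_text(json.dumps(_clean(self.to_dict()), indent=2))


# --------------------------------------------------------------------------
# Plausibility ranges and exclusions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlausibilityRanges:
    """Admissible [min, max] bounds per worst-value column."""

    ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for var, (lo, hi) in dict(self.ranges).items():
            if not lo < hi:
                raise ValueError(f"plausibility range for {var!r}: min must be < max")

    @classmethod
    def from_yaml(cls, path) -> "PlausibilityRanges":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(ranges={k: (float(v["min"]), float(v["max"])) for k, v in raw.items()})

    @classmethod
    def default(cls) -> "PlausibilityRanges":
        text = resources.files("sofa2audit.data").joinpath(
            "plausibility_default.yaml").read_text()
        raw = yaml.safe_load(text)
        return cls(ranges={k: (float(v["min"]), float(v["max"])) for k, v in raw.items()})

    def violations(self, worst: pd.DataFrame) -> pd.Series:
        """Boolean per stay: any present worst value outside its range."""
        bad = pd.Series(False, index=worst.index)
        for var, (lo, hi) in dict(self.ranges).items():
            if var not in worst.columns:
                continue
            v = worst[var]
            bad |= v.notna() & ((v < lo) | (v > hi))
        return bad


def apply_exclusions(stays: pd.DataFrame, worst_values: pd.DataFrame,
                     ranges: PlausibilityRanges, min_los_hours: float = 6.0,
                     log: AttritionLog | None = None) -> tuple[pd.DataFrame, AttritionLog]:
    """Drop stays with ICU length-of-stay strictly below *min_los_hours*
    (default 6 h; exactly 6 h is retained) and then stays with any worst
    value outside its plausibility range, logging both steps."""
    log = log or AttritionLog.start(stays)
    los_h = (stays["outtime"] - stays["intime"]).dt.total_seconds() / 3600.0
    kept = stays.loc[los_h >= min_los_hours]
    log.add_step(f"ICU length-of-stay >= {min_los_hours:g} h", stays, kept)

    bad = ranges.violations(worst_values.loc[worst_values.index.intersection(
        kept["stay_id"])])
    bad_ids = set(bad.index[bad])
    kept2 = kept.loc[~kept["stay_id"].isin(bad_ids)]
    log.add_step("plausible physiologic worst values", kept, kept2)
    return kept2.copy(), log


# --------------------------------------------------------------------------
# Outcome
# --------------------------------------------------------------------------

def define_outcome(stays: pd.DataFrame, grace_hours: float = 6.0) -> pd.Series:
    """ICU mortality: 1 iff a death time is recorded at or before ICU
    discharge plus *grace_hours* (default 6 h), else 0."""
    if grace_hours < 0:
        raise ValueError("grace_hours must be >= 0")
    cutoff = stays["outtime"] + pd.Timedelta(hours=grace_hours)
    died = stays["death_time"].notna() & (stays["death_time"] <= cutoff)
    return died.astype(int).rename("outcome")
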