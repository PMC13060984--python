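"""Mapping of raw demographic fields to analysis subgroup categories.

Five dimensions are audited: age band, sex, race/ethnicity, primary
language and insurance.  Raw free-text labels (MIMIC-style) are mapped to
closed category sets via editable vocabularies; labels outside the
vocabulary fall to a per-dimension default and are counted, never dropped.
Unknown is analysed as its own category, not imputed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = ["DIMENSIONS", "SubgroupScheme", "assign_subgroups"]

#: Category columns produced by :func:`assign_subgroups`, in audit order.
DIMENSIONS = ("age_group", "sex", "race_ethnicity", "language", "insurance")

RACE_CATEGORIES = ("White", "Black", "Hispanic", "Asian", "Other", "Unknown")
LANGUAGE_CATEGORIES = ("English", "Non-English", "Unknown")
INSURANCE_CATEGORIES = ("Private", "Medicare", "Medicaid", "Other")


class SubgroupSchemeError(ValueError):
    pass


def _norm(label: str) -> str:
    return str(label).strip().upper()


@dataclass(frozen=True)
class SubgroupScheme:
    """Age-band edges, raw-label vocabularies and reference levels."""

    age_bins: tuple[float, ...] = (18, 45, 65, 75)   # left-closed breakpoints
    sex_map: Mapping[str, str] = field(default_factory=dict)
    sex_default: str = "Unknown"
    race_map: Mapping[str, str] = field(default_factory=dict)
    race_default: str = "Other"
    hispanic_precedence: bool = True
    language_map: Mapping[str, str] = field(default_factory=dict)
    language_default: str = "Non-English"
    insurance_map: Mapping[str, str] = field(default_factory=dict)
    insurance_default: str = "Other"
    reference_levels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.age_bins) != sorted(self.age_bins) or len(self.age_bins) < 2:
            raise SubgroupSchemeError("age_bins must be >= 2 increasing breakpoints")
        if self.age_bins[0] != 18:
            raise SubgroupSchemeError("age bands must start at 18 (adult cohort)")

    @property
    def age_labels(self) -> tuple[str, ...]:
        edges = [int(e) for e in self.age_bins]
        labels = [f"{lo}-{hi - 1}" for lo, hi in zip(edges[:-1], edges[1:])]
        labels.append(f"{edges[-1]}+")
        return tuple(labels)

    def reference_level(self, dimension: str) -> str:
        try:
            return self.reference_levels[dimension]
        except KeyError:
            raise SubgroupSchemeError(f"no reference level declared for {dimension!r}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SubgroupScheme":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise SubgroupSchemeError(f"unknown scheme keys: {sorted(unknown)}")
        kw = dict(d)
        if "age_bins" in kw:
            kw["age_bins"] = tuple(kw["age_bins"])
        for m in ("sex_map", "race_map", "language_map", "insurance_map"):
            if m in kw:
                kw[m] = {_norm(k): v for k, v in kw[m].items()}
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "SubgroupScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "SubgroupScheme":
        text = resources.files("sofa2audit.data").joinpath("subgroups_default.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


def _map_column(raw: pd.Series, vocab: Mapping[str, str], default: str,
                counter: dict[str, int]) -> pd.Series:
    normed = raw.fillna("UNKNOWN").map(_norm)
    mapped = normed.map(lambda s: vocab.get(s))
    miss = mapped.isna()
    for lbl in normed[miss].unique():
        counter[lbl] = counter.get(lbl, 0) + int((normed[miss] == lbl).sum())
    return mapped.where(~miss, default)


def assign_subgroups(stays: pd.DataFrame, scheme: SubgroupScheme | None = None) -> pd.DataFrame:
    """Assign one category per dimension to every stay.

    Expects columns ``age_years, sex, race_ethnicity_raw, language_raw,
    insurance_raw``.  Returns a frame aligned with *stays* holding the five
    :data:`DIMENSIONS` columns; unmapped raw labels are routed to each
    dimension's default and tallied in ``result.attrs['unmapped']``.
    """
    scheme = scheme or SubgroupScheme.default()
    unmapped: dict[str, dict[str, int]] = {d: {} for d in DIMENSIONS}
    out = pd.DataFrame(index=stays.index)

    edges = list(scheme.age_bins) + [np.inf]
    out["age_group"] = pd.cut(stays["age_years"], bins=edges, labels=scheme.age_labels,
                              right=False, include_lowest=True).astype(object)

    out["sex"] = _map_column(stays["sex"], dict(scheme.sex_map) or
                             {"M": "Male", "MALE": "Male", "F": "Female", "FEMALE": "Female"},
                             scheme.sex_default, unmapped["sex"])

    race_raw = stays["race_ethnicity_raw"]
    race = _map_column(race_raw, scheme.race_map, scheme.race_default,
                       unmapped["race_ethnicity"])
    if scheme.hispanic_precedence:
        hisp = race_raw.fillna("").map(_norm).str.contains("HISPANIC")
        race = race.where(~hisp, "Hispanic")
    out["race_ethnicity"] = race

    out["language"] = _map_column(stays["language_raw"], scheme.language_map,
                                  scheme.language_default, unmapped["language"])
    out["insurance"] = _map_column(stays["insurance_raw"], scheme.insurance_map,
                                   scheme.insurance_default, unmapped["insurance"])
    out.attrs["unmapped"] = {d: c for d, c in unmapped.items() if c}
    return out
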