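"""End-to-end pipeline orchestration and report generation.

``run_pipeline`` executes read -> index-stay selection -> scoring ->
exclusions -> outcome -> subgroup assignment -> performance audit, and
emits the full artifact set: an attrition log with SMDs
(``attrition.json``), a baseline-characteristics table
(``baseline_table.csv``), the subgroup performance table
(``performance.csv``), observed mortality by score level
(``mortality_by_score.csv``), a per-component missingness report
(``missingness.json``), calibration-curve data and plots, scored stays
(``scores.csv``) and a reproducibility manifest (``manifest.json``).
Partial outputs are removed if any stage fails.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_builder, performance_eval, sofa2_engine, subgroup_defs
from .cohort_builder import AttritionLog, PlausibilityRanges
from .performance_eval import EvalConfig
from .sofa2_engine import COMPONENTS, Sofa2Config
from .subgroup_defs import DIMENSIONS, SubgroupScheme

__all__ = ["RunManifest", "PipelineError", "run_pipeline", "baseline_table",
           "missingness_report"]

log = logging.getLogger("sofa2audit")


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    seed: int | None
    config_hashes: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()


# --------------------------------------------------------------------------
# Report tables
# --------------------------------------------------------------------------

def _iqr(x: pd.Series) -> tuple[float, float, float]:
    """Median and linear-interpolation (type-7) quartiles."""
    if len(x) == 0:
        return (np.nan, np.nan, np.nan)
    q1, med, q3 = np.percentile(np.asarray(x, float), [25, 50, 75])
    return float(med), float(q1), float(q3)


def baseline_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics per subgroup category: n (%), median score
    (IQR), median LOS in days (IQR), deaths n (%).

    *cohort* needs ``score``, ``outcome``, ``los_days`` and the five
    subgroup columns.
    """
    rows = []

    def add(dimension, category, sub):
        med, q1, q3 = _iqr(sub["score"])
        lmed, lq1, lq3 = _iqr(sub["los_days"])
        n = len(sub)
        rows.append(dict(
            dimension=dimension, category=category, n=n,
            pct=100.0 * n / len(cohort) if len(cohort) else np.nan,
            score_median=med, score_q1=q1, score_q3=q3,
            los_days_median=round(lmed, 1) if n else np.nan,
            los_days_q1=round(lq1, 1) if n else np.nan,
            los_days_q3=round(lq3, 1) if n else np.nan,
            deaths=int(sub["outcome"].sum()),
            mortality_pct=100.0 * sub["outcome"].mean() if n else np.nan))

    add("overall", "Overall", cohort)
    for dim in DIMENSIONS:
        for cat in pd.unique(cohort[dim]):
            add(dim, cat, cohort.loc[cohort[dim] == cat])
    return pd.DataFrame(rows)


def missingness_report(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-component count and proportion of stays with the missing flag."""
    rows = []
    for comp in COMPONENTS:
        flag = scores[f"{comp}_missing"].astype(bool)
        rows.append(dict(component=comp, n_missing=int(flag.sum()),
                         proportion=float(flag.mean()) if len(flag) else np.nan))
    return pd.DataFrame(rows)


def _calibration_curve(risk: np.ndarray, outcome: np.ndarray,
                       frac: float = 0.5) -> pd.DataFrame:
    """Loess-smoothed observed outcome against predicted risk."""
    import statsmodels.api as sm
    order = np.argsort(risk)
    sm_y = sm.nonparametric.lowess(outcome[order], risk[order], frac=frac,
                                   return_sorted=False)
    return pd.DataFrame({"predicted_risk": risk[order],
                         "observed_smoothed": np.clip(sm_y, 0, 1)})


def _plots(out_dir: Path, cohort: pd.DataFrame, mort: pd.DataFrame,
           curve: pd.DataFrame) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="ideal")
    ax.plot(curve["predicted_risk"], curve["observed_smoothed"], lw=2)
    ax.set_xlabel("Predicted risk")
    ax.set_ylabel("Observed mortality (smoothed)")
    ax.set_title("Calibration, overall cohort")
    fig.tight_layout()
    p = out_dir / "calibration_overall.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharey=True)
    for ax, dim in zip(axes, ("age_group", "sex")):
        sub = mort.loc[mort["dimension"] == dim]
        for cat in sub["stratum"].unique():
            rows = sub.loc[(sub["stratum"] == cat) & (sub["n"] > 0)]
            x = [int(v.replace(">=", "")) for v in rows["score"]]
            ax.plot(x, 100 * rows["mortality"], marker="o", ms=3, label=str(cat))
        ax.set_xlabel("First-day score")
        ax.set_title(f"Observed mortality by {dim}")
        ax.legend(fontsize=7)
    axes[0].set_ylabel("ICU mortality, %")
    fig.tight_layout()
    p = out_dir / "mortality_by_score.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

def run_pipeline(data_dir, out_dir, sofa2_config: Sofa2Config | None = None,
                 plausibility: PlausibilityRanges | None = None,
                 scheme: SubgroupScheme | None = None,
                 eval_config: EvalConfig | None = None,
                 min_los_hours: float = 6.0, grace_hours: float = 6.0,
                 order_by: str = "admittime", make_plots: bool = True) -> RunManifest:
    """Run the full audit on the flat files in *data_dir*, writing the
    artifact set to *out_dir*.  Returns the run manifest."""
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    sofa2_config = sofa2_config or Sofa2Config.default()
    plausibility = plausibility or PlausibilityRanges.default()
    scheme = scheme or SubgroupScheme.default()
    eval_config = eval_config or EvalConfig()

    manifest = RunManifest(seed=eval_config.seed)
    manifest.config_hashes = {
        "sofa2_config": _hash_obj(sofa2_config.to_dict()),
        "plausibility": _hash_obj({k: list(v) for k, v in dict(plausibility.ranges).items()}),
        "eval": _hash_obj(vars(eval_config)),
    }
    for f in ("stays.csv", "events.csv", "infusions.csv", "supports.csv"):
        p = data_dir / f
        if p.exists():
            manifest.input_digests[f] = _sha256(p)

    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "read"
    t0 = time.perf_counter()

    def tick(next_stage):
        nonlocal stage, t0
        manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done (%.2fs)", stage, manifest.stage_seconds[stage])
        stage, t0 = next_stage, time.perf_counter()

    try:
        raw = cohort_builder.read_cohort(data_dir)
        tick("select")
        attrition = AttritionLog.start(raw.stays)
        candidates = cohort_builder.select_index_stays(raw.stays, order_by=order_by)
        attrition.add_step("adult (>=18), first hospitalization, index ICU stay",
                           raw.stays, candidates)
        tick("score")
        scores = sofa2_engine.score_cohort(candidates, raw.events, raw.infusions,
                                           raw.supports, sofa2_config)
        manifest.warnings += list(scores.attrs.get("notes", []))
        tick("exclude")
        worst = scores[[c for c in scores.columns if c.startswith("wv_")]]
        worst = worst.rename(columns=lambda c: c[3:])
        cohort, attrition = cohort_builder.apply_exclusions(
            candidates, worst, plausibility, min_los_hours, log=attrition)
        tick("outcome")
        cohort = cohort.copy()
        cohort["outcome"] = cohort_builder.define_outcome(cohort, grace_hours)
        tick("assign")
        groups = subgroup_defs.assign_subgroups(cohort, scheme)
        for warn_dim, counts in groups.attrs.get("unmapped", {}).items():
            manifest.warnings.append(f"unmapped {warn_dim} labels: {counts}")
        cohort = pd.concat([cohort.reset_index(drop=True).rename(
            columns={"sex": "sex_raw"}),  # canonical 'sex' comes from the scheme
                            groups.reset_index(drop=True)], axis=1)
        cohort["score"] = scores["total"].reindex(cohort["stay_id"]).to_numpy()
        cohort["los_days"] = ((cohort["outtime"] - cohort["intime"])
                              .dt.total_seconds() / 86400.0)
        tick("evaluate")
        perf, mort = performance_eval.evaluate_all(cohort, scheme, eval_config)
        tick("report")
        model = performance_eval.fit_calibration_model(
            cohort["score"].to_numpy(float), cohort["outcome"].to_numpy(int))
        curve = _calibration_curve(model.predicted_risk(cohort["score"]),
                                   cohort["outcome"].to_numpy(int))

        def save(df: pd.DataFrame, name: str, index=False):
            p = out_dir / name
            df.to_csv(p, index=index)
            written.append(p)

        save(scores.reset_index(), "scores.csv")
        save(perf, "performance.csv")
        save(mort, "mortality_by_score.csv")
        save(baseline_table(cohort), "baseline_table.csv")
        save(curve, "calibration_curves.csv")
        miss = missingness_report(scores.loc[scores.index.isin(cohort["stay_id"])])
        p = out_dir / "missingness.json"
        p.write_text(miss.to_json(orient="records", indent=2))
        written.append(p)
        p = out_dir / "attrition.json"
        attrition.to_json(p)
        written.append(p)
        if make_plots:
            written += _plots(out_dir, cohort, mort, curve)
        manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 3)
    except BaseException as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc

    manifest.outputs = {p.name: _sha256(p) for p in written}
    manifest.to_json(out_dir / "manifest.json")
    return manifest
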