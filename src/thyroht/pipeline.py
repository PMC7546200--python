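"""End-to-end analysis pipeline: cohort -> bands -> endpoint -> selection ->
threshold inference -> cutpoints -> risk strata -> incidence curves.

Every stage that draws random numbers receives a seed derived by hashing
(global seed, stage name), so adding a stage never perturbs an earlier
stage's randomness, and the whole run is reproducible from one integer.
All artifacts are plain CSV/JSON plus a machine-readable manifest recording
every default and derived seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    BAND_PREDICTORS,
    PatientRecord,
    TwoYearDataset,
    baseline_comparison,
    derive_two_year_endpoint,
    km_cumulative_incidence,
    load_cohort,
    spearman_matrix,
)
from .cutpoints import merge_strata, minp_cutpoint, strata_incidence_curves, stratify
from .reference import (
    EXPECTED_INCIDENCE_PCT,
    REFERENCE_COUNTS,
    REFERENCE_CUTS,
    reference_counts_dataset,
)
from .selection import (
    LassoConfig,
    backward_eliminate,
    fit_logistic,
    lasso_select,
    selection_report,
    univariate_screen,
)
from .simulate import SimConfig, generate_cohort
from .threshold import DEFAULT_CANDIDATES, compare_candidates

__all__ = ["RunConfig", "run_pipeline", "validate_against_fixture", "derive_seed"]

_BASELINE_VARS = ("age", "sex", "t_stage", "n_stage", "overall_stage", "chemotherapy",
                  "volume_cm3") + BAND_PREDICTORS
_SELECTION_PREDICTORS = ("volume_cm3",) + BAND_PREDICTORS


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, from (global seed, stage name)."""
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """Configuration for one full analysis run (synthetic or file-backed)."""

    mode: str = "synthetic"                 # "synthetic" | "files"
    seed: int = 0
    sim: SimConfig | None = None            # synthetic mode; defaults applied if None
    cohort_csv: str | None = None           # files mode: manifest path
    horizon_months: float = 24.0
    alpha: float = 0.05
    stay_alpha: float = 0.05
    lasso: LassoConfig = field(default_factory=LassoConfig)
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    cutpoint_min_fraction: float = 0.10
    stratify_band: str = "v30_60"
    merge: tuple[str, ...] | None = None    # explicit merge request, e.g. ("cohort1","cohort2")
    out_dir: str = "results/run"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.mode == "files" and not self.cohort_csv:
            raise ValueError("files mode needs cohort_csv")
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if isinstance(self.lasso, dict):
            self.lasso = LassoConfig(**self.lasso)
        if self.merge is not None:
            self.merge = tuple(self.merge)
        self.candidates = tuple(self.candidates)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _obtain_cohort(config: RunConfig) -> tuple[list[PatientRecord], dict]:
    if config.mode == "files":
        return load_cohort(config.cohort_csv), {"source": config.cohort_csv}
    sim = config.sim or SimConfig()
    sim = sim.replace(seed=derive_seed(config.seed, "simulate"),
                      horizon_months=config.horizon_months)
    cohort, truth = generate_cohort(sim)
    return cohort, {"source": "synthetic", "sim": dataclasses.asdict(sim),
                    "truth": dataclasses.asdict(truth)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in analysis order and write all artifacts.

    Returns the run report (also written as ``manifest.json``); any stage
    failure raises with the stage name after flushing partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items() if k != "sim"},
            "sim": dataclasses.asdict(config.sim) if config.sim else None,
        },
        "stages": {},
    }
    stage = "cohort"
    try:
        cohort, provenance = _obtain_cohort(config)
        manifest["stages"]["cohort"] = {**provenance, "n": len(cohort)}

        stage = "endpoint"
        dataset = derive_two_year_endpoint(cohort, config.horizon_months)
        manifest["stages"]["endpoint"] = {
            "horizon_months": config.horizon_months,
            "n_included": dataset.n,
            "n_excluded": dataset.n_excluded,
            "n_events": dataset.n_events,
            "incidence_pct": 100.0 * dataset.n_events / dataset.n,
        }

        stage = "whole-cohort incidence"
        frame = dataset.frame
        curve = km_cumulative_incidence(frame["time_months"], frame["event"])
        pd.DataFrame({
            "time_months": curve.times,
            "cumulative_incidence": curve.cumulative_incidence,
            "at_risk": curve.at_risk,
        }).to_csv(out / "incidence_whole_cohort.csv", index=False)

        stage = "baseline"
        baseline = [baseline_comparison(dataset, v) for v in _BASELINE_VARS]
        pd.DataFrame(
            [{"variable": b.variable, "test": b.test, "statistic": b.statistic,
              "p_value": b.p_value} for b in baseline]
        ).to_csv(out / "baseline_table.csv", index=False)

        stage = "spearman"
        spearman_matrix(dataset, _SELECTION_PREDICTORS).to_csv(out / "spearman_matrix.csv")

        stage = "univariate"
        uni_step, uni_fits = univariate_screen(dataset, _SELECTION_PREDICTORS, config.alpha)
        manifest["stages"]["univariate"] = {"alpha": config.alpha,
                                            "flagged": list(uni_step.selected)}

        stage = "lasso"
        lasso_cfg = dataclasses.replace(
            config.lasso, fold_seed=derive_seed(config.seed, "lasso-folds"))
        lasso_sel, lasso_step = lasso_select(dataset, _SELECTION_PREDICTORS, lasso_cfg)
        lasso_fit = fit_logistic(dataset, lasso_sel) if lasso_sel else None
        manifest["stages"]["lasso"] = {"selected": list(lasso_sel), **lasso_step.detail}

        stage = "backward"
        if lasso_sel:
            final_fit, trace = backward_eliminate(dataset, lasso_sel, config.stay_alpha)
        else:
            final_fit, trace = None, None
        manifest["stages"]["backward"] = {
            "stay_alpha": config.stay_alpha,
            "survivors": list(final_fit.predictors) if final_fit else [],
            "trace": [dataclasses.asdict(s) for s in trace.steps] if trace else [],
        }
        report = selection_report(uni_fits, lasso_sel, lasso_fit, final_fit)
        report.to_csv(out / "selection_table.csv", index=False)

        stage = "candidate-auc"
        cand = compare_candidates(dataset, candidates=config.candidates)
        cand.table().to_csv(out / "candidate_models.csv", index=False)
        manifest["stages"]["candidate_auc"] = {
            "winner": cand.winner,
            "tied": list(cand.tied),
            "auc": {k: v.auc for k, v in cand.aucs.items()},
            "ci_method": "delong",
        }

        stage = "cutpoints"
        cuts = {}
        for var in ("volume_cm3", config.stratify_band):
            res = minp_cutpoint(
                frame[var].to_numpy(float),
                frame["ht_within_2y"].to_numpy(bool),
                min_fraction=config.cutpoint_min_fraction,
            )
            cuts[var] = res
        manifest["stages"]["cutpoints"] = {
            var: {"cutoff": r.cutoff, "chi2": r.statistic, "p_raw": r.p_raw,
                  "p_corrected": r.p_corrected, "correction": "miller-siegmund",
                  "min_fraction": config.cutpoint_min_fraction}
            for var, r in cuts.items()
        }

        stage = "stratify"
        summary = stratify(dataset, cuts["volume_cm3"].cutoff,
                           cuts[config.stratify_band].cutoff, band=config.stratify_band)
        if config.merge:
            summary = merge_strata(summary, config.merge)
        summary.table().to_csv(out / "strata.csv", index=False)
        manifest["stages"]["stratify"] = {
            "volume_cut": summary.volume_cut,
            "band_cut": summary.band_cut,
            "strata": summary.table().to_dict(orient="records"),
        }

        stage = "strata-curves"
        curves, pairwise = strata_incidence_curves(cohort, summary)
        rows = []
        for label, c in curves.items():
            for t, ci, ar in zip(c.times, c.cumulative_incidence, c.at_risk):
                rows.append({"stratum": label, "time_months": t,
                             "cumulative_incidence": ci, "at_risk": ar})
        pd.DataFrame(rows).to_csv(out / "strata_incidence_curves.csv", index=False)
        pairwise.to_csv(out / "strata_logrank.csv", index=False)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_json(out / "manifest.json", manifest)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    _write_json(out / "manifest.json", manifest)
    return manifest


def validate_against_fixture() -> dict:
    """Check stratify/merge arithmetic against the published reference counts.

    Builds the row-level counts dataset, stratifies at the published cuts,
    merges the two low-risk cohorts, and compares every one-decimal
    incidence percentage and the totals with the published values.
    """
    dataset = reference_counts_dataset()
    summary = stratify(dataset, REFERENCE_CUTS["volume_cm3"], REFERENCE_CUTS["v30_60"])
    merged = merge_strata(summary, ("cohort1", "cohort2"))
    observed = {s.label: round(s.incidence_pct, 1) for s in summary.strata}
    observed["cohort1+cohort2"] = round(
        next(s for s in merged.strata if s.label == "cohort1+cohort2").incidence_pct, 1
    )
    observed["overall"] = round(100.0 * summary.total_events / summary.total_n, 1)
    failures = {
        key: {"expected": exp, "observed": observed.get(key)}
        for key, exp in EXPECTED_INCIDENCE_PCT.items()
        if observed.get(key) != exp
    }
    totals_ok = summary.total_n == sum(n for n, _ in REFERENCE_COUNTS.values()) == 545
    events_ok = summary.total_events == sum(e for _, e in REFERENCE_COUNTS.values()) == 138
    return {
        "passed": not failures and totals_ok and events_ok,
        "observed_incidence_pct": observed,
        "expected_incidence_pct": EXPECTED_INCIDENCE_PCT,
        "failures": failures,
        "total_n": summary.total_n,
        "total_events": summary.total_events,
    }
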