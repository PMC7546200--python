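"""Patient records, the fixed-horizon hypothyroidism endpoint, and survival summaries.

The primary endpoint is biochemical hypothyroidism (first TSH elevation)
within a fixed horizon after the end of radiotherapy, default 24 months.
Patients censored strictly before the horizon carry no information about the
binary endpoint and are excluded (and counted); an event at exactly the
horizon counts as within it, and censoring at exactly the horizon is
retained.  Death is treated as censoring throughout — cumulative incidence
here means 1 minus the Kaplan-Meier survivor function, not a competing-risk
estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .dvh import DVHCurve, ThyroidDosimetry, dosimetry_from_curve, read_dvh_table

__all__ = [
    "SEXES",
    "T_STAGES",
    "N_STAGES",
    "OVERALL_STAGES",
    "PatientRecord",
    "TwoYearDataset",
    "IncidenceCurve",
    "BaselineTest",
    "derive_two_year_endpoint",
    "km_cumulative_incidence",
    "logrank_test",
    "baseline_comparison",
    "spearman_matrix",
    "load_cohort",
    "save_cohort",
]

SEXES = ("male", "female")
T_STAGES = ("T1-2", "T3-4")
N_STAGES = ("N0-1", "N2-3")
OVERALL_STAGES = ("I-II", "III-IVA")

#: dosimetry columns exposed on the analysis frame
DOSIMETRY_COLUMNS = (
    "volume_cm3",
    "v0_10",
    "v10_20",
    "v20_30",
    "v30_40",
    "v40_50",
    "v50_60",
    "v30_60",
    "v40_60",
)

BAND_PREDICTORS = ("v0_10", "v10_20", "v20_30", "v30_40", "v40_50", "v50_60")


@dataclass(frozen=True)
class PatientRecord:
    """One patient: clinical covariates, thyroid dosimetry, time-to-HT outcome."""

    id: str
    age: float
    sex: str
    t_stage: str
    n_stage: str
    overall_stage: str
    chemotherapy: bool
    dosimetry: ThyroidDosimetry
    time_months: float
    event: bool
    curve: "DVHCurve | None" = None  # optional raw curve, kept for file round-trips

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time_months) and self.time_months > 0):
            raise ValueError(f"time_months must be positive, got {self.time_months!r}")
        for val, allowed, name in (
            (self.sex, SEXES, "sex"),
            (self.t_stage, T_STAGES, "t_stage"),
            (self.n_stage, N_STAGES, "n_stage"),
            (self.overall_stage, OVERALL_STAGES, "overall_stage"),
        ):
            if val not in allowed:
                raise ValueError(f"{name} must be one of {allowed}, got {val!r}")


@dataclass
class TwoYearDataset:
    """Analysis table after the censoring-exclusion rule.

    ``frame`` has one row per retained patient with the clinical covariates,
    the dosimetry columns and the binary label ``ht_within_2y``;
    ``n_excluded`` counts the patients censored before the horizon.
    """

    frame: pd.DataFrame
    n_excluded: int
    horizon_months: float = 24.0

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def n_events(self) -> int:
        return int(self.frame["ht_within_2y"].sum())


@dataclass
class IncidenceCurve:
    """Kaplan-Meier cumulative incidence: 1 - S(t) with at-risk counts."""

    times: np.ndarray
    cumulative_incidence: np.ndarray
    at_risk: np.ndarray
    all_censored: bool = False

    def at(self, t: float) -> float:
        """Step-function value of the cumulative incidence at time ``t``."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.cumulative_incidence[idx]) if idx >= 0 else 0.0


@dataclass(frozen=True)
class BaselineTest:
    variable: str
    test: str
    statistic: float
    p_value: float
    summary: dict = field(default_factory=dict)
    degenerate: bool = False


def _record_row(rec: PatientRecord) -> dict:
    d = rec.dosimetry
    return {
        "id": rec.id,
        "age": rec.age,
        "sex": rec.sex,
        "t_stage": rec.t_stage,
        "n_stage": rec.n_stage,
        "overall_stage": rec.overall_stage,
        "chemotherapy": rec.chemotherapy,
        "volume_cm3": d.volume_cm3,
        "v0_10": d.bands.v0_10,
        "v10_20": d.bands.v10_20,
        "v20_30": d.bands.v20_30,
        "v30_40": d.bands.v30_40,
        "v40_50": d.bands.v40_50,
        "v50_60": d.bands.v50_60,
        "v30_60": d.v30_60,
        "v40_60": d.v40_60,
        "time_months": rec.time_months,
        "event": rec.event,
    }


def cohort_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flatten records into one analysis row per patient."""
    return pd.DataFrame([_record_row(r) for r in cohort])


def derive_two_year_endpoint(
    cohort: Sequence[PatientRecord] | pd.DataFrame, horizon_months: float = 24.0
) -> TwoYearDataset:
    """Apply the censoring-exclusion rule and label the fixed-horizon endpoint.

    Patients censored (no event) strictly before ``horizon_months`` are
    dropped and counted in ``n_excluded``; every retained patient gets
    ``ht_within_2y = event and time_months <= horizon``.
    """
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_frame(cohort)
    if len(frame) == 0:
        raise ValueError("empty cohort")
    excluded = (~frame["event"].astype(bool)) & (frame["time_months"] < horizon_months)
    kept = frame.loc[~excluded].copy()
    kept["ht_within_2y"] = kept["event"].astype(bool) & (kept["time_months"] <= horizon_months)
    return TwoYearDataset(
        frame=kept.reset_index(drop=True),
        n_excluded=int(excluded.sum()),
        horizon_months=horizon_months,
    )


def km_cumulative_incidence(
    times: Sequence[float], events: Sequence[bool]
) -> IncidenceCurve:
    """Product-limit cumulative incidence 1 - S(t), censoring-aware."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.shape != events.shape:
        raise ValueError("times and events must have the same length")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    all_censored = not events.any()
    if all_censored:
        warnings.warn("all subjects censored: cumulative incidence is identically 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    t = kmf.survival_function_.index.to_numpy(dtype=float)
    s = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    # at-risk count just before each tabulated time
    at_risk = np.array([(times >= ti).sum() for ti in t])
    return IncidenceCurve(
        times=t, cumulative_incidence=1.0 - s, at_risk=at_risk, all_censored=all_censored
    )


def logrank_test(
    group_a: tuple[Sequence[float], Sequence[bool]],
    group_b: tuple[Sequence[float], Sequence[bool]],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square with 1 df, p-value)."""
    (ta, ea), (tb, eb) = group_a, group_b
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(ta, tb, event_observed_A=np.asarray(ea, bool), event_observed_B=np.asarray(eb, bool))
    return float(res.test_statistic), float(res.p_value)


def baseline_comparison(
    dataset: TwoYearDataset,
    variable: str,
    continuity_correction: bool = False,
) -> BaselineTest:
    """Compare a baseline variable between patients with and without 2-year HT.

    Continuous variables get a Wilcoxon rank-sum (Mann-Whitney) test with
    median (IQR) summaries; categorical variables get a chi-square test of
    the 2 x k contingency table (no continuity correction by default) with
    count (%) summaries.
    """
    frame = dataset.frame
    if variable not in frame.columns:
        raise KeyError(f"unknown variable {variable!r}")
    x = frame[variable]
    y = frame["ht_within_2y"].astype(bool)
    if x.nunique(dropna=True) <= 1:
        warnings.warn(f"variable {variable!r} is constant: degenerate comparison")
        return BaselineTest(variable, "degenerate", np.nan, np.nan, degenerate=True)
    if pd.api.types.is_numeric_dtype(x) and not pd.api.types.is_bool_dtype(x):
        a, b = x[y], x[~y]
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        summary = {
            "with_ht": _median_iqr(a),
            "without_ht": _median_iqr(b),
        }
        return BaselineTest(variable, "rank-sum", float(stat), float(p), summary)
    table = pd.crosstab(x, y)
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=continuity_correction)
    summary = {
        str(level): {
            "with_ht": int(table.loc[level].get(True, 0)),
            "without_ht": int(table.loc[level].get(False, 0)),
        }
        for level in table.index
    }
    return BaselineTest(variable, "chi-square", float(chi2), float(p), summary)


def _median_iqr(x: pd.Series) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"median": float(med), "iqr": (float(q1), float(q3))}


def spearman_matrix(dataset: TwoYearDataset, variables: Sequence[str]) -> pd.DataFrame:
    """Pairwise Spearman rho (midrank ties) between the named columns.

    Constant columns yield NaN (undefined correlation), never 0.
    """
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    sub = dataset.frame[list(variables)].astype(float)
    out = sub.corr(method="spearman")
    np.fill_diagonal(out.values, 1.0)
    for v in variables:
        if sub[v].nunique() <= 1:
            out.loc[v, :] = np.nan
            out.loc[:, v] = np.nan
    return out


# ---------------------------------------------------------------------------
# cohort file round-trip (manifest CSV + per-patient DVH tables)

def save_cohort(cohort: Sequence[PatientRecord], out_dir: str | Path) -> Path:
    """Write ``cohort.csv`` plus one DVH table per patient under ``dvh/``.

    The manifest columns are: id, age, sex, t_stage, n_stage, overall_stage,
    chemotherapy, thyroid_volume_cm3, dvh_path, time_months, event.
    """
    from .dvh import write_dvh_table  # local import to keep module load light

    out_dir = Path(out_dir)
    dvh_dir = out_dir / "dvh"
    dvh_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        rel = f"dvh/{rec.id}.csv"
        if rec.curve is None:
            raise ValueError(f"record {rec.id} carries no DVH curve to write")
        write_dvh_table(rec.curve, out_dir / rel)
        rows.append(
            {
                "id": rec.id,
                "age": rec.age,
                "sex": rec.sex,
                "t_stage": rec.t_stage,
                "n_stage": rec.n_stage,
                "overall_stage": rec.overall_stage,
                "chemotherapy": rec.chemotherapy,
                "thyroid_volume_cm3": rec.dosimetry.volume_cm3,
                "dvh_path": rel,
                "time_months": rec.time_months,
                "event": rec.event,
            }
        )
    manifest = out_dir / "cohort.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_csv: str | Path) -> list[PatientRecord]:
    """Read a cohort manifest and the per-patient DVH tables it points to."""
    manifest_csv = Path(manifest_csv)
    base = manifest_csv.parent
    frame = pd.read_csv(manifest_csv)
    records = []
    for row in frame.itertuples(index=False):
        curve = read_dvh_table(base / row.dvh_path)
        records.append(
            PatientRecord(
                id=str(row.id),
                age=float(row.age),
                sex=str(row.sex),
                t_stage=str(row.t_stage),
                n_stage=str(row.n_stage),
                overall_stage=str(row.overall_stage),
                chemotherapy=bool(row.chemotherapy),
                dosimetry=dosimetry_from_curve(curve, float(row.thyroid_volume_cm3)),
                time_months=float(row.time_months),
                event=bool(row.event),
                curve=curve,
            )
        )
    return records


def iter_ids(cohort: Iterable[PatientRecord]) -> list[str]:
    return [r.id for r in cohort]
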