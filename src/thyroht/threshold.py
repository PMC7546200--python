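"""Threshold-dose inference by candidate-model AUC comparison.

The damage model assumes thyroid follicles are destroyed above some
threshold dose, so the volume fraction irradiated above that threshold (and
below the top of the clinical dose range) should be the best companion to
absolute thyroid volume in a two-variable logistic model.  Candidate
aggregate bands (V_40,50, V_30,60, V_40,60) are substituted into the model
and compared by the area under the ROC curve of the fitted linear
predictor; the winner localizes the threshold.

AUC is computed from the midrank (Mann-Whitney) statistic and its 95%
interval by the DeLong structural-components variance; both are computed
in-sample, matching a single-cohort analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .cohort import TwoYearDataset, derive_two_year_endpoint
from .dvh import ThyroidDosimetry
from .selection import ModelFit, fit_logistic
from .simulate import SimConfig, generate_cohort

__all__ = [
    "AUCResult",
    "CandidateModelSet",
    "aggregate_band",
    "delong_auc",
    "auc_of_model",
    "compare_candidates",
    "threshold_recovery_experiment",
    "DEFAULT_CANDIDATES",
]

#: the three candidate aggregate bands, in reporting order
DEFAULT_CANDIDATES = ("v40_50", "v30_60", "v40_60")

_VX_GRID = (10, 20, 30, 40, 50, 60)


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    method: str = "delong"

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.auc <= self.ci_high <= 1.0):
            raise ValueError(f"inconsistent AUC interval {self}")


@dataclass
class CandidateModelSet:
    """Per-candidate fits and AUCs on identical rows, with the argmax marked."""

    fits: dict[str, ModelFit]
    aucs: dict[str, AUCResult]
    winner: str
    tied: tuple[str, ...] = ()
    failures: dict[str, str] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for name, fit in self.fits.items():
            a = self.aucs[name]
            rows.append(
                {
                    "model": f"volume_cm3 + {name}",
                    "band": name,
                    "or_volume": fit.odds_ratio["volume_cm3"],
                    "or_band": fit.odds_ratio[name],
                    "auc": a.auc,
                    "auc_ci_low": a.ci_low,
                    "auc_ci_high": a.ci_high,
                    "winner": name == self.winner,
                }
            )
        return pd.DataFrame(rows)


def aggregate_band(dosimetry: ThyroidDosimetry, lo: int, hi: int) -> float:
    """V_lo,hi = V_lo - V_hi on the 10-Gy grid; equals the sum of its 10-Gy bands."""
    if lo >= hi:
        raise ValueError(f"need lo < hi, got ({lo}, {hi})")
    if lo not in _VX_GRID or hi not in _VX_GRID:
        raise ValueError(f"bounds must lie on the grid {_VX_GRID}")
    vx = dict(zip(_VX_GRID, dosimetry.vx.as_tuple()))
    return float(vx[lo] - vx[hi])


def delong_auc(scores: Sequence[float], labels: Sequence[bool]) -> AUCResult:
    """Midrank AUC of ``scores`` for ``labels`` with a DeLong 95% CI.

    The point estimate is the Mann-Whitney statistic (ties counted half);
    the variance sums the empirical variances of the case and control
    structural components.  Degenerate variance (perfect separation or a
    constant score) collapses the interval onto the estimate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    m, n = int(labels.sum()), int((~labels).sum())
    if m == 0 or n == 0:
        raise ValueError("AUC undefined: one outcome class is empty")
    x, y = scores[labels], scores[~labels]
    all_r = rankdata(scores)  # midranks over the pooled sample
    rx, ry = rankdata(x), rankdata(y)
    v10 = (all_r[labels] - rx) / n          # case components P(Y < x) + ties/2
    v01 = 1.0 - (all_r[~labels] - ry) / m   # control components
    auc = float(v10.mean())
    var = 0.0
    if m > 1:
        var += float(np.var(v10, ddof=1)) / m
    if n > 1:
        var += float(np.var(v01, ddof=1)) / n
    half = _Z975 * np.sqrt(max(var, 0.0))
    return AUCResult(
        auc=auc,
        ci_low=float(np.clip(auc - half, 0.0, auc)),
        ci_high=float(np.clip(auc + half, auc, 1.0)),
    )


_Z975 = float(norm.ppf(0.975))


def auc_of_model(fit: ModelFit, dataset: TwoYearDataset) -> AUCResult:
    """In-sample AUC of the fitted linear predictor against the 2-year label."""
    y = dataset.frame["ht_within_2y"].astype(bool).to_numpy()
    if len(fit.linear_predictor) != len(y):
        raise ValueError("fit and dataset have different row counts")
    return delong_auc(fit.linear_predictor, y)


def compare_candidates(
    dataset: TwoYearDataset,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    volume: str = "volume_cm3",
    tie_tol: float = 1e-12,
) -> CandidateModelSet:
    """Fit volume + each candidate band on identical rows and rank by AUC.

    Ties within ``tie_tol`` of the maximum are reported, never silently
    broken; individual fit failures leave a failure record and the set is
    ranked over the models that did fit.
    """
    fits: dict[str, ModelFit] = {}
    aucs: dict[str, AUCResult] = {}
    failures: dict[str, str] = {}
    for band in candidates:
        try:
            fit = fit_logistic(dataset, [volume, band])
            fits[band] = fit
            aucs[band] = auc_of_model(fit, dataset)
        except Exception as exc:  # noqa: BLE001 - failures are data, not fatal
            failures[band] = str(exc)
    if not aucs:
        raise RuntimeError(f"no candidate model could be fitted: {failures}")
    best = max(aucs.values(), key=lambda a: a.auc).auc
    tied = tuple(b for b, a in aucs.items() if best - a.auc <= tie_tol)
    winner = tied[0] if len(tied) == 1 else max(tied)  # deterministic on real ties
    return CandidateModelSet(fits=fits, aucs=aucs, winner=winner,
                             tied=tied if len(tied) > 1 else (), failures=failures)


def threshold_recovery_experiment(
    config: SimConfig,
    replicates: int,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
) -> pd.DataFrame:
    """Win fractions and mean AUCs of the candidate models over replicates.

    Each replicate generates a fresh cohort (seed offset from
    ``config.seed``), derives the 2-year endpoint and runs the candidate
    comparison.  Returns one row per candidate with win counts, win
    fractions, binomial Monte-Carlo SEs, and mean AUC with its MC SE.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    wins = {c: 0 for c in candidates}
    auc_samples: dict[str, list[float]] = {c: [] for c in candidates}
    for rep in range(replicates):
        cohort, _ = generate_cohort(config.replace(seed=int(config.seed) + rep))
        dataset = derive_two_year_endpoint(cohort, config.horizon_months)
        result = compare_candidates(dataset, candidates=candidates)
        wins[result.winner] += 1
        for c in candidates:
            if c in result.aucs:
                auc_samples[c].append(result.aucs[c].auc)
    rows = []
    for c in candidates:
        frac = wins[c] / replicates
        aucs = np.array(auc_samples[c])
        rows.append(
            {
                "candidate": c,
                "wins": wins[c],
                "win_fraction": frac,
                "win_mc_se": float(np.sqrt(frac * (1 - frac) / replicates)),
                "mean_auc": float(aucs.mean()) if aucs.size else float("nan"),
                "auc_mc_se": float(aucs.std(ddof=1) / np.sqrt(aucs.size)) if aucs.size > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
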