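"""Predictor selection for the 2-year hypothyroidism endpoint.

The chain mirrors standard clinical-modelling practice for dose-band
predictors: unadjusted univariate logistic screening, L1-penalized (LASSO)
selection over the standardized predictors with a cross-validated penalty,
and a multivariate logistic model pruned by backward elimination on Wald
p-values.  Odds ratios are reported per stated increment (per cm^3 for
thyroid volume, per 10% for dose bands) with Wald 95% intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .cohort import TwoYearDataset

__all__ = [
    "ModelFit",
    "SelectionStep",
    "SelectionTrace",
    "LassoConfig",
    "SeparationError",
    "fit_logistic",
    "univariate_screen",
    "lasso_select",
    "backward_eliminate",
    "selection_report",
]

#: default reporting increments: volume per cm^3, every band per 10 percentage points
DEFAULT_INCREMENTS = {"volume_cm3": 1.0}
_Z975 = float(norm.ppf(0.975))


class SeparationError(RuntimeError):
    """The likelihood is degenerate (perfect or quasi-perfect separation)."""


class ConvergenceError(RuntimeError):
    pass


@dataclass
class ModelFit:
    """A fitted logistic model with increment-scaled odds-ratio reporting."""

    predictors: tuple[str, ...]
    coef: dict[str, float]            # log-odds per original unit
    intercept: float
    increments: dict[str, float]
    odds_ratio: dict[str, float]      # per stated increment
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p_values: dict[str, float]
    log_likelihood: float
    linear_predictor: np.ndarray
    converged: bool = True

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "predictor": p,
                "increment": self.increments.get(p, 1.0),
                "odds_ratio": self.odds_ratio[p],
                "ci_low": self.ci_low[p],
                "ci_high": self.ci_high[p],
                "p_value": self.p_values[p],
            }
            for p in self.predictors
        ]
        return pd.DataFrame(rows)


@dataclass
class SelectionStep:
    name: str
    candidates: tuple[str, ...]
    selected: tuple[str, ...]
    detail: dict = field(default_factory=dict)


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)

    def add(self, step: SelectionStep) -> None:
        self.steps.append(step)

    @property
    def final_selected(self) -> tuple[str, ...]:
        return self.steps[-1].selected if self.steps else ()


def _design(dataset: TwoYearDataset, predictors: Sequence[str]):
    X = dataset.frame[list(predictors)].astype(float).to_numpy()
    y = dataset.frame["ht_within_2y"].astype(int).to_numpy()
    return X, y


def fit_logistic(
    dataset: TwoYearDataset,
    predictors: Sequence[str],
    increments: Mapping[str, float] | None = None,
    min_events: int = 10,
) -> ModelFit:
    """Maximum-likelihood logistic fit with Wald inference per increment.

    Raises :class:`SeparationError` when the data separate (detected by a
    runaway coefficient) and :class:`ConvergenceError` when the optimizer
    fails to converge.
    """
    predictors = tuple(predictors)
    X, y = _design(dataset, predictors)
    if y.sum() < min_events:
        raise ValueError(f"need at least {min_events} events, got {int(y.sum())}")
    for j, name in enumerate(predictors):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"predictor {name!r} is constant")
    inc = dict(DEFAULT_INCREMENTS)
    for band in predictors:
        inc.setdefault(band, 10.0 if band.startswith("v") else 1.0)
    if increments:
        inc.update(increments)

    exog = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation warnings handled below
            model = sm.Logit(y, exog)
            res = model.fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
        raise SeparationError(
            f"degenerate likelihood for predictors {predictors}: {exc}"
        ) from exc
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    if not np.all(np.isfinite(params)) or np.any(np.abs(params[1:]) > 20):
        worst = predictors[int(np.argmax(np.abs(params[1:])))]
        raise SeparationError(f"(quasi-)perfect separation involving predictor {worst!r}")
    if not res.mle_retvals.get("converged", True):
        raise ConvergenceError(f"logistic fit did not converge: {res.mle_retvals}")

    coef = {p: float(params[j + 1]) for j, p in enumerate(predictors)}
    se = {p: float(bse[j + 1]) for j, p in enumerate(predictors)}
    odds, lo, hi, pv = {}, {}, {}, {}
    for p in predictors:
        c, s, k = coef[p], se[p], inc[p]
        odds[p] = float(np.exp(c * k))
        lo[p] = float(np.exp((c - _Z975 * s) * k))
        hi[p] = float(np.exp((c + _Z975 * s) * k))
        pv[p] = float(2 * norm.sf(abs(c / s))) if s > 0 else float("nan")
    return ModelFit(
        predictors=predictors,
        coef=coef,
        intercept=float(params[0]),
        increments={p: inc[p] for p in predictors},
        odds_ratio=odds,
        ci_low=lo,
        ci_high=hi,
        p_values=pv,
        log_likelihood=float(res.llf),
        linear_predictor=np.asarray(exog @ params, dtype=float),
        converged=True,
    )


def univariate_screen(
    dataset: TwoYearDataset,
    predictors: Sequence[str],
    alpha: float = 0.05,
    increments: Mapping[str, float] | None = None,
) -> tuple[SelectionStep, dict[str, ModelFit]]:
    """One single-predictor logistic fit per candidate; flag Wald p < alpha.

    Per-predictor fit failures are recorded in the step detail, not raised.
    """
    fits: dict[str, ModelFit] = {}
    errors: dict[str, str] = {}
    flagged = []
    for p in predictors:
        try:
            fit = fit_logistic(dataset, [p], increments=increments)
        except (ValueError, SeparationError, ConvergenceError) as exc:
            errors[p] = str(exc)
            continue
        fits[p] = fit
        if fit.p_values[p] < alpha:
            flagged.append(p)
    step = SelectionStep(
        name="univariate-screen",
        candidates=tuple(predictors),
        selected=tuple(flagged),
        detail={"alpha": alpha, "errors": errors,
                "p_values": {p: f.p_values[p] for p, f in fits.items()}},
    )
    return step, fits


@dataclass(frozen=True)
class LassoConfig:
    """Penalty settings for L1-penalized logistic selection.

    ``penalty`` fixes the glmnet-style lambda (objective: mean deviance +
    lambda * ||beta||_1 on standardized predictors); ``None`` selects it by
    k-fold cross-validated deviance with a fixed fold seed.  ``rule`` is
    ``"min"`` (lambda at minimum mean CV deviance) or ``"1se"``.
    """

    penalty: float | None = None
    k_folds: int = 10
    fold_seed: int = 1234
    rule: str = "min"
    n_lambdas: int = 60
    coef_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.rule not in ("min", "1se"):
            raise ValueError("rule must be 'min' or '1se'")


def _l1_fit(Xs: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Standardized-scale L1 logistic coefficients at glmnet-style lambda."""
    if lam <= 0:
        clf = LogisticRegression(C=np.inf, max_iter=2000)
    else:
        C = 1.0 / (lam * len(y))
        clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                 max_iter=2000, random_state=0)
    clf.fit(Xs, y)
    return clf.coef_[0]


def _mean_deviance(Xs, y, lam, train, test) -> float:
    if lam <= 0:
        clf = LogisticRegression(C=np.inf, max_iter=2000)
    else:
        clf = LogisticRegression(l1_ratio=1.0, C=1.0 / (lam * len(train)),
                                 solver="liblinear", max_iter=2000, random_state=0)
    clf.fit(Xs[train], y[train])
    p = np.clip(clf.predict_proba(Xs[test])[:, 1], 1e-12, 1 - 1e-12)
    return float(-2 * np.mean(y[test] * np.log(p) + (1 - y[test]) * np.log(1 - p)))


def lasso_select(
    dataset: TwoYearDataset,
    predictors: Sequence[str],
    config: LassoConfig = LassoConfig(),
) -> tuple[tuple[str, ...], SelectionStep]:
    """Names with nonzero coefficients at the chosen L1 penalty.

    Predictors are standardized (mean 0, sd 1) internally before
    penalization; an all-zero solution returns an empty set, which is a
    valid outcome rather than an error.
    """
    predictors = tuple(predictors)
    if not predictors:
        return (), SelectionStep("lasso", (), (), {"note": "no candidates"})
    X, y = _design(dataset, predictors)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    if np.any(sd == 0):
        bad = predictors[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"predictor {bad!r} is constant")
    Xs = (X - mu) / sd

    detail: dict = {"rule": config.rule, "k_folds": config.k_folds}
    if config.penalty is not None:
        lam = float(config.penalty)
        detail["penalty"] = lam
    else:
        # glmnet-style path: lambda_max kills every coefficient, descend by
        # factors to lambda_max / 1000
        lam_max = float(np.max(np.abs(Xs.T @ (y - y.mean()))) / len(y))
        lams = np.geomspace(lam_max, lam_max / 1000.0, config.n_lambdas)
        folds = list(
            StratifiedKFold(config.k_folds, shuffle=True,
                            random_state=config.fold_seed).split(Xs, y)
        )
        dev = np.array([[_mean_deviance(Xs, y, l, tr, te) for (tr, te) in folds] for l in lams])
        mean_dev, se_dev = dev.mean(axis=1), dev.std(axis=1, ddof=1) / np.sqrt(config.k_folds)
        i_min = int(np.argmin(mean_dev))
        if config.rule == "1se":
            ok = np.flatnonzero(mean_dev <= mean_dev[i_min] + se_dev[i_min])
            i_choice = int(ok[0])  # lams descend, so the first is the largest penalty
        else:
            i_choice = i_min
        lam = float(lams[i_choice])
        detail.update(penalty=lam, cv_mean_deviance=float(mean_dev[i_choice]),
                      lambda_grid=(float(lams[0]), float(lams[-1])))

    if np.isinf(lam):
        coefs = np.zeros(len(predictors))
    else:
        coefs = _l1_fit(Xs, y, lam)
    selected = tuple(p for p, c in zip(predictors, coefs) if abs(c) > config.coef_tol)
    detail["standardized_coef"] = {p: float(c) for p, c in zip(predictors, coefs)}
    return selected, SelectionStep("lasso", predictors, selected, detail)


def backward_eliminate(
    dataset: TwoYearDataset,
    predictors: Sequence[str],
    stay_alpha: float = 0.05,
    increments: Mapping[str, float] | None = None,
) -> tuple[ModelFit | None, SelectionTrace]:
    """Iteratively drop the largest-p predictor at or above ``stay_alpha``.

    Ties break toward the larger p, then the lexically larger name.  Returns
    the final fit (None when every predictor is eliminated) and the full
    trace of strictly nested candidate sets.
    """
    current = list(predictors)
    trace = SelectionTrace()
    fit: ModelFit | None = None
    while current:
        try:
            fit = fit_logistic(dataset, current, increments=increments)
        except (ValueError, SeparationError, ConvergenceError) as exc:
            trace.add(SelectionStep("backward-abort", tuple(current), tuple(current),
                                    {"error": str(exc)}))
            raise
        worst = max(current, key=lambda p: (fit.p_values[p], p))
        if fit.p_values[worst] < stay_alpha:
            trace.add(SelectionStep("backward-final", tuple(current), tuple(current),
                                    {"p_values": dict(fit.p_values)}))
            return fit, trace
        current.remove(worst)
        trace.add(SelectionStep("backward-drop", tuple(current) + (worst,), tuple(current),
                                {"dropped": worst, "p": fit.p_values[worst]}))
    trace.add(SelectionStep("backward-final", (), (), {"note": "all predictors eliminated"}))
    return None, trace


def selection_report(
    univariate_fits: Mapping[str, ModelFit],
    lasso_selected: Sequence[str],
    lasso_fit: ModelFit | None,
    final_fit: ModelFit | None,
) -> pd.DataFrame:
    """Three-column report: univariate, LASSO-multivariate, backward survivors."""
    rows = []
    for p, fit in univariate_fits.items():
        row = {
            "predictor": p,
            "uni_or": fit.odds_ratio[p],
            "uni_ci": (fit.ci_low[p], fit.ci_high[p]),
            "uni_p": fit.p_values[p],
        }
        if lasso_fit is not None and p in lasso_fit.predictors:
            row.update(multi_or=lasso_fit.odds_ratio[p],
                       multi_ci=(lasso_fit.ci_low[p], lasso_fit.ci_high[p]),
                       multi_p=lasso_fit.p_values[p])
        if final_fit is not None and p in final_fit.predictors:
            row.update(final_or=final_fit.odds_ratio[p],
                       final_ci=(final_fit.ci_low[p], final_fit.ci_high[p]),
                       final_p=final_fit.p_values[p])
        rows.append(row)
    return pd.DataFrame(rows)
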