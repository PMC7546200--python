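"""Select hypothyroidism predictors: univariate screen -> LASSO -> backward.

Runs the full selection chain over thyroid volume and the six disjoint
dose bands, and writes the three-column selection report (univariate ORs,
LASSO-multivariate fit, backward-elimination survivors).

Run:  python analysis/03_select_predictors.py [--seed 11] [--out results/analysis]
"""

import argparse
from pathlib import Path

from thyroht.cohort import BAND_PREDICTORS, derive_two_year_endpoint
from thyroht.pipeline import derive_seed
from thyroht.selection import (
    LassoConfig,
    backward_eliminate,
    fit_logistic,
    lasso_select,
    selection_report,
    univariate_screen,
)
from thyroht.simulate import SimConfig, generate_cohort

PREDICTORS = ("volume_cm3",) + BAND_PREDICTORS


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    cohort, _ = generate_cohort(SimConfig(n=545, seed=derive_seed(args.seed, "simulate")))
    dataset = derive_two_year_endpoint(cohort)

    uni_step, uni_fits = univariate_screen(dataset, PREDICTORS)
    print(f"univariate p<0.05: {list(uni_step.selected)}")

    lasso_cfg = LassoConfig(fold_seed=derive_seed(args.seed, "lasso-folds"))
    selected, lasso_step = lasso_select(dataset, PREDICTORS, lasso_cfg)
    print(f"LASSO (min-CV-deviance lambda {lasso_step.detail['penalty']:.4g}): "
          f"{list(selected)}")
    lasso_fit = fit_logistic(dataset, selected) if selected else None

    final_fit, trace = backward_eliminate(dataset, selected) if selected else (None, None)
    survivors = list(final_fit.predictors) if final_fit else []
    print(f"backward-elimination survivors: {survivors}")
    if final_fit:
        for p in final_fit.predictors:
            print(f"  {p}: OR {final_fit.odds_ratio[p]:.3f} "
                  f"({final_fit.ci_low[p]:.3f}-{final_fit.ci_high[p]:.3f}) "
                  f"per {final_fit.increments[p]:g} unit, p={final_fit.p_values[p]:.4f}")

    table = selection_report(uni_fits, selected, lasso_fit, final_fit)
    (args.out / "tables").mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "tables" / "selection_report.csv", index=False)


if __name__ == "__main__":
    main()
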