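"""Minimum-p-value cutpoint search and four-cohort risk stratification.

A continuous marker (thyroid volume, or an aggregate dose band) is
dichotomized at the candidate cut whose 2 x 2 association with the 2-year
hypothyroidism endpoint has the smallest chi-square p-value — the approach
popularized by outcome-based cutoff tools.  The scanned minimum p is
anti-conservative, so the Miller-Siegmund corrected p is reported alongside
it.  The joint stratification crosses the volume cut with the dose-band
cut into four cohorts; similarly-behaving cohorts can be merged explicitly
by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    IncidenceCurve,
    PatientRecord,
    TwoYearDataset,
    km_cumulative_incidence,
    logrank_test,
)

__all__ = [
    "CutpointResult",
    "RiskStratum",
    "StratifiedSummary",
    "minp_cutpoint",
    "miller_siegmund_p",
    "stratify",
    "merge_strata",
    "strata_incidence_curves",
]


@dataclass(frozen=True)
class CutpointResult:
    variable: str
    cutoff: float
    statistic: float
    p_raw: float
    p_corrected: float
    grid: np.ndarray

    def __post_init__(self) -> None:
        if self.p_corrected < self.p_raw - 1e-12:
            raise ValueError("corrected p must not be below the raw minimum p")


@dataclass(frozen=True)
class RiskStratum:
    label: str
    rule: str
    n: int
    events: int
    merged_from: tuple[str, ...] = ()

    @property
    def incidence_pct(self) -> float:
        """Exact percentage; NaN for an empty stratum (undefined incidence)."""
        return 100.0 * self.events / self.n if self.n > 0 else float("nan")


@dataclass
class StratifiedSummary:
    strata: list[RiskStratum]
    volume_cut: float
    band_cut: float
    band: str = "v30_60"

    @property
    def total_n(self) -> int:
        return sum(s.n for s in self.strata)

    @property
    def total_events(self) -> int:
        return sum(s.events for s in self.strata)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": s.label,
                    "rule": s.rule,
                    "n": s.n,
                    "events": s.events,
                    "incidence_pct": s.incidence_pct,
                    "merged_from": ",".join(s.merged_from),
                }
                for s in self.strata
            ]
        )


def miller_siegmund_p(z: float, eps_low: float, eps_high: float) -> float:
    """Corrected p for the maximum of a scanned standardized statistic.

    Approximates P(sup |B(t)|/sqrt(t(1-t)) > z) over the scanned quantile
    window (eps_low, eps_high).  Below z = 1 the asymptotic expression is
    meaningless and the corrected p is reported as 1.
    """
    if not 0 < eps_low < eps_high < 1:
        raise ValueError("need 0 < eps_low < eps_high < 1")
    if z <= 1.0:
        return 1.0
    phi = stats.norm.pdf(z)
    span = np.log(eps_high * (1 - eps_low) / (eps_low * (1 - eps_high)))
    p = phi * (z - 1.0 / z) * span + 4.0 * phi / z
    return float(min(1.0, p))


def _chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square of the 2x2 table [[a, b], [c, d]], no correction."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)


def minp_cutpoint(
    values: Sequence[float],
    outcome: Sequence[bool],
    min_fraction: float = 0.10,
    min_subjects: int = 20,
) -> CutpointResult:
    """Exhaustive minimum-p scan over the distinct observed values.

    Candidate cuts dichotomize as (<= cut) vs (> cut); cuts leaving fewer
    than ``min_fraction`` of subjects on either side are excluded.  The cut
    with the smallest chi-square p-value wins (ties broken toward the
    smallest cut); the Miller-Siegmund adjustment over the scanned quantile
    window is reported as the corrected p.
    """
    values = np.asarray(values, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    if values.shape != outcome.shape:
        raise ValueError("values and outcome must align")
    n = values.size
    if n < min_subjects:
        raise ValueError(f"need at least {min_subjects} subjects, got {n}")
    if not outcome.any() or outcome.all():
        raise ValueError("both outcome classes must be present")
    if np.ptp(values) == 0:
        raise ValueError("constant marker: no admissible cut")

    order = np.argsort(values, kind="mergesort")
    v_sorted, y_sorted = values[order], outcome[order]
    distinct, last_idx = np.unique(v_sorted, return_index=True)
    # cumulative events/counts up to and including each distinct value
    counts = np.searchsorted(v_sorted, distinct, side="right")
    cum_events = np.cumsum(y_sorted)[counts - 1]
    total_events = int(outcome.sum())

    lo_n = int(np.ceil(min_fraction * n))
    admissible = (counts >= lo_n) & ((n - counts) >= lo_n)
    grid = distinct[admissible]
    if grid.size == 0:
        raise ValueError("no admissible cut satisfies the group-size constraint")

    best = None
    for cut, n_low, e_low in zip(grid, counts[admissible], cum_events[admissible]):
        a, b = int(e_low), int(n_low - e_low)            # <= cut: events, non-events
        c, d = total_events - a, (n - n_low) - (total_events - a)
        chi2 = _chi2_2x2(a, b, c, d)
        p = float(stats.chi2.sf(chi2, df=1))
        if best is None or p < best[1] - 1e-15:
            best = (float(cut), p, float(chi2))
    cut, p_raw, chi2 = best
    p_corr = max(
        p_raw,
        miller_siegmund_p(float(np.sqrt(chi2)), min_fraction, 1.0 - min_fraction),
    )
    return CutpointResult(
        variable="", cutoff=cut, statistic=chi2, p_raw=p_raw, p_corrected=p_corr, grid=grid
    )


_STRATUM_DEFS = (
    ("cohort1", "volume > {v:.4g} & {b} <= {c:.4g}", lambda vol, band, vc, bc: (vol > vc) & (band <= bc)),
    ("cohort2", "volume > {v:.4g} & {b} > {c:.4g}", lambda vol, band, vc, bc: (vol > vc) & (band > bc)),
    ("cohort3", "volume <= {v:.4g} & {b} <= {c:.4g}", lambda vol, band, vc, bc: (vol <= vc) & (band <= bc)),
    ("cohort4", "volume <= {v:.4g} & {b} > {c:.4g}", lambda vol, band, vc, bc: (vol <= vc) & (band > bc)),
)


def stratify(
    dataset: TwoYearDataset,
    volume_cut: float,
    band_cut: float,
    band: str = "v30_60",
) -> StratifiedSummary:
    """Four strata from the volume cut crossed with the dose-band cut.

    Boundary values go to the "<=" side of each rule.  Empty strata are
    retained with n = 0 and undefined (NaN) incidence.
    """
    if not (np.isfinite(volume_cut) and np.isfinite(band_cut)):
        raise ValueError("cuts must be finite")
    frame = dataset.frame
    if len(frame) == 0:
        raise ValueError("empty dataset")
    vol = frame["volume_cm3"].to_numpy(dtype=float)
    bnd = frame[band].to_numpy(dtype=float)
    y = frame["ht_within_2y"].to_numpy(dtype=bool)
    strata = []
    for label, rule, mask_fn in _STRATUM_DEFS:
        mask = mask_fn(vol, bnd, volume_cut, band_cut)
        strata.append(
            RiskStratum(
                label=label,
                rule=rule.format(v=volume_cut, b=band, c=band_cut),
                n=int(mask.sum()),
                events=int(y[mask].sum()),
            )
        )
    return StratifiedSummary(strata=strata, volume_cut=volume_cut, band_cut=band_cut, band=band)


def merge_strata(summary: StratifiedSummary, labels: Sequence[str]) -> StratifiedSummary:
    """Pool the named strata into one, recording the merge provenance."""
    labels = tuple(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 strata to merge")
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate labels in merge request: {labels}")
    by_label = {s.label: s for s in summary.strata}
    unknown = [l for l in labels if l not in by_label]
    if unknown:
        raise KeyError(f"unknown strata {unknown}")
    pooled = RiskStratum(
        label="+".join(labels),
        rule=" | ".join(by_label[l].rule for l in labels),
        n=sum(by_label[l].n for l in labels),
        events=sum(by_label[l].events for l in labels),
        merged_from=labels,
    )
    kept = [s for s in summary.strata if s.label not in labels]
    first_pos = min(i for i, s in enumerate(summary.strata) if s.label in labels)
    kept.insert(min(first_pos, len(kept)), pooled)
    return StratifiedSummary(
        strata=kept,
        volume_cut=summary.volume_cut,
        band_cut=summary.band_cut,
        band=summary.band,
    )


def _assign_stratum(summary: StratifiedSummary, vol: float, band_val: float) -> str:
    base = None
    for label, _, mask_fn in _STRATUM_DEFS:
        if mask_fn(np.array(vol), np.array(band_val), summary.volume_cut, summary.band_cut):
            base = label
            break
    for s in summary.strata:
        if s.label == base or base in s.merged_from:
            return s.label
    raise RuntimeError(f"no stratum for volume={vol}, band={band_val}")


def strata_incidence_curves(
    cohort: Sequence[PatientRecord],
    summary: StratifiedSummary,
) -> tuple[dict[str, IncidenceCurve], pd.DataFrame]:
    """Kaplan-Meier cumulative incidence per (possibly merged) stratum.

    Returns the per-stratum curves and a pairwise log-rank table over the
    full follow-up.
    """
    groups: dict[str, tuple[list[float], list[bool]]] = {s.label: ([], []) for s in summary.strata}
    for rec in cohort:
        band_val = {
            "v30_60": rec.dosimetry.v30_60,
            "v40_60": rec.dosimetry.v40_60,
            "v40_50": rec.dosimetry.bands.v40_50,
        }.get(summary.band)
        if band_val is None:
            raise KeyError(f"unsupported stratification band {summary.band!r}")
        label = _assign_stratum(summary, rec.dosimetry.volume_cm3, band_val)
        groups[label][0].append(rec.time_months)
        groups[label][1].append(rec.event)
    curves = {
        label: km_cumulative_incidence(times, events)
        for label, (times, events) in groups.items()
        if times
    }
    labels = [l for l in groups if groups[l][0]]
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            chi2, p = logrank_test(groups[la], groups[lb])
            rows.append({"stratum_a": la, "stratum_b": lb, "chi2": chi2, "p_value": p})
    return curves, pd.DataFrame(rows)
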