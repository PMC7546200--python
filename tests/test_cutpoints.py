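"""Minimum-p cutpoint scan, multiplicity correction, four-cohort stratification."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from thyroht.cohort import derive_two_year_endpoint
from thyroht.cutpoints import (
    merge_strata,
    miller_siegmund_p,
    minp_cutpoint,
    strata_incidence_curves,
    stratify,
)
from thyroht.reference import (
    EXPECTED_INCIDENCE_PCT,
    REFERENCE_CUTS,
    reference_counts_dataset,
)
from thyroht.simulate import SimConfig, generate_cohort

from conftest import make_dataset


def brute_force_minp(values, outcome, min_fraction=0.10):
    """Independent scan: every distinct value, chi2_contingency, smallest p."""
    values = np.asarray(values, float)
    outcome = np.asarray(outcome, bool)
    n = len(values)
    lo = int(np.ceil(min_fraction * n))
    best = None
    for cut in np.unique(values):
        low = values <= cut
        if low.sum() < lo or (~low).sum() < lo:
            continue
        table = [
            [int((low & outcome).sum()), int((low & ~outcome).sum())],
            [int((~low & outcome).sum()), int((~low & ~outcome).sum())],
        ]
        if min(sum(r) for r in table) == 0 or min(table[0][j] + table[1][j] for j in (0, 1)) == 0:
            p, chi2 = 1.0, 0.0
        else:
            chi2, p, _, _ = chi2_contingency(table, correction=False)
        if best is None or p < best[1] - 1e-15:
            best = (float(cut), float(p), float(chi2))
    return best


class TestMinpCutpoint:
    def test_perfect_separator_found(self):
        values = np.arange(1.0, 21.0)
        outcome = values > 10
        res = minp_cutpoint(values, outcome)
        assert res.cutoff == 10.0
        assert res.p_raw == min(
            res.p_raw,
            brute_force_minp(values, outcome)[1],
        )

    def test_matches_bruteforce_on_random_data(self, rng):
        for _ in range(25):
            n = int(rng.integers(30, 200))
            values = np.round(rng.normal(size=n), 1)
            outcome = rng.random(n) < 0.4
            if outcome.all() or not outcome.any() or np.ptp(values) == 0:
                continue
            res = minp_cutpoint(values, outcome)
            cut, p, chi2 = brute_force_minp(values, outcome)
            assert res.cutoff == cut
            assert res.p_raw == pytest.approx(p, abs=1e-12)
            assert res.statistic == pytest.approx(chi2, rel=1e-9)

    def test_corrected_never_below_raw(self, rng):
        for _ in range(50):
            values = rng.normal(size=60)
            outcome = rng.random(60) < 0.5
            if outcome.all() or not outcome.any():
                continue
            res = minp_cutpoint(values, outcome)
            assert res.p_corrected >= res.p_raw

    def test_null_correction_tempers_anticonservatism(self, rng):
        """Scanned minimum p is far below uniform under the null; corrected is not."""
        raws, corrs = [], []
        for _ in range(150):
            values = rng.normal(size=100)
            outcome = rng.random(100) < 0.5
            if outcome.all() or not outcome.any():
                continue
            res = minp_cutpoint(values, outcome)
            raws.append(res.p_raw)
            corrs.append(res.p_corrected)
        assert np.median(raws) < 0.25  # stochastically far below uniform
        assert np.median(corrs) > 2 * np.median(raws)
        assert np.mean(np.array(corrs) <= 0.05) < 0.15  # roughly honest size

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            minp_cutpoint([1.0] * 5, [True, False] * 2 + [True])
        with pytest.raises(ValueError, match="classes"):
            minp_cutpoint(np.arange(25.0), [True] * 25)
        with pytest.raises(ValueError, match="constant"):
            minp_cutpoint([3.0] * 25, [True, False] * 12 + [True])

    def test_miller_siegmund_monotone_in_z(self):
        ps = [miller_siegmund_p(z, 0.1, 0.9) for z in (1.5, 2.0, 3.0, 4.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert miller_siegmund_p(0.5, 0.1, 0.9) == 1.0


class TestStratify:
    def test_reference_counts_reproduced(self):
        ds = reference_counts_dataset()
        summary = stratify(ds, REFERENCE_CUTS["volume_cm3"], REFERENCE_CUTS["v30_60"])
        observed = {s.label: round(s.incidence_pct, 1) for s in summary.strata}
        for label in ("cohort1", "cohort2", "cohort3", "cohort4"):
            assert observed[label] == EXPECTED_INCIDENCE_PCT[label]
        assert summary.total_n == 545
        assert summary.total_events == 138

    def test_partition_conserves_totals(self, rng):
        ds = make_dataset(
            volume_cm3=rng.uniform(5, 30, 300),
            v30_60=rng.uniform(0, 100, 300),
            ht_within_2y=rng.random(300) < 0.3,
        )
        summary = stratify(ds, 20.0, 80.0)
        assert summary.total_n == 300
        assert summary.total_events == int(ds.frame["ht_within_2y"].sum())

    def test_boundary_values_go_low_side(self):
        ds = make_dataset(
            volume_cm3=[20.0, 20.0001], v30_60=[80.0, 80.0001],
            ht_within_2y=[True, False],
        )
        summary = stratify(ds, 20.0, 80.0)
        by_label = {s.label: s.n for s in summary.strata}
        assert by_label["cohort3"] == 1  # (<=20, <=80)
        assert by_label["cohort2"] == 1  # (>20, >80)

    def test_row_order_irrelevant(self, rng):
        ds = make_dataset(
            volume_cm3=rng.uniform(5, 30, 100),
            v30_60=rng.uniform(0, 100, 100),
            ht_within_2y=rng.random(100) < 0.3,
        )
        shuffled = type(ds)(frame=ds.frame.sample(frac=1, random_state=1), n_excluded=0)
        t1 = stratify(ds, 20.0, 80.0).table().drop(columns="rule")
        t2 = stratify(shuffled, 20.0, 80.0).table().drop(columns="rule")
        assert t1.equals(t2)

    def test_empty_stratum_retained_with_nan_incidence(self):
        ds = make_dataset(volume_cm3=[10.0] * 4, v30_60=[90.0] * 4,
                          ht_within_2y=[True, False, False, True])
        summary = stratify(ds, 20.0, 80.0)
        by_label = {s.label: s for s in summary.strata}
        assert by_label["cohort4"].n == 4
        assert by_label["cohort1"].n == 0
        assert np.isnan(by_label["cohort1"].incidence_pct)
        assert summary.total_n == 4


class TestMergeStrata:
    def test_low_risk_pool_matches_published_value(self):
        ds = reference_counts_dataset()
        summary = stratify(ds, 20.0, 80.0)
        merged = merge_strata(summary, ("cohort1", "cohort2"))
        pooled = next(s for s in merged.strata if s.merged_from)
        assert (pooled.n, pooled.events) == (137, 16)
        assert round(pooled.incidence_pct, 1) == 11.7

    def test_merging_everything_recovers_whole_cohort(self):
        ds = reference_counts_dataset()
        summary = stratify(ds, 20.0, 80.0)
        merged = merge_strata(summary, tuple(s.label for s in summary.strata))
        assert len(merged.strata) == 1
        assert round(merged.strata[0].incidence_pct, 1) == 25.3

    def test_duplicate_and_unknown_labels_rejected(self):
        summary = stratify(reference_counts_dataset(), 20.0, 80.0)
        with pytest.raises(ValueError, match="duplicate"):
            merge_strata(summary, ("cohort1", "cohort1"))
        with pytest.raises(KeyError):
            merge_strata(summary, ("cohort1", "nope"))


@pytest.fixture(scope="module")
def cohort_and_summary():
    cohort, _ = generate_cohort(SimConfig(n=2000, seed=91))
    ds = derive_two_year_endpoint(cohort)
    summary = stratify(ds, 20.0, 80.0)
    return cohort, ds, summary


class TestStrataCurves:
    def test_highest_risk_stratum_tops_at_two_years(self, cohort_and_summary):
        cohort, _, summary = cohort_and_summary
        curves, _ = strata_incidence_curves(cohort, summary)
        at24 = {label: c.at(24.0) for label, c in curves.items()}
        # small volume + high band is the designed high-risk corner
        assert at24["cohort4"] == max(at24.values())

    def test_curves_consistent_with_binary_incidence(self, cohort_and_summary):
        cohort, ds, summary = cohort_and_summary
        curves, _ = strata_incidence_curves(cohort, summary)
        for stratum in summary.strata:
            km24 = curves[stratum.label].at(24.0)
            # KM at the horizon tracks the binary rate (exclusions are few)
            assert km24 == pytest.approx(stratum.incidence_pct / 100.0, abs=0.05)

    def test_pairwise_logrank_table_complete(self, cohort_and_summary):
        cohort, _, summary = cohort_and_summary
        _, pairwise = strata_incidence_curves(cohort, summary)
        assert len(pairwise) == 6  # all unordered pairs of 4 strata
        assert (pairwise["p_value"] <= 1).all()

    def test_identical_patterns_give_null_logrank(self):
        cohort, _ = generate_cohort(SimConfig(n=200, seed=17))
        ds = derive_two_year_endpoint(cohort)
        summary = stratify(ds, np.median(ds.frame["volume_cm3"]), 200.0)
        # band cut at 200% puts everyone on the low side: two strata populated
        curves, pairwise = strata_incidence_curves(cohort, summary)
        assert set(curves) <= {"cohort1", "cohort3"}
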