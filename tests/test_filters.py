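"""Hard-filter semantics, depth/missingness rules, MAF, HWE, and the
cohort funnel tally."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from baitforge import filters
from baitforge.filters import (
    FilterThresholds,
    apply_hard_filter,
    compute_maf,
    filter_cohort,
    hwe_chisq,
    missingness_filter,
    site_depth_filter,
    site_verdict,
)
from baitforge.formats import HET, HOM_ALT, HOM_REF, MISSING, VariantRecord

T = FilterThresholds()


def make_record(info=None, genotypes=(0,), depths=None, ref="A", alts=("G",)):
    g = list(genotypes)
    d = list(depths) if depths is not None else [10] * len(g)
    return VariantRecord("chr1", 100, ref, tuple(alts), info=dict(info or {}), genotypes=g, sample_depths=d)


class TestHardFilter:
    def test_low_qd_fails_with_all_else_absent(self):
        verdict = apply_hard_filter(make_record({"QD": 1.5}), T)
        assert verdict.reasons == [filters.HARD_FILTER]

    def test_boundaries_are_strict(self):
        rec = make_record({"QD": 2.0, "FS": 60.0, "MQ": 40.0})
        assert apply_hard_filter(rec, T).passed

    def test_absent_keys_never_trigger(self):
        assert apply_hard_filter(make_record({}), T).passed

    def test_matches_literal_expression_on_random_records(self):
        """Verdicts equal a direct re-evaluation of the printed boolean
        OR-expression, with keys dropped at random."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            info = {}
            for key, (lo, hi) in {
                "QD": (0, 40), "FS": (0, 120), "MQ": (0, 70),
                "MQRankSum": (-20, 5), "ReadPosRankSum": (-15, 5),
            }.items():
                if rng.random() < 0.8:
                    info[key] = float(rng.uniform(lo, hi))
            rec = make_record(info)
            g = info.get
            expected_fail = (
                ("QD" in info and g("QD") < 2.0)
                or ("FS" in info and g("FS") > 60.0)
                or ("MQ" in info and g("MQ") < 40.0)
                or ("MQRankSum" in info and g("MQRankSum") < -12.5)
                or ("ReadPosRankSum" in info and g("ReadPosRankSum") < -8.0)
            )
            assert apply_hard_filter(rec, T).passed == (not expected_fail)

    def test_gwa_clause_set_supported(self):
        t = T.with_(hard_filter_clauses=filters.GWA_HARD_FILTER_CLAUSES)
        assert not apply_hard_filter(make_record({"HaplotypeScore": 14.0}), t).passed
        assert apply_hard_filter(make_record({"HaplotypeScore": 13.0, "QD": 4.0}), t).passed


class TestSiteDepth:
    @pytest.mark.parametrize(
        "dp,passes",
        [(80, True), (79, False), (1000, True), (1001, False), (500, True)],
    )
    def test_inclusive_bounds(self, dp, passes):
        verdict = site_depth_filter(make_record({"DP": dp}), T)
        assert verdict.passed == passes

    def test_sum_of_sample_depths_fallback(self):
        rec = make_record({}, genotypes=[0, 1, 2], depths=[40, 40, 40])
        assert site_depth_filter(rec, T).passed  # sums to 120
        rec2 = make_record({}, genotypes=[0, 1], depths=[30, 30])
        assert not site_depth_filter(rec2, T).passed  # 60 < 80

    def test_unknown_depth_distinguished(self):
        rec = make_record({}, genotypes=[0], depths=[-1])
        assert site_depth_filter(rec, T).reasons == [filters.DEPTH_UNKNOWN]


class TestMissingness:
    def test_thirty_percent_missing_fails(self):
        rec = make_record({}, genotypes=[MISSING] * 3 + [HOM_REF] * 7)
        assert missingness_filter(rec, T).reasons == [filters.MISSINGNESS]

    def test_twenty_percent_boundary_passes(self):
        rec = make_record(
            {},
            genotypes=[MISSING] * 2 + [HOM_REF] * 8,
            depths=[1, 1] + [10] * 8,
        )
        assert missingness_filter(rec, T).passed  # 0.20 is not > 0.20

    def test_both_mode_requires_both_triggers(self):
        t = T.with_(missingness_mode="both")
        rec = make_record({}, genotypes=[MISSING] * 5 + [HOM_REF] * 5)
        assert missingness_filter(rec, t).passed
        rec2 = make_record(
            {}, genotypes=[MISSING] * 5 + [HOM_REF] * 5, depths=[1] * 5 + [0] * 3 + [9, 9]
        )
        assert not missingness_filter(rec2, t).passed

    def test_random_cohorts_match_direct_recount(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(5, 60))
            genotypes = rng.choice([HOM_REF, HET, HOM_ALT, MISSING], size=n)
            depths = rng.integers(0, 10, size=n)
            rec = make_record({}, genotypes=genotypes, depths=depths)
            miss = np.mean(genotypes == MISSING)
            low = np.mean(depths < 2)
            expect_fail = miss > 0.2 or low > 0.2
            assert missingness_filter(rec, T).passed == (not expect_fail)


class TestMaf:
    def test_direct_count(self):
        genotypes = [HOM_REF] * 7 + [HET] * 3
        assert compute_maf(genotypes) == pytest.approx(0.15)

    def test_all_hom_alt_folds_to_zero(self):
        assert compute_maf([HOM_ALT] * 10) == 0.0

    def test_missing_excluded_from_denominator(self):
        assert compute_maf([HET, MISSING, MISSING, HOM_REF]) == pytest.approx(0.25)

    def test_all_missing_is_an_error(self):
        with pytest.raises(ValueError):
            compute_maf([MISSING, MISSING])

    @pytest.mark.parametrize("p", [0.05, 0.2, 0.4])
    def test_binomial_recovery_within_three_sd(self, p):
        rng = np.random.default_rng(int(p * 1000))
        n = 500
        counts = rng.binomial(2, p, size=n)
        genotypes = np.select([counts == 0, counts == 1, counts == 2], [HOM_REF, HET, HOM_ALT])
        sd = np.sqrt(p * (1 - p) / (2 * n))
        assert abs(compute_maf(genotypes) - p) <= 3 * sd

    @given(st.lists(st.sampled_from([HOM_REF, HET, HOM_ALT, MISSING]), min_size=1, max_size=60))
    @settings(derandomize=True)
    def test_folding_invariance_under_label_swap(self, genotypes):
        if all(g == MISSING for g in genotypes):
            return
        swapped = [{HOM_REF: HOM_ALT, HOM_ALT: HOM_REF}.get(g, g) for g in genotypes]
        assert compute_maf(genotypes) == pytest.approx(compute_maf(swapped))
        assert 0.0 <= compute_maf(genotypes) <= 0.5


class TestHwe:
    def test_exact_proportions_give_p_one(self):
        genotypes = [HOM_REF] * 25 + [HET] * 50 + [HOM_ALT] * 25
        assert hwe_chisq(genotypes) == pytest.approx(1.0)

    def test_monomorphic_convention(self):
        assert hwe_chisq([HOM_REF] * 20) == 1.0

    def test_statistic_matches_direct_formula(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        for _ in range(50):
            counts = rng.integers(1, 50, size=3)
            genotypes = (
                [HOM_REF] * int(counts[0]) + [HET] * int(counts[1]) + [HOM_ALT] * int(counts[2])
            )
            n = counts.sum()
            p = (2 * counts[0] + counts[1]) / (2 * n)
            expected = np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2]) * n
            stat = float(np.sum((counts - expected) ** 2 / expected))
            assert hwe_chisq(genotypes) == pytest.approx(stats.chi2.sf(stat, 1))


class TestCohortFunnel:
    def _random_records(self, rng, n=60):
        records = []
        for i in range(n):
            genotypes = rng.choice(
                [HOM_REF, HET, HOM_ALT, MISSING], size=20, p=[0.4, 0.3, 0.2, 0.1]
            )
            depths = rng.integers(0, 15, size=20)
            info = {"DP": float(rng.integers(40, 1200)), "QD": float(rng.uniform(0, 30))}
            alts = ("G",) if rng.random() < 0.8 else ("G", "T")
            records.append(
                VariantRecord(
                    "chr1", i + 1, "A", alts, info=info,
                    genotypes=genotypes, sample_depths=depths, id=f"s{i}",
                )
            )
        return records

    def test_empty_input(self):
        result = filter_cohort([], T)
        assert result.survivors == [] and result.tally == {}

    def test_disabled_filters_keep_all_biallelic(self):
        rng = np.random.default_rng(5)
        records = self._random_records(rng)
        result = filter_cohort(records, FilterThresholds.disabled())
        n_biallelic = sum(r.is_biallelic_snp for r in records)
        assert len(result.survivors) == n_biallelic

    def test_tally_conservation(self):
        rng = np.random.default_rng(6)
        records = self._random_records(rng)
        result = filter_cohort(records, T.with_(maf_min=0.05, hwe_p_min=0.001))
        assert result.n_input == len(result.survivors) + sum(result.tally.values())

    def test_survivors_invariant_under_filter_order(self):
        """Filters are independent predicates: the surviving set equals
        the intersection of per-filter passes in any order."""
        rng = np.random.default_rng(8)
        records = self._random_records(rng)
        t = T.with_(maf_min=0.05)
        survivors = {r.id for r in filter_cohort(records, t).survivors}
        predicates = [
            lambda r: r.is_biallelic_snp,
            lambda r: apply_hard_filter(r, t).passed,
            lambda r: site_depth_filter(r, t).passed,
            lambda r: missingness_filter(r, t).passed,
        ]
        for order in itertools.permutations(range(len(predicates))):
            surviving = [r for r in records if all(predicates[i](r) for i in order)]
            surviving = [
                r for r in surviving
                if not (np.all(np.asarray(r.genotypes) == MISSING))
                and compute_maf(r.genotypes) >= 0.05
            ]
            assert {r.id for r in surviving} == survivors

    def test_planted_truth_tally(self, planted_fixture):
        """Each planted hard-filter clause violation is rejected and the
        tally equals the plant design exactly."""
        result = filter_cohort(planted_fixture["records"], T)
        truth = planted_fixture["truth_table"]
        n_violating = int((truth["info_fate"] != "pass").sum())
        assert result.tally == {filters.HARD_FILTER: n_violating}
        rejected_ids = set(truth.loc[truth["info_fate"] != "pass", "snp_id"])
        survivor_ids = {r.id for r in result.survivors}
        assert survivor_ids.isdisjoint(rejected_ids)
        assert len(result.survivors) == len(truth) - n_violating
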