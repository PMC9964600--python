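"""Bivariate battery: odds ratios, chi-square, Wilcoxon, banding, forest."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import comorbnet as cn
from comorbnet.stats import STRATA, ContingencyTable, benjamini_hochberg


class TestOddsRatio:
    def test_frailty_counts_reproduce_published_interval(self):
        r = cn.odds_ratio(269, 125, 188, 158)
        assert round(r.or_point, 2) == 1.81
        assert round(r.ci_low, 2) == 1.34
        assert round(r.ci_high, 2) == 2.44

    def test_pim_counts_reproduce_published_interval(self):
        r = cn.odds_ratio(303, 91, 239, 107)
        assert round(r.or_point, 2) == 1.49
        assert round(r.ci_low, 2) == 1.08
        assert round(r.ci_high, 2) == 2.07

    def test_symmetric_table_gives_unity(self):
        assert cn.odds_ratio(1, 1, 1, 1).or_point == pytest.approx(1.0)

    def test_zero_cell_is_an_error_unless_haldane(self):
        with pytest.raises(ValueError, match="zero cell"):
            cn.odds_ratio(0, 5, 3, 7)
        r = cn.odds_ratio(0, 5, 3, 7, haldane=True)
        assert r.or_point == pytest.approx(0.5 * 7.5 / (5.5 * 3.5))

    @settings(max_examples=60, deadline=None)
    @given(*(st.integers(1, 500) for _ in range(4)))
    def test_reciprocity_and_ci_log_symmetry(self, a, b, c, d):
        r = cn.odds_ratio(a, b, c, d)
        flipped = cn.odds_ratio(b, a, d, c)
        assert flipped.or_point == pytest.approx(1 / r.or_point, rel=1e-9)
        assert math.log(r.ci_high) - math.log(r.or_point) == pytest.approx(
            math.log(r.or_point) - math.log(r.ci_low), abs=1e-9
        )

    @settings(max_examples=30, deadline=None)
    @given(*(st.integers(1, 200) for _ in range(4)), st.integers(2, 9))
    def test_row_scaling_invariance_and_alpha_monotonicity(self, a, b, c, d, k):
        r = cn.odds_ratio(a, b, c, d)
        scaled = cn.odds_ratio(a * k, b * k, c, d)
        assert scaled.or_point == pytest.approx(r.or_point, rel=1e-9)
        wider = cn.odds_ratio(a, b, c, d, alpha=0.01)
        assert wider.ci_low <= r.ci_low and wider.ci_high >= r.ci_high


def _table(counts, levels=("a", "b"), variable="v"):
    return ContingencyTable(variable=variable, levels=tuple(levels),
                            counts=tuple(tuple(r) for r in counts))


class TestChiSquare:
    def test_printed_frailty_table_is_highly_significant(self):
        res = cn.chi_square_test(_table([(269, 125), (188, 158)]))
        assert res.p_value < 0.001
        assert res.df == 1

    def test_homogeneous_table(self):
        res = cn.chi_square_test(_table([(15, 15), (15, 15)]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_statistic_without_correction(self):
        # all expected counts are 15; sum of (O-E)^2/E = 4 * 25/15 = 6.667
        res = cn.chi_square_test(_table([(20, 10), (10, 20)]))
        assert res.statistic == pytest.approx(20 / 3, rel=1e-9)
        assert res.df == 1

    def test_zero_margin_names_the_level(self):
        with pytest.raises(ValueError, match="empty level 'b'"):
            cn.chi_square_test(_table([(5, 0), (7, 0)]))

    def test_level_permutation_invariance_and_z_squared_identity(self):
        res = cn.chi_square_test(_table([(30, 12), (18, 25)]))
        perm = cn.chi_square_test(_table([(12, 30), (25, 18)]))
        assert res.statistic == pytest.approx(perm.statistic)
        # 2x2 chi-square equals the squared two-proportion z statistic
        n1, n2 = 42, 43
        p1, p2 = 30 / n1, 18 / n2
        p = (30 + 18) / (n1 + n2)
        z = (p1 - p2) / math.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
        assert res.statistic == pytest.approx(z**2, rel=1e-9)


def _exact_two_sided_p(x, y):
    """Brute-force enumeration over all rank assignments (no ties)."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in x)
    n = len(pooled)
    sums = [sum(c) for c in itertools.combinations(range(1, n + 1), len(x))]
    mean = len(x) * (n + 1) / 2
    dev = abs(observed - mean)
    extreme = sum(1 for s in sums if abs(s - mean) >= dev - 1e-9)
    return extreme / len(sums)


class TestWilcoxon:
    def test_identical_multisets_give_p_one(self):
        res = cn.wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_matches_enumeration(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]
        res = cn.wilcoxon_rank_sum(x, y)
        assert res.p_value == pytest.approx(2 / 70, rel=1e-9)
        assert _exact_two_sided_p(x, y) == pytest.approx(2 / 70)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(0, 40), min_size=2, max_size=6, unique=True),
           st.lists(st.integers(41, 90), min_size=2, max_size=6, unique=True))
    def test_exact_p_matches_brute_force_enumeration(self, xi, yi):
        # shift y into a disjoint range, then interleave via value mapping to
        # generate overlapping tie-free samples
        x = [float(v) + 0.25 for v in xi]
        y = [float(v) - 40.0 for v in yi]
        res = cn.wilcoxon_rank_sum(x, y)
        assert res.p_value == pytest.approx(_exact_two_sided_p(x, y), rel=1e-9)

    def test_normal_approximation_close_to_exact_at_n8(self):
        # the implementation takes the exact path at n=8+8; the asymptotic
        # path on the same data should agree to < 0.01 on average
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(0)
        devs = []
        for _ in range(40):
            x = list(rng.permutation(np.arange(16.0))[:8])
            y = [v for v in np.arange(16.0) if v not in x]
            exact = _exact_two_sided_p(x, y)
            assert cn.wilcoxon_rank_sum(x, y).p_value == pytest.approx(exact)
            asym = mannwhitneyu(x, y, alternative="two-sided",
                                method="asymptotic").pvalue
            devs.append(abs(min(asym, 1.0) - exact))
        assert np.mean(devs) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            cn.wilcoxon_rank_sum([], [1.0])


class TestBanding:
    @pytest.mark.parametrize("value,scheme,expected", [
        (100, "barthel", "independent"),
        (95, "barthel", "low_dependence"),
        (15, "barthel", "total_dependence"),
        (20, "barthel", "severe_dependence"),
        (9, "polypharmacy", "moderate_polypharmacy"),
        (10, "polypharmacy", "excessive_polypharmacy"),
        (4, "polypharmacy", "oligopharmacy"),
        (84, "age4", "75-84"),
        (85, "age4", "85-94"),
        (84, "age2", "65-84"),
        (85, "age2", ">=85"),
        (95, "age4", ">=95"),
        (7, "charlson_tertiles", "6-8"),
    ])
    def test_interval_assignment(self, value, scheme, expected):
        assert cn.band_variable(value, scheme) == expected

    def test_out_of_domain_barthel_rejected(self):
        with pytest.raises(ValueError, match="multiple of 5"):
            cn.band_variable(37, "barthel")


class TestBattery:
    def test_fixture_frailty_reproduces_published_result(self):
        recs = cn.expand_printed_table("frailty", [[125, 269], [158, 188]],
                                       levels=["no", "yes"])
        df = cn.cohort_to_frame(recs)
        res = cn.run_bivariate_battery(df, ["frailty"], continuous=(), strata=("all",))
        assert res.tests[0].p_value < 0.001
        assert round(res.odds_ratios[0].or_point, 2) == 1.81
        assert res.odds_ratios[0].exposure_level == "yes"

    def test_constant_variable_skipped_with_warning(self, caplog):
        recs = cn.expand_printed_table("v", [[5, 0], [5, 0]], levels=["a", "b"])
        df = cn.cohort_to_frame(recs)
        import logging

        with caplog.at_level(logging.WARNING, logger="comorbnet.stats"):
            res = cn.run_bivariate_battery(df, ["v"], continuous=(), strata=("all",))
        assert res.tests == []
        assert res.skipped and res.skipped[0][2] == "constant variable"
        assert "constant" in caplog.text

    def test_unknown_variable_is_an_error(self):
        df = cn.cohort_to_frame(cn.expand_printed_table("v", [[1, 1], [1, 1]]))
        with pytest.raises(KeyError, match="nope"):
            cn.run_bivariate_battery(df, ["nope"], continuous=())

    def test_stratified_counts_recombine_to_total(self):
        spec = cn.CohortSpec(n_patients=400, seed=2,
                             condition_prevalence={"A": (0.4, 0.3)})
        df = cn.cohort_to_frame(cn.generate_cohort(spec))
        total = ContingencyTable.from_frame(df, "A", "all").array
        parts = sum(ContingencyTable.from_frame(df, "A", s).array
                    for s in ("65-84", ">=85"))
        assert (total == parts).all()

    def test_battery_covers_all_strata(self):
        spec = cn.CohortSpec(n_patients=600, seed=8,
                             condition_prevalence={"A": (0.4, 0.2)})
        df = cn.cohort_to_frame(cn.generate_cohort(spec))
        res = cn.run_bivariate_battery(df, ["A", "los_days"])
        assert {t.stratum for t in res.tests} == set(STRATA)
        assert {t.test for t in res.tests} == {"chi_square", "wilcoxon"}


class TestForest:
    def test_sorted_descending_with_cis_containing_points(self):
        ors = [cn.odds_ratio(*cells) for cells in
               [(269, 125, 188, 158), (303, 91, 239, 107), (60, 10, 20, 30)]]
        recs = cn.assemble_forest(ors)
        points = [r["or"] for r in recs]
        assert points == sorted(points, reverse=True)
        assert all(r["ci_low"] <= r["or"] <= r["ci_high"] for r in recs)

    def test_single_record_and_svg_render(self, tmp_path):
        recs = cn.assemble_forest([cn.odds_ratio(10, 5, 4, 8)])
        assert len(recs) == 1
        out = tmp_path / "forest.svg"
        from comorbnet.stats import render_forest

        render_forest(recs, out)
        assert out.read_text().lstrip().startswith("<?xml")


def test_benjamini_hochberg_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.04, 0.2, 0.9])
    adj = benjamini_hochberg(p)
    assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
    assert (np.diff(adj[np.argsort(p)]) >= -1e-12).all()
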