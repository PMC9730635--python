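"""Group comparison, correlation grading, and seasonal inference tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from avicond import (
    CauseDefinition,
    Dataset,
    MonthKey,
    asi_month_anova,
    asi_vs_one,
    compare_groups,
    month_inference,
    rank_biserial,
    spearman_matrix,
    strength_label,
)
from avicond.errors import DegenerateSampleError, InsufficientDataError
from avicond.inference import holm_correction

from conftest import make_record


def pair_count_rank_biserial(a, b):
    """O(n*m) definition: mean of sign(a_i - b_j) over all pairs."""
    total = 0.0
    for x in a:
        for y in b:
            total += int(x > y) - int(x < y)
    return total / (len(a) * len(b))


def average_ranks(x):
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def rank_then_pearson(x, y):
    rx, ry = average_ranks(x), average_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def _ab_dataset(a_percents, b_percents):
    """Build a dataset whose group-A months have the given overall percent
    ratios (via turkey+heavy) and group-B months likewise (heavy only)."""
    causes = (CauseDefinition("contamination", "Contamination", technological=True),)
    records = []
    month_iter = iter(
        MonthKey(2010 + i // 12, i % 12 + 1) for i in range(400)
    )
    for pct in a_percents:
        k = next(month_iter)
        records.append(make_record(k.year, k.month, heavy=900, turkey=100,
                                   contamination=int(round(10 * pct))))
    for pct in b_percents:
        k = next(month_iter)
        records.append(make_record(k.year, k.month, heavy=1000,
                                   contamination=int(round(10 * pct))))
    return Dataset(records, causes)


class TestRankBiserial:
    def test_matches_pair_counting_on_random_instances(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            a = rng.integers(0, 20, size=rng.integers(2, 15)).astype(float)
            b = rng.integers(0, 20, size=rng.integers(2, 15)).astype(float)
            assert rank_biserial(a, b) == pytest.approx(
                pair_count_rank_biserial(a, b), abs=1e-12
            )

    def test_complete_separation_is_exactly_one(self):
        assert rank_biserial([5.0, 6.0, 7.0], [1.0, 2.0]) == 1.0
        assert rank_biserial([1.0, 2.0], [5.0, 6.0, 7.0]) == -1.0

    @given(
        a=st.lists(st.floats(-100, 100), min_size=2, max_size=20),
        b=st.lists(st.floats(-100, 100), min_size=2, max_size=20),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_and_antisymmetric(self, a, b):
        rb = rank_biserial(a, b)
        assert -1.0 <= rb <= 1.0
        assert rb == pytest.approx(-rank_biserial(b, a), abs=1e-12)


class TestCompareGroups:
    def test_identical_multisets_give_null_result(self):
        ds = _ab_dataset([6, 7, 8, 9], [6, 7, 8, 9])
        cmp = compare_groups(ds)
        assert cmp.rank_biserial == 0.0
        assert cmp.p_value == pytest.approx(1.0)
        assert abs(cmp.point_biserial) < 1e-12

    def test_complete_separation_pattern(self):
        """Group A strictly above group B in every month: the headline
        effect is exactly 1.000 (the separation signature of a
        near-zero-in-B cause such as aerosacculitis in heavy chickens)."""
        ds = _ab_dataset([5, 6, 7, 8, 9], [0.1, 0.2, 0.1])
        cmp = compare_groups(ds)
        assert cmp.rank_biserial == 1.0
        assert cmp.effect_size == 1.0
        assert cmp.p_value < 0.01

    def test_sign_convention_negative_when_b_exceeds_a(self):
        ds = _ab_dataset([5, 6, 7], [10, 11, 12])
        assert compare_groups(ds).rank_biserial == -1.0

    def test_welch_statistics_match_summary_invariant(self):
        ds = _ab_dataset([5, 6, 7, 9], [10, 11, 13])
        cmp = compare_groups(ds)
        assert cmp.group_a.se == pytest.approx(cmp.group_a.sd / math.sqrt(cmp.group_a.n))
        assert cmp.group_b.n == 3

    def test_insufficient_group_rejected(self):
        ds = _ab_dataset([5, 6, 7], [10])
        with pytest.raises(InsufficientDataError):
            compare_groups(ds)


class TestStrengthGrading:
    @pytest.mark.parametrize(
        "rho,label",
        [
            (0.95, "very high"), (0.9, "very high"),
            (0.722, "high"), (0.7, "high"),
            (0.541, "moderate"), (0.5, "moderate"),
            (0.3, "low"), (-0.45, "low"),
            (0.29, "negligible"), (0.0, "negligible"),
            (-0.722, "high"),
        ],
    )
    def test_band_assignment(self, rho, label):
        assert strength_label(rho) == label


def _multicause_dataset(matrix, codes):
    causes = tuple(CauseDefinition(c, c, asi_eligible=True) for c in codes)
    records = []
    for i, row in enumerate(matrix):
        k = MonthKey(2010 + i // 12, i % 12 + 1)
        records.append(
            make_record(k.year, k.month, heavy=10_000,
                        **{c: int(v) for c, v in zip(codes, row)})
        )
    return Dataset(records, causes)


class TestSpearmanMatrix:
    def test_comonotone_pair_is_unit_rho_very_high(self):
        mat = [[i, 2 * i + 3] for i in range(1, 9)]
        rep = spearman_matrix(_multicause_dataset(mat, ["a", "b"]))
        assert rep.rho.loc["a", "b"] == pytest.approx(1.0)
        assert rep.strength.loc["a", "b"] == "very high"

    def test_matrix_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(0, 50, size=(10, 3))
        rep = spearman_matrix(_multicause_dataset(mat, ["a", "b", "c"]))
        assert np.allclose(rep.rho, rep.rho.T)
        assert np.allclose(np.diag(rep.rho), 1.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(43)
        for _ in range(100):
            n = int(rng.integers(4, 15))
            mat = rng.integers(0, 10, size=(n, 2))
            if len(np.unique(mat[:, 0])) < 2 or len(np.unique(mat[:, 1])) < 2:
                continue
            rep = spearman_matrix(_multicause_dataset(mat, ["a", "b"]))
            assert rep.rho.loc["a", "b"] == pytest.approx(
                rank_then_pearson(mat[:, 0], mat[:, 1]), abs=1e-12
            )

    def test_constant_series_reported_missing_not_zero(self):
        mat = [[5, i] for i in range(8)]
        rep = spearman_matrix(_multicause_dataset(mat, ["a", "b"]))
        assert np.isnan(rep.rho.loc["a", "b"])
        assert rep.strength.loc["a", "b"] == "undefined"

    def test_needs_three_months(self):
        with pytest.raises(InsufficientDataError):
            spearman_matrix(_multicause_dataset([[1, 2], [3, 4]], ["a", "b"]))


def _ratios(values_by_year_month):
    return {MonthKey(y, m): v for (y, m), v in values_by_year_month.items()}


class TestAsiVsOne:
    def test_all_ratios_exactly_one_is_degenerate(self):
        r = _ratios({(2010 + i, 7): 1.0 for i in range(5)})
        with pytest.raises(DegenerateSampleError):
            asi_vs_one(r, 7)

    def test_mean_exactly_one_gives_t_zero_p_one(self):
        r = _ratios({(2010, 7): 1.1, (2011, 7): 0.9, (2012, 7): 1.0})
        res = asi_vs_one(r, 7)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        vals = [0.96, 0.95, 0.94, 0.95]
        r = _ratios({(2010 + i, 3): v for i, v in enumerate(vals)})
        res = asi_vs_one(r, 3)
        mean = sum(vals) / 4
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 3)
        t = (mean - 1.0) / (sd / 2.0)
        p = 2 * stats.t.sf(abs(t), df=3)
        assert res.t == pytest.approx(t)
        assert res.p_value == pytest.approx(p)

    def test_single_year_rejected(self):
        with pytest.raises(InsufficientDataError):
            asi_vs_one(_ratios({(2010, 7): 1.2}), 7)


class TestMonthAnova:
    def test_all_equal_ratios_nothing_significant(self):
        r = _ratios({(2010 + y, m): 1.0 for y in range(4) for m in range(1, 13)})
        f, p, tukey = asi_month_anova(r)
        assert (tukey["p_adj"] == 1.0).all()
        assert not tukey["reject"].any()

    def test_full_series_has_66_pairs(self):
        rng = np.random.default_rng(7)
        r = _ratios({(2010 + y, m): float(rng.normal(1, 0.05))
                     for y in range(5) for m in range(1, 13)})
        _, _, tukey = asi_month_anova(r)
        assert len(tukey) == 66

    def test_single_replicate_months_dropped(self):
        r = _ratios({(2010 + y, m): float(m + y) for y in range(3) for m in (1, 2)})
        r[MonthKey(2010, 5)] = 1.0  # only one May
        _, _, tukey = asi_month_anova(r)
        months = set(tukey["month_1"]) | set(tukey["month_2"])
        assert months == {1, 2}

    def test_adjusted_p_matches_studentized_range_oracle(self):
        """Tukey HSD adjusted p-values agree with the textbook
        construction: q = |mean_i - mean_j| / sqrt(MSE / n), referred to
        the studentized range distribution with k groups and N - k df."""
        rng = np.random.default_rng(47)
        for _ in range(10):
            k, n = 4, 6
            data = rng.normal(1, 0.1, size=(k, n))
            r = _ratios({(2010 + y, m + 1): float(data[m, y])
                         for m in range(k) for y in range(n)})
            _, _, tukey = asi_month_anova(r)
            mse = np.mean([np.var(data[m], ddof=1) for m in range(k)])
            for _, row in tukey.iterrows():
                i, j = int(row["month_1"]) - 1, int(row["month_2"]) - 1
                q = abs(data[i].mean() - data[j].mean()) / math.sqrt(mse / n)
                p = stats.studentized_range.sf(q, k, k * (n - 1))
                assert row["p_adj"] == pytest.approx(p, abs=1e-4)

    def test_familywise_error_under_global_null(self):
        """Tukey FWER stays near its nominal 5% level: 500 null
        replicates of a 6-month x 5-year balanced design."""
        rng = np.random.default_rng(53)
        false_alarms = 0
        for _ in range(500):
            r = _ratios({(2010 + y, m): float(rng.normal(1, 0.05))
                         for y in range(5) for m in range(1, 7)})
            _, _, tukey = asi_month_anova(r)
            false_alarms += int(tukey["reject"].any())
        assert false_alarms / 500 <= 0.07


class TestMonthInference:
    def test_bundles_tukey_and_vs_one(self):
        rng = np.random.default_rng(59)
        r = _ratios({(2010 + y, m): float(rng.normal(1, 0.05))
                     for y in range(6) for m in range(1, 13)})
        inf = month_inference(r, scope="dermatosis")
        assert len(inf.tukey) == 66
        assert list(inf.vs_one["month"]) == list(range(1, 13))
        assert inf.vs_one["n"].eq(6).all()

    def test_degenerate_months_reported_as_nan(self):
        r = _ratios({(2010 + y, m): 1.0 if m == 1 else float(1 + 0.1 * y)
                     for y in range(4) for m in (1, 2)})
        inf = month_inference(r)
        jan = inf.vs_one.set_index("month").loc[1]
        assert np.isnan(jan["p_value"])


def test_holm_correction_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(61)
    p = rng.uniform(0, 1, 20)
    expected = multipletests(p, method="holm")[1]
    np.testing.assert_allclose(holm_correction(p), expected, atol=1e-12)
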