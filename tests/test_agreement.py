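"""Agreement statistics: ICC(1), Friedman, Kendall's W, Bland-Altman."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phonect.agreement import (
    AgreementError,
    RatingTable,
    analyze_table,
    bland_altman,
    friedman,
    icc1,
    kendall_w,
    randomize_order,
)


def icc1_oracle(values):
    """First-principles one-way ANOVA from sum-of-squares definitions."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    grand = values.mean()
    ssb = sum(k * (row.mean() - grand) ** 2 for row in values)
    ssw = sum(((row - row.mean()) ** 2).sum() for row in values)
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


class TestICC1:
    HAND_TABLE = np.array(
        [[9.0, 10.0, 8.0], [5.0, 6.0, 4.0], [12.0, 11.0, 13.0], [3.0, 2.0, 4.0]]
    )

    def test_hand_table_matches_anova_oracle(self):
        icc, _ = icc1(self.HAND_TABLE)
        assert icc == pytest.approx(icc1_oracle(self.HAND_TABLE), abs=1e-12)

    def test_hand_table_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n, k = self.HAND_TABLE.shape
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "value": self.HAND_TABLE.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="value"
        )
        one_way = ref[ref["Type"].str.startswith("ICC(1,1)") | (ref["Type"] == "ICC1")]
        icc_ref = one_way["ICC"].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        ci_ref = one_way[ci_col].iloc[0]
        icc, ci = icc1(self.HAND_TABLE)
        assert icc == pytest.approx(icc_ref, abs=1e-6)
        assert ci[0] == pytest.approx(ci_ref[0], abs=0.01)
        assert ci[1] == pytest.approx(ci_ref[1], abs=0.01)

    def test_identical_methods_give_one(self):
        table = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        icc, ci = icc1(table)
        assert icc == 1.0
        assert ci == (1.0, 1.0)

    def test_pure_noise_gives_near_zero(self):
        rng = np.random.default_rng(12)
        table = rng.normal(0.0, 1.0, size=(50, 6))
        icc, _ = icc1(table)
        assert abs(icc) < 0.15

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(3)
        table = rng.normal(0, 1, size=(20, 4)) + rng.normal(0, 2, size=(20, 1))
        icc, (lo, hi) = icc1(table)
        assert lo <= icc <= hi

    def test_zero_variance_rejected(self):
        with pytest.raises(AgreementError):
            icc1(np.full((4, 3), 2.0))

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        table = rng.normal(10, 3, size=(12, 4)) + rng.normal(0, 4, size=(12, 1))
        icc, _ = icc1(table)
        icc2, _ = icc1(3.7 * table - 11.0)
        assert icc2 == pytest.approx(icc, abs=1e-10)

    def test_parameter_recovery_one_way_model(self):
        """Mean ICC over replicates approximates the generative variance ratio."""
        rho = 0.8
        sigma_b = np.sqrt(rho)
        sigma_w = np.sqrt(1 - rho)
        rng = np.random.default_rng(99)
        estimates = []
        for _ in range(500):
            subjects = rng.normal(0.0, sigma_b, size=(50, 1))
            table = subjects + rng.normal(0.0, sigma_w, size=(50, 6))
            estimates.append(icc1(table)[0])
        assert np.mean(estimates) == pytest.approx(rho, abs=0.03)


def friedman_enumeration_p(values, chi2_fn):
    """Exhaustive permutation oracle: all (k!)^n within-row orderings."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    observed = chi2_fn(values)
    perms = list(itertools.permutations(range(k)))
    count = total = 0
    for assignment in itertools.product(perms, repeat=n):
        permuted = np.stack([values[i, list(p)] for i, p in enumerate(assignment)])
        total += 1
        if chi2_fn(permuted) >= observed - 1e-12:
            count += 1
    return count / total


class TestFriedman:
    def test_identical_columns_no_effect(self):
        table = np.tile(np.array([[3.0], [1.0], [7.0]]), (1, 4))
        chi2, p = friedman(table)
        assert chi2 == 0.0
        assert p == 1.0

    def test_matches_scipy_on_untied_table(self):
        from scipy import stats

        rng = np.random.default_rng(8)
        table = rng.normal(size=(10, 4))
        chi2, p = friedman(table)
        ref = stats.friedmanchisquare(*table.T)
        assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exact_p_matches_enumeration_oracle(self):
        from phonect.agreement import _friedman_chi2

        table = np.array([[1.0, 2.5, 2.0], [4.0, 3.0, 5.0], [6.5, 6.0, 7.0]])
        chi2, p_exact = friedman(table, exact=True)
        assert p_exact == pytest.approx(
            friedman_enumeration_p(table, _friedman_chi2), abs=1e-12
        )

    def test_maximal_concordance_closed_form(self):
        """Every subject ranking the methods identically gives chi2 = n(k-1)."""
        n, k = 8, 6
        table = np.tile(np.arange(k, dtype=float), (n, 1)) + \
            np.arange(n, dtype=float)[:, None]
        chi2, p = friedman(table)
        assert chi2 == pytest.approx(n * (k - 1), abs=1e-10)
        assert kendall_w(chi2, n, k) == pytest.approx(1.0, abs=1e-12)

    def test_single_method_rejected(self):
        with pytest.raises(AgreementError):
            friedman(np.ones((3, 1)))


class TestKendallW:
    def test_zero_chi2(self):
        assert kendall_w(0.0, 5, 3) == 0.0

    def test_identity_with_chi2(self):
        """W * n * (k-1) returns the chi-square statistic exactly (no ties)."""
        rng = np.random.default_rng(4)
        table = rng.normal(size=(7, 5))
        chi2, _ = friedman(table)
        assert kendall_w(chi2, 7, 5) * 7 * 4 == pytest.approx(chi2, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(AgreementError):
            kendall_w(-1.0, 5, 3)
        with pytest.raises(AgreementError):
            kendall_w(1.0, 5, 1)


class TestBlandAltman:
    def test_identity_within_critical(self):
        x = [1.0, 2.0, 3.0, 4.0]
        ba = bland_altman(x, x, critical_difference=0.5)
        assert ba.bias == 0.0
        assert ba.within_critical

    def test_constant_offset_violates_small_critical_difference(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(x, x + 1.0, critical_difference=0.5)
        assert not ba.within_critical
        assert ba.bias == pytest.approx(1.0)

    def test_limits_of_agreement(self):
        rng = np.random.default_rng(2)
        x = rng.normal(10, 2, size=200)
        y = x + rng.normal(0.5, 1.0, size=200)
        ba = bland_altman(x, y, critical_difference=10.0)
        d = y - x
        assert ba.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
        assert ba.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))

    def test_length_mismatch_rejected(self):
        with pytest.raises(AgreementError):
            bland_altman([1.0, 2.0], [1.0], critical_difference=1.0)


class TestRandomizeOrder:
    def test_single_id(self):
        assert randomize_order(["a"], seed=0) == ["a"]

    def test_deterministic_per_seed(self):
        ids = list(range(10))
        assert randomize_order(ids, seed=3) == randomize_order(ids, seed=3)

    def test_is_permutation(self):
        ids = list("abcdef")
        assert sorted(randomize_order(ids, seed=11)) == sorted(ids)

    def test_uniform_over_permutations(self):
        """Each of the 3! orderings of 3 ids appears with frequency 1/6 +- 3 SE."""
        ids = ("a", "b", "c")
        counts = {}
        n = 10_000
        for seed in range(n):
            perm = tuple(randomize_order(ids, seed=seed))
            counts[perm] = counts.get(perm, 0) + 1
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        assert len(counts) == 6
        for perm, count in counts.items():
            assert count / n == pytest.approx(1 / 6, abs=3 * se), perm


class TestRatingTableAndReport:
    def test_csv_round_trip(self, tmp_path):
        table = RatingTable(
            values=np.arange(12, dtype=float).reshape(4, 3),
            measure_name="volume_cc",
            method_names=["PACS", "cap0", "cap1"],
            subject_ids=["a", "b", "c", "d"],
        )
        path = tmp_path / "table.csv"
        table.to_csv(path)
        back = RatingTable.from_csv(path, "volume_cc")
        np.testing.assert_array_equal(back.values, table.values)
        assert back.method_names == table.method_names
        assert back.subject_ids == table.subject_ids

    def test_missing_cells_rejected(self):
        values = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(AgreementError, match="missing"):
            RatingTable(values=values, measure_name="x")

    def test_analyze_table_consistency(self):
        rng = np.random.default_rng(6)
        values = rng.normal(10, 3, size=(8, 4)) + rng.normal(0, 5, size=(8, 1))
        table = RatingTable(values=values, measure_name="demo")
        report = analyze_table(table, critical_difference=50.0)
        assert report.icc_ci[0] <= report.icc <= report.icc_ci[1]
        assert 0.0 <= report.kendall_w <= 1.0
        assert len(report.bland_altman) == 3
        d = report.to_dict()
        assert d["measure"] == "demo"

    def test_analyze_table_without_critical_difference_skips_ba(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(5, 3)) + np.arange(5)[:, None]
        table = RatingTable(values=values, measure_name="ordinal")
        report = analyze_table(table, critical_difference=None)
        assert report.bland_altman == {}
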