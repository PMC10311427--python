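"""Statistical primitives against closed forms, printed-table values and
independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy import stats as sps
from scipy.special import expit

from ropscreen.stats import (ContingencyTable2x2, adjusted_or_logistic,
                             clopper_pearson, hosmer_lemeshow,
                             mn_risk_difference, odds_ratio_2x2, roc_youden,
                             sign_test, spearman)


class TestOddsRatio:
    # 2x2 tables reconstructed from published registry counts, with the
    # odds ratios and Woolf CIs the source table prints
    @pytest.mark.parametrize("table, expected", [
        ((1477, 831, 1340, 5888), (7.81, 7.04, 8.66)),
        ((362, 1241, 1340, 5888), (1.28, 1.12, 1.46)),
        ((418, 1890, 115, 7113), (13.68, 11.06, 16.92)),
        ((66, 1537, 115, 7113), (2.66, 1.95, 3.61)),
    ])
    def test_reproduces_printed_or_and_ci(self, table, expected):
        assert odds_ratio_2x2(table).rounded(2) == expected

    def test_symmetric_table_gives_unity(self):
        assert odds_ratio_2x2((10, 10, 10, 10)).point == pytest.approx(1.0)

    def test_row_scaling_invariance_and_antisymmetry(self):
        a = odds_ratio_2x2((20, 30, 10, 40))
        b = odds_ratio_2x2((40, 60, 10, 40))   # exposed row doubled
        assert a.point == pytest.approx(b.point)
        sw = odds_ratio_2x2((10, 40, 20, 30))  # exposure groups swapped
        assert np.log(sw.point) == pytest.approx(-np.log(a.point))

    def test_zero_cell_needs_continuity(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2((0, 10, 5, 5))
        iv = odds_ratio_2x2((0, 10, 5, 5), continuity=0.5)
        assert iv.point > 0

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 3, 4)


class TestAdjustedOr:
    def test_no_adjusters_reduces_to_crude(self):
        rng = np.random.default_rng(1)
        exp = rng.random(400) < 0.4
        y = rng.random(400) < np.where(exp, 0.5, 0.25)
        a = int((exp & y).sum()); b = int((exp & ~y).sum())
        c = int((~exp & y).sum()); d = int((~exp & ~y).sum())
        df = pd.DataFrame({"y": y.astype(int),
                           "e": np.where(exp, "yes", "no")})
        res = adjusted_or_logistic(df, "y", "e", adjusters=())
        crude = odds_ratio_2x2((a, b, c, d))
        assert res["e[yes]"].point == pytest.approx(crude.point, rel=1e-6)

    def test_wald_interval_covers_null_at_nominal_rate(self):
        rng = np.random.default_rng(2)
        n, reps, covered = 400, 120, 0
        for _ in range(reps):
            x = rng.normal(size=n)
            exp = rng.random(n) < 0.5
            y = (rng.random(n) < expit(-1 + 0.8 * x)).astype(int)
            df = pd.DataFrame({"y": y, "e": np.where(exp, "b", "a"),
                               "x": x})
            res = adjusted_or_logistic(df, "y", "e", adjusters=("x",))
            iv = res["e[b]"]
            covered += iv.lo <= 1.0 <= iv.hi
        assert 0.88 <= covered / reps <= 1.0

    def test_adjustment_removes_confounding(self):
        rng = np.random.default_rng(3)
        n = 6000
        conf = rng.normal(size=n)
        exp = rng.random(n) < expit(1.5 * conf)
        y = (rng.random(n) < expit(-1.5 + 1.2 * conf)).astype(int)  # no true effect
        a = int((exp & (y == 1)).sum()); b = int((exp & (y == 0)).sum())
        c = int((~exp & (y == 1)).sum()); d = int((~exp & (y == 0)).sum())
        crude = odds_ratio_2x2((a, b, c, d)).point
        df = pd.DataFrame({"y": y, "e": np.where(exp, "exposed", "control"),
                           "conf": conf})
        adj = adjusted_or_logistic(df, "y", "e", adjusters=("conf",))
        assert abs(np.log(adj["e[exposed]"].point)) < abs(np.log(crude))
        assert res_auc_ok(adj["auc"])


def res_auc_ok(auc):
    return 0.5 <= auc <= 1.0


def _mn_oracle_ci(a, b, c, d, level=0.95):
    """Independent score-interval oracle: restricted MLE by bounded numeric
    likelihood maximization, limits by root bracketing."""
    n1, n2 = a + b, c + d

    def z(delta):
        def negll(p2):
            p1 = p2 + delta
            if not (1e-12 < p1 < 1 - 1e-12 and 1e-12 < p2 < 1 - 1e-12):
                return np.inf
            return -(a * np.log(p1) + b * np.log(1 - p1)
                     + c * np.log(p2) + d * np.log(1 - p2))
        lo = max(1e-10, -delta + 1e-10)
        hi = min(1 - 1e-10, 1 - delta - 1e-10)
        r = optimize.minimize_scalar(negll, bounds=(lo, hi),
                                     method="bounded",
                                     options={"xatol": 1e-13})
        p2t = r.x
        p1t = p2t + delta
        var = (p1t * (1 - p1t) / n1 + p2t * (1 - p2t) / n2) \
            * (n1 + n2) / (n1 + n2 - 1)
        return (a / n1 - c / n2 - delta) / np.sqrt(var)

    zc = sps.norm.ppf(0.5 + level / 2)
    point = a / n1 - c / n2
    lo = optimize.brentq(lambda dl: z(dl) - zc, -1 + 1e-9, point, xtol=1e-12)
    hi = optimize.brentq(lambda dl: z(dl) + zc, point, 1 - 1e-9, xtol=1e-12)
    return lo, hi


class TestMiettinenNurminen:
    def test_printed_risk_differences(self):
        any_rop = mn_risk_difference((1477, 831, 1340, 5888))
        assert round(100 * any_rop.point) == 45
        assert (round(100 * any_rop.lo), round(100 * any_rop.hi)) == (43, 48)
        trt = mn_risk_difference((418, 1890, 115, 7113))
        assert round(100 * trt.point) == 17
        assert (round(100 * trt.lo), round(100 * trt.hi)) == (15, 18)

    def test_identical_groups_straddle_zero(self):
        iv = mn_risk_difference((10, 10, 10, 10))
        assert iv.point == 0
        assert iv.lo < 0 < iv.hi

    @pytest.mark.parametrize("table", [
        (1477, 831, 1340, 5888), (8, 12, 3, 17), (5, 5, 5, 5), (1, 19, 10, 10),
    ])
    def test_limits_match_numeric_oracle(self, table):
        mine = mn_risk_difference(table)
        olo, ohi = _mn_oracle_ci(*table)
        assert mine.lo == pytest.approx(olo, abs=1e-6)
        assert mine.hi == pytest.approx(ohi, abs=1e-6)

    def test_width_shrinks_with_counts(self):
        small = mn_risk_difference((8, 12, 3, 17))
        big = mn_risk_difference((80, 120, 30, 170))
        assert (big.hi - big.lo) < (small.hi - small.lo)
        assert small.lo <= small.point <= small.hi


class TestClopperPearson:
    @pytest.mark.parametrize("x, n, printed_lower", [
        (447, 447, 99.2), (152, 152, 97.6),
    ])
    def test_full_success_lower_bounds_print_correctly(self, x, n,
                                                       printed_lower):
        iv = clopper_pearson(x, n)
        assert round(100 * iv.lo, 1) == printed_lower
        assert iv.hi == 1.0
        # closed form for x == n
        assert iv.lo == pytest.approx(0.025 ** (1 / n), rel=1e-9)

    def test_boundary_cases(self):
        assert clopper_pearson(0, 10).lo == 0.0
        with pytest.raises(ValueError):
            clopper_pearson(5, 0)
        with pytest.raises(ValueError):
            clopper_pearson(11, 10)

    @pytest.mark.parametrize("n", [10, 100])
    def test_exact_coverage_at_least_nominal(self, n):
        # exact coverage by enumeration, no simulation needed
        for p in (0.05, 0.3, 0.7, 0.95):
            cover = 0.0
            for k in range(n + 1):
                iv = clopper_pearson(k, n)
                if iv.lo <= p <= iv.hi:
                    cover += sps.binom.pmf(k, n, p)
            assert cover >= 0.95 - 1e-12


class TestRocYouden:
    def test_perfect_separation(self):
        res = roc_youden([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1],
                         candidate_cutoffs=range(4, 10))
        assert res["auc"] == 1.0
        assert res["youden_j"] == pytest.approx(1.0)

    def test_null_scores_auc_half(self):
        rng = np.random.default_rng(4)
        scores = rng.integers(7, 29, size=4000)
        y = rng.integers(0, 2, size=4000)
        res = roc_youden(scores, y, range(7, 29))
        assert abs(res["auc"] - 0.5) < 0.03

    def test_matches_bruteforce_over_candidates(self):
        rng = np.random.default_rng(5)
        days = rng.integers(0, 60, size=300)
        y = (rng.random(300) < expit((days - 14) / 6)).astype(int)
        res = roc_youden(days, y, range(7, 29))
        best_j, best_c = -np.inf, None
        for c in range(7, 29):
            sens = ((days >= c) & (y == 1)).sum() / (y == 1).sum()
            spec = ((days < c) & (y == 0)).sum() / (y == 0).sum()
            if sens + spec - 1 > best_j + 1e-12:
                best_j, best_c = sens + spec - 1, c
        assert res["best_cutoff"] == best_c
        assert res["youden_j"] == pytest.approx(best_j)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_youden([1, 2, 3], [1, 1, 1], [2])


class TestHosmerLemeshow:
    def test_constant_half_predictions_give_zero_statistic(self):
        p = np.full(200, 0.5)
        y = np.r_[np.ones(100), np.zeros(100)]
        with pytest.warns(RuntimeWarning):
            stat, pval = hosmer_lemeshow(p, y)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_two_group_toy_matches_hand_arithmetic(self):
        p = np.array([0.2, 0.2, 0.2, 0.8, 0.8, 0.8])
        y = np.array([0, 0, 1, 1, 1, 0])
        stat, _ = hosmer_lemeshow(p, y, n_groups=2)
        # group lo: o=1, e=0.6, n=3; group hi: o=2, e=2.4, n=3
        expected = (1 - 0.6) ** 2 / (0.6 * (1 - 0.2)) \
            + (2 - 2.4) ** 2 / (2.4 * (1 - 0.8))
        assert stat == pytest.approx(expected)

    def test_requires_enough_observations(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.5] * 5, [1] * 5, n_groups=10)


class TestSignTest:
    def test_all_discordance_one_way_closed_form(self):
        a = np.ones(10, dtype=int)
        b = np.zeros(10, dtype=int)
        res = sign_test(a, b)
        assert res["p_value"] == pytest.approx(2 * 0.5 ** 10)

    def test_balanced_discordance_p_one(self):
        a = np.array([1, 1, 0, 0] * 5)
        b = np.array([0, 0, 1, 1] * 5)
        assert sign_test(a, b)["p_value"] == pytest.approx(1.0)

    def test_no_discordant_pairs_warns_p_one(self):
        with pytest.warns(RuntimeWarning):
            res = sign_test([1, 0, 1], [1, 0, 1])
        assert res["p_value"] == 1.0

    def test_exhaustive_exact_binomial_oracle_n_le_20(self):
        # oracle: two-sided exact binomial p summing pmf <= pmf(observed)
        for n in range(1, 21):
            pmf = np.array([sps.binom.pmf(k, n, 0.5) for k in range(n + 1)])
            for k in range(n + 1):
                expected = float(pmf[pmf <= pmf[k] + 1e-12].sum())
                a = np.r_[np.ones(k), np.zeros(n - k)].astype(int)
                b = np.r_[np.zeros(k), np.ones(n - k)].astype(int)
                got = sign_test(a, b)["p_value"]
                assert got == pytest.approx(min(expected, 1.0), abs=1e-10), \
                    (n, k)


class TestSpearman:
    def test_monotone_and_reversed(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [2, 4, 9, 16, 30]) == pytest.approx(1.0)
        assert spearman(x, [30, 16, 9, 4, 2]) == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_bruteforce(self):
        x = np.array([1, 2, 2, 3, 3, 3, 4], dtype=float)
        y = np.array([5, 5, 7, 8, 8, 9, 9], dtype=float)

        def midranks(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j + 1 < len(v) and sv[j + 1] == sv[i]:
                    j += 1
                ranks[order[i:j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        rx, ry = midranks(x), midranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2])
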