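import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from jellyom import _fit
from jellyom.growth import (
    CarbonBudget,
    GrowthWindow,
    NoGrowthError,
    aggregate_budgets,
    carbon_budget,
    detect_exponential_window,
    growth_rate,
    two_sample_t_test,
    welch_t_test,
)
from jellyom.stoichiometry import ATOMIC_MASS, CellCarbonFactor


def brute_force_best_window(t, cells):
    """Independent oracle: enumerate every contiguous window of >=3 points
    ending at or before the abundance maximum; pick max R^2 of ln(cells),
    ties to longer then earlier."""
    ln = np.log(cells)
    i_max = int(np.argmax(cells))
    best = None
    for start, end in itertools.combinations(range(i_max + 1), 2):
        if end - start < 2:
            continue
        mu, r2 = _fit.ols_slope(t[start:end + 1], ln[start:end + 1])
        if mu <= 0:
            continue
        key = (r2, end - start, -t[start])
        if best is None or key > best[0]:
            best = (key, (t[start], t[end], mu))
    return None if best is None else best[1]


class TestDetectWindow:
    def test_exact_exponential(self):
        t = np.array([0.0, 6.0, 12.0, 24.0])
        cells = 1e5 * np.exp(0.1 * t)
        w = detect_exponential_window(t, cells)
        assert (w.t_start_h, w.t_end_h) == (0.0, 24.0)
        assert w.mu_per_h == pytest.approx(0.1)
        assert w.r_squared == pytest.approx(1.0)

    def test_exponential_then_plateau(self):
        t = np.array([0.0, 6.0, 12.0, 24.0, 32.0, 46.0, 56.0])
        cells = np.where(t <= 32.0, 1e5 * np.exp(0.09 * t), 1e5 * math.exp(0.09 * 32))
        w = detect_exponential_window(t, cells)
        assert w.t_end_h <= 32.0
        assert w.mu_per_h == pytest.approx(0.09)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            t = np.sort(rng.choice(np.arange(0, 60, 2.0), size=6, replace=False))
            cells = 1e5 * np.exp(0.08 * t) * rng.lognormal(0, 0.1, t.size)
            oracle = brute_force_best_window(t, cells)
            if oracle is None:
                with pytest.raises(NoGrowthError):
                    detect_exponential_window(t, cells)
                continue
            w = detect_exponential_window(t, cells)
            assert (w.t_start_h, w.t_end_h) == oracle[:2]
            assert w.mu_per_h == pytest.approx(oracle[2])

    def test_constant_series_errors(self):
        with pytest.raises(NoGrowthError):
            detect_exponential_window([0, 6, 12, 24], [1e5] * 4)

    def test_decreasing_series_errors(self):
        with pytest.raises(NoGrowthError):
            detect_exponential_window([0, 6, 12, 24], [1e6, 5e5, 2e5, 1e5])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            detect_exponential_window([0, 6, 12], [1, 2, 4])

    def test_nonpositive_cells_rejected(self):
        with pytest.raises(ValueError):
            detect_exponential_window([0, 6, 12, 24], [1e5, 0, 2e5, 4e5])


class TestGrowthRate:
    def test_daily_conversion(self):
        w = GrowthWindow(0, 24, 4, 0.09, 1.0)
        out = growth_rate(w)
        assert out["mu_per_d"] == pytest.approx(2.16)

    def test_zero(self):
        # degenerate mu; window itself is valid
        w = GrowthWindow(0, 24, 4, 0.0, 0.5)
        assert growth_rate(w)["mu_per_d"] == 0

    def test_doubling_per_hour(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        cells = np.array([1.0, 2.0, 4.0, 8.0])
        w = detect_exponential_window(t, cells)
        assert w.mu_per_h == pytest.approx(math.log(2))


class TestCarbonBudget:
    WINDOW = GrowthWindow(0.0, 32.0, 5, 0.09, 1.0)
    T = np.array([0.0, 6.0, 12.0, 24.0, 32.0])

    def test_constant_doc_flags_no_consumption(self):
        cells = 5.7e5 * np.exp(0.09 * self.T)
        b = carbon_budget(self.T, np.full(5, 44.0), self.T, cells, self.WINDOW)
        assert b.bcd_ugc_l_h == pytest.approx(0.0)
        assert b.bge_pct is None
        assert "no_net_consumption" in b.flags

    def test_programmed_bge_recovered_exactly(self):
        # closed-form closure: DOC drawdown = biomass increase / BGE
        bge = 0.65
        fg = 19.8
        cells = 5.7e5 * np.exp(0.09 * self.T)
        biomass_ugc = (cells - cells[0]) * 1e3 * fg * 1e-9
        doc = 69.0 - biomass_ugc / (bge * ATOMIC_MASS["C"])
        b = carbon_budget(self.T, doc, self.T, cells, self.WINDOW)
        assert b.bge_pct == pytest.approx(65.0, rel=1e-12)
        assert b.br_ugc_l_h / b.bcd_ugc_l_h == pytest.approx(0.35, rel=1e-12)

    def test_bp_equals_bcd_boundary(self):
        fg = 19.8
        cells = 5.7e5 * np.exp(0.09 * self.T)
        doc = 69.0 - (cells - cells[0]) * 1e3 * fg * 1e-9 / ATOMIC_MASS["C"]
        b = carbon_budget(self.T, doc, self.T, cells, self.WINDOW)
        assert b.br_ugc_l_h == pytest.approx(0.0, abs=1e-9)
        assert b.bge_pct == pytest.approx(100.0)

    def test_budget_identity_exact(self):
        rng = np.random.default_rng(3)
        cells = 5.7e5 * np.exp(0.09 * self.T) * rng.lognormal(0, 0.05, 5)
        doc = np.maximum(44.0 - self.T * 0.5, 1.0) * rng.lognormal(0, 0.05, 5)
        b = carbon_budget(self.T, doc, self.T, cells, self.WINDOW)
        assert b.br_ugc_l_h + b.bp_ugc_l_h == pytest.approx(b.bcd_ugc_l_h, rel=1e-12)

    def test_window_not_covered_rejected(self):
        with pytest.raises(ValueError):
            carbon_budget([40.0, 50.0], [1.0, 2.0], self.T,
                          5.7e5 * np.exp(0.09 * self.T), self.WINDOW)

    def test_bb_from_peak_cells(self):
        cells = 5.7e5 * np.exp(0.09 * self.T)
        doc = 69.0 - self.T * 0.1
        b = carbon_budget(self.T, doc, self.T, cells, self.WINDOW,
                          factor=CellCarbonFactor(19.8))
        assert b.bb_ugc_l == pytest.approx(cells[-1] * 1e3 * 19.8e-9)


class TestTTest:
    def test_identical_arms(self):
        res = two_sample_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == 1.0 and res.t == 0.0

    def test_large_shift(self):
        res = two_sample_t_test([101.0, 102.0, 103.0], [1.0, 2.0, 3.0])
        assert res.p < 1e-6

    def test_hand_computed_t(self):
        # pooled sp2 = 2.5, se = sqrt(2.5 * 2/3), t = 10/se = sqrt(60)
        res = two_sample_t_test([10.0, 12.0, 14.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(math.sqrt(60), rel=1e-12)
        assert res.df == 4

    def test_agrees_with_scipy(self):
        a, b = [10.0, 12.0, 14.0], [1.0, 2.0, 3.0]
        ours = two_sample_t_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert ours.t == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue)

    def test_zero_variance_unequal_means(self):
        res = two_sample_t_test([1.0, 1.0], [2.0, 2.0])
        assert res.p == 0.0 and "zero_variance" in res.flags

    def test_single_value_arm_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t_test([1.0], [1.0, 2.0])

    def test_welch_matches_scipy(self):
        a, b = [10.0, 12.0, 19.0], [1.0, 2.0, 3.0]
        ours = welch_t_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert ours.p == pytest.approx(ref.pvalue)

    def test_agrees_with_exact_permutation(self):
        # exact enumeration of all 20 label assignments (n=3+3)
        a = np.array([9.0, 12.0, 15.0])
        b = np.array([4.0, 6.0, 8.0])
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = 0
        total = 0
        for idx in itertools.combinations(range(6), 3):
            mask = np.zeros(6, bool)
            mask[list(idx)] = True
            diff = abs(pooled[mask].mean() - pooled[~mask].mean())
            count += diff >= obs - 1e-12
            total += 1
        p_perm = count / total
        p_t = two_sample_t_test(a, b).p
        assert abs(p_t - p_perm) < 0.15  # permutation granularity is 1/20


def make_budget(rid, bcd, bp, mu=0.09, bb=200.0):
    return CarbonBudget(rid, bcd, bp, bcd - bp, 100.0 * bp / bcd, mu, bb)


class TestAggregate:
    def test_mean_of_ratios_not_ratio_of_means(self):
        budgets = [make_budget("J1", 10.0, 3.8), make_budget("J2", 50.0, 46.0)]
        control = [make_budget("C1", 1.0, 0.1), make_budget("C2", 1.2, 0.1)]
        out = aggregate_budgets(budgets, control)
        # per-replicate BGEs are 38 and 92 -> mean 65
        assert out["quantities"]["bge"]["mean"] == pytest.approx(65.0)
        # the ratio-of-means diagnostic differs: 100*49.8/60 = 83
        assert out["bge_ratio_of_means_pct"] == pytest.approx(83.0)

    def test_identical_replicates_sd_zero(self):
        budgets = [make_budget("J1", 10.0, 5.0), make_budget("J2", 10.0, 5.0)]
        control = [make_budget("C1", 1.0, 0.5), make_budget("C2", 1.0, 0.5)]
        out = aggregate_budgets(budgets, control)
        assert out["quantities"]["bcd"]["sd"] == 0.0

    def test_p_value_matches_direct_t_test(self):
        budgets = [make_budget(f"J{i}", v, v / 2) for i, v in enumerate((10.0, 12.0, 14.0))]
        control = [make_budget(f"C{i}", v, v / 2) for i, v in enumerate((1.0, 2.0, 3.0))]
        out = aggregate_budgets(budgets, control)
        direct = two_sample_t_test([10.0, 12.0, 14.0], [1.0, 2.0, 3.0])
        assert out["quantities"]["bcd"]["p_value"] == pytest.approx(direct.p)
        assert direct.p == pytest.approx(0.0015, abs=2e-4)

    def test_permutation_invariance(self):
        budgets = [make_budget(f"J{i}", v, v / 2) for i, v in enumerate((10.0, 12.0, 14.0))]
        control = [make_budget(f"C{i}", v, v / 2) for i, v in enumerate((1.0, 2.0, 3.0))]
        out1 = aggregate_budgets(budgets, control)
        out2 = aggregate_budgets(budgets[::-1], control[::-1])
        assert out1["quantities"] == out2["quantities"]

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            aggregate_budgets([make_budget("J1", 10.0, 5.0)],
                              [make_budget("C1", 1.0, 0.5), make_budget("C2", 1.0, 0.5)])
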