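"""MAD/MAPD/RMSE, stratified reports, Bland-Altman, bootstrap procedures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wearbp.evaluation as ev


def oracle_metrics(pairs):
    """Independent elementwise arithmetic oracle for the three metrics."""
    n = len(pairs)
    sum_abs = sum_sq = sum_pct = 0.0
    for p, y in pairs:
        sum_abs += abs(p - y)
        sum_sq += (p - y) ** 2
        sum_pct += 100.0 * abs(p - y) / y
    return sum_abs / n, sum_pct / n, (sum_sq / n) ** 0.5


class TestMetrics:
    def test_worked_example(self):
        p, y = [122, 116], [120, 120]
        assert ev.mad(p, y) == 3.0  # mean of |2| and |-4|
        assert ev.rmse(p, y) == pytest.approx(np.sqrt(10.0))
        assert ev.mapd(p, y) == pytest.approx(2.5)

    def test_perfect_agreement(self):
        y = [118.0, 140.0, 92.0]
        assert ev.mad(y, y) == ev.rmse(y, y) == ev.mapd(y, y) == 0.0

    def test_single_pair_degenerate(self):
        assert ev.mad([125], [120]) == ev.rmse([125], [120]) == 5.0

    def test_empty_pairs_error(self):
        with pytest.raises(ValueError, match="empty"):
            ev.mad([], [])

    def test_mapd_zero_reference_error(self):
        with pytest.raises(ValueError, match="y_i = 0"):
            ev.mapd([1.0], [0.0])

    @given(st.integers(0, 2**31 - 1), st.integers(1, 60))
    @settings(max_examples=100, deadline=None)
    def test_matches_oracle_and_rmse_dominates_mad(self, seed, n):
        rng = np.random.default_rng(seed)
        p = rng.uniform(60, 200, n)
        y = rng.uniform(60, 200, n)
        o_mad, o_mapd, o_rmse = oracle_metrics(list(zip(p, y)))
        assert ev.mad(p, y) == pytest.approx(o_mad, rel=1e-12)
        assert ev.mapd(p, y) == pytest.approx(o_mapd, rel=1e-12)
        assert ev.rmse(p, y) == pytest.approx(o_rmse, rel=1e-12)
        assert ev.rmse(p, y) >= ev.mad(p, y) - 1e-12


class TestStratifiedReport:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["target", "p", "y", "condition", "split"])

    def test_single_condition_equals_overall(self):
        pairs = self._pairs([("sbp", 122, 120, "static", "test"),
                             ("sbp", 116, 120, "static", "test")])
        rep = ev.stratified_report(pairs)
        assert (rep["sbp"]["strata"]["static"]["test"]
                == rep["sbp"]["strata"]["overall"]["test"])
        assert rep["sbp"]["strata"]["overall"]["test"]["mad"] == 3.0

    def test_overall_mad_is_weighted_mean(self, rng):
        rows = []
        for cond, n in (("static", 12), ("cold_walk", 30)):
            for _ in range(n):
                y = rng.uniform(100, 160)
                rows.append(("sbp", y + rng.normal(0, 6), y, cond, "test"))
        rep = ev.stratified_report(self._pairs(rows))["sbp"]["strata"]
        m1, n1 = rep["static"]["test"]["mad"], rep["static"]["test"]["n"]
        m2, n2 = rep["cold_walk"]["test"]["mad"], rep["cold_walk"]["test"]["n"]
        overall = rep["overall"]["test"]["mad"]
        assert overall == pytest.approx((n1 * m1 + n2 * m2) / (n1 + n2), rel=1e-12)

    def test_empty_stratum_reports_n_zero(self):
        pairs = self._pairs([("dbp", 82, 80, "rest", "train")])
        rep = ev.stratified_report(pairs)
        assert rep["dbp"]["strata"]["warm_rest"]["train"] == {"n": 0}
        assert rep["dbp"]["strata"]["rest"]["test"] == {"n": 0}

    def test_bland_altman_symmetric_errors(self):
        """Zero-mean +/-e errors give mean diff 0 and limits +/-1.96 e."""
        e = 4.0
        y = np.full(200, 120.0)
        p = y + np.tile([e, -e], 100)
        ba = ev.bland_altman(p, y)
        sd = np.std(np.tile([e, -e], 100), ddof=1)
        assert ba["mean_diff"] == 0.0
        assert ba["loa_upper"] == pytest.approx(1.96 * sd)
        assert ba["loa_lower"] == pytest.approx(-1.96 * sd)


class TestBootstrapComparison:
    def test_identical_models_never_superior(self, rng):
        y = rng.uniform(100, 160, 100)
        p = y + rng.normal(0, 5, 100)
        cmp = ev.bootstrap_rmse_comparison(p, p, y, n_resamples=2000, seed=1)
        assert cmp.p_value == 1.0
        assert not cmp.superior
        assert cmp.diff == 0.0

    def test_uniform_error_inflation_forces_superiority(self, rng):
        y = rng.uniform(100, 160, 300)
        err = rng.normal(0, 4, 300)
        model_p = y + err
        baseline_p = y + err + np.sign(err + 1e-12) * 5.0  # every |error| grows 5
        cmp = ev.bootstrap_rmse_comparison(model_p, baseline_p, y,
                                           n_resamples=2000, seed=2)
        assert cmp.diff_ci[1] < 0
        assert cmp.superior
        assert cmp.p_value == pytest.approx(1 / 2000)

    def test_paired_draws_and_determinism(self, rng):
        y = rng.uniform(100, 160, 80)
        pm = y + rng.normal(0, 3, 80)
        pb = y + rng.normal(0, 5, 80)
        a = ev.bootstrap_rmse_comparison(pm, pb, y, n_resamples=500, seed=7)
        b = ev.bootstrap_rmse_comparison(pm, pb, y, n_resamples=500, seed=7)
        assert a == b
        assert a.model_ci[0] <= a.model_rmse <= a.model_ci[1]
        assert a.diff_ci[0] <= a.diff <= a.diff_ci[1]

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            ev.bootstrap_rmse_comparison([1.0, 2.0], [1.0], [1.0, 2.0])


class TestBootstrapMadCI:
    def test_constant_errors_degenerate_ci(self):
        y = np.full(30, 120.0)
        p = y + 3.0
        assert ev.bootstrap_mad_ci(p, y, seed=0) == (3.0, 3.0)

    def test_deterministic_given_seed(self, rng):
        y = rng.uniform(100, 160, 50)
        p = y + rng.normal(0, 5, 50)
        assert ev.bootstrap_mad_ci(p, y, seed=3) == ev.bootstrap_mad_ci(p, y, seed=3)

    def test_ci_brackets_point_estimate(self, rng):
        y = rng.uniform(100, 160, 200)
        p = y + rng.normal(0, 5, 200)
        lo, hi = ev.bootstrap_mad_ci(p, y, seed=4)
        assert lo <= ev.mad(p, y) <= hi
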