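import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import trialsens as ts
from trialsens.errors import BoundarySolutionError

from conftest import random_trial_tables

VERTEX = (0.49578, 2.0170)  # anti-diagonal vertex of the skeptical region


def _loglik(zeta, eta, table, r_c, r_t):
    out = 0.0
    for arm, z in (("c", 0.0), ("t", 1.0)):
        y = getattr(table, f"y_{arm}")
        m = getattr(table, f"m_{arm}")
        n = getattr(table, f"n_{arm}")
        lp = zeta + eta * z
        gamma = np.log(r_c if arm == "c" else r_t)
        out += lp * y - n * np.log1p(np.exp(lp)) + (n - m) * np.log1p(np.exp(lp + gamma))
    return out


def _oracle_z(table, r_c, r_t, h=1e-5):
    """Score statistic computed straight from the log-likelihood: scalar
    maximization for the constrained MLE, finite differences for the score,
    and the profile information for the variance."""
    res = minimize_scalar(
        lambda z: -_loglik(z, 0.0, table, r_c, r_t),
        bounds=(-12, 12), method="bounded", options={"xatol": 1e-12},
    )
    zeta = res.x
    f = lambda a, b: _loglik(a, b, table, r_c, r_t)
    u_eta = (f(zeta, h) - f(zeta, -h)) / (2 * h)
    i_zz = -(f(zeta + h, 0) - 2 * f(zeta, 0) + f(zeta - h, 0)) / h**2
    i_ee = -(f(zeta, h) - 2 * f(zeta, 0) + f(zeta, -h)) / h**2
    i_ze = -(f(zeta + h, h) - f(zeta + h, -h) - f(zeta - h, h) + f(zeta - h, -h)) / (
        4 * h**2
    )
    return -u_eta / np.sqrt(i_ee - i_ze**2 / i_zz)


class TestNullEstimate:
    def test_mar_gives_pooled_proportion(self, table2):
        assert ts.solve_null_p(table2, 1.0, 1.0) == pytest.approx(59 / 180, abs=1e-10)

    def test_skeptical_vertex(self, table2):
        assert ts.solve_null_p(table2, *VERTEX) == pytest.approx(0.32804, abs=5e-5)

    def test_worst_case_limit_closed_form(self, table2):
        # r_c -> 0, r_t -> inf: the score equation collapses to
        # 59 - 200 p + 9 = 0
        assert ts.solve_null_p(table2, 0.0, np.inf) == pytest.approx(68 / 200, abs=1e-9)

    def test_residual_small_across_extreme_ratios(self, table2):
        for r_c in (1e-12, 1e-6, 1.0, 1e6, 1e12):
            for r_t in (1e-12, 1.0, 1e12):
                p = ts.solve_null_p(table2, r_c, r_t)
                resid = (table2.y_c + table2.y_t) - sum(
                    n * p - (n - m) * r * p / (1 - p + r * p)
                    for n, m, r in (
                        (table2.n_c, table2.m_c, r_c),
                        (table2.n_t, table2.m_t, r_t),
                    )
                )
                assert 0.0 < p < 1.0
                assert abs(resid) < 1e-10

    @pytest.mark.parametrize("y_c, y_t", [(0, 0), (89, 91)])
    def test_boundary_tables_raise(self, y_c, y_t):
        t = ts.TrialTable(y_c=y_c, m_c=89, n_c=100, y_t=y_t, m_t=91, n_t=100)
        with pytest.raises(BoundarySolutionError):
            ts.solve_null_p(t, 1.0, 1.0)


class TestScoreAndVariance:
    def test_mar_reduction(self, table2):
        """At r = 1 the score and variance collapse to the complete-case
        forms."""
        p = 59 / 180
        score, var = ts.score_and_variance(table2, 1.0, 1.0, p)
        assert score == pytest.approx(table2.y_t - table2.m_t * p, abs=1e-9)
        m_c, m_t = table2.m_c, table2.m_t
        assert var == pytest.approx(p * (1 - p) * m_c * m_t / (m_c + m_t), abs=1e-9)

    def test_skeptical_vertex_values(self, table2):
        p = ts.solve_null_p(table2, *VERTEX)
        score, var = ts.score_and_variance(table2, *VERTEX, p)
        assert score == pytest.approx(-7.339, abs=2e-3)
        assert var == pytest.approx(10.026, abs=2e-3)

    def test_no_missing_variance(self):
        t = ts.TrialTable(y_c=30, m_c=100, n_c=100, y_t=20, m_t=100, n_t=100)
        _, var = ts.score_and_variance(t, 3.0, 0.2, 0.25)
        full = 0.25 * 0.75 * 100
        assert var == pytest.approx(1 / (2 / full), abs=1e-9)


class TestZStatistic:
    def test_mar_identity_with_complete_case(self):
        """Z(1,1) is exactly the complete-case statistic."""
        for t in random_trial_tables(seed=31, count=100):
            z = ts.z_statistic(t, 1.0, 1.0).z
            assert z == pytest.approx(ts.complete_case_stats(t).z_tilde, abs=1e-9)

    def test_limits_match_extreme_imputation(self):
        """r -> (0, inf) and (inf, 0) reproduce worst/best imputed tables."""
        for t in random_trial_tables(seed=32, count=50):
            worst = ts.complete_case_stats(ts.impute_extreme(t, "worst")).z_tilde
            best = ts.complete_case_stats(ts.impute_extreme(t, "best")).z_tilde
            assert ts.z_statistic(t, 0.0, np.inf).z == pytest.approx(worst, abs=1e-9)
            assert ts.z_statistic(t, np.inf, 0.0).z == pytest.approx(best, abs=1e-9)
            assert ts.z_statistic(t, 1e-12, 1e12).z == pytest.approx(worst, abs=1e-6)

    def test_skeptical_vertex_value(self, table2):
        assert ts.z_statistic(table2, *VERTEX).z == pytest.approx(2.3178, abs=1e-3)

    def test_matches_numerical_likelihood_oracle(self, table2):
        tables = [table2, ts.table3_fixture("b").table, ts.table3_fixture("g").table]
        points = [(1.0, 1.0), VERTEX, (0.82, 3.14), (3.0, 0.4)]
        for t in tables:
            for r_c, r_t in points:
                assert ts.z_statistic(t, r_c, r_t).z == pytest.approx(
                    _oracle_z(t, r_c, r_t), abs=2e-3
                )

    def test_monotone_in_each_ratio(self, table2):
        """On the worked example, z falls as r_t grows (missing t subjects
        treated as more likely failures) and rises with r_c."""
        grid = np.exp(np.linspace(-np.log(6), np.log(6), 25))
        z_rt = ts.z_values(table2, 1.0, grid)
        assert np.all(np.diff(z_rt) <= 1e-12)
        z_rc = ts.z_values(table2, grid, 1.0)
        assert np.all(np.diff(z_rc) >= -1e-12)

    def test_vectorized_matches_scalar(self, table2):
        pts = np.array([[0.5, 2.0], [1.0, 1.0], [4.0, 0.3]])
        vec = ts.z_values(table2, pts[:, 0], pts[:, 1])
        for row, expected in zip(pts, vec):
            assert ts.z_statistic(table2, *row).z == pytest.approx(expected, abs=1e-12)

    def test_result_invariants(self, table2):
        res = ts.z_statistic(table2, 0.7, 1.4)
        assert 0 < res.p_null < 1
        assert res.variance > 0
        assert res.z == pytest.approx(-res.score / np.sqrt(res.variance))
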