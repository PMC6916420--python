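from dataclasses import replace

import numpy as np
import pytest

import trialsens as ts
from trialsens.design import (
    DesignSpec,
    attainability_scan,
    inflation_factor,
    n_star_complete,
    simulated_power,
    theta,
)
from trialsens.errors import InfeasibleParameterError, ValidationError
from trialsens.plausibility_region import PlausibilityRegion


def _mar_spec(n_star=1000, q=0.10, p_t=0.236):
    return DesignSpec(
        p_c=0.3, p_t=p_t, q_c=q, q_t=q, region=PlausibilityRegion(1.0), n_star=n_star
    )


class TestNStar:
    @pytest.mark.parametrize(
        "p_t, nominal, rel_tol",
        [(0.236, 1000, 0.01), (0.116, 100, 0.035), (0.279, 10000, 0.02)],
    )
    def test_conventional_panel_sizes(self, p_t, nominal, rel_tol):
        assert n_star_complete(0.3, p_t) == pytest.approx(nominal, rel=rel_tol)

    def test_symmetric_in_rates(self):
        assert n_star_complete(0.3, 0.236) == n_star_complete(0.236, 0.3)

    def test_equal_rates_rejected(self):
        with pytest.raises(ValidationError):
            n_star_complete(0.3, 0.3)


class TestTheta:
    def test_mar_expected_z(self):
        """theta(1,1) for the MAR singleton equals the complete-case Z of the
        expected table (independent recomputation from the closed form)."""
        val = theta(_mar_spec(), 1.0, 1.0)
        pbar = (270.0 + 212.4) / 1800.0
        z_exp = (0.30 - 0.236) / np.sqrt(pbar * (1 - pbar) * (2 / 900.0))
        assert val == pytest.approx(z_exp, abs=1e-6)
        assert val == pytest.approx(3.07, abs=0.01)

    def test_no_missingness_recovers_complete_data_z(self):
        spec = _mar_spec(q=0.0)
        pbar = 0.268
        z_exp = 0.064 / np.sqrt(pbar * (1 - pbar) * (2 / 1000.0))
        assert theta(spec, 1.0, 1.0) == pytest.approx(z_exp, abs=1e-9)

    def test_bounded_by_matched_analysis_point(self):
        """theta at (r_c, r_t) cannot exceed the expected Z when the true
        mechanism equals the analysis point (the min ranges over a set that
        contains it)."""
        spec = replace(ts.scenario("fig4"), region=PlausibilityRegion(1.6, 0.9))
        from trialsens.missingness_model import SelectionModel, expected_table
        from trialsens.score_test import z_statistic

        r = (1.3, 0.9)
        model = SelectionModel.from_q(
            p_c=0.3, p_t=0.236, q_c=0.1, q_t=0.1, n_c=1000, n_t=1000,
            r_c=r[0], r_t=r[1],
        )
        matched = z_statistic(expected_table(model), *r).z
        assert theta(spec, *r, resolution=31, boundary_count=64) <= matched + 1e-9


class TestInflation:
    def test_mar_recovers_usual_factor(self):
        res = inflation_factor(_mar_spec())
        assert res.attainable
        assert res.inflation == pytest.approx(1 / 0.9, abs=0.02)
        assert res.n_required == int(np.ceil(res.inflation * 1000))

    def test_mar_rounded_arithmetic(self):
        res = inflation_factor(_mar_spec(), rounded_z=True)
        assert res.z_sum == 3.24
        assert res.inflation == pytest.approx(1.11, abs=0.05)

    def test_moderate_region_printed_values(self):
        """q = 0.10, n* = 1000, a = 2.30: minimized theta about 1.46 and a
        near-fivefold inflation with the rounded z sum."""
        res = inflation_factor(
            ts.scenario("fig4"), resolution=31, boundary_count=128, rounded_z=True
        )
        assert res.theta_min == pytest.approx(1.46, abs=0.02)
        assert res.inflation == pytest.approx(4.92, abs=0.05)

    def test_skeptical_region_unattainable_at_ten_percent(self):
        res = inflation_factor(ts.scenario("fig5-B"), resolution=31, boundary_count=128)
        assert not res.attainable
        assert res.theta_min < 0
        assert np.isinf(res.inflation) and res.n_required is None

    def test_theta_min_decreases_with_scale_and_missingness(self):
        spec = ts.scenario("fig5-B")
        by_a = [
            inflation_factor(
                replace(spec, region=PlausibilityRegion(a, 0.9)),
                resolution=21, boundary_count=64,
            ).theta_min
            for a in (1.0, 2.0, 3.0)
        ]
        assert np.all(np.diff(by_a) < 0)
        by_q = [
            inflation_factor(
                replace(spec, q_c=q, q_t=q, region=PlausibilityRegion(2.0, 0.9)),
                resolution=21, boundary_count=64,
            ).theta_min
            for q in (0.05, 0.10, 0.15)
        ]
        assert np.all(np.diff(by_q) < 0)

    def test_infeasible_missingness_raises(self):
        spec = DesignSpec(
            p_c=0.3, p_t=0.116, q_c=0.4, q_t=0.4,
            region=PlausibilityRegion(5.0, 0.9), n_star=100,
        )
        with pytest.raises(InfeasibleParameterError):
            inflation_factor(spec, resolution=21, boundary_count=64)


class TestAttainabilityScan:
    def test_monotone_and_reports_boundary_crossing(self):
        spec = ts.scenario("fig5-B")
        frame = attainability_scan(
            spec, [1.0, 2.0, 3.0, 4.0, 5.0], resolution=21, boundary_count=64
        )
        infl = frame.inflation.to_numpy()
        assert np.all(np.diff(infl) >= -1e-9)
        assert frame.attainable.iloc[0]
        assert not frame.attainable.iloc[-1]

    def test_descending_scales_rejected(self):
        with pytest.raises(ValidationError, match="ascending"):
            attainability_scan(ts.scenario("fig5-B"), [2.0, 1.0])


class TestSimulatedPower:
    def test_reproducible(self):
        spec = replace(
            ts.scenario("fig5-A"), region=PlausibilityRegion(2.0, 0.9), q_c=0.05, q_t=0.05
        )
        kw = dict(n=200, true_point=(1.0, 1.0), replicates=200, seed=8,
                  resolution=21, boundary_count=32)
        assert simulated_power(spec, **kw) == simulated_power(spec, **kw)

    def test_unattainable_design_power_shrinks_with_n(self):
        """When the minimized expected Z is negative, the adversarial
        (true, analysis) pair drives the one-sided rejection rate toward
        zero as n grows — more subjects cannot rescue the design."""
        spec = ts.scenario("fig5-B")
        res = inflation_factor(spec, resolution=31, boundary_count=128)
        assert res.theta_min < 0
        rates = [
            simulated_power(
                spec, n, res.least_favorable, replicates=400, seed=5,
                points=np.array([res.theta_argmin]),
            )
            for n in (1000, 10_000)
        ]
        assert rates[1] <= rates[0] + 0.02
        assert rates[1] < 0.05
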