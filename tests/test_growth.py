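"""Deterministic growth law: rates, equilibria, approximations, trajectories."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from xlogistic import (GrowthParams, apr, apr_derivative, find_equilibria,
                       inflection_densities, max_rpr_density_approx,
                       mssd_approx, potential, rpr, solve_trajectory,
                       threshold_approx)

# strategy for physically sensible random hexads
hexads = hst.builds(
    GrowthParams,
    r_p=hst.floats(0.05, 1.0),
    K=hst.floats(0.5, 5.0),
    n=hst.floats(0.0, 0.05),
    alpha=hst.floats(0.0, 3.0),
    beta=hst.floats(0.2, 3.0),
    delta=hst.floats(0.0, 3.0),
)


class TestRates:
    def test_apr_vanishes_at_zero(self, seeding1):
        assert apr(seeding1, 0.0) == 0.0

    def test_apr_zero_at_equilibrium(self, seeding1):
        assert abs(apr(seeding1, 1.3507)) < 1e-3

    def test_apr_at_carrying_capacity(self, seeding1):
        # bracket vanishes at x=K, leaving the pure feedback term
        expected = -seeding1.n * seeding1.K ** (seeding1.delta + 1.0)
        assert apr(seeding1, seeding1.K) == pytest.approx(expected, rel=1e-12)
        assert apr(seeding1, seeding1.K) == pytest.approx(-0.0146, abs=5e-5)

    def test_apr_rejects_negative_density(self, seeding1):
        with pytest.raises(ValueError):
            apr(seeding1, -0.1)

    def test_apr_vectorizes(self, seeding1):
        xs = np.linspace(0, 2, 7)
        vals = apr(seeding1, xs)
        assert vals.shape == xs.shape
        assert vals[0] == 0.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(p=hexads, x=hst.floats(0.01, 4.0))
    def test_rpr_times_density_is_apr(self, p, x):
        assert rpr(p, x) * x == pytest.approx(apr(p, x), rel=1e-12, abs=1e-300)

    def test_rpr_negative_below_threshold(self, seeding1):
        # Allee behaviour: negative per-capita rate at low positive density
        assert rpr(seeding1, 0.05) < 0

    def test_rpr_zero_at_equilibrium(self, seeding1):
        assert abs(rpr(seeding1, 1.3507)) < 1e-3

    def test_rpr_rejects_nonpositive(self, seeding1):
        with pytest.raises(ValueError):
            rpr(seeding1, 0.0)


class TestDerivative:
    def test_zero_at_highest_inflection(self, seeding1):
        assert abs(apr_derivative(seeding1, 0.9325)) < 1e-3

    def test_negative_at_stable_equilibrium(self, seeding1):
        assert apr_derivative(seeding1, 1.3507) < 0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(p=hexads, x=hst.floats(0.05, 3.0))
    def test_matches_central_difference(self, p, x):
        h = 1e-6 * x
        fd = (apr(p, x + h) - apr(p, x - h)) / (2 * h)
        assert apr_derivative(p, x) == pytest.approx(fd, rel=1e-5, abs=1e-10)


class TestEquilibria:
    @pytest.mark.parametrize("seeding", [1, 2, 3])
    def test_reference_roots(self, pre, table3, seeding):
        p = pre.table2_hexads[seeding]
        eq = find_equilibria(p)
        ref = table3[seeding]
        assert eq.threshold == pytest.approx(ref["threshold"], abs=5e-4)
        assert eq.mssd == pytest.approx(ref["mssd"], abs=5e-4)
        stabs = {round(e.density, 4): e.stability for e in eq.equilibria}
        assert stabs[0.0] == "stable"

    def test_seeding1_structure(self, seeding1):
        eq = find_equilibria(seeding1)
        assert [e.stability for e in eq.equilibria] == ["stable", "unstable", "stable"]
        assert eq.threshold < eq.mssd

    def test_residual_invariant(self, pre):
        for p in pre.table2_hexads.values():
            eq = find_equilibria(p)
            scale = max(1.0, p.r_p * p.K ** (p.alpha + 1.0))
            for e in eq.equilibria:
                assert abs(apr(p, e.density)) <= 1e-9 * scale

    def test_equal_exponent_closed_form(self):
        # alpha = delta collapses the feedback into the growth term:
        # interior stable root K (1 - n/r_p)^(1/beta), zero unstable
        p = GrowthParams(r_p=0.2, K=2.0, n=0.1, alpha=0.5, beta=1.0, delta=0.5)
        eq = find_equilibria(p)
        assert eq.mssd == pytest.approx(1.0, abs=1e-9)
        assert eq.threshold is None
        assert eq.equilibria[0].stability == "unstable"

    def test_no_feedback_reduces_to_generalized_logistic(self):
        p = GrowthParams(r_p=0.13, K=1.43, n=0.0, alpha=1.15, beta=0.99, delta=0.2)
        eq = find_equilibria(p)
        assert eq.mssd == pytest.approx(p.K, abs=1e-9)
        assert eq.equilibria[0].stability == "unstable"
        assert eq.threshold is None

    def test_search_upper_must_exceed_K(self, seeding1):
        with pytest.raises(ValueError):
            find_equilibria(seeding1, search_upper=0.5)

    @pytest.mark.parametrize("offset", [0.99, 1.01])
    def test_stability_consistent_with_dynamics(self, seeding1, offset):
        eq = find_equilibria(seeding1)
        for e in eq.equilibria:
            if e.density == 0.0:
                continue
            x0 = e.density * offset
            traj = solve_trajectory(seeding1, x0, [0.0, 80.0])
            moved = abs(traj.terminal - e.density) - abs(x0 - e.density)
            if e.stability == "stable":
                assert moved < 0
            else:
                assert moved > 0


class TestSeriesApproximations:
    def test_mssd_minus_branch_seeding1(self, seeding1):
        res = mssd_approx(seeding1)
        assert res.exists
        assert res.value == pytest.approx(1.3507, abs=5e-4)

    def test_mssd_exact_K_without_feedback(self):
        p = GrowthParams(r_p=0.13, K=1.43, n=0.0, alpha=1.15, beta=0.99, delta=0.2)
        assert mssd_approx(p).value == pytest.approx(p.K, rel=1e-12)

    @pytest.mark.parametrize("seeding", [2, 3])
    def test_mssd_within_2pct_of_numeric(self, pre, seeding):
        p = pre.table2_hexads[seeding]
        numeric = find_equilibria(p).mssd
        assert mssd_approx(p).value == pytest.approx(numeric, rel=0.02)

    def test_no_msscd_region(self):
        # strong feedback regulation with weak crowding: negative discriminant
        p = GrowthParams(r_p=0.13, K=1.43, n=0.0095, alpha=1.15, beta=0.19, delta=5.0)
        res = mssd_approx(p)
        assert not res.exists and res.value is None and res.discriminant < 0

    def test_threshold_plus_branch_diverges_from_numeric(self, seeding1):
        # the expansion about K is poor for a root far below K; both values
        # are surfaced so the caller sees the gap
        res = threshold_approx(seeding1)
        assert res.value == pytest.approx(0.2426, abs=5e-4)
        assert res.numeric == pytest.approx(0.0671, abs=5e-4)
        assert res.value > 3 * res.numeric

    def test_branch_ordering(self, pre):
        for p in pre.table2_hexads.values():
            plus = threshold_approx(p, with_numeric=False)
            minus = mssd_approx(p)
            if plus.exists and minus.exists:
                assert plus.value < minus.value


class TestInflections:
    @pytest.mark.parametrize("seeding,key_lo,key_hi", [
        (1, "inflection_low", "inflection_high"),
        (2, "inflection_low", "inflection_high"),
        (3, "inflection_low", "inflection_high"),
    ])
    def test_reference_inflections(self, pre, table3, seeding, key_lo, key_hi):
        p = pre.table2_hexads[seeding]
        infl = inflection_densities(p)
        assert len(infl) == 2
        assert infl[0] == pytest.approx(table3[seeding][key_lo], abs=5e-4)
        assert infl[1] == pytest.approx(table3[seeding][key_hi], abs=5e-4)

    def test_logistic_single_inflection_at_half_K(self):
        p = GrowthParams(r_p=0.2, K=2.0, n=0.0, alpha=0.0, beta=1.0, delta=0.0)
        infl = inflection_densities(p)
        assert len(infl) == 1
        assert infl[0] == pytest.approx(1.0, abs=1e-9)


class TestMaxRPR:
    def test_equal_exponent_case_is_exact(self):
        # alpha=delta=1, beta=1: RPR is the parabola 0.1 x - 0.1 x^2
        p = GrowthParams(r_p=0.2, K=2.0, n=0.1, alpha=1.0, beta=1.0, delta=1.0)
        res = max_rpr_density_approx(p)
        assert res.exact and res.concave
        assert res.value == pytest.approx(0.5, rel=1e-12)

    def test_no_feedback_reduction(self):
        p = GrowthParams(r_p=0.2, K=2.0, n=0.0, alpha=1.5, beta=2.0, delta=1.5)
        res = max_rpr_density_approx(p)
        expected = p.K * (p.alpha / (p.alpha + p.beta)) ** (1.0 / p.beta)
        assert res.value == pytest.approx(expected, rel=1e-12)

    def test_series_value_near_numeric_argmax(self, seeding1):
        res = max_rpr_density_approx(seeding1)
        assert res.value == pytest.approx(0.797, abs=1e-3)
        # golden-section oracle for the true argmax of the RPR profile
        from scipy.optimize import minimize_scalar
        opt = minimize_scalar(lambda x: -rpr(seeding1, x),
                              bounds=(1e-6, seeding1.K), method="bounded")
        assert abs(res.value - opt.x) / res.value < 0.10


class TestPotential:
    def test_zero_at_origin(self, seeding1):
        assert potential(seeding1, 0.0) == 0.0

    def test_equal_exponent_printed_form(self):
        p = GrowthParams(r_p=0.2, K=2.0, n=0.05, alpha=0.7, beta=1.3, delta=0.7)
        xs = np.linspace(0, 2.5, 50)
        merged = -((p.r_p - p.n) * xs ** (p.alpha + 2) / (p.alpha + 2)
                   - p.r_p / p.K ** p.beta * xs ** (p.alpha + p.beta + 2)
                   / (p.alpha + p.beta + 2))
        assert potential(p, xs) == pytest.approx(merged, rel=1e-12, abs=1e-14)

    def test_gradient_is_minus_apr(self, seeding1):
        for x in (0.3, 0.9, 1.4):
            h = 1e-6
            fd = (potential(seeding1, x + h) - potential(seeding1, x - h)) / (2 * h)
            assert fd == pytest.approx(-apr(seeding1, x), rel=1e-6)

    def test_double_well_structure(self, seeding1):
        # barrier maximum at the threshold, well minimum at the MSSCD
        xs = np.linspace(1e-4, 2.0, 4000)
        U = potential(seeding1, xs)
        i_max = np.argmax(U[xs < 0.5])
        i_min = np.argmin(U)
        assert xs[xs < 0.5][i_max] == pytest.approx(0.0671, abs=2e-3)
        assert xs[i_min] == pytest.approx(1.3507, abs=2e-3)


class TestTrajectories:
    def test_survival_above_threshold(self, seeding1):
        traj = solve_trajectory(seeding1, 0.1, np.linspace(0, 800, 30))
        assert traj.terminal == pytest.approx(1.3507, abs=1e-3)

    def test_extinction_below_threshold(self, seeding1):
        traj = solve_trajectory(seeding1, 0.06, np.linspace(0, 3000, 30))
        assert traj.terminal < 1e-3

    def test_fixed_point_is_constant(self, seeding1):
        mssd = find_equilibria(seeding1).mssd
        traj = solve_trajectory(seeding1, mssd, np.linspace(0, 100, 20))
        assert np.allclose(traj.densities, mssd, rtol=1e-7)

    def test_logistic_closed_form(self):
        p = GrowthParams(r_p=0.2, K=2.0, n=0.0, alpha=0.0, beta=1.0, delta=0.0)
        x0, times = 0.1, np.linspace(0, 40, 25)
        traj = solve_trajectory(p, x0, times)
        exact = (p.K * x0 * np.exp(p.r_p * times)
                 / (p.K + x0 * (np.exp(p.r_p * times) - 1.0)))
        assert traj.densities == pytest.approx(exact, rel=1e-6)

    def test_rejects_bad_inputs(self, seeding1):
        with pytest.raises(ValueError):
            solve_trajectory(seeding1, -0.1, [0, 1])
        with pytest.raises(ValueError):
            solve_trajectory(seeding1, 0.1, [0, 0])


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(r_p=0.0), dict(K=-1.0), dict(beta=0.0), dict(n=-0.1),
        dict(alpha=-0.5), dict(delta=-0.5), dict(r_p=float("nan")),
        dict(K=float("inf")),
    ])
    def test_invalid_hexads_rejected(self, kwargs):
        base = dict(r_p=0.13, K=1.43, n=0.0095, alpha=1.15, beta=0.99, delta=0.2)
        base.update(kwargs)
        with pytest.raises(ValueError):
            GrowthParams(**base)

    def test_dict_round_trip(self, seeding1):
        assert GrowthParams.from_dict(seeding1.to_dict()) == seeding1

    def test_from_dict_rejects_unknown_and_missing(self):
        with pytest.raises(ValueError):
            GrowthParams.from_dict({"r_p": 0.1, "K": 1.0, "n": 0.0, "alpha": 0,
                                    "beta": 1, "delta": 0, "extra": 1})
        with pytest.raises(ValueError):
            GrowthParams.from_dict({"r_p": 0.1})
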