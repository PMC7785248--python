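"""The constrained-optimization endpoint search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from profci import (
    BORDER_FOUND_BY_SCAN_TOL,
    CONTINUE,
    MAX_ITER_STOP,
    SCAN_BOUNDS_REACHED,
    EndpointRequest,
    InfeasibleStartError,
    augmented_objective,
    certify_termination,
    compute_profile,
    counted_evaluator,
    crossing_from_profile,
    find_endpoint,
    find_endpoint_for,
    find_interval,
    make_threshold,
)
from profci.fixtures import (
    SyntheticDataset,
    biexponential_model,
    fit_mle,
    make_biexponential_dataset,
    readme_quadratic,
    wssr_loss,
)


def quadratic_request(direction="lower", mu_rho_probe=False):
    ev = counted_evaluator(readme_quadratic)
    return EndpointRequest(
        evaluator=ev,
        theta_init=np.array([3.0, 2.0]),
        index=0,
        direction=direction,
        threshold=make_threshold(5.0, loss_crit=9.0),
        scan_bounds=(-100.0, 100.0),
        theta_bounds=[(-1e9, 1e9)] * 2,
        scales=["direct", "direct"],
    )


class TestAugmentedObjective:
    def test_zero_penalty_reduces_to_target(self):
        req = quadratic_request("lower")
        assert augmented_objective([3.0, 2.0], mu=0.0, rho=0.0, request=req) == 3.0

    def test_on_constraint_boundary_penalty_vanishes(self):
        # l(1, 0) = 9 exactly, so g = 0 and the objective is theta_1 itself
        req = quadratic_request("lower")
        assert augmented_objective([1.0, 0.0], mu=1.0, rho=0.0, request=req) == pytest.approx(1.0)
        assert augmented_objective([1.0, 0.0], mu=2.5, rho=7.0, request=req) == pytest.approx(1.0)

    def test_upper_direction_flips_sign(self):
        req = quadratic_request("upper")
        assert augmented_objective([3.0, 2.0], mu=0.0, rho=0.0, request=req) == -3.0

    def test_violation_is_penalized(self):
        req = quadratic_request("lower")
        inside = augmented_objective([3.0, 2.0], mu=0.0, rho=10.0, request=req)  # g = -4
        outside = augmented_objective([0.0, -1.0], mu=0.0, rho=10.0, request=req)  # g = 5
        assert inside == 3.0  # satisfied constraint adds nothing at mu = 0
        assert outside == pytest.approx(0.0 + 0.5 * 10.0 * 5.0**2)

    def test_loss_failure_dominates(self):
        ev = counted_evaluator(lambda t: np.nan)
        req = EndpointRequest(
            evaluator=ev,
            theta_init=np.array([0.0]),
            index=0,
            direction="lower",
            threshold=make_threshold(0.0, loss_crit=1.0),
            scan_bounds=(-1.0, 1.0),
            theta_bounds=[(-10.0, 10.0)],
            scales=["direct"],
        )
        assert augmented_objective([0.5], mu=1.0, rho=1.0, request=req) == np.inf


class TestQuadraticEndpoints:
    """The hand-solvable quadratic: intervals [1, 5] and [2 - 2*sqrt(2), 2 + 2*sqrt(2)]."""

    def test_theta1_interval(self):
        ev = counted_evaluator(readme_quadratic)
        res = find_interval(ev, [3.0, 2.0], 0, loss_crit=9.0, scan_bounds=(-100.0, 100.0))
        assert res.lower.status == BORDER_FOUND_BY_SCAN_TOL
        assert res.upper.status == BORDER_FOUND_BY_SCAN_TOL
        assert res.lower.endpoint == pytest.approx(1.0, abs=1e-3)
        assert res.upper.endpoint == pytest.approx(5.0, abs=1e-3)
        assert res.identifiable_within_bounds

    def test_theta2_interval(self):
        ev = counted_evaluator(readme_quadratic)
        res = find_interval(ev, [3.0, 2.0], 1, loss_crit=9.0, scan_bounds=(-100.0, 100.0))
        s = 2.0 * np.sqrt(2.0)
        assert res.lower.endpoint == pytest.approx(2.0 - s, abs=1e-3)
        assert res.upper.endpoint == pytest.approx(2.0 + s, abs=1e-3)

    def test_endpoint_constraint_is_active(self):
        ev = counted_evaluator(readme_quadratic)
        res = find_interval(ev, [3.0, 2.0], 0, loss_crit=9.0, scan_bounds=(-100.0, 100.0))
        for ep in (res.lower, res.upper):
            assert abs(readme_quadratic(ep.argument) - 9.0) <= 1e-3 * 4.0  # default loss_tol

    def test_loss_calls_equal_evaluator_delta(self):
        ev = counted_evaluator(readme_quadratic)
        res = find_endpoint_for(ev, [3.0, 2.0], 0, "lower", loss_crit=9.0, scan_bounds=(-100.0, 100.0))
        # one extra call resolves l_min at theta_init before the search starts
        assert ev.call_count == res.loss_calls + 1

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(crit=st.floats(6.0, 13.0))
    def test_lower_endpoint_tracks_threshold_analytically(self, crit):
        # profile of theta_1 is 5 + (theta_1 - 3)^2, so the lower endpoint
        # is 3 - sqrt(crit - 5) for any threshold above the minimum
        ev = counted_evaluator(readme_quadratic)
        res = find_endpoint_for(ev, [3.0, 2.0], 0, "lower", loss_crit=crit, scan_bounds=(-100.0, 100.0))
        assert res.status == BORDER_FOUND_BY_SCAN_TOL
        assert res.endpoint == pytest.approx(3.0 - np.sqrt(crit - 5.0), abs=5e-3)

    def test_threshold_monotonicity(self):
        intervals = []
        for crit in (7.0, 9.0, 13.0):
            ev = counted_evaluator(readme_quadratic)
            res = find_interval(ev, [3.0, 2.0], 0, loss_crit=crit, scan_bounds=(-100.0, 100.0))
            intervals.append((res.lower.endpoint, res.upper.endpoint))
        tol = 2e-3
        for (lo1, hi1), (lo2, hi2) in zip(intervals, intervals[1:]):
            assert lo2 <= lo1 + tol
            assert hi2 >= hi1 - tol

    def test_shrinking_threshold_collapses_interval(self):
        ev = counted_evaluator(readme_quadratic)
        res = find_interval(
            ev, [3.0, 2.0], 0, loss_crit=5.0 + 1e-6, scan_bounds=(-100.0, 100.0),
            scan_tol=1e-4, loss_tol=1e-8,
        )
        assert res.lower.endpoint == pytest.approx(3.0, abs=3e-3)
        assert res.upper.endpoint == pytest.approx(3.0, abs=3e-3)


class TestBoothEndpoints:
    def test_both_parameters(self, booth_problem):
        r = np.sqrt(200.0 / 1.8)
        expected = {0: (1.0 - r, 1.0 + r), 1: (3.0 - r, 3.0 + r)}
        for idx, (lo, hi) in expected.items():
            ev = booth_problem.evaluator()
            res = find_interval(
                ev, booth_problem.theta_init, idx,
                loss_crit=booth_problem.loss_crit, scan_bounds=booth_problem.scan_bounds,
            )
            assert res.lower.endpoint == pytest.approx(lo, abs=1e-2)
            assert res.upper.endpoint == pytest.approx(hi, abs=1e-2)
            assert res.lower.endpoint <= booth_problem.theta_init[idx] <= res.upper.endpoint


class TestNonIdentifiable:
    def test_rosenbrock_hits_scan_bounds_both_sides(self, rosenbrock_problem):
        p = rosenbrock_problem
        ev = p.evaluator()
        res = find_interval(ev, p.theta_init, 0, loss_crit=p.loss_crit, scan_bounds=p.scan_bounds)
        assert res.lower.status == SCAN_BOUNDS_REACHED
        assert res.upper.status == SCAN_BOUNDS_REACHED
        assert res.lower.endpoint is None
        assert res.upper.endpoint is None
        assert not res.identifiable_within_bounds

    def test_symmetric_biexponential_amplitude_not_identifiable(self):
        # k1 == k2: only a1 + a2 is constrained by the data, the a1 profile is flat
        times = np.linspace(0.0, 10.0, 25)
        ds = make_biexponential_dataset(2.0, 0.5, 1.0, 0.5, times, 0.05, seed=7)
        ev = wssr_loss(ds, biexponential_model)
        l0 = ev(ds.true_params)
        res = find_interval(
            ev, ds.true_params, 0, loss_crit=l0 + 3.84, l_min=l0,
            scan_bounds=(-50.0, 50.0),
            theta_bounds=[(-100.0, 100.0), (1e-6, 10.0), (-100.0, 100.0), (1e-6, 10.0)],
        )
        assert SCAN_BOUNDS_REACHED in (res.lower.status, res.upper.status)
        assert not res.identifiable_within_bounds


class TestScales:
    def test_log_scale_agrees_with_direct(self):
        # positive-parameter bowl: endpoints 8 and 12 for theta_1 at threshold 4
        def loss(t):
            return (t[0] - 10.0) ** 2 + (t[0] - t[1]) ** 2

        scan_tol = 1e-3
        ev_d = counted_evaluator(loss)
        direct = find_interval(ev_d, [10.0, 10.0], 0, loss_crit=4.0,
                               scan_bounds=(1e-3, 1e3), scan_tol=scan_tol)
        ev_l = counted_evaluator(loss)
        logged = find_interval(ev_l, [10.0, 10.0], 0, loss_crit=4.0,
                               scan_bounds=(-3.0, 3.0), scales="log", scan_tol=scan_tol)
        assert logged.lower.endpoint == pytest.approx(direct.lower.endpoint, abs=10 * scan_tol)
        assert logged.upper.endpoint == pytest.approx(direct.upper.endpoint, abs=10 * scan_tol)
        assert direct.lower.endpoint == pytest.approx(8.0, abs=1e-3)
        assert direct.upper.endpoint == pytest.approx(12.0, abs=1e-3)

    def test_logit_scale_for_unit_interval_parameter(self):
        from profci.transforms import to_search_scale

        def loss(t):
            return 100.0 * (t[0] - 0.5) ** 2

        ev = counted_evaluator(loss)
        sb = (to_search_scale(1e-4, "logit"), to_search_scale(1 - 1e-4, "logit"))
        res = find_interval(ev, [0.5], 0, loss_crit=1.0, scan_bounds=sb, scales="logit")
        assert res.lower.endpoint == pytest.approx(0.4, abs=1e-3)
        assert res.upper.endpoint == pytest.approx(0.6, abs=1e-3)


class TestOracleEquivalence:
    """Endpoints from the constrained search match grid-profile crossings."""

    def test_identifiable_biexponential(self):
        times = np.linspace(0.0, 20.0, 30)
        true = np.array([3.0, 1.0, 1.0, 0.1])
        ds = make_biexponential_dataset(*true, times, 0.1, seed=42)
        ev = wssr_loss(ds, biexponential_model)
        theta_hat, l_min = fit_mle(ev, true)
        crit = l_min + 3.8415
        res = find_interval(
            ev, theta_hat, 0, loss_crit=crit, l_min=l_min,
            scan_bounds=(-50.0, 50.0),
            theta_bounds=[(-100.0, 100.0), (1e-6, 10.0), (-100.0, 100.0), (1e-6, 10.0)],
        )
        assert res.identifiable_within_bounds
        lo, hi = res.lower.endpoint, res.upper.endpoint
        span = hi - lo
        grid = np.linspace(lo - 0.3 * span, hi + 0.3 * span, 41)
        spacing = grid[1] - grid[0]
        profile = compute_profile(wssr_loss(ds, biexponential_model), theta_hat, 0, grid)
        tol = max(1e-3, spacing)
        assert crossing_from_profile(profile, crit, "lower") == pytest.approx(lo, abs=tol)
        assert crossing_from_profile(profile, crit, "upper") == pytest.approx(hi, abs=tol)


class TestCertifyTermination:
    def test_feasible_point_at_bound_certifies_scan_bounds(self):
        req = quadratic_request("lower")
        loss_tol = req.loss_tol
        best = (np.array([-100.0, 2.0]), 9.0 - 10 * loss_tol)
        assert certify_termination(best, -100.0, req) == SCAN_BOUNDS_REACHED

    def test_stalled_estimate_on_boundary_certifies_border(self):
        req = quadratic_request("lower")
        status = certify_termination(
            None, -100.0, req,
            endpoint_estimate=1.0,
            previous_estimate=1.0 + req.scan_tol / 10,
            endpoint_loss=9.0 + req.loss_tol / 2,
        )
        assert status == BORDER_FOUND_BY_SCAN_TOL

    def test_neither_condition_continues(self):
        req = quadratic_request("lower")
        status = certify_termination(
            (np.array([2.0, 1.0]), 8.0), -100.0, req,
            endpoint_estimate=2.0, previous_estimate=3.0, endpoint_loss=8.0,
        )
        assert status == CONTINUE


class TestErrorsAndBudget:
    def test_infeasible_start_raises(self):
        ev = counted_evaluator(readme_quadratic)
        with pytest.raises(InfeasibleStartError):
            find_interval(ev, [10.0, 0.0], 0, loss_crit=9.0, scan_bounds=(-100.0, 100.0))

    def test_exhausted_budget_reports_max_iter(self):
        ev = counted_evaluator(readme_quadratic)
        res = find_endpoint_for(
            ev, [3.0, 2.0], 0, "lower", loss_crit=9.0, scan_bounds=(-100.0, 100.0), max_evals=10
        )
        assert res.status == MAX_ITER_STOP
        assert res.endpoint is None

    def test_start_outside_scan_bounds_rejected(self):
        ev = counted_evaluator(readme_quadratic)
        with pytest.raises(Exception):
            find_interval(ev, [3.0, 2.0], 0, loss_crit=9.0, scan_bounds=(5.0, 100.0))

    def test_report_serialization(self):
        ev = counted_evaluator(readme_quadratic)
        res = find_interval(ev, [3.0, 2.0], 0, loss_crit=9.0, scan_bounds=(-100.0, 100.0))
        report = res.to_report()
        assert report["parameter"] == 1
        assert report["loss_crit"] == 9.0
        assert report["lower"]["status"] == BORDER_FOUND_BY_SCAN_TOL
        assert isinstance(res.to_json(), str)
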