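"""TI estimator: parsing, discard, blocking, pooling, quadrature, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ticycle import ti_core
from ticycle.synthetic_data import SurrogateSpec, gen_ar1_dhdl, true_integral
from ticycle.ti_core import (
    DhdlSeries,
    LambdaPointEstimate,
    XvgParseError,
    block_sem,
    build_lambda_schedule,
    combine_replicas,
    discard_equilibration,
    estimate_free_energy,
    parse_xvg,
    protocol_accounting,
    quadrature_weights,
    simpson_nonuniform,
)


def make_series(values, lam=0.5, dt=1.0, replica=0):
    values = np.asarray(values, dtype=float)
    return DhdlSeries(lam=lam, replica_id=replica,
                      times=dt * np.arange(1, len(values) + 1), values=values)


class TestParseXvg:
    def test_hand_written_two_row_file(self, tmp_path):
        path = tmp_path / "a.xvg"
        path.write_text("# comment\n@ lambda 0.5\n0.0 1.5\n2.0 2.5\n")
        s = parse_xvg(path)
        assert len(s) == 2 and s.lam == 0.5
        np.testing.assert_array_equal(s.values, [1.5, 2.5])

    def test_comments_only_is_an_error(self, tmp_path):
        path = tmp_path / "empty.xvg"
        path.write_text("# nothing\n@ title \"x\"\n")
        with pytest.raises(XvgParseError, match="no data"):
            parse_xvg(path)

    def test_bad_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.xvg"
        path.write_text("0.0 1.0\n1.0 not-a-number\n")
        with pytest.raises(XvgParseError, match="bad.xvg:2"):
            parse_xvg(path)


class TestDiscardEquilibration:
    def test_default_window_retains_150_of_500_ps(self):
        s = make_series(np.arange(500.0))  # 1 ps stride, ends at 500 ps
        out = discard_equilibration(s)
        assert len(out) == 150
        assert out.times[0] > 350.0 and out.times[-1] == 500.0

    def test_window_equal_to_span_is_identity(self):
        s = make_series(np.arange(100.0))
        out = discard_equilibration(s, keep_last=100.0)
        assert len(out) == len(s)

    def test_short_series_returned_whole_with_warning(self):
        s = make_series(np.arange(50.0))
        with pytest.warns(UserWarning, match="full series"):
            out = discard_equilibration(s, keep_last=150.0)
        assert len(out) == 50


class TestBlockSem:
    def test_constant_sequence_has_zero_error(self):
        assert block_sem(np.full(100, 3.7)) == 0.0

    def test_iid_matches_naive_sem(self, rng):
        x = rng.standard_normal(10**4)
        assert block_sem(x) == pytest.approx(0.01, rel=0.20)

    def test_ar1_matches_effective_sample_size(self):
        spec = SurrogateSpec(coeffs=(0.0,), sigma_n=1.0, phi=0.9,
                             n_steps=10**5, n_replicas=1, seed=8)
        v = gen_ar1_dhdl(spec, 0.5)[0].values
        # sd * sqrt((1+phi)/(1-phi)) / sqrt(n) with sd^2 = 1/(1-phi^2)
        expected = np.sqrt(1.0 / 0.19 * 19.0 / 1e5)
        assert block_sem(v) == pytest.approx(expected, rel=0.25)

    def test_exceeds_naive_sem_for_correlated_data(self):
        spec = SurrogateSpec(coeffs=(0.0,), sigma_n=1.0, phi=0.8,
                             n_steps=2 * 10**4, n_replicas=1, seed=9)
        v = gen_ar1_dhdl(spec, 0.5)[0].values
        naive = np.std(v, ddof=1) / np.sqrt(len(v))
        assert block_sem(v) > 1.5 * naive

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            block_sem(np.arange(5.0))


class TestCombineReplicas:
    def test_constant_replicas_pool_exactly(self):
        reps = [make_series(np.full(100, 4.2), replica=r) for r in range(9)]
        est = combine_replicas(reps)
        assert est.mean == pytest.approx(4.2, rel=1e-14)
        assert est.sem == 0.0
        assert est.n_replicas == 9 and est.n_samples_used == 900

    def test_scatter_of_replica_means_dominates(self, rng):
        # distinct means, negligible within-replica noise
        means = rng.normal(0.0, 5.0, size=9)
        reps = [make_series(m + 1e-9 * rng.standard_normal(64), replica=r)
                for r, m in enumerate(means)]
        est = combine_replicas(reps)
        assert est.mean == pytest.approx(np.mean(means), abs=1e-6)
        assert est.sem == pytest.approx(np.std(means, ddof=1) / 3.0, rel=1e-4)

    def test_single_replica_degenerates_to_block_sem(self, rng):
        v = rng.standard_normal(512)
        est = combine_replicas([make_series(v)])
        assert est.sem == pytest.approx(block_sem(v), rel=1e-12)

    def test_mixed_lambda_values_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            combine_replicas([make_series(np.ones(10), lam=0.1),
                              make_series(np.ones(10), lam=0.2)])


class TestLambdaSchedule:
    def test_default_has_25_distinct_nodes(self):
        sch = build_lambda_schedule()
        assert len(sch) == 25
        assert sch.nodes[0] == 0.0 and sch.nodes[-1] == 1.0
        assert len(np.unique(sch.nodes)) == 25

    def test_default_extra_nodes_quarter_the_end_intervals(self):
        sch = build_lambda_schedule()
        for node in (0.0125, 0.0375, 0.9625, 0.9875):
            assert np.any(np.isclose(sch.nodes, node))

    def test_minimal_schedule_is_endpoints_only(self):
        sch = build_lambda_schedule(n_uniform=2, extra_per_end=0)
        np.testing.assert_array_equal(sch.nodes, [0.0, 1.0])

    def test_colliding_extra_node_rejected(self):
        with pytest.raises(ValueError, match="coincides"):
            build_lambda_schedule(n_uniform=21, extra_per_end=1, end_offsets=(0.05,))


class TestSimpsonNonuniform:
    def test_exact_for_quadratic_on_uneven_nodes(self):
        xs = np.array([0.0, 0.5, 1.0])
        assert simpson_nonuniform(xs, xs**2) == pytest.approx(1 / 3, rel=1e-15)

    def test_constant_integrates_to_span(self):
        xs = np.array([0.0, 0.07, 0.3, 0.55, 0.8, 1.0])
        assert simpson_nonuniform(xs, np.full(6, 2.5)) == pytest.approx(2.5, rel=1e-14)

    def test_cubic_on_default_layout_matches_bruteforce_trapezoid(self):
        sch = build_lambda_schedule()
        got = simpson_nonuniform(sch.nodes, 4 * sch.nodes**3)
        fine = np.linspace(0, 1, 10**6 + 1)
        oracle = np.trapezoid(4 * fine**3, fine)
        assert got == pytest.approx(oracle, rel=1e-4)

    def test_unsorted_nodes_rejected(self):
        with pytest.raises(ValueError):
            simpson_nonuniform([0.0, 0.5, 0.4], [1, 2, 3])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        gaps=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=12),
        coeffs=st.tuples(st.floats(-10, 10), st.floats(-10, 10), st.floats(-10, 10)),
    )
    def test_property_exact_for_random_quadratics(self, gaps, coeffs):
        xs = np.concatenate([[0.0], np.cumsum(gaps)])
        a, b, c = coeffs
        ys = a + b * xs + c * xs**2
        exact = (a * xs[-1] + b * xs[-1] ** 2 / 2 + c * xs[-1] ** 3 / 3)
        scale = max(1.0, float(np.sum(np.abs(ys))) * (xs[-1] - xs[0]))
        assert abs(simpson_nonuniform(xs, ys) - exact) <= 1e-12 * scale


class TestQuadratureWeights:
    def test_uniform_three_node_textbook_weights(self):
        w = quadrature_weights(np.linspace(0, 1, 3))
        np.testing.assert_allclose(w, [1 / 6, 4 / 6, 1 / 6], rtol=1e-15)

    def test_weights_sum_to_span(self):
        xs = np.array([0.0, 0.03, 0.2, 0.5, 0.6, 0.95, 1.0])
        assert np.sum(quadrature_weights(xs)) == pytest.approx(1.0, rel=1e-14)

    def test_weighted_sum_reproduces_simpson_on_random_inputs(self, rng):
        for _ in range(20):
            xs = np.sort(rng.uniform(0, 1, size=7))
            xs[0], xs[-1] = 0.0, 1.0
            ys = rng.standard_normal(7)
            assert np.dot(quadrature_weights(xs), ys) == pytest.approx(
                simpson_nonuniform(xs, ys), rel=1e-13, abs=1e-13
            )


class TestEstimateFreeEnergy:
    @staticmethod
    def points_from_curve(schedule, fn, sem=0.0):
        return [LambdaPointEstimate(lam=float(l), mean=float(fn(l)), sem=sem,
                                    n_replicas=1, n_samples_used=1)
                for l in schedule]

    def test_zero_means_give_zero(self):
        sch = build_lambda_schedule()
        est = estimate_free_energy(self.points_from_curve(sch, lambda l: 0.0), sch)
        assert est.delta_g == 0.0 and est.sigma == 0.0

    def test_noiseless_quadratic_curve_recovers_integral(self):
        sch = build_lambda_schedule()
        est = estimate_free_energy(self.points_from_curve(sch, lambda l: 3 * l**2), sch)
        assert est.delta_g == pytest.approx(1.0, rel=1e-12)

    def test_missing_node_error_lists_lambdas(self):
        sch = build_lambda_schedule(n_uniform=3, extra_per_end=0)
        points = self.points_from_curve(sch, lambda l: 1.0)[:-1]
        with pytest.raises(ValueError, match="1.0"):
            estimate_free_energy(points, sch)

    def test_surrogate_recovery_within_three_sigma(self):
        spec = SurrogateSpec(coeffs=(15.0, -12.0, 6.0), sigma_n=8.0, phi=0.8,
                             n_steps=500, n_replicas=9, seed=77)
        sch = build_lambda_schedule()
        points = []
        for lam in sch:
            reps = [discard_equilibration(s) for s in gen_ar1_dhdl(spec, float(lam))]
            points.append(combine_replicas(reps))
        est = estimate_free_energy(points, sch)
        assert est.delta_g == pytest.approx(true_integral(spec), abs=3 * est.sigma)

    def test_sigma_shrinks_with_more_replicas(self):
        sch = build_lambda_schedule(n_uniform=5, extra_per_end=0)
        sigmas = []
        for n_rep in (1, 3, 9):
            spec = SurrogateSpec(coeffs=(10.0,), sigma_n=6.0, phi=0.8,
                                 n_steps=500, n_replicas=n_rep, seed=55)
            points = []
            for lam in sch:
                reps = [discard_equilibration(s) for s in gen_ar1_dhdl(spec, float(lam))]
                points.append(combine_replicas(reps))
            sigmas.append(estimate_free_energy(points, sch).sigma)
        assert sigmas[0] > sigmas[1] > sigmas[2]


class TestProtocolAccounting:
    def test_default_protocol_totals_112_5_ns(self):
        sch = build_lambda_schedule()
        assert protocol_accounting(sch, 9, 500.0) == pytest.approx(112.5)

    def test_minimal_protocol(self):
        sch = build_lambda_schedule(n_uniform=2, extra_per_end=0)
        assert protocol_accounting(sch, 1, 500.0) == pytest.approx(1.0)

    def test_node_count_drives_the_total(self):
        sch23 = build_lambda_schedule(n_uniform=23, extra_per_end=0)
        assert protocol_accounting(sch23, 9, 500.0) == pytest.approx(103.5)
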