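"""Information estimators: frozen oracle values, invariants, error contracts."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oifnet as o
from oifnet.exceptions import InsufficientDataError, ZeroVarianceError


class TestStandardize:
    def test_definition(self):
        z = o.standardize_series(np.array([1.0, 2.0, 3.0]))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self, rng):
        z = o.standardize_series(rng.normal(3.0, 2.0, 100))
        np.testing.assert_allclose(o.standardize_series(z), z, atol=1e-12)

    def test_constant_raises(self):
        with pytest.raises(ZeroVarianceError):
            o.standardize_series(np.array([5.0, 5.0, 5.0]))


class TestJointPdf:
    def test_identical_points_single_cell(self):
        est = o.joint_pdf(np.zeros((10, 2)) + 0.1, r=0.25)
        assert est.probabilities.shape == (1,)
        assert est.probabilities[0] == 1.0

    def test_two_cells_half_each(self):
        pts = np.array([[0.1], [0.1], [0.6], [0.6]])
        est = o.joint_pdf(pts, r=0.5)
        np.testing.assert_allclose(sorted(est.probabilities), [0.5, 0.5])

    def test_uniform_large_n_quarter_cells(self, rng):
        x = rng.uniform(0.0, 1.0, 100_000)[:, None]
        est = o.joint_pdf(x, r=0.25)
        assert est.probabilities.size == 4
        np.testing.assert_allclose(est.probabilities, 0.25, atol=0.01)

    def test_kernel_densities_bounded(self, rng):
        est = o.joint_pdf(rng.standard_normal((500, 2)), r=0.25, kind="kernel")
        assert est.kind == "kernel"
        assert np.all(est.probabilities > 0) and np.all(est.probabilities <= 1)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            o.joint_pdf(np.empty((0, 1)), r=0.25)


class TestPearson:
    def test_self_and_sign(self, rng):
        x = rng.standard_normal(50)
        assert o.pearson_corr(x, x) == pytest.approx(1.0)
        assert o.pearson_corr(x, -x) == pytest.approx(-1.0)

    def test_hand_value(self):
        # corr([1,2,3],[1,2,4]) = 3 / sqrt(2 * 14/3) = 0.9820 (4 d.p.)
        assert o.pearson_corr(
            np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])
        ) == pytest.approx(0.9820, abs=5e-5)

    def test_constant_raises(self):
        with pytest.raises(ZeroVarianceError):
            o.pearson_corr(np.ones(10), np.arange(10.0))


class TestMutualInformation:
    def test_independent_near_zero(self, rng):
        x, y = rng.standard_normal(10_000), rng.standard_normal(10_000)
        assert o.mutual_information(x, y) <= 0.05

    def test_self_mi_is_entropy(self, rng, plain_config):
        x = rng.standard_normal(2_000)
        mi = o.mutual_information(x, x, u=0, config=plain_config)
        assert mi == pytest.approx(o.plugin_entropy(x, plain_config), abs=1e-12)

    def test_matched_binary_one_bit(self, plain_config):
        cfg = dataclasses.replace(plain_config, standardize=False, r=1.0)
        bits = np.tile([0.0, 1.0], 500)
        assert o.mutual_information(bits, bits, u=0, config=cfg) == pytest.approx(1.0)

    def test_symmetry_at_zero_delay(self, rng):
        x, y = rng.standard_normal(3_000), rng.standard_normal(3_000)
        assert abs(
            o.mutual_information(x, y, 0) - o.mutual_information(y, x, 0)
        ) <= 1e-12

    def test_insufficient_overlap(self, rng):
        x = rng.standard_normal(40)
        with pytest.raises(InsufficientDataError):
            o.mutual_information(x, x, u=20)

    def test_bits_nats_exact_ratio(self, rng, plain_config):
        x, y = rng.standard_normal(1_000), rng.standard_normal(1_000)
        nats_cfg = dataclasses.replace(plain_config, log_base=math.e)
        assert o.mutual_information(x, y, 0, plain_config) * math.log(2) == \
            o.mutual_information(x, y, 0, nats_cfg)

    def test_bounded_by_marginal_entropies(self, chaotic_pair, plain_config):
        x, y = chaotic_pair
        mi = o.mutual_information(x, y, 0, plain_config)
        assert mi <= min(o.plugin_entropy(x, plain_config),
                         o.plugin_entropy(y, plain_config)) + 1e-12

    def test_kernel_kind_runs_and_agrees_in_sign(self, chaotic_pair):
        x, y = chaotic_pair
        cfg = o.EstimatorConfig(estimator_kind="kernel")
        assert o.mutual_information(x[:500], y[:500], 0, cfg) > 0.0


class TestTransferEntropy:
    def test_independent_near_zero(self, rng):
        x, y = rng.standard_normal(10_000), rng.standard_normal(10_000)
        assert o.transfer_entropy(x, y) <= 0.05

    def test_shifted_symbol_sequence_recovers_alphabet_entropy(self, rng):
        b = 4
        s = rng.integers(0, b, 4_000).astype(float)
        g = np.roll(s, 1)  # target(t) = source(t-1)
        cfg = o.EstimatorConfig(standardize=False, r=1.0, te_correction="none")
        fwd = o.transfer_entropy(s, g, cfg)
        back = o.transfer_entropy(g, s, cfg)
        assert fwd == pytest.approx(math.log2(b), abs=0.05)
        assert back <= 0.05

    def test_direction_on_chaotic_pair(self, chaotic_pair):
        x, y = chaotic_pair
        assert o.transfer_entropy(x, y) > 10 * o.transfer_entropy(y, x)

    def test_nonnegative_and_deterministic(self, rng):
        x, y = rng.standard_normal(2_000), rng.standard_normal(2_000)
        a = o.transfer_entropy(x, y)
        assert a >= -1e-12
        assert a == o.transfer_entropy(x, y)  # same config, same surrogate seed

    def test_bounded_by_target_entropy(self, chaotic_pair, plain_config):
        x, y = chaotic_pair
        assert o.transfer_entropy(x, y, plain_config) <= \
            o.plugin_entropy(y, plain_config) + 1e-12

    def test_self_te_is_computable(self, chaotic_pair, plain_config):
        x, _ = chaotic_pair
        assert o.transfer_entropy(x, x, plain_config) >= 0.0

    def test_window_floor(self, rng):
        with pytest.raises(InsufficientDataError):
            o.transfer_entropy(rng.standard_normal(25), rng.standard_normal(25))
        # 30-point windows are admissible (the network resolution g)
        o.transfer_entropy(rng.standard_normal(30), rng.standard_normal(30))

    def test_alternative_target_lag_reading(self, chaotic_pair):
        x, y = chaotic_pair
        cfg = o.EstimatorConfig(u=3, lag_target_history=False, te_correction="none")
        assert o.transfer_entropy(x, y, cfg) >= 0.0


class TestOptimalDelay:
    def test_exact_copy_lag_three(self, rng):
        x = rng.uniform(0, 1, 1_000)
        y = np.roll(x, 3)
        res = o.optimal_delay(x, y, range(1, 11))
        assert res.u_star == 3
        assert res.mi_profile[res.u_range.index(3)] == np.nanmax(res.mi_profile)

    def test_lag_one(self, rng):
        x = rng.uniform(0, 1, 500)
        res = o.optimal_delay(x, np.roll(x, 1), range(1, 6))
        assert res.u_star == 1

    def test_distance_profile_is_exp_minus_nats(self, rng):
        x = rng.uniform(0, 1, 500)
        res = o.optimal_delay(x, np.roll(x, 2), range(1, 4))
        nats = res.mi_profile * math.log(2)
        np.testing.assert_allclose(res.distance_profile, np.exp(-nats), atol=1e-12)
        assert np.all(res.distance_profile > 0) and np.all(res.distance_profile <= 1)

    def test_constant_series_raises(self):
        with pytest.raises(ZeroVarianceError):
            o.optimal_delay(np.ones(100), np.arange(100.0), range(1, 4))

    def test_info_distance_values(self):
        assert o.info_distance(0.0) == 1.0
        assert o.info_distance(math.log(2)) == pytest.approx(0.5, abs=1e-15)
        assert o.info_distance(50.0) < 1e-20
        with pytest.raises(ValueError):
            o.info_distance(-0.1)


class TestGaussianOracle:
    A = np.array([[0.5, 0.0], [0.4, 0.5]])

    def test_no_cross_coefficient_zero_te(self):
        p = o.VARParams(A=np.diag([0.5, 0.3]))
        assert o.analytic_gaussian_te(p, "x_to_y") == pytest.approx(0.0, abs=1e-14)
        assert o.analytic_gaussian_te(p, "y_to_x") == pytest.approx(0.0, abs=1e-14)

    def test_triangular_coupling_one_sided(self):
        p = o.VARParams(A=self.A)
        assert o.analytic_gaussian_te(p, "x_to_y") > 0.0
        assert o.analytic_gaussian_te(p, "y_to_x") == pytest.approx(0.0, abs=1e-14)

    def test_matches_regression_brute_force(self):
        p = o.VARParams(A=self.A, n=1_000_000, seed=2)
        z = o.simulate_gaussian_var(p).values
        yt, lag = z[1:, 1], z[:-1]
        full = np.column_stack([lag[:, 1], lag[:, 0], np.ones(len(yt))])
        rest = full[:, [0, 2]]
        rss_full = (yt - full @ np.linalg.lstsq(full, yt, rcond=None)[0]).var()
        rss_rest = (yt - rest @ np.linalg.lstsq(rest, yt, rcond=None)[0]).var()
        te_reg = 0.5 * math.log2(rss_rest / rss_full)
        an = o.analytic_gaussian_te(p, "x_to_y")
        assert te_reg == pytest.approx(an, rel=0.02)


class TestPluginOracle:
    def test_constant_source_zero(self, rng):
        g = rng.integers(0, 3, 200)
        assert o.plugin_te_oracle(np.zeros(200, dtype=int), g) == pytest.approx(0.0, abs=1e-14)

    def test_shifted_uniform_source(self, rng):
        b, u = 5, 2
        s = rng.integers(0, b, 5_000)
        assert o.plugin_te_oracle(s, np.roll(s, u), u=u) == pytest.approx(
            math.log2(b), abs=0.05
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            o.plugin_te_oracle([1, 2], [1, 2, 3])


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_te_histogram_equals_oracle(seed):
    """The vectorized histogram TE and the dictionary-counting oracle are
    two independent evaluations of the same plug-in functional."""
    rng = np.random.default_rng(seed)
    n = 200 + int(rng.integers(0, 200))
    b = int(rng.integers(2, 7))
    s = rng.integers(0, b, n)
    g = rng.integers(0, b, n)
    k, l, u = int(rng.integers(1, 3)), int(rng.integers(1, 3)), int(rng.integers(1, 4))
    cfg = o.EstimatorConfig(r=1.0, k=k, l=l, u=u, standardize=False,
                            te_correction="none")
    te = o.transfer_entropy(s.astype(float), g.astype(float), cfg)
    assert te == pytest.approx(o.plugin_te_oracle(s, g, u=u, k=k, l=l), abs=1e-12)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=15, deadline=None, derandomize=True)
def test_mi_nonnegative_and_symmetric(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(300)
    y = rng.standard_normal(300) + 0.5 * x
    mi_xy = o.mutual_information(x, y, 0)
    mi_yx = o.mutual_information(y, x, 0)
    assert mi_xy >= -1e-12
    assert abs(mi_xy - mi_yx) <= 1e-12
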