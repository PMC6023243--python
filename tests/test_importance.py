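import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad_vec
from scipy.linalg import expm, solve_sylvester

import stochshield as ss
from stochshield.importance import ThreeStateRates, _eta_beta
from stochshield.network import NonReversibleError

positive_rate = st.floats(1e-3, 1e3)


def quadrature_covariance(model, k, t_upper_factor=40.0):
    """Independent oracle: C_k = int_0^inf e^{tL} B_k B_k^T e^{tL^T} dt."""
    L = ss.laplacian(model)
    s = ss.stationary_summary(model)
    dec = ss.spectral_decomposition(L, s.pi)
    _, B_k = ss.noise_matrix(model, s)
    F = B_k[k] @ B_k[k].T
    T = t_upper_factor / abs(dec.eigenvalues[1])

    def integrand(t):
        E = expm(t * L)
        return E @ F @ E.T

    val, _ = quad_vec(integrand, 0.0, T, epsabs=1e-10, epsrel=1e-9)
    return val


class TestEdgeImportance:
    def test_unit_chain_pair_shares(self, unit_chain):
        imp = ss.edge_importance(unit_chain)
        assert imp.pair_share(1, 2) == pytest.approx(1.0 / 8.0, abs=1e-12)
        assert imp.pair_share(2, 3) == pytest.approx(7.0 / 8.0, abs=1e-12)

    def test_unit_chain_total_is_multinomial_variance(self, unit_chain):
        imp = ss.edge_importance(unit_chain)
        assert imp.total == pytest.approx(2.0 / 9.0, rel=1e-12)

    def test_reciprocal_edges_equal(self, reversible_model):
        imp = ss.edge_importance(reversible_model)
        for e in reversible_model.edges:
            rk = reversible_model.reciprocal_edge(e.index)
            assert imp.per_edge[e.index - 1] == pytest.approx(
                imp.per_edge[rk - 1], rel=1e-8
            )

    def test_relative_sums_to_one(self, reversible_model):
        imp = ss.edge_importance(reversible_model)
        assert imp.relative.sum() == pytest.approx(1.0, abs=1e-12)
        assert sum(imp.pair_relative.values()) == pytest.approx(1.0, abs=1e-12)
        assert np.all(imp.per_edge >= 0)

    def test_total_matches_multinomial_variance(self, reversible_model):
        s = ss.stationary_summary(reversible_model)
        imp = ss.edge_importance(reversible_model)
        expected = ss.observable_variance(s.pi, reversible_model.measurement)
        assert imp.total == pytest.approx(expected, rel=1e-8)

    def test_non_reversible_rejected(self):
        # a directed 3-cycle has no reciprocal edges at all
        m = ss.build_model(
            ("1", "2", "3"),
            [(1, 2, 1.0), (2, 3, 1.0), (3, 1, 1.0)],
            [0, 0, 1],
        )
        with pytest.raises(NonReversibleError):
            ss.edge_importance(m)


class TestLyapunov:
    def test_zero_forcing_gives_zero(self, unit_chain):
        L = ss.laplacian(unit_chain)
        s = ss.stationary_summary(unit_chain)
        dec = ss.spectral_decomposition(L, s.pi)
        C = ss.lyapunov_solve(L, np.zeros((3, 3)), dec)
        assert np.allclose(C, 0.0)

    def test_unit_chain_multinomial_covariance(self, unit_chain):
        L = ss.laplacian(unit_chain)
        s = ss.stationary_summary(unit_chain)
        dec = ss.spectral_decomposition(L, s.pi)
        B, _ = ss.noise_matrix(unit_chain, s)
        C = ss.lyapunov_solve(L, B @ B.T, dec)
        expected = np.diag(s.pi) - np.outer(s.pi, s.pi)
        assert np.allclose(C, expected, atol=1e-12)
        assert C[2, 2] == pytest.approx(2.0 / 9.0)
        assert C[0, 1] == pytest.approx(-1.0 / 9.0)

    def test_invalid_forcing_rejected(self, unit_chain):
        L = ss.laplacian(unit_chain)
        s = ss.stationary_summary(unit_chain)
        dec = ss.spectral_decomposition(L, s.pi)
        with pytest.raises(ValueError, match="symmetric"):
            ss.lyapunov_solve(L, np.array([[0, 1, -1], [0, 0, 0], [0, -1, 1.0]]), dec)
        with pytest.raises(ValueError, match="zero column sums"):
            ss.lyapunov_solve(L, np.eye(3), dec)

    def test_agrees_with_sylvester_and_quadrature(self, reversible_model):
        """Spectral solver vs dense Sylvester solve vs time quadrature."""
        L = ss.laplacian(reversible_model)
        s = ss.stationary_summary(reversible_model)
        dec = ss.spectral_decomposition(L, s.pi)
        _, B_k = ss.noise_matrix(reversible_model, s)
        F = B_k[0] @ B_k[0].T
        C = ss.lyapunov_solve(L, F, dec)
        resid = L @ C + C @ L.T + F
        assert np.max(np.abs(resid)) < 1e-8 * max(np.max(np.abs(F)), 1e-12)
        # Sylvester with the zero mode deflated by shifting along pi 1^T
        n = reversible_model.n_states
        shift = np.outer(s.pi, np.ones(n))
        C_syl = solve_sylvester(L - shift, (L - shift).T, -F)
        assert np.allclose(C, C_syl, atol=1e-8 * max(np.max(np.abs(C)), 1e-12))
        C_quad = quadrature_covariance(reversible_model, 0)
        assert np.allclose(C, C_quad, atol=1e-6 * max(np.max(np.abs(C)), 1e-12))


class TestCovarianceDecomposition:
    def test_oracle_triangle(self, reversible_model):
        """R_k from the spectral sum, from M^T C_k M, and from quadrature of
        the per-edge covariance integral all agree."""
        imp = ss.edge_importance(reversible_model)
        dec = ss.covariance_decomposition(reversible_model)
        M = reversible_model.measurement
        for k in range(reversible_model.n_edges):
            r_lyap = M @ dec.C_k[k] @ M
            assert r_lyap == pytest.approx(imp.per_edge[k], rel=1e-8, abs=1e-12)
        # quadrature only for the largest edge (expensive)
        k_big = int(np.argmax(imp.per_edge))
        r_quad = M @ quadrature_covariance(reversible_model, k_big) @ M
        assert r_quad == pytest.approx(imp.per_edge[k_big], rel=1e-6)

    def test_sum_is_stationary_covariance(self, unit_chain):
        dec = ss.covariance_decomposition(unit_chain)
        s = ss.stationary_summary(unit_chain)
        expected = np.diag(s.pi) - np.outer(s.pi, s.pi)
        assert np.allclose(dec.C, expected, atol=1e-10)
        assert dec.lyapunov_residual < 1e-10

    def test_pair_share_from_covariance(self, unit_chain):
        dec = ss.covariance_decomposition(unit_chain)
        M = unit_chain.measurement
        total = M @ dec.C @ M
        pair_12 = (M @ dec.C_k[0] @ M + M @ dec.C_k[1] @ M) / total
        assert pair_12 == pytest.approx(1.0 / 8.0, abs=1e-12)

    def test_nachr_high_c_observable_pair_dominates(self, nachr_high):
        dec = ss.covariance_decomposition(nachr_high)
        M = nachr_high.measurement
        shares = {}
        for e in nachr_high.edges:
            key = tuple(sorted((e.source, e.target)))
            shares[key] = shares.get(key, 0.0) + float(M @ dec.C_k[e.index - 1] @ M)
        assert max(shares, key=shares.get) == (2, 3)


class TestObservableVariance:
    def test_unit_chain(self):
        assert ss.observable_variance([1 / 3, 1 / 3, 1 / 3], [0, 0, 1]) == pytest.approx(2 / 9)

    def test_constant_observable_conserved(self):
        pi = np.array([0.2, 0.3, 0.5])
        assert ss.observable_variance(pi, [2.0, 2.0, 2.0], 7) == pytest.approx(0.0, abs=1e-14)

    def test_matches_quadratic_form(self, reversible_model):
        s = ss.stationary_summary(reversible_model)
        dec = ss.covariance_decomposition(reversible_model)
        M = reversible_model.measurement
        assert ss.observable_variance(s.pi, M) == pytest.approx(
            float(M @ dec.C @ M), abs=1e-10
        )


class TestEtaClosedForm:
    @pytest.mark.parametrize(
        "rates,eta",
        [
            ((1, 1, 1, 1), 1.0 / 8.0),
            ((1, 1, 10, 0.1), 0.4132),
            ((0.1, 1, 10, 10), 0.4308),
        ],
    )
    def test_reference_values(self, rates, eta):
        d = ss.eta_closed_form(ThreeStateRates(*rates))
        assert d.eta == pytest.approx(eta, abs=5e-5)
        assert d.eta == pytest.approx(d.F1 * d.F2, rel=1e-12)

    def test_unit_rate_factors(self):
        d = ss.eta_closed_form(ThreeStateRates(1, 1, 1, 1))
        assert d.F1 == pytest.approx(0.5)
        assert d.F2 == pytest.approx(0.25)
        assert not d.inverted

    @given(st.tuples(positive_rate, positive_rate, positive_rate, positive_rate))
    @settings(max_examples=200, deadline=None)
    def test_matches_spectral_ratio(self, rates):
        """Closed form equals the pair ratio from the full spectral formula."""
        d = ss.eta_closed_form(ThreeStateRates(*rates))
        imp = ss.edge_importance(ss.three_state_chain(*rates))
        r12 = imp.pair_share(1, 2)
        r23 = imp.pair_share(2, 3)
        assert d.eta == pytest.approx(r12 / (r12 + r23), rel=1e-8)

    def test_diagnostics_consistency(self):
        d = ss.eta_closed_form(ThreeStateRates(0.2, 3.0, 50.0, 0.7))
        assert d.deltaJ == pytest.approx((3.0 - 50.0) / (3.0 + 50.0))
        assert d.tau12 == pytest.approx(1 / 3.2)
        assert d.tau23 == pytest.approx(1 / 50.7)
        assert d.nu >= 1.0
        assert d.pi.sum() == pytest.approx(1.0)

    def test_middle_state_rejected(self):
        with pytest.raises(ValueError, match="observable_state=3"):
            ss.eta_closed_form(ThreeStateRates(1, 1, 1, 1, observable_state=2))


class TestEtaBounds:
    def test_unit_rate_flux_bound(self):
        b = ss.eta_bounds(ThreeStateRates(1, 1, 1, 1))
        assert b[3] == pytest.approx(0.5)

    def test_example_a_rate_bound(self):
        b = ss.eta_bounds(ThreeStateRates(1, 1, 10, 0.1))
        assert b[1] == pytest.approx(10 / 10.1)

    def test_bounds_hold_on_random_quadruples(self):
        rng = np.random.default_rng(7)
        a = np.exp(rng.normal(0, 3, size=(10_000, 4)))
        for row in a:
            r = ThreeStateRates(*row)
            eta = ss.eta_closed_form(r).eta
            for b in ss.eta_bounds(r):
                assert eta <= b + 1e-12


class TestCanonicalTransform:
    def test_identity_at_eps_one(self):
        r = ThreeStateRates(2.0, 3.0, 4.0, 5.0)
        assert ss.canonical_transform(r, 1.0) == r

    def test_unit_start_eps_tenth(self):
        out = ss.canonical_transform(ThreeStateRates(1, 1, 1, 1), 0.1)
        assert out.as_tuple() == pytest.approx((0.1, 1.0, 10.0, 1.0))
        # this lands on the beta slice with beta = 10: eta = (10/11)^3
        eta = ss.eta_closed_form(out).eta
        assert eta == pytest.approx(1000 / 1331, rel=1e-12)

    def test_eta_monotone_to_one(self):
        r = ThreeStateRates(0.7, 2.0, 1.5, 0.9)
        etas = [
            ss.eta_closed_form(ss.canonical_transform(r, 10.0**-p)).eta
            for p in range(0, 7)
        ]
        assert all(b >= a for a, b in zip(etas, etas[1:]))
        assert etas[-1] > 0.99

    def test_invalid_eps(self):
        with pytest.raises(ValueError):
            ss.canonical_transform(ThreeStateRates(1, 1, 1, 1), 0.0)


class TestBetaInversionThreshold:
    def test_matches_analytic_root(self):
        thr = ss.beta_inversion_threshold(resolution=1e-9)
        assert thr == pytest.approx(ss.BETA_SLICE_THRESHOLD, abs=1e-8)

    def test_brackets_printed_values(self):
        thr = ss.beta_inversion_threshold()
        assert 3.847 < thr < 3.848

    def test_eta_at_unit_beta(self):
        assert _eta_beta(1.0) == pytest.approx(1.0 / 8.0)

    def test_eta_monotone_on_slice(self):
        betas = np.logspace(-1, 2, 50)
        etas = [_eta_beta(b) for b in betas]
        assert all(b > a for a, b in zip(etas, etas[1:]))
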