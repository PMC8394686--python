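"""Renormalized partial directed coherence: transform, covariance, test."""

import numpy as np
import pytest

import gcnet as g
from gcnet.rpdc import (
    FrequencyGrid,
    compute_rpdc,
    default_grid,
    fourier_coefficients,
    rpdc_critical_value,
    rpdc_significance,
    z_covariance,
    z_vector,
)


class TestFrequencyGrid:
    def test_default_grid_excludes_endpoints(self):
        grid = default_grid(64)
        assert len(grid) == 64
        assert 0 < grid.omegas[0] and grid.omegas[-1] < np.pi

    @pytest.mark.parametrize("om", [[0.0, 1.0], [1.0, 1.0], [1.0, np.pi], []])
    def test_invalid_grids_rejected(self, om):
        with pytest.raises(ValueError):
            FrequencyGrid(np.asarray(om))


class TestFourierCoefficients:
    def test_zero_coefficients_give_identity(self, white_panel):
        fit = g.fit_var(white_panel, 1)
        fit = type(fit)(**{**fit.__dict__, "Ahat": np.zeros_like(fit.Ahat)})
        Aw = fourier_coefficients(fit, default_grid(5))
        assert np.allclose(Aw, np.eye(3)[None], atol=1e-14)

    def test_univariate_at_pi(self, bivariate_panel):
        # univariate lag-1 coefficient a at omega = pi: A = 1 - a e^{-i pi} = 1 + a
        panel = g.TimeSeriesPanel(bivariate_panel.values[:, :1], ("x",))
        fit = g.fit_var(panel, 1)
        a = fit.Ahat[0, 0, 0]
        grid = FrequencyGrid(np.array([np.pi - 1e-9]))
        Aw = fourier_coefficients(fit, grid)
        assert Aw[0, 0, 0] == pytest.approx(1 + a, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_term_by_term_summation(self, seed):
        rng = np.random.default_rng(seed)
        Ahat = rng.normal(scale=0.2, size=(3, 4, 4))
        fit = _raw_fit(Ahat, np.eye(4), np.eye(12))
        grid = default_grid(7)
        Aw = fourier_coefficients(fit, grid)
        for f, w in enumerate(grid.omegas):
            ref = np.eye(4, dtype=complex)
            for r in range(1, 4):
                ref = ref - Ahat[r - 1] * np.exp(-1j * w * r)
            assert np.allclose(Aw[f], ref, atol=1e-12)


def _raw_fit(Ahat, Sigma, Rp, labels=None):
    from gcnet.var import VARFit
    p, n = Ahat.shape[0], Ahat.shape[1]
    labels = labels or tuple(f"X{i+1}" for i in range(n))
    return VARFit(p=p, Ahat=Ahat, SigmaHat=Sigma, residuals=np.zeros((1, n)),
                  Rp=Rp, rp=np.zeros((n, p * n)), T=1000 + p, labels=labels)


class TestZVector:
    def test_identity_off_diagonal_is_zero(self):
        Aw = np.eye(3, dtype=complex)[None]
        assert np.allclose(z_vector(Aw, 0, 1), 0.0)

    def test_single_lag_coupling_components(self):
        # A_kj(w) = -c e^{-iw}  ->  (Re, Im) = (-c cos w, c sin w)
        c, w = 0.4, 0.9
        Aw = np.zeros((1, 2, 2), dtype=complex)
        Aw[0, 1, 0] = -c * np.exp(-1j * w)
        z = z_vector(Aw, 1, 0)[0]
        assert z == pytest.approx([-c * np.cos(w), c * np.sin(w)])

    def test_purely_real_entry_has_zero_second_component(self):
        Aw = np.full((1, 2, 2), 0.3 + 0j)
        assert z_vector(Aw, 0, 1)[0, 1] == 0.0

    def test_self_influence_rejected(self):
        with pytest.raises(ValueError):
            z_vector(np.eye(2, dtype=complex)[None], 1, 1)


class TestZCovariance:
    def test_order_one_reduction(self):
        # p = 1: V = H_jj * Sigma_kk * [[cos^2, -cs], [-sc, sin^2]]
        Sigma = np.diag([2.0, 3.0])
        Rp = np.array([[4.0, 1.0], [1.0, 2.0]])
        fit = _raw_fit(np.zeros((1, 2, 2)), Sigma, Rp)
        w = 0.7
        H = np.linalg.inv(Rp)
        cw, sw = np.cos(w), np.sin(w)
        expect = H[0, 0] * Sigma[1, 1] * np.array(
            [[cw * cw, -cw * sw], [-sw * cw, sw * sw]])
        assert np.allclose(z_covariance(fit, 1, 0, w), expect, atol=1e-12)
        assert np.linalg.matrix_rank(z_covariance(fit, 1, 0, w)) == 1

    def test_matches_plug_in_oracle(self, white_panel):
        fit = g.fit_var(white_panel, 2)
        Rp_inv = np.linalg.inv(fit.Rp)
        n, p, w = 3, 2, 1.1
        for k in range(n):
            for j in range(n):
                if k == j:
                    continue
                V_ref = np.zeros((2, 2))
                for l in range(1, p + 1):
                    for m in range(1, p + 1):
                        H = Rp_inv[(l - 1) * n + j, (m - 1) * n + j]
                        cl = np.array([np.cos(l * w), -np.sin(l * w)])
                        cm = np.array([np.cos(m * w), -np.sin(m * w)])
                        V_ref += H * fit.SigmaHat[k, k] * np.outer(cl, cm)
                assert np.allclose(z_covariance(fit, k, j, w), V_ref, atol=1e-10)


class TestComputeRpdc:
    def test_matches_scalar_oracle_on_bivariate_var1(self, bivariate_panel):
        fit = g.fit_var(bivariate_panel, 1)
        grid = default_grid(16)
        res = compute_rpdc(fit, grid)
        H = np.linalg.inv(fit.Rp)
        a = fit.Ahat[0]
        for f, w in enumerate(grid.omegas):
            for k, j in ((0, 1), (1, 0)):
                Akj = -a[k, j] * np.exp(-1j * w)
                Z = np.array([Akj.real, Akj.imag])
                cw = np.array([np.cos(w), -np.sin(w)])
                V = H[j, j] * fit.SigmaHat[k, k] * np.outer(cw, cw)
                lam_ref = Z @ np.linalg.pinv(V) @ Z
                assert res.lam[k, j, f] == pytest.approx(lam_ref, abs=1e-10)

    def test_nonnegative_on_random_fits(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            model = g.VARModel(A=rng.normal(scale=0.15, size=(2, 3, 3)),
                               Sigma=np.eye(3))
            if not model.is_stationary():
                continue
            panel = g.simulate_var(model, 300, burn_in=50, seed=seed)
            res = compute_rpdc(g.fit_var(panel, 2), default_grid(8))
            off = ~np.eye(3, dtype=bool)
            assert np.all(res.lam[off] >= 0)

    def test_null_statistic_is_chi_square_calibrated(self):
        # no influence 2 -> 1: N * lambda should follow chi2 with 2 dof
        model = g.VARModel(A=np.zeros((2, 3, 3)), Sigma=np.eye(3))
        grid = default_grid(8)
        vals = []
        for seed in range(500):
            panel = g.simulate_var(model, 400, burn_in=20, seed=seed)
            res = compute_rpdc(g.fit_var(panel, 2), grid)
            vals.append(res.N * res.lam[0, 1, 3])
        assert 5.0 <= np.quantile(vals, 0.95) <= 7.2

    def test_strong_edge_dominates_absent_pairs(self, bivariate_var1):
        wins = 0
        for seed in range(10):
            panel = g.simulate_var(bivariate_var1, 2000, seed=seed)
            res = compute_rpdc(g.fit_var(panel, 1), default_grid(16))
            wins += res.lam[1, 0].min() > res.lam[0, 1].max()
        assert wins >= 9


class TestCriticalValue:
    def test_closed_form_chi2_quantile(self):
        # chi2(2) quantile has the closed form -2 ln(alpha)
        assert rpdc_critical_value(0.05, 1) == pytest.approx(-2 * np.log(0.05), rel=1e-12)
        assert rpdc_critical_value(0.05, 1000) == pytest.approx(-2 * np.log(0.05) / 1000)

    def test_decreases_with_sample_size(self):
        values = [rpdc_critical_value(0.05, N) for N in (10, 100, 1000)]
        assert values == sorted(values, reverse=True)

    @pytest.mark.parametrize("alpha,N", [(0.0, 10), (1.0, 10), (0.05, 0)])
    def test_invalid_arguments_rejected(self, alpha, N):
        with pytest.raises(ValueError):
            rpdc_critical_value(alpha, N)


class TestSignificanceRules:
    def _result(self, lam, critical=1.0):
        from gcnet.rpdc import RPDCResult
        lam = np.asarray(lam, dtype=float)
        return RPDCResult(lam=lam, critical=critical, N=100, alpha=0.05,
                          dof=2, omegas=np.linspace(0.1, 3.0, lam.shape[2]),
                          labels=tuple("ab"))

    def test_all_below_critical_gives_empty_graph(self):
        res = self._result(np.full((2, 2, 4), 0.5))
        assert rpdc_significance(res).edges == {}

    def test_all_frequencies_rule_requires_every_frequency(self):
        lam = np.zeros((2, 2, 4))
        lam[1, 0] = [2.0, 2.0, 0.5, 2.0]    # dips below at one frequency
        res = self._result(lam)
        assert rpdc_significance(res, rule="all_frequencies").edges == {}
        assert set(rpdc_significance(res, rule="any_frequency").edges) == {("a", "b")}
        assert set(rpdc_significance(res, rule="fraction", fraction=0.5).edges) == {("a", "b")}

    def test_weight_is_min_over_frequencies(self):
        lam = np.zeros((2, 2, 4))
        lam[1, 0] = [2.0, 3.0, 4.0, 2.5]
        graph = rpdc_significance(self._result(lam))
        assert graph.edges[("a", "b")] == pytest.approx(2.0)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            rpdc_significance(self._result(np.zeros((2, 2, 3))), rule="sometimes")

    def test_benchmark_true_edges_recovered_with_few_extras(self):
        # all 7 true links clear the all-frequency rule; false alarms stay
        # at the few-percent-per-pair level the pointwise test implies
        truth = set(g.true_graph().edges)
        recovered, extras = 0, []
        for seed in range(10):
            panel = g.benchmark_panel(T=2000, seed=seed + 200)
            res = compute_rpdc(g.fit_var(panel, 2))
            graph = rpdc_significance(res)
            recovered += truth <= set(graph.edges)
            extras.append(len(set(graph.edges) - truth))
        assert recovered >= 9
        assert np.mean(extras) <= 2.0
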