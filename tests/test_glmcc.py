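"""Penalized Poisson-GLM fitting and likelihood-ratio detection."""

import numpy as np
import pytest
from scipy import optimize

from spikeconn import (
    Correlogram,
    HyperParams,
    SpikeDataset,
    build_penalty,
    cross_correlogram,
    ei_dominance,
    estimate_connectivity,
    fit_pair,
    inject_synaptic_pair,
    kernel_bin_average,
    lr_decide,
    synaptic_kernel,
)
from .conftest import poisson_pair, poisson_train


class TestSynapticKernel:
    def test_zero_at_and_before_delay(self):
        assert synaptic_kernel(2.0, tau_s=2.0, d=2.0) == 0.0
        assert synaptic_kernel(-1.0, tau_s=2.0, d=2.0) == 0.0

    def test_exponential_decay_value(self):
        assert synaptic_kernel(4.0, tau_s=2.0, d=2.0) == pytest.approx(
            np.exp(-1), rel=1e-12)

    def test_bin_average_matches_quadrature(self):
        from scipy.integrate import quad

        edges = np.arange(-50.0, 51.0)
        fbar = kernel_bin_average(edges, tau_s=3.0, d=2.0)
        for b in (50, 52, 53, 60):
            num, _ = quad(lambda t: synaptic_kernel(t, 3.0, 2.0),
                          edges[b], edges[b + 1])
            assert fbar[b] == pytest.approx(num, abs=1e-10)
        assert np.all(fbar[:50] == 0)


class TestPenalty:
    hyper = HyperParams()

    def test_constant_background_costs_nothing(self):
        for method, n in (("glmcc", 100), ("shin", 101)):
            Q = build_penalty(method, self.hyper, 100)
            a = np.full(n, 3.7)
            # rounding floor set by the ~1e6-scale penalty coefficients
            assert a @ Q @ a == pytest.approx(0.0, abs=1e-6)

    def test_linear_background_shin_free_glmcc_penalized(self):
        Qg = build_penalty("glmcc", self.hyper, 100)
        Qs = build_penalty("shin", self.hyper, 100)
        centers = np.arange(-49.5, 50.0)
        lin = 0.01 * centers
        lin_s = np.concatenate([lin, [0.0]])  # origin knot on the line
        assert lin_s @ Qs @ lin_s == pytest.approx(0.0, abs=1e-6)
        assert lin @ Qg @ lin > 0

    def test_v_shape_shin_free(self):
        Qs = build_penalty("shin", self.hyper, 100)
        v = np.concatenate([0.02 * np.abs(np.arange(-49.5, 50.0)), [0.0]])
        assert v @ Qs @ v == pytest.approx(0.0, abs=1e-6)

    def test_v_shape_invariance_of_shin_penalty(self):
        # adding any continuous V to a candidate leaves the penalty unchanged
        rng = np.random.default_rng(0)
        Qs = build_penalty("shin", self.hyper, 100)
        a = np.concatenate([rng.normal(0, 0.1, 100), [0.05]])
        v = np.concatenate([0.03 * np.abs(np.arange(-49.5, 50.0)), [0.0]])
        assert (a + v) @ Qs @ (a + v) == pytest.approx(
            a @ Qs @ a + 2 * (v @ Qs @ a), abs=1e-6)
        assert v @ Qs @ v == pytest.approx(0.0, abs=1e-6)

    def test_odd_bins_rejected(self):
        with pytest.raises(ValueError):
            build_penalty("glmcc", self.hyper, 99)


def _cc_from_counts(counts, duration=300.0):
    edges = np.arange(-50.0, 51.0)
    return Correlogram(edges, counts, 0, 0, duration, 1.0, 50.0)


class TestFitPair:
    hyper = HyperParams()

    def test_flat_cc_recovers_mean(self):
        cc = _cc_from_counts(np.full(100, 77))
        for method in ("glmcc", "shin"):
            fit = fit_pair(cc, method, self.hyper, 2.0, 1.0, fix_J="both")
            assert fit.converged
            np.testing.assert_allclose(np.exp(fit.a), 77.0, rtol=1e-6)
            assert fit.J_pos == 0.0 and fit.J_neg == 0.0

    def test_logpost_below_loglik(self):
        rng = np.random.default_rng(3)
        cc = _cc_from_counts(rng.poisson(100, 100))
        for method in ("glmcc", "shin"):
            fit = fit_pair(cc, method, self.hyper, 2.0, 1.0)
            assert fit.logpost <= fit.loglik

    def test_coupling_recovery_from_generative_twin(self):
        # counts drawn from exp(a0 + J*fbar) with J=1: mean J-hat near 1
        edges = np.arange(-50.0, 51.0)
        fbar = kernel_bin_average(edges, 2.0, 2.0)
        lam = 150 * np.exp(1.0 * fbar)
        for method in ("glmcc", "shin"):
            js = []
            for s in range(12):
                counts = np.random.default_rng(s).poisson(lam)
                fit = fit_pair(_cc_from_counts(counts), method, self.hyper,
                               2.0, 2.0)
                js.append(fit.J_pos)
            assert abs(np.mean(js) - 1.0) < 0.15

    def test_window_mismatch_rejected(self):
        cc = _cc_from_counts(np.full(100, 10))
        with pytest.raises(ValueError):
            fit_pair(cc, "glmcc", HyperParams(W=40.0, bin_width=1.0), 2.0, 1.0)

    def test_oracle_equivalence_derivative_free(self):
        # 10-bin toy: Newton optimum matches a derivative-free optimizer
        hyper = HyperParams(W=5.0, bin_width=1.0)
        rng = np.random.default_rng(7)
        counts = rng.poisson(60, 10)
        edges = np.arange(-5.0, 6.0)
        cc = Correlogram(edges, counts, 0, 0, 50.0, 1.0, 5.0)
        from scipy.special import gammaln

        for method, na in (("glmcc", 10), ("shin", 11)):
            fit = fit_pair(cc, method, hyper, 2.0, 1.0)
            Q = build_penalty(method, hyper, 10)
            fp = kernel_bin_average(edges, 2.0, 1.0)
            fn = fp[::-1]
            p = na + 2

            def neg_obj(x):
                eta = x[:10] + x[na] * fp + x[na + 1] * fn
                ll = np.sum(counts * eta - np.exp(eta))
                return -(ll - x[:na] @ Q @ x[:na])

            # precondition with a crude curvature estimate so the stiff
            # penalty directions do not stall the direction-set search
            x0 = np.concatenate([np.full(na, np.log(counts.mean())), [0.0, 0.0]])
            A = np.zeros((p, p))
            A[:na, :na] = 2 * Q
            A[:10, :10] += np.diag(np.full(10, counts.mean()))
            A[na, na] = A[na + 1, na + 1] = counts.mean()
            L = np.linalg.cholesky(A + 1e-3 * np.eye(p))

            def g(z):
                return neg_obj(x0 + np.linalg.solve(L.T, z))

            res = optimize.minimize(g, np.zeros(p), method="Powell",
                                    options={"xtol": 1e-12, "ftol": 1e-15,
                                             "maxiter": 400_000,
                                             "maxfev": 400_000})
            res = optimize.minimize(g, res.x, method="Powell",
                                    options={"xtol": 1e-12, "ftol": 1e-15,
                                             "maxiter": 400_000,
                                             "maxfev": 400_000})
            newton_obj = fit.logpost + float(np.sum(gammaln(counts + 1.0)))
            # Newton must be at least as good, and agree to 1e-6
            assert newton_obj >= -res.fun - 1e-6
            assert abs(newton_obj - (-res.fun)) < 1e-6


class TestLRDecide:
    hyper = HyperParams()

    def test_z_alpha_quantile(self):
        # chi-square(1) upper 1e-4 quantile, cross-checked by numerical
        # integration of the density
        from scipy.integrate import quad

        z = HyperParams().z_alpha
        assert z == pytest.approx(15.137, abs=2e-3)
        dens = lambda x: np.exp(-x / 2) / np.sqrt(2 * np.pi * x)
        tail, _ = quad(dens, z, np.inf)
        assert tail == pytest.approx(1e-4, rel=1e-3)

    def test_wilks_null_calibration_fixed_kernel(self):
        # 2D ~ chi-square(1) under the null at the detection kernel
        hyper = HyperParams(alpha=0.05)
        n = 150
        rej = {"glmcc": 0, "shin": 0}
        for s in range(n):
            a, b = poisson_pair(5, 1800.0, 40_000 + s)
            cc = cross_correlogram(a, b)
            for m in rej:
                dec = lr_decide(cc, m, hyper)
                rej[m] += (dec.sign_pos != "none") + (dec.sign_neg != "none")
        for m, k in rej.items():
            rate = k / (2 * n)
            assert 0.05 - 3 * np.sqrt(0.05 * 0.95 / (2 * n)) < rate \
                < 0.05 + 3 * np.sqrt(0.05 * 0.95 / (2 * n)), (m, rate)

    def test_injected_pair_detected_directionally(self):
        detected = {"glmcc": 0, "shin": 0}
        reverse_clean = {"glmcc": 0, "shin": 0}
        n = 8
        for s in range(n):
            pre, post, _ = inject_synaptic_pair(
                5, 5, J=1.5, tau_s=2.0, d=2.0, duration=3600.0,
                seed=600 + s, dt=2e-4)
            cc = cross_correlogram(pre, post)
            for m in detected:
                dec = lr_decide(cc, m, self.hyper)
                detected[m] += dec.sign_pos == "excitatory"
                reverse_clean[m] += dec.sign_neg == "none"
        for m in detected:
            assert detected[m] >= n - 1
            assert reverse_clean[m] >= n - 1

    def test_swap_symmetry(self):
        pre, post, _ = inject_synaptic_pair(
            8, 8, J=1.2, tau_s=2.0, d=2.0, duration=900.0, seed=9, dt=2e-4)
        cc = cross_correlogram(pre, post)
        cc_sw = cross_correlogram(post, pre)
        for m in ("glmcc", "shin"):
            d1 = lr_decide(cc, m, self.hyper)
            d2 = lr_decide(cc_sw, m, self.hyper)
            assert d1.sign_pos == d2.sign_neg and d1.sign_neg == d2.sign_pos
            assert d1.D_pos == pytest.approx(d2.D_neg, abs=1e-5)
            assert d1.fit.J_pos == pytest.approx(d2.fit.J_neg, abs=1e-5)


class TestEstimateConnectivity:
    def test_null_dataset_no_edges_and_full_coverage(self):
        ds = SpikeDataset(tuple(
            poisson_train(10, 300.0, 700 + u, unit_id=u) for u in range(5)),
            0.0, 300.0)
        conn = estimate_connectivity(ds, method="shin")
        assert conn.n_excitatory == 0 and conn.n_inhibitory == 0
        assert conn.sign.shape == (5, 5)
        assert not conn.failures

    def test_injected_edge_recovered_in_matrix(self):
        pre, post, _ = inject_synaptic_pair(
            8, 8, J=1.5, tau_s=2.0, d=2.0, duration=1800.0, seed=11, dt=2e-4)
        extra = poisson_train(8, 1800.0, 12, unit_id=2)
        ds = SpikeDataset((pre, post, extra), 0.0, 1800.0)
        conn = estimate_connectivity(ds, method="glmcc")
        assert conn.sign[0, 1] == 1
        edges = conn.to_edge_list()
        # matrix and edge list agree cell-by-cell
        assert len(edges) == (conn.sign != 0).sum()
        row = edges[(edges.pre == 0) & (edges.post == 1)].iloc[0]
        assert row["sign"] == "E" and row.J > 0

    def test_classical_method_runs(self):
        ds = SpikeDataset(tuple(
            poisson_train(15, 120.0, 800 + u, unit_id=u) for u in range(4)),
            0.0, 120.0)
        conn = estimate_connectivity(ds, method="classical")
        assert conn.sign.shape == (4, 4)

    def test_requires_two_units(self):
        ds = SpikeDataset((poisson_train(5, 10.0, 0),), 0.0, 10.0)
        with pytest.raises(ValueError):
            estimate_connectivity(ds)


class TestEIDominance:
    def _conn(self, sign):
        from spikeconn.glmcc import ConnectionMatrix

        n = sign.shape[0]
        nan = np.full((n, n), np.nan)
        return ConnectionMatrix(list(range(n)), "shin", sign, nan, nan,
                                nan, nan)

    def test_values(self):
        sign = np.zeros((5, 5), np.int8)
        sign[0, 1:5] = [1, 1, 1, -1]   # ne=3, ni=1 -> 0.5
        sign[1, [0, 2, 3, 4]] = -1     # ne=0, ni=4 -> -1
        df = ei_dominance(self._conn(sign))
        assert df.loc[0, "dei"] == pytest.approx(0.5)
        assert df.loc[1, "dei"] == pytest.approx(-1.0)
        assert np.isnan(df.loc[2, "dei"])  # no outgoing edges: undefined
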