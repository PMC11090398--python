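import numpy as np
import pytest
import scipy.stats

import dynsrm
from dynsrm.params import FamilyEffects, cov2x2, default_params
from dynsrm.reparam import (
    NonstationaryError,
    continuous_loglik,
    family_mean,
    implied_family_cov,
    loglik_residual_form,
    loglik_response_form,
    residual_cov_sequence,
    stationary_residual_cov,
    tilde_effects,
    to_tilde,
)
from dynsrm.roles import DirectedDyad, UndirectedDyad, undirected_dyads
from dynsrm.simulate import draw_effects, simulate_family


def random_params(rng, roles=("M", "F", "S1", "S2"), stationary=True):
    p = default_params("continuous", roles=roles)
    for d in p.mu:
        p.mu[d] = rng.normal(3, 1)
        p.phi1[d] = rng.uniform(-0.4, 0.4) if stationary else rng.uniform(0.8, 1.2)
        p.phi2[d] = rng.uniform(-0.3, 0.3)
    p.sigma2_f = rng.uniform(0.01, 0.3)
    for r in p.Sigma_ap:
        p.Sigma_ap[r] = cov2x2(rng.uniform(0.05, 0.4), rng.uniform(0.05, 0.4), rng.uniform(-0.8, 0.8))
    for u in p.Sigma_d:
        p.Sigma_d[u] = cov2x2(rng.uniform(0.05, 0.4), rng.uniform(0.05, 0.4), rng.uniform(-0.8, 0.8))
        p.Sigma_eta[u] = cov2x2(rng.uniform(0.3, 1.5), rng.uniform(0.3, 1.5), rng.uniform(-0.7, 0.7))
        p.Sigma_e1[u] = cov2x2(rng.uniform(0.3, 1.5), rng.uniform(0.3, 1.5), rng.uniform(-0.7, 0.7))
    return p


class TestTilde:
    def test_identity_when_no_dynamics(self):
        p = default_params("continuous")
        for d in p.mu:
            p.phi1[d] = p.phi2[d] = 0.0
            p.mu[d] = 3.67
        assert to_tilde(p)[DirectedDyad("M", "F")] == pytest.approx(3.67)

    def test_direct_substitution(self):
        p = default_params("continuous")
        ij = DirectedDyad("M", "F")
        p.mu[ij], p.mu[ij.reverse] = 3.0, 2.0
        p.phi1[ij], p.phi2[ij] = 0.2, 0.1
        assert to_tilde(p)[ij] == pytest.approx(0.8 * 3.0 - 0.1 * 2.0)

    def test_symmetric_case(self):
        p = default_params("continuous")
        ij = DirectedDyad("S1", "S2")
        for d in (ij, ij.reverse):
            p.phi1[d], p.phi2[d], p.mu[d] = 0.25, 0.05, 2.0
        mt = to_tilde(p)
        expect = (1 - 0.25 - 0.05) * 2.0
        assert mt[ij] == pytest.approx(expect)
        assert mt[ij.reverse] == pytest.approx(expect)

    def test_tilde_effects_reduce_to_originals_without_dynamics(self, rng):
        p = default_params("continuous")
        for d in p.mu:
            p.phi1[d] = p.phi2[d] = 0.0
        eff = draw_effects(p, ("M", "F", "S1", "S2"), rng)
        te = tilde_effects(p, eff)
        ij = DirectedDyad("M", "F")
        f_t, a_t, p_t, d_t = te[ij]
        assert f_t == pytest.approx(eff.f)
        assert a_t == pytest.approx(eff.a["M"])
        assert p_t == pytest.approx(eff.p["F"])
        assert d_t == pytest.approx(eff.d[ij])

    def test_tilde_family_effect_substitution(self):
        p = default_params("continuous")
        ij = DirectedDyad("M", "F")
        p.phi1[ij], p.phi2[ij] = 0.2, 0.1
        eff = FamilyEffects(
            f=1.0,
            a={r: 0.0 for r in ("M", "F")},
            p={r: 0.0 for r in ("M", "F")},
            d={ij: 0.0, ij.reverse: 0.0},
        )
        assert tilde_effects(p, eff)[ij][0] == pytest.approx(0.8 - 0.1)

    def test_tilde_sum_matches_transformed_linear_predictor(self, rng):
        from dynsrm.params import linear_predictor

        for seed in range(10):
            r = np.random.default_rng(seed)
            p = random_params(r)
            eff = draw_effects(p, ("M", "F", "S1", "S2"), r)
            mt = to_tilde(p)
            te = tilde_effects(p, eff)
            for ij in p.mu:
                lhs = mt[ij] + sum(te[ij])
                rhs = (1 - p.phi1[ij]) * linear_predictor(p, eff, ij) - p.phi2[
                    ij
                ] * linear_predictor(p, eff, ij.reverse)
                assert lhs == pytest.approx(rhs, abs=1e-12)


class TestStationaryCov:
    def test_zero_dynamics_returns_innovation_cov(self):
        S = cov2x2(1.0, 2.0, 0.4)
        assert np.allclose(stationary_residual_cov(np.zeros((2, 2)), S), S)

    def test_univariate_ar1_closed_form(self):
        S = stationary_residual_cov(np.diag([0.5, 0.5]), np.eye(2))
        assert np.allclose(S, np.diag([4 / 3, 4 / 3]))

    def test_lyapunov_residual_tiny(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            Phi = rng.uniform(-0.45, 0.45, (2, 2))
            Seta = cov2x2(rng.uniform(0.5, 2), rng.uniform(0.5, 2), rng.uniform(-0.6, 0.6))
            S = stationary_residual_cov(Phi, Seta)
            assert np.abs(S - Phi @ S @ Phi.T - Seta).max() <= 1e-10
            assert np.linalg.eigvalsh(S).min() > 0

    def test_long_run_simulation_oracle(self):
        Phi = np.array([[0.2, 0.1], [0.05, 0.3]])
        Seta = cov2x2(1.0, 1.0, 0.3)
        S = stationary_residual_cov(Phi, Seta)
        rng = np.random.default_rng(7)
        L = np.linalg.cholesky(Seta)
        n_chains, T = 2000, 250
        E = np.zeros((n_chains, 2))
        keep = []
        for t in range(T):
            E = E @ Phi.T + rng.normal(size=(n_chains, 2)) @ L.T
            if t >= 50:
                keep.append(E.copy())
        X = np.concatenate(keep)  # 400k correlated samples
        emp = np.cov(X.T)
        assert np.allclose(emp, S, rtol=0.03, atol=0.01)

    def test_nonstationary_raises(self):
        with pytest.raises(NonstationaryError):
            stationary_residual_cov(np.diag([1.01, 0.2]), np.eye(2))


class TestResidualCovSequence:
    def test_t1_returns_first_snapshot_cov(self):
        S1 = cov2x2(0.9, 1.1, 0.2)
        V = residual_cov_sequence(S1, np.zeros((2, 2)), np.eye(2), 1)
        assert V.shape == (1, 2, 2) and np.allclose(V[0], S1)

    def test_zero_dynamics_gives_innovation_cov_after_first(self):
        S1 = cov2x2(0.9, 1.1, 0.2)
        Seta = cov2x2(1.0, 1.0, 0.5)
        V = residual_cov_sequence(S1, np.zeros((2, 2)), Seta, 4)
        for t in range(1, 4):
            assert np.allclose(V[t], Seta)

    def test_stationary_start_is_fixed_point(self):
        Phi = np.array([[0.3, -0.1], [0.2, 0.25]])
        Seta = cov2x2(1.0, 0.8, 0.3)
        S = stationary_residual_cov(Phi, Seta)
        V = residual_cov_sequence(S, Phi, Seta, 6)
        for t in range(6):
            assert np.allclose(V[t], S, atol=1e-12)


class TestImpliedFamilyCov:
    def test_single_dyad_t1_matches_variance_partition(self):
        p = default_params("continuous", roles=("M", "F"))
        u = UndirectedDyad.of("M", "F")
        dur = {u: 1}
        C, layout = implied_family_cov(p, ("M", "F"), dur)
        ij, ji = u.directed
        var_ij = (
            p.sigma2_f
            + p.Sigma_ap["M"][0, 0]
            + p.Sigma_ap["F"][1, 1]
            + p.Sigma_d[u][0, 0]
            + p.Sigma_e1[u][0, 0]
        )
        assert C.shape == (2, 2)
        assert C[0, 0] == pytest.approx(var_ij)
        cov_pair = (
            p.sigma2_f
            + p.Sigma_ap["M"][0, 1]
            + p.Sigma_ap["F"][0, 1]
            + p.Sigma_d[u][0, 1]
            + p.Sigma_e1[u][0, 1]
        )
        assert C[0, 1] == pytest.approx(cov_pair)

    def test_family_variance_only_gives_all_ones(self):
        eps = 1e-12
        p = default_params("continuous", roles=("M", "F", "S1"))
        p.sigma2_f = 1.0
        for r in p.Sigma_ap:
            p.Sigma_ap[r] = cov2x2(eps, eps, 0.0)
        for u in p.Sigma_d:
            p.Sigma_d[u] = cov2x2(eps, eps, 0.0)
            p.Sigma_eta[u] = cov2x2(eps, eps, 0.0)
            p.Sigma_e1[u] = cov2x2(eps, eps, 0.0)
        for d in p.mu:
            p.phi1[d] = p.phi2[d] = 0.0
        dur = {u: 2 for u in undirected_dyads(("M", "F", "S1"))}
        C, _ = implied_family_cov(p, ("M", "F", "S1"), dur)
        assert np.allclose(C, 1.0, atol=1e-9)

    def test_symmetric_psd_for_random_params(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            p = random_params(rng)
            dur = {u: int(rng.integers(1, 5)) for u in undirected_dyads(("M", "F", "S1", "S2"))}
            C, _ = implied_family_cov(p, ("M", "F", "S1", "S2"), dur)
            assert np.allclose(C, C.T)
            assert np.linalg.eigvalsh(C).min() >= -1e-8

    def test_monte_carlo_oracle_three_member_family(self):
        rng = np.random.default_rng(3)
        p = dynsrm.paper_like_params("continuous")
        comp = ("M", "S1", "S2")
        dur = {u: 4 for u in undirected_dyads(comp)}
        C, layout = implied_family_cov(p, comp, dur)
        n = 20000
        X = np.empty((n, len(layout)))
        for i in range(n):
            eff = draw_effects(p, comp, rng)
            y = simulate_family(p, eff, dur, rng)
            X[i] = np.concatenate([y[u].reshape(-1) for u in undirected_dyads(comp)])
        emp = np.cov(X.T)
        se = np.sqrt((np.outer(np.diag(C), np.diag(C)) + C**2) / n)
        z = np.abs(emp - C) / se
        assert (z < 3).mean() > 0.985
        assert z.max() < 6


class TestContinuousLoglik:
    def _single_obs_dataset(self, y=3.5):
        import pandas as pd

        from dynsrm.data import COLUMNS, PanelDataset

        rows = [("f1", "M", "F", 1, y, True), ("f1", "F", "M", 1, y, True)]
        return PanelDataset(pd.DataFrame(rows, columns=COLUMNS))

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        p = random_params(rng, roles=("M", "F"))
        data = self._single_obs_dataset(2.2)
        base = continuous_loglik(p, data, "f1")
        shifted = p.copy()
        for d in shifted.mu:
            shifted.mu[d] += 5.0
        data2 = self._single_obs_dataset(7.2)
        assert continuous_loglik(shifted, data2, "f1") == pytest.approx(base)

    def test_standard_normal_mode_value(self):
        eps = 1e-9
        p = default_params("continuous", roles=("M", "F"))
        u = UndirectedDyad.of("M", "F")
        # variances summing to 1 with an uncorrelated pair: y = mu gives the
        # standard-normal mode density per observation
        p.sigma2_f = eps
        p.Sigma_ap = {r: cov2x2(eps, eps, 0.0) for r in ("M", "F")}
        p.Sigma_d = {u: cov2x2(eps, eps, 0.0)}
        p.Sigma_e1 = {u: cov2x2(1.0, 1.0, 0.0)}
        for d in p.mu:
            p.mu[d] = 3.5
            p.phi1[d] = p.phi2[d] = 0.0
        data = self._single_obs_dataset(3.5)
        ll = continuous_loglik(p, data, "f1")
        assert ll == pytest.approx(2 * (-0.5 * np.log(2 * np.pi)), abs=1e-6)

    def test_quadrature_oracle_family_effect_only(self, rng):
        from numpy.polynomial.hermite_e import hermegauss

        eps = 1e-10
        p = default_params("continuous", roles=("M", "F"))
        u = UndirectedDyad.of("M", "F")
        p.sigma2_f = 0.7
        p.Sigma_ap = {r: cov2x2(eps, eps, 0.0) for r in ("M", "F")}
        p.Sigma_d = {u: cov2x2(eps, eps, 0.0)}
        for d in p.mu:
            p.phi1[d], p.phi2[d] = 0.3, 0.15
        eff0 = draw_effects(p, ("M", "F"), rng)
        dur = {u: 3}
        y = simulate_family(p, eff0, dur, rng)

        nodes, w = hermegauss(60)
        total = 0.0
        for nd, wt in zip(nodes, w):
            eff = FamilyEffects(
                f=nd * np.sqrt(p.sigma2_f),
                a={"M": 0.0, "F": 0.0},
                p={"M": 0.0, "F": 0.0},
                d={d: 0.0 for d in p.mu},
            )
            total += wt / np.sqrt(2 * np.pi) * np.exp(loglik_residual_form(p, eff, y))
        C, layout = implied_family_cov(p, ("M", "F"), dur)
        m = family_mean(p, layout)
        marg = scipy.stats.multivariate_normal.logpdf(y[u].reshape(-1), mean=m, cov=C)
        assert np.log(total) == pytest.approx(marg, abs=1e-6)


class TestParameterisationEquivalence:
    def test_residual_and_response_forms_agree(self):
        worst = 0.0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            p = random_params(rng)
            comp = ("M", "F", "S1", "S2") if seed % 2 else ("M", "S1", "S2")
            eff = draw_effects(p, comp, rng)
            dur = {u: int(rng.integers(1, 8)) for u in undirected_dyads(comp)}
            y = simulate_family(p, eff, dur, rng)
            a = loglik_residual_form(p, eff, y)
            b = loglik_response_form(p, eff, y)
            worst = max(worst, abs(a - b))
        assert worst < 1e-8
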