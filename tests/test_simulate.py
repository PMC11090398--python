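import numpy as np
import pytest
import scipy.special

import dynsrm
from dynsrm.params import cov2x2, default_params
from dynsrm.roles import UndirectedDyad, undirected_dyads
from dynsrm.simulate import (
    SimDesign,
    draw_effects,
    headline_params,
    ordinalize,
    paper_like_params,
    simulate_dataset,
    simulate_family,
)


class TestDrawEffects:
    def test_all_variances_zero_gives_zero_effects(self, rng):
        eps = 0.0
        p = default_params("continuous")
        p.sigma2_f = 0.0
        for r in p.Sigma_ap:
            p.Sigma_ap[r] = np.zeros((2, 2))
        for u in p.Sigma_d:
            p.Sigma_d[u] = np.zeros((2, 2))
        eff = draw_effects(p, ("M", "F", "S1", "S2"), rng)
        assert eff.f == 0.0
        assert all(v == 0.0 for v in eff.a.values())
        assert all(v == 0.0 for v in eff.d.values())

    def test_perfect_correlation_ties_actor_and_partner(self, rng):
        p = default_params("continuous")
        for r in p.Sigma_ap:
            p.Sigma_ap[r] = cov2x2(0.2, 0.2, 1.0 - 1e-12)
        for _ in range(20):
            eff = draw_effects(p, ("M", "F"), rng)
            for r in ("M", "F"):
                assert eff.a[r] == pytest.approx(eff.p[r], abs=1e-5)

    def test_moment_recovery(self):
        rng = np.random.default_rng(5)
        p = paper_like_params("continuous")
        n = 30000
        ap = {r: np.empty((n, 2)) for r in ("M", "F")}
        for i in range(n):
            eff = draw_effects(p, ("M", "F"), rng)
            for r in ("M", "F"):
                ap[r][i] = (eff.a[r], eff.p[r])
        for r in ("M", "F"):
            S = p.Sigma_ap[r]
            emp = np.cov(ap[r].T)
            se = np.sqrt((np.outer(np.diag(S), np.diag(S)) + S**2) / n)
            assert np.all(np.abs(emp - S) < 3.5 * se)


class TestSimulateFamily:
    def test_noiseless_returns_linear_predictor(self, rng):
        p = default_params("continuous", roles=("M", "F"))
        u = UndirectedDyad.of("M", "F")
        p.Sigma_eta[u] = np.zeros((2, 2))
        p.Sigma_e1[u] = np.zeros((2, 2))
        eff = draw_effects(p, ("M", "F"), rng)
        y = simulate_family(p, eff, {u: 4}, rng)
        from dynsrm.params import linear_predictor

        ij, ji = u.directed
        expect = [linear_predictor(p, eff, ij), linear_predictor(p, eff, ji)]
        assert np.allclose(y[u], np.tile(expect, (4, 1)))

    def test_iid_standard_normal_when_undynamic_unit_noise(self):
        rng = np.random.default_rng(11)
        p = default_params("continuous", roles=("M", "F"))
        u = UndirectedDyad.of("M", "F")
        for d in p.mu:
            p.mu[d] = 0.0
            p.phi1[d] = p.phi2[d] = 0.0
        p.sigma2_f = 0.0
        p.Sigma_ap = {r: np.zeros((2, 2)) for r in ("M", "F")}
        p.Sigma_d = {u: np.zeros((2, 2))}
        p.Sigma_eta = {u: np.eye(2)}
        p.Sigma_e1 = {u: np.eye(2)}
        eff = draw_effects(p, ("M", "F"), rng)
        ys = np.concatenate(
            [simulate_family(p, eff, {u: 50}, rng)[u].reshape(-1) for _ in range(200)]
        )
        assert abs(ys.mean()) < 0.02
        assert abs(ys.std() - 1.0) < 0.02

    def test_lag1_autocorrelation_matches_ar_coefficient(self):
        rng = np.random.default_rng(13)
        p = default_params("continuous", roles=("M", "F"))
        u = UndirectedDyad.of("M", "F")
        for d in p.mu:
            p.mu[d] = 0.0
            p.phi1[d], p.phi2[d] = 0.3, 0.0
        p.sigma2_f = 0.0
        p.Sigma_ap = {r: np.zeros((2, 2)) for r in ("M", "F")}
        p.Sigma_d = {u: np.zeros((2, 2))}
        p.Sigma_eta = {u: np.eye(2)}
        eff = draw_effects(p, ("M", "F"), rng)
        # stationary start so the autocorrelation is constant over t
        chunks = [
            simulate_family(p, eff, {u: 100}, rng, start_mode="stationary")[u][:, 0]
            for _ in range(1000)
        ]
        num = sum(np.sum(c[1:] * c[:-1]) for c in chunks)
        den = sum(np.sum(c**2) for c in chunks)
        assert num / den == pytest.approx(0.3, abs=0.02)

    def test_nonstationary_start_raises(self, rng):
        p = default_params("continuous", roles=("M", "F"))
        u = UndirectedDyad.of("M", "F")
        for d in p.mu:
            p.phi1[d] = 1.1
        eff = draw_effects(p, ("M", "F"), rng)
        from dynsrm.reparam import NonstationaryError

        with pytest.raises(NonstationaryError):
            simulate_family(p, eff, {u: 3}, rng, start_mode="stationary")


class TestOrdinalize:
    def test_below_first_threshold(self):
        assert ordinalize(-0.5, np.array([0.0, 1.0, 2.0])) == 1

    def test_boundary_is_half_open(self):
        tau = np.array([0.0, 1.0, 2.0])
        assert ordinalize(0.0, tau) == 2
        assert ordinalize(1.0, tau) == 3
        assert ordinalize(np.nextafter(1.0, 0.0), tau) == 2

    def test_probit_cell_probabilities(self):
        rng = np.random.default_rng(21)
        tau = np.array([0.0, 0.9, 1.8])
        y = rng.normal(size=1_000_000)
        cats = ordinalize(y, tau)
        freqs = np.bincount(cats, minlength=5)[1:5] / len(y)
        edges = np.concatenate([[-np.inf], tau, [np.inf]])
        probs = np.diff(scipy.special.ndtr(edges))
        assert np.all(np.abs(freqs - probs) < 3.5 * np.sqrt(probs * (1 - probs) / len(y)))


class TestSimulateDataset:
    def test_minimal_design_record_count(self):
        p = default_params("ordinal", roles=("M", "S1"))
        design = SimDesign(
            K=1,
            composition_probs={("M", "S1"): 1.0},
            duration_p_max=0.0,
            duration_lo=3,
            duration_hi=3,
            missing_rate=0.0,
            seed=0,
        )
        data = simulate_dataset(p, design)
        assert len(data.df) == 6  # 2 directions x 3 snapshots
        assert data.df["observed"].all()

    def test_seed_reproducibility_is_exact(self):
        p = paper_like_params("ordinal")
        d1 = simulate_dataset(p, SimDesign(K=10, seed=99))
        d2 = simulate_dataset(p, SimDesign(K=10, seed=99))
        assert d1.df.equals(d2.df)
        d3 = simulate_dataset(p, SimDesign(K=10, seed=100))
        assert not d1.df.equals(d3.df)

    def test_missingness_is_pairwise(self):
        p = paper_like_params("ordinal")
        data = simulate_dataset(p, SimDesign(K=60, seed=5, missing_rate=0.15))
        assert data.satisfies_pair_rule()
        assert 0.6 < data.observed_fraction() < 0.95

    def test_mean_duration_matches_design(self):
        design = SimDesign(K=1)
        assert design.mean_duration() == pytest.approx(9.7, abs=0.01)
        p = paper_like_params("ordinal")
        data = simulate_dataset(p, SimDesign(K=300, seed=8))
        df = data.durations().reset_index(name="T")
        df["pair"] = [tuple(sorted(x)) for x in zip(df["actor"], df["partner"])]
        per_undirected = df.groupby(["family_id", "pair"])["T"].first()
        assert per_undirected.mean() == pytest.approx(9.7, abs=0.35)

    def test_variance_partition_at_single_snapshot(self):
        # dynamics off, T = 1: total variance = sum of the five components
        rng = np.random.default_rng(0)
        p = paper_like_params("continuous")
        for d in p.mu:
            p.phi1[d] = p.phi2[d] = 0.0
        design = SimDesign(
            K=4000,
            composition_probs={("M", "F", "S1", "S2"): 1.0},
            duration_p_max=0.0,
            duration_lo=1,
            duration_hi=1,
            missing_rate=0.0,
            seed=17,
        )
        data = simulate_dataset(p, design)
        from dynsrm.roles import DirectedDyad

        ij = DirectedDyad("M", "F")
        u = ij.undirected
        y = data.df[(data.df.actor == "M") & (data.df.partner == "F")]["y"]
        expect = (
            p.sigma2_f
            + p.Sigma_ap["M"][0, 0]
            + p.Sigma_ap["F"][1, 1]
            + p.Sigma_d[u][0, 0]
            + p.Sigma_e1[u][0, 0]
        )
        se = expect * np.sqrt(2.0 / len(y))
        assert abs(y.var() - expect) < 3.5 * se
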