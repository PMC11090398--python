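import numpy as np
import pytest
import scipy.stats

import dynsrm
from dynsrm.model import fit as run_fit
from dynsrm.params import validate_params
from dynsrm.roles import DirectedDyad, UndirectedDyad
from dynsrm.sampler import FitConfig, GibbsSampler, _State, log_posterior, truncnorm_draw


class TestFitConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"dynamics": "vector"},
            {"response_kind": "binary"},
            {"n_chains": 1},
            {"thin": 0},
            {"n_iter": 3, "thin": 5},
            {"effects": "some"},
        ],
    )
    def test_invalid_settings_rejected(self, kw):
        with pytest.raises(ValueError):
            FitConfig(**kw)

    def test_longrun_chain_preset(self):
        cfg = dynsrm.longrun_chain_config(response_kind="ordinal")
        assert cfg.n_chains == 5
        assert cfg.n_burnin == 200_000
        assert cfg.n_iter == 50_000 and cfg.thin == 10


class TestTruncnorm:
    def test_draws_match_truncated_normal_cdf(self):
        rng = np.random.default_rng(0)
        n = 100000
        mean, sd, lo, hi = 0.3, 1.2, -0.5, 1.0
        x = truncnorm_draw(
            np.full(n, mean), np.full(n, sd), np.full(n, lo), np.full(n, hi), rng
        )
        assert x.min() >= lo and x.max() < hi
        a, b = (lo - mean) / sd, (hi - mean) / sd
        ks = scipy.stats.kstest(x, scipy.stats.truncnorm(a, b, loc=mean, scale=sd).cdf)
        assert ks.pvalue > 0.01

    def test_degenerate_interval_returns_clipped_mean(self):
        rng = np.random.default_rng(0)
        x = truncnorm_draw(
            np.array([5.0]), np.array([1e-12]), np.array([-1.0]), np.array([1.0]), rng
        )
        assert x[0] == pytest.approx(1.0, abs=1e-9)

    def test_untruncated_reduces_to_normal(self):
        rng = np.random.default_rng(1)
        n = 50000
        x = truncnorm_draw(
            np.zeros(n), np.ones(n), np.full(n, -np.inf), np.full(n, np.inf), rng
        )
        assert scipy.stats.kstest(x, "norm").pvalue > 0.01


class TestLatentAugmentation:
    def test_observed_latents_stay_in_category_intervals(self, tiny_ordinal_data):
        params, data = tiny_ordinal_data
        cfg = FitConfig(response_kind="ordinal", n_chains=2, n_adapt=10, n_burnin=0, n_iter=10, thin=1, seed=3)
        s = GibbsSampler(data, cfg)
        rng = np.random.default_rng(0)
        st = _State(s.plan, cfg, rng)
        for _ in range(15):
            s.sweep(st, rng)
        tau_ext = np.concatenate([[-np.inf], st.tau, [np.inf]])
        obs = s.plan.obs
        cat = s.plan.cat
        lo = tau_ext[np.clip(cat - 1, 0, None)][obs]
        hi = tau_ext[cat][obs]
        y = st.ystar[obs]
        assert np.all(y >= lo) and np.all(y < hi)


class TestDeterminismAndValidity:
    def test_same_seed_identical_draws(self, tiny_ordinal_data):
        _, data = tiny_ordinal_data
        cfg = FitConfig(response_kind="ordinal", n_chains=2, n_adapt=20, n_burnin=20, n_iter=40, thin=2, seed=11)
        d1 = run_fit(data, cfg)
        d2 = run_fit(data, cfg)
        for nm in d1.names:
            assert np.array_equal(d1.values[nm], d2.values[nm])
        d3 = run_fit(data, FitConfig(**{**cfg.__dict__, "seed": 12, "priors": cfg.priors}))
        assert any(not np.array_equal(d1.values[nm], d3.values[nm]) for nm in d1.names)

    def test_every_stored_draw_is_a_valid_parameter_set(self, tiny_ordinal_data):
        _, data = tiny_ordinal_data
        cfg = FitConfig(response_kind="ordinal", n_chains=2, n_adapt=30, n_burnin=30, n_iter=60, thin=3, seed=2)
        draws = run_fit(data, cfg)
        for c in range(draws.n_chains):
            for i in range(draws.n_stored):
                assert validate_params(draws.to_params(c, i)) == []

    def test_input_errors(self, tiny_ordinal_data):
        import pandas as pd

        from dynsrm.data import COLUMNS, PanelDataset

        cfg = FitConfig(response_kind="ordinal", n_chains=2, n_iter=10, thin=1, n_adapt=0, n_burnin=0)
        empty = PanelDataset(pd.DataFrame(columns=COLUMNS), response_kind="ordinal", n_categories=4)
        with pytest.raises(ValueError, match="empty"):
            run_fit(empty, cfg)
        rows = [("f1", "M", "F", 1, 2, True), ("f1", "F", "M", 1, 2, True)]
        single_cat = PanelDataset(pd.DataFrame(rows, columns=COLUMNS), response_kind="ordinal", n_categories=4)
        with pytest.raises(ValueError, match="two observed categories"):
            run_fit(single_cat, cfg)
        broken = PanelDataset(
            pd.DataFrame(
                [("f1", "M", "F", 1, 2, True), ("f1", "F", "M", 1, np.nan, False),
                 ("f1", "M", "F", 2, 3, True), ("f1", "F", "M", 2, 2, True)],
                columns=COLUMNS,
            ),
            response_kind="ordinal",
            n_categories=4,
        )
        with pytest.raises(ValueError, match="both-or-neither"):
            run_fit(broken, cfg)


class TestPriorPredictive:
    def test_empty_likelihood_run_matches_priors(self, tiny_ordinal_data):
        _, data = tiny_ordinal_data
        cfg = FitConfig(
            response_kind="ordinal", n_chains=2, n_adapt=0, n_burnin=100,
            n_iter=1500, thin=1, seed=9, start_jitter=0.0,
        )
        draws = run_fit(data, cfg, prior_only=True)
        g2 = draws.pooled("tau[2]") - draws.pooled("tau[1]")
        g3 = draws.pooled("tau[3]") - draws.pooled("tau[2]")
        assert scipy.stats.kstest(g2, "expon").pvalue > 0.01
        assert scipy.stats.kstest(g3, "expon").pvalue > 0.01
        # family precision ~ Gamma(0.001, 0.001): compare upper quantiles on
        # the log scale (lower quantiles underflow float64)
        lam = 1.0 / draws.pooled("sigma2_f")
        qs = np.array([0.8, 0.9, 0.95])
        emp = np.quantile(np.log(lam), qs)
        theo = np.log(scipy.stats.gamma.ppf(qs, 0.001, scale=1000.0))
        assert np.allclose(emp, theo, rtol=0.15)
        # fixed-part prior: N(0, precision 0.001)
        assert draws.pooled("mu[M.F]").std() == pytest.approx(31.6, rel=0.1)


class TestLogPosterior:
    def _toy(self):
        import pandas as pd

        from dynsrm.data import COLUMNS, PanelDataset
        from dynsrm.params import FamilyEffects, cov2x2, default_params

        p = default_params("continuous", roles=("M", "F"))
        rows = [("f1", "M", "F", 1, 3.2, True), ("f1", "F", "M", 1, 3.6, True)]
        data = PanelDataset(pd.DataFrame(rows, columns=COLUMNS))
        eff = FamilyEffects(
            f=0.4,
            a={"M": 0.1, "F": -0.2},
            p={"M": 0.0, "F": 0.3},
            d={d: 0.05 for d in p.mu},
        )
        return p, data, eff

    def test_family_effect_delta_matches_hand_computation(self):
        from dynsrm.reparam import loglik_residual_form

        p, data, eff = self._toy()
        cfg = FitConfig(response_kind="continuous", dynamics="ar_crosslag", n_chains=2)
        lp1 = log_posterior(p, {"f1": eff}, data, cfg)
        eff2 = dynsrm.FamilyEffects(f=0.8, a=dict(eff.a), p=dict(eff.p), d=dict(eff.d))
        lp2 = log_posterior(p, {"f1": eff2}, data, cfg)
        u = UndirectedDyad.of("M", "F")
        y = {u: np.array([[3.2, 3.6]])}
        expect = (
            scipy.stats.norm.logpdf(0.8, 0, np.sqrt(p.sigma2_f))
            - scipy.stats.norm.logpdf(0.4, 0, np.sqrt(p.sigma2_f))
            + loglik_residual_form(p, eff2, y)
            - loglik_residual_form(p, eff, y)
        )
        assert lp2 - lp1 == pytest.approx(expect, abs=1e-9)

    def test_out_of_range_correlation_raises(self):
        from dynsrm.params import cov2x2

        p, data, eff = self._toy()
        u = UndirectedDyad.of("M", "F")
        S = p.Sigma_d[u]
        S[0, 1] = S[1, 0] = 1.1 * np.sqrt(S[0, 0] * S[1, 1])
        cfg = FitConfig(response_kind="continuous", n_chains=2)
        with pytest.raises(ValueError, match="Sigma_d"):
            log_posterior(p, {"f1": eff}, data, cfg)

    def test_ordinal_latent_outside_interval_rejected(self):
        import pandas as pd

        from dynsrm.data import COLUMNS, PanelDataset
        from dynsrm.params import FamilyEffects, default_params

        p = default_params("ordinal", roles=("M", "F"))
        rows = [("f1", "M", "F", 1, 2, True), ("f1", "F", "M", 1, 3, True)]
        data = PanelDataset(pd.DataFrame(rows, columns=COLUMNS), response_kind="ordinal", n_categories=4)
        eff = FamilyEffects(f=0.0, a={"M": 0, "F": 0}, p={"M": 0, "F": 0}, d={d: 0 for d in p.mu})
        u = UndirectedDyad.of("M", "F")
        cfg = FitConfig(response_kind="ordinal", n_chains=2)
        good = {"f1": {u: np.array([[0.5, 2.0]])}}  # category 2 in [0, 1.8), 3 in [1.8, 3.6)
        lp = log_posterior(p, {"f1": eff}, data, cfg, latents=good)
        assert np.isfinite(lp)
        bad = {"f1": {u: np.array([[2.5, 2.0]])}}  # 2.5 outside category 2's interval
        with pytest.raises(ValueError, match="interval"):
            log_posterior(p, {"f1": eff}, data, cfg, latents=bad)


def test_cross_sectional_reduction_reports_pair_block_as_relationship(tiny_continuous_data):
    """T = 1 continuous fits merge the pair residual into the relationship
    covariance and expose no separate temporal-residual parameters."""
    import pandas as pd

    _, data = tiny_continuous_data
    df = data.df[data.df.snapshot == 1]
    from dynsrm.data import PanelDataset

    xs = PanelDataset(df, response_kind="continuous")
    cfg = FitConfig(response_kind="continuous", dynamics="none", n_chains=2,
                    n_adapt=10, n_burnin=10, n_iter=20, thin=1, seed=0)
    draws = run_fit(xs, cfg)
    assert "sigma2_d[M.F]" in draws
    assert "sigma2_eta[M.F]" not in draws
    assert "rho_e1[M:F]" not in draws
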