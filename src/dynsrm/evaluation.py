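"""End-to-end evaluation suites for the dynamic social relations model.

Each function simulates its own study-condition data, runs the package's
actual machinery (simulator, sampler, post-processing), and returns scalar
metrics.  They power both the acceptance test-suite and the standalone
``scripts/acceptance.py`` runner.  Problem sizes are chosen so that the
whole battery runs on a single CPU in minutes; the chain settings are the
short desk-scale ones, which the recovery metrics are calibrated for.
"""

from __future__ import annotations

import numpy as np

from . import postprocess
from .data import PanelDataset
from .draws import PosteriorDraws
from .model import fit as run_fit
from .params import SRMParams, cov2x2, default_params
from .reparam import (
    implied_family_cov,
    loglik_residual_form,
    loglik_response_form,
    stationary_residual_cov,
)
from .roles import DirectedDyad, UndirectedDyad, undirected_dyads
from .sampler import FitConfig
from .simulate import SimDesign, draw_effects, headline_params, paper_like_params, simulate_dataset, simulate_family


def random_valid_params(rng: np.random.Generator, roles=("M", "F", "S1", "S2")) -> SRMParams:
    """A random continuous-model parameter set with mild (stationary) dynamics."""
    p = default_params("continuous", roles=roles)
    for d in p.mu:
        p.mu[d] = rng.normal(3, 1)
        p.phi1[d] = rng.uniform(-0.4, 0.4)
        p.phi2[d] = rng.uniform(-0.3, 0.3)
    p.sigma2_f = rng.uniform(0.01, 0.3)
    for r in p.Sigma_ap:
        p.Sigma_ap[r] = cov2x2(rng.uniform(0.05, 0.4), rng.uniform(0.05, 0.4), rng.uniform(-0.8, 0.8))
    for u in p.Sigma_d:
        p.Sigma_d[u] = cov2x2(rng.uniform(0.05, 0.4), rng.uniform(0.05, 0.4), rng.uniform(-0.8, 0.8))
        p.Sigma_eta[u] = cov2x2(rng.uniform(0.3, 1.5), rng.uniform(0.3, 1.5), rng.uniform(-0.7, 0.7))
        p.Sigma_e1[u] = cov2x2(rng.uniform(0.3, 1.5), rng.uniform(0.3, 1.5), rng.uniform(-0.7, 0.7))
    return p


# ---------------------------------------------------------------------------
# identification constraints on an ordinal fit
# ---------------------------------------------------------------------------

def identification_check(seed: int) -> tuple[dict[str, float], PosteriorDraws]:
    """Short ordinal AR+cross-lag fit (K = 20, T = 5): the identification
    constraints tau_1 = 0 and unit innovation/first-snapshot variances must
    hold exactly in every stored draw."""
    params = headline_params("ordinal")
    design = SimDesign(K=20, seed=seed, duration_p_max=0.0, duration_lo=5, duration_hi=5)
    data = simulate_dataset(params, design)
    cfg = FitConfig(
        response_kind="ordinal", dynamics="ar_crosslag", n_chains=2,
        n_adapt=100, n_burnin=150, n_iter=300, thin=3, seed=seed,
    )
    draws = run_fit(data, cfg)
    tau1_dev = float(np.abs(draws.pooled("tau[1]")).max())
    var_names = [n for n in draws.names if n.startswith(("sigma2_eta[", "sigma2_e1["))]
    var_dev = float(max(np.abs(draws.pooled(n) - 1.0).max() for n in var_names))
    return {"tau1_max_abs": tau1_dev, "innovation_var_max_dev": var_dev}, draws


# ---------------------------------------------------------------------------
# parameterisation equivalence
# ---------------------------------------------------------------------------

def equivalence_error(seed: int, n_sets: int = 100) -> float:
    """Max |residual-form - response-form| joint log-density over random
    parameter sets and simulated families."""
    worst = 0.0
    for i in range(n_sets):
        rng = np.random.default_rng([seed, 1, i])
        p = random_valid_params(rng)
        comp = ("M", "F", "S1", "S2") if i % 2 else ("M", "S1", "S2")
        eff = draw_effects(p, comp, rng)
        dur = {u: int(rng.integers(1, 8)) for u in undirected_dyads(comp)}
        y = simulate_family(p, eff, dur, rng)
        a = loglik_residual_form(p, eff, y)
        b = loglik_response_form(p, eff, y)
        worst = max(worst, abs(a - b))
    return worst


# ---------------------------------------------------------------------------
# Lyapunov / stationary covariance oracle
# ---------------------------------------------------------------------------

def lyapunov_error(seed: int, n_mats: int = 10, n_samples: int = 1_000_000) -> float:
    """Worst relative error between stationary_residual_cov and the
    empirical covariance of ~n_samples simulated VAR(1) residual steps.

    Error is normalised by the dominant entry of the true matrix so that
    near-zero off-diagonals do not inflate the ratio.
    """
    rng = np.random.default_rng([seed, 2])
    worst = 0.0
    done = 0
    while done < n_mats:
        Phi = rng.uniform(-0.5, 0.5, (2, 2))
        if np.abs(np.linalg.eigvals(Phi)).max() > 0.9:
            continue
        done += 1
        Seta = cov2x2(rng.uniform(0.5, 2.0), rng.uniform(0.5, 2.0), rng.uniform(-0.6, 0.6))
        S = stationary_residual_cov(Phi, Seta)
        L = np.linalg.cholesky(Seta)
        n_chains = 5000
        T = n_samples // n_chains + 20
        E = np.zeros((n_chains, 2))
        acc = np.zeros((2, 2))
        count = 0
        for t in range(T):
            E = E @ Phi.T + rng.normal(size=(n_chains, 2)) @ L.T
            if t >= 20:
                acc += E.T @ E
                count += n_chains
        emp = acc / count
        rel = np.abs(emp - S).max() / np.abs(S).max()
        worst = max(worst, float(rel))
    return worst


# ---------------------------------------------------------------------------
# simulator moment recovery
# ---------------------------------------------------------------------------

def simulator_moment_check(seed: int, K: int = 2000) -> dict[str, float]:
    """Empirical covariance of K simulated families against the implied
    marginal covariance, in Monte-Carlo standard-error units."""
    params = paper_like_params("continuous")
    comp = ("M", "S1", "S2")
    design = SimDesign(
        K=K, seed=seed, missing_rate=0.0, duration_p_max=0.0, duration_lo=4, duration_hi=4,
        composition_probs={comp: 1.0},
    )
    data = simulate_dataset(params, design)
    dur = {u: 4 for u in undirected_dyads(comp)}
    C, layout = implied_family_cov(params, comp, dur)
    pos = {key: i for i, key in enumerate(layout)}
    X = np.empty((K, len(layout)))
    for k, (fam, g) in enumerate(data.df.groupby("family_id", sort=True)):
        idx = [pos[(DirectedDyad(a, p), t)] for a, p, t in zip(g["actor"], g["partner"], g["snapshot"])]
        X[k, idx] = g["y"].to_numpy()
    emp = np.cov(X.T)
    se = np.sqrt((np.outer(np.diag(C), np.diag(C)) + C**2) / K)
    z = np.abs(emp - C) / se
    return {"frac_within_3se": float((z < 3).mean()), "max_z": float(z.max())}


# ---------------------------------------------------------------------------
# ordered-probit reduction
# ---------------------------------------------------------------------------

def ordered_probit_check(seed: int, n_obs: int = 2000) -> dict[str, float]:
    """No random effects, no dynamics: the fitter must agree with an
    independent maximum-likelihood ordered-probit fit on the same data.

    Returns the worst |posterior mean - MLE| / combined SE over the mean
    and the free thresholds.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    p = default_params("ordinal", roles=("M", "F"))
    eps = 1e-10
    for r in p.Sigma_ap:
        p.Sigma_ap[r] = cov2x2(eps, eps, 0.0)
    for u in p.Sigma_d:
        p.Sigma_d[u] = cov2x2(eps, eps, 0.0)
    p.sigma2_f = 0.0
    for u in p.Sigma_e1:
        p.Sigma_e1[u] = cov2x2(1.0, 1.0, 0.0)
    for d in p.phi1:
        p.phi1[d] = p.phi2[d] = 0.0
        p.mu[d] = 1.2
    p.thresholds = np.array([0.0, 0.9, 1.8])
    design = SimDesign(
        K=n_obs // 2, seed=seed, missing_rate=0.0, duration_p_max=0.0,
        duration_lo=1, duration_hi=1, composition_probs={("M", "F"): 1.0},
    )
    data = simulate_dataset(p, design)
    cfg = FitConfig(
        response_kind="ordinal", dynamics="none", effects="none", n_chains=2,
        n_adapt=200, n_burnin=400, n_iter=1600, thin=2, seed=seed,
    )
    draws = run_fit(data, cfg)

    y = data.df.loc[data.df["observed"], "y"].to_numpy().astype(int)
    m = OrderedModel(y, None, distr="probit")
    res = m.fit(method="bfgs", disp=False)
    th = m.transform_threshold_params(res.params)[1:-1]
    mu_hat, tau2_hat, tau3_hat = -th[0], th[1] - th[0], th[2] - th[0]
    cov = np.asarray(res.cov_params())
    g2, g3 = np.exp(res.params[1]), np.exp(res.params[2])
    se_mu = np.sqrt(cov[0, 0])
    se_t2 = np.sqrt(g2**2 * cov[1, 1])
    J3 = np.array([0.0, g2, g3])
    se_t3 = np.sqrt(J3 @ cov @ J3)

    zs = []
    for nm, mle, se in [
        ("mu[M.F]", mu_hat, se_mu),
        ("mu[F.M]", mu_hat, se_mu),
        ("tau[2]", tau2_hat, se_t2),
        ("tau[3]", tau3_hat, se_t3),
    ]:
        x = draws.pooled(nm)
        zs.append(abs(x.mean() - mle) / np.sqrt(se**2 + x.var()))
    return {"max_z_vs_mle": float(max(zs))}


# ---------------------------------------------------------------------------
# cross-sectional SRM recovery
# ---------------------------------------------------------------------------

def cross_sectional_recovery(seed: int, K: int = 500) -> dict[str, float]:
    """Continuous, T = 1, no dynamics: posterior means of the variance
    components and reciprocity correlations against their generating values,
    in posterior-SD units."""
    p = paper_like_params("continuous")
    for d in p.phi1:
        p.phi1[d] = p.phi2[d] = 0.0
    for u in p.Sigma_e1:  # cross-sectional truth: relationship carries the pair variance
        p.Sigma_e1[u] = cov2x2(1e-8, 1e-8, 0.0)
    design = SimDesign(K=K, seed=seed, missing_rate=0.0, duration_p_max=0.0, duration_lo=1, duration_hi=1)
    data = simulate_dataset(p, design)
    cfg = FitConfig(
        response_kind="continuous", dynamics="none", n_chains=2,
        n_adapt=100, n_burnin=300, n_iter=600, thin=2, seed=seed,
    )
    draws = run_fit(data, cfg)

    checks: dict[str, float] = {"sigma2_f": p.sigma2_f}
    for r in p.roles:
        S = p.Sigma_ap[r]
        checks[f"sigma2_a[{r}]"] = S[0, 0]
        checks[f"sigma2_p[{r}]"] = S[1, 1]
        checks[f"rho_ap[{r}]"] = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])
    for u in p.undirected:
        ij, ji = u.directed
        S = p.Sigma_d[u]
        checks[f"sigma2_d[{ij}]"] = S[0, 0]
        checks[f"sigma2_d[{ji}]"] = S[1, 1]
        checks[f"rho_d[{u}]"] = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])
    zs = {}
    for nm, truth in checks.items():
        x = draws.pooled(nm)
        zs[nm] = abs(x.mean() - truth) / x.std()
    worst = max(zs, key=zs.get)
    return {"max_z": float(zs[worst]), "n_checked": float(len(zs))}


# ---------------------------------------------------------------------------
# dynamic recovery (scaled-down headline)
# ---------------------------------------------------------------------------

def dynamic_recovery(seed: int, n_reps: int = 20, K: int = 100) -> dict[str, float]:
    """Replicated ordinal AR+cross-lag fits: 95% credible-interval coverage
    of the generating phi1, phi2 and innovation correlations, and the
    pooled posterior-mean bias per coefficient class."""
    p = headline_params("ordinal")
    phi1_names = [f"phi1[{d}]" for d in p.phi1]
    phi2_names = [f"phi2[{d}]" for d in p.phi2]
    rho_names = [f"rho_eta[{u}]" for u in undirected_dyads()]
    truth = {**{n: 0.2 for n in phi1_names}, **{n: 0.1 for n in phi2_names}, **{n: 0.2 for n in rho_names}}

    covered = []
    bias1: list[float] = []
    bias2: list[float] = []
    for rep in range(n_reps):
        data = simulate_dataset(p, SimDesign(K=K, seed=seed * 1000 + rep))
        cfg = FitConfig(
            response_kind="ordinal", dynamics="ar_crosslag", n_chains=2,
            n_adapt=150, n_burnin=250, n_iter=400, thin=2, seed=seed * 1000 + rep,
        )
        draws = run_fit(data, cfg)
        for n in phi1_names + phi2_names + rho_names:
            x = draws.pooled(n)
            lo, hi = np.percentile(x, [2.5, 97.5])
            covered.append(lo <= truth[n] <= hi)
            if n in phi1_names:
                bias1.append(x.mean() - truth[n])
            elif n in phi2_names:
                bias2.append(x.mean() - truth[n])
    return {
        "coverage": float(np.mean(covered)),
        "bias_phi1": float(np.mean(bias1)),
        "bias_phi2": float(np.mean(bias2)),
    }


# ---------------------------------------------------------------------------
# post-processing identities
# ---------------------------------------------------------------------------

def postprocess_identities(draws: PosteriorDraws) -> dict[str, float]:
    """Exact per-draw identities of the derived-quantity chains."""
    share_dev = 0.0
    vpc_dev = 0.0
    for us in draws.meta["undirected"]:
        for dyad in UndirectedDyad.parse(us).directed:
            f = draws.pooled("sigma2_f")
            a = draws.pooled(f"sigma2_a[{dyad.actor}]")
            pp = draws.pooled(f"sigma2_p[{dyad.partner}]")
            dd = draws.pooled(f"sigma2_d[{dyad}]")
            total = f + a + pp + dd
            s = f / total + a / total + pp / total + dd / total
            share_dev = max(share_dev, float(np.abs(s - 1.0).max()))
            resid, stat = postprocess._stationary_var_chain(draws, dyad)
            tot5 = total[stat] + resid[stat]
            s5 = (f[stat] + a[stat] + pp[stat] + dd[stat] + resid[stat]) / tot5
            vpc_dev = max(vpc_dev, float(np.abs(s5 - 1.0).max()))
    name = "sigma2_f"
    c = postprocess.contrast(draws, name, name).iloc[0]
    contrast_dev = max(abs(c["mean"]), abs(c["p2.5"]), abs(c["p97.5"]))
    return {
        "share_sum_max_dev": share_dev,
        "vpc_sum_max_dev": vpc_dev,
        "self_contrast_max_abs": float(contrast_dev),
    }
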