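"""Exact model mathematics for the dynamic social relations model.

Two equivalent parameterisations exist for the dynamics.  In the *residual
form* the time-varying deviation of the stacked undirected-dyad pair
``e_t = (e_t,ij, e_t,ji)`` follows a VAR(1),

    e_t = Phi e_{t-1} + eta_t,   Phi = [[phi1_ij, phi2_ij],
                                        [phi2_ji, phi1_ji]],

with the observation ``y_t = theta + e_t`` and time-invariant linear
predictor ``theta_ij = mu_ij + f + a_i + p_j + d_ij``.  In the *response
form* the lag structure is on the responses themselves,

    y_t = theta_tilde + Phi y_{t-1} + eta_t,

with transformed intercept and effects obtained from the originals by
``x_tilde_ij = (1 - phi1_ij) x_ij - phi2_ij x_ji`` (and the scalar family
effect transforming with x_ij = x_ji = f).  The two forms give identical
joint densities; this module implements both, the stationary and
time-indexed residual covariances, the implied marginal covariance of one
family's stacked observations, and the marginal Gaussian log-likelihood used
as a brute-force oracle for the MCMC fitter.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
import scipy.stats

from .data import PanelDataset
from .params import CONTINUOUS, FamilyEffects, SRMParams, linear_predictor
from .roles import DirectedDyad, UndirectedDyad, undirected_dyads


class NonstationaryError(ValueError):
    """Raised when a stationary quantity is requested for spectral radius >= 1."""


def spectral_radius(Phi: np.ndarray) -> float:
    return float(np.abs(np.linalg.eigvals(np.asarray(Phi, float))).max())


def to_tilde(params: SRMParams) -> dict[DirectedDyad, float]:
    """Transformed intercepts mu~_ij = (1 - phi1_ij) mu_ij - phi2_ij mu_ji."""
    out = {}
    for ij in params.mu:
        ji = ij.reverse
        out[ij] = (1.0 - params.phi1[ij]) * params.mu[ij] - params.phi2[ij] * params.mu[ji]
    return out


def tilde_effects(
    params: SRMParams, effects: FamilyEffects
) -> dict[DirectedDyad, tuple[float, float, float, float]]:
    """Transformed (f~, a~, p~, d~) per directed dyad within the composition.

    Their sum plus mu~_ij equals theta~_ij = (1-phi1_ij) theta_ij - phi2_ij theta_ji.
    """
    comp = effects.composition
    out = {}
    for ij in params.mu:
        i, j = ij.actor, ij.partner
        if i not in comp or j not in comp:
            continue
        c1 = 1.0 - params.phi1[ij]
        c2 = params.phi2[ij]
        out[ij] = (
            c1 * effects.f - c2 * effects.f,
            c1 * effects.a[i] - c2 * effects.a[j],
            c1 * effects.p[j] - c2 * effects.p[i],
            c1 * effects.d[ij] - c2 * effects.d[ij.reverse],
        )
    return out


def stationary_residual_cov(Phi: np.ndarray, Sigma_eta: np.ndarray) -> np.ndarray:
    """Solve Sigma_e = Phi Sigma_e Phi' + Sigma_eta (discrete Lyapunov equation)."""
    Phi = np.asarray(Phi, float)
    rho = spectral_radius(Phi)
    if rho >= 1.0:
        raise NonstationaryError(
            f"spectral radius {rho:.4f} >= 1: stationary residual covariance undefined"
        )
    S = scipy.linalg.solve_discrete_lyapunov(Phi, np.asarray(Sigma_eta, float))
    return (S + S.T) / 2.0


def residual_cov_sequence(
    Sigma_e1: np.ndarray, Phi: np.ndarray, Sigma_eta: np.ndarray, T: int
) -> np.ndarray:
    """Time-indexed residual variances V[t-1] = Var(e_t), t = 1..T.

    Var(e_1) = Sigma_e1 and Var(e_t) = Phi Var(e_{t-1}) Phi' + Sigma_eta.
    Lagged covariances follow as Cov(e_t, e_{t-s}) = Phi^s Var(e_{t-s}).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    Phi = np.asarray(Phi, float)
    V = np.empty((T, 2, 2))
    V[0] = np.asarray(Sigma_e1, float)
    for t in range(1, T):
        V[t] = Phi @ V[t - 1] @ Phi.T + np.asarray(Sigma_eta, float)
    return V


def family_layout(
    composition: tuple[str, ...], durations: dict[UndirectedDyad, int]
) -> list[tuple[DirectedDyad, int]]:
    """Canonical observation ordering for one family's stacked vector.

    For each undirected dyad of the composition (sorted), snapshots run
    1..T with the canonical direction first, then the reverse.
    """
    out = []
    for u in undirected_dyads(composition):
        T = durations[u]
        ij, ji = u.directed
        for t in range(1, T + 1):
            out.append((ij, t))
            out.append((ji, t))
    return out


def implied_family_cov(
    params: SRMParams,
    composition: tuple[str, ...],
    durations: dict[UndirectedDyad, int],
) -> tuple[np.ndarray, list[tuple[DirectedDyad, int]]]:
    """Marginal covariance of one family's stacked directed observations.

    Assembles the cross-classified random-effect covariances (family, actor,
    partner, actor-partner, relationship) plus the within-undirected-dyad
    residual covariance sequence.  Residuals are independent across
    undirected dyads and families.  Returns (cov, layout).
    """
    layout = family_layout(composition, durations)
    n = len(layout)
    C = np.zeros((n, n))

    sf2 = params.sigma2_f
    for r1, (d1, t1) in enumerate(layout):
        i, j = d1.actor, d1.partner
        for r2 in range(r1, n):
            d2, t2 = layout[r2]
            i2, j2 = d2.actor, d2.partner
            c = sf2
            if i == i2:
                c += params.Sigma_ap[i][0, 0]
            if j == j2:
                c += params.Sigma_ap[j][1, 1]
            if i == j2:  # actor effect of i with partner effect of i
                c += params.Sigma_ap[i][0, 1]
            if j == i2:
                c += params.Sigma_ap[j][0, 1]
            if (i, j) == (i2, j2):
                u = d1.undirected
                k = 0 if d1 == u.directed[0] else 1
                c += params.Sigma_d[u][k, k]
            elif (i, j) == (j2, i2):
                u = d1.undirected
                c += params.Sigma_d[u][0, 1]
            C[r1, r2] = C[r2, r1] = c

    # residual covariances within each undirected dyad block
    offset = 0
    for u in undirected_dyads(composition):
        T = durations[u]
        Phi = params.dynamics_matrix(u)
        V = residual_cov_sequence(params.Sigma_e1[u], Phi, params.Sigma_eta[u], T)
        # block rows ordered (t, direction): index = offset + 2*(t-1) + dir
        for t in range(1, T + 1):
            for s in range(1, t + 1):
                same_t = s == t
                blk = V[s - 1] if same_t else np.linalg.matrix_power(Phi, t - s) @ V[s - 1]
                for a in range(2):
                    for b in range(2):
                        r1 = offset + 2 * (t - 1) + a
                        r2 = offset + 2 * (s - 1) + b
                        C[r1, r2] += blk[a, b]
                        if not same_t:  # same-snapshot block covers (a,b) and (b,a) itself
                            C[r2, r1] += blk[a, b]
        offset += 2 * T
    return C, layout


def family_mean(
    params: SRMParams, layout: list[tuple[DirectedDyad, int]]
) -> np.ndarray:
    """Marginal mean (mu + optional trend) along a family layout."""
    return np.array(
        [params.mu[d] + params.beta1_for(d) * t for d, t in layout]
    )


def family_table(
    data: PanelDataset, family_id: str
) -> tuple[tuple[str, ...], dict[UndirectedDyad, int], np.ndarray, np.ndarray]:
    """One family's stacked response vector in canonical layout.

    Returns (composition, durations, y, observed_mask); y is NaN where
    unobserved.
    """
    sub = data.df[data.df["family_id"] == str(family_id)]
    if sub.empty:
        raise KeyError(f"no records for family {family_id!r}")
    comp = data.composition(family_id)
    durations: dict[UndirectedDyad, int] = {}
    for (a, p), g in sub.groupby(["actor", "partner"]):
        u = UndirectedDyad.of(a, p)
        T = int(g["snapshot"].max())
        if durations.setdefault(u, T) != T:
            raise ValueError(f"directions of dyad {u} have different durations")
    layout = family_layout(comp, durations)
    idx = {(DirectedDyad(a, p), int(t)): (yv if o else np.nan)
           for a, p, t, yv, o in sub[["actor", "partner", "snapshot", "y", "observed"]].itertuples(index=False)}
    y = np.array([idx.get(key, np.nan) for key in layout])
    obs = np.isfinite(y)
    return comp, durations, y, obs


def continuous_loglik(params: SRMParams, data: PanelDataset, family_id: str) -> float:
    """Marginal Gaussian log-density of one family's observations.

    Brute-force oracle: the random effects are integrated analytically via
    :func:`implied_family_cov`.  Continuous responses only; requires the
    family to be fully observed.
    """
    if params.response_kind != CONTINUOUS:
        raise ValueError("continuous_loglik requires a continuous-response model")
    comp, durations, y, obs = family_table(data, family_id)
    if not obs.all():
        raise ValueError("continuous_loglik requires fully observed family data")
    C, layout = implied_family_cov(params, comp, durations)
    m = family_mean(params, layout)
    try:
        return float(scipy.stats.multivariate_normal.logpdf(y, mean=m, cov=C))
    except np.linalg.LinAlgError as err:  # pragma: no cover - degenerate params
        raise np.linalg.LinAlgError(
            f"singular implied covariance for family {family_id}: {err}"
        ) from err


# ---------------------------------------------------------------------------
# conditional (given effects) log-densities in both parameterisations
# ---------------------------------------------------------------------------

def _norm2_logpdf(x: np.ndarray, S: np.ndarray) -> float:
    return float(scipy.stats.multivariate_normal.logpdf(x, mean=np.zeros(2), cov=S))


def loglik_residual_form(
    params: SRMParams,
    effects: FamilyEffects,
    y: dict[UndirectedDyad, np.ndarray],
) -> float:
    """log p(y | effects) via the residual VAR(1) form.

    ``y[u]`` is a (T, 2) array of responses for undirected dyad ``u`` with
    columns in canonical direction order.
    """
    total = 0.0
    for u, arr in y.items():
        ij, ji = u.directed
        theta = np.array(
            [linear_predictor(params, effects, ij), linear_predictor(params, effects, ji)]
        )
        if params.beta1 is not None:
            raise NotImplementedError("trend handled in the sampler, not this oracle")
        e = np.asarray(arr, float) - theta
        Phi = params.dynamics_matrix(u)
        total += _norm2_logpdf(e[0], params.Sigma_e1[u])
        for t in range(1, len(e)):
            total += _norm2_logpdf(e[t] - Phi @ e[t - 1], params.Sigma_eta[u])
    return total


def loglik_response_form(
    params: SRMParams,
    effects: FamilyEffects,
    y: dict[UndirectedDyad, np.ndarray],
) -> float:
    """log p(y | effects) via the autoregressive cross-lagged response form.

    The t > 1 conditional mean is theta~ + Phi y_{t-1} with theta~ assembled
    from the transformed intercept and the four transformed effects; the
    first snapshot keeps its marginal N(theta, Sigma_e1) density.
    """
    mu_t = to_tilde(params)
    eff_t = tilde_effects(params, effects)
    total = 0.0
    for u, arr in y.items():
        arr = np.asarray(arr, float)
        ij, ji = u.directed
        theta = np.array(
            [linear_predictor(params, effects, ij), linear_predictor(params, effects, ji)]
        )
        theta_tilde = np.array(
            [mu_t[ij] + sum(eff_t[ij]), mu_t[ji] + sum(eff_t[ji])]
        )
        Phi = params.dynamics_matrix(u)
        total += _norm2_logpdf(arr[0] - theta, params.Sigma_e1[u])
        for t in range(1, len(arr)):
            total += _norm2_logpdf(
                arr[t] - theta_tilde - Phi @ arr[t - 1], params.Sigma_eta[u]
            )
    return total
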