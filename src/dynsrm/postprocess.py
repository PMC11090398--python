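"""Derived quantities computed from parameter chains.

Everything here is a function of the stored draws, never of the data:
posterior summaries, proportions of the time-invariant variance (family /
actor / partner / relationship), extended variance partitioning
coefficients that add the stationary temporal-residual variance, and
difference ("contrast") chains between any two parameters.  Significance
follows the usual convention for Bayesian tables of this kind: the 95%
equal-tailed credible interval excludes 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .draws import PosteriorDraws
from .roles import DirectedDyad


def _summary_row(x: np.ndarray) -> dict:
    lo, hi = np.percentile(x, [2.5, 97.5])
    return {
        "mean": float(np.mean(x)),
        "p2.5": float(lo),
        "p97.5": float(hi),
        "significant": bool(lo > 0 or hi < 0),
    }


def summarise(draws: PosteriorDraws, names: list[str] | None = None) -> pd.DataFrame:
    """Posterior mean, 2.5/97.5 percentiles and significance per parameter."""
    if draws.n_stored == 0:
        raise ValueError("no stored draws to summarise")
    names = names or draws.names
    return pd.DataFrame({n: _summary_row(draws.pooled(n)) for n in names}).T


def _component_chains(draws: PosteriorDraws, dyad: DirectedDyad):
    f = draws.pooled("sigma2_f")
    a = draws.pooled(f"sigma2_a[{dyad.actor}]")
    p = draws.pooled(f"sigma2_p[{dyad.partner}]")
    d = draws.pooled(f"sigma2_d[{dyad}]")
    return f, a, p, d


def time_invariant_shares(draws: PosteriorDraws, dyad: DirectedDyad | str) -> pd.DataFrame:
    """Proportions of the time-invariant variance for one directed dyad type.

    Per draw, each share is the component variance over the sum of the
    family variance, the actor variance of the dyad's actor role, the
    partner variance of its partner role, and the dyad's relationship
    variance; the four shares sum to 1 exactly in every draw.
    """
    if isinstance(dyad, str):
        dyad = DirectedDyad.parse(dyad)
    f, a, p, d = _component_chains(draws, dyad)
    total = f + a + p + d
    shares = {"family": f / total, "actor": a / total, "partner": p / total, "relationship": d / total}
    return pd.DataFrame({k: _summary_row(v) for k, v in shares.items()}).T


def share_table(draws: PosteriorDraws) -> pd.DataFrame:
    """Time-invariant variance shares for every directed dyad type."""
    rows = []
    for us in draws.meta["undirected"]:
        from .roles import UndirectedDyad

        for dyad in UndirectedDyad.parse(us).directed:
            t = time_invariant_shares(draws, dyad)
            for comp, row in t.iterrows():
                rows.append({"dyad": str(dyad), "component": comp, **row})
    return pd.DataFrame(rows)


def _stationary_var_chain(
    draws: PosteriorDraws, dyad: DirectedDyad
) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw stationary residual variance for one direction.

    Returns (variance, stationary_mask); nonstationary draws get NaN.
    Solves vec(S) = (I4 - Phi (x) Phi)^{-1} vec(Sigma_eta) in batch.
    """
    u = dyad.undirected
    ij, ji = u.directed
    canonical = dyad == ij
    if f"sigma2_eta[{ij}]" not in draws:
        raise ValueError(
            "cross-sectional fit has no temporal residual: extended VPCs undefined"
        )
    if f"phi1[{ij}]" not in draws:  # dynamics = none
        zero = np.zeros(draws.n_chains * draws.n_stored)
        p1a = p1b = p2a = p2b = zero
    else:
        p1a = draws.pooled(f"phi1[{ij}]")
        p1b = draws.pooled(f"phi1[{ji}]")
        p2a = draws.pooled(f"phi2[{ij}]") if f"phi2[{ij}]" in draws else np.zeros_like(p1a)
        p2b = draws.pooled(f"phi2[{ji}]") if f"phi2[{ji}]" in draws else np.zeros_like(p1a)
    n = len(p1a)
    Phi = np.empty((n, 2, 2))
    Phi[:, 0, 0], Phi[:, 0, 1] = p1a, p2a
    Phi[:, 1, 0], Phi[:, 1, 1] = p2b, p1b
    v0 = draws.pooled(f"sigma2_eta[{ij}]")
    v1 = draws.pooled(f"sigma2_eta[{ji}]")
    r = draws.pooled(f"rho_eta[{u}]")
    c = r * np.sqrt(v0 * v1)
    Seta = np.empty((n, 2, 2))
    Seta[:, 0, 0], Seta[:, 1, 1] = v0, v1
    Seta[:, 0, 1] = Seta[:, 1, 0] = c
    ev = np.linalg.eigvals(Phi)
    stat = np.abs(ev).max(axis=1) < 1.0
    A = np.eye(4)[None] - np.einsum("nij,nkl->nikjl", Phi, Phi).reshape(n, 4, 4)
    vecS = np.full((n, 4), np.nan)
    if stat.any():
        vecS[stat] = np.linalg.solve(A[stat], Seta[stat].reshape(-1, 4, 1))[:, :, 0]
    var = vecS[:, 0] if canonical else vecS[:, 3]
    return var, stat


def vpc_total(draws: PosteriorDraws, dyad: DirectedDyad | str) -> tuple[pd.DataFrame, int]:
    """Extended VPCs: proportions of the *total* unexplained variance.

    Adds the stationary temporal-residual variance implied by each draw's
    (Phi, Sigma_eta) to the four time-invariant components; the five shares
    sum to 1 per included draw.  Draws with spectral radius >= 1 have no
    stationary variance and are excluded; their count is returned.
    """
    if isinstance(dyad, str):
        dyad = DirectedDyad.parse(dyad)
    f, a, p, d = _component_chains(draws, dyad)
    resid, stat = _stationary_var_chain(draws, dyad)
    n_excluded = int((~stat).sum())
    if not stat.any():
        raise ValueError("all draws are nonstationary: extended VPCs undefined")
    f, a, p, d, resid = (x[stat] for x in (f, a, p, d, resid))
    total = f + a + p + d + resid
    shares = {
        "family": f / total,
        "actor": a / total,
        "partner": p / total,
        "relationship": d / total,
        "residual": resid / total,
    }
    table = pd.DataFrame({k: _summary_row(v) for k, v in shares.items()}).T
    return table, n_excluded


def contrast(
    draws: PosteriorDraws, name_a: str, name_b: str, absolute: bool = False
) -> pd.DataFrame:
    """Summary of the per-draw difference a - b (optionally |a| - |b|)."""
    a = draws.pooled(name_a)
    b = draws.pooled(name_b)
    if absolute:
        a, b = np.abs(a), np.abs(b)
    label = f"|{name_a}| - |{name_b}|" if absolute else f"{name_a} - {name_b}"
    return pd.DataFrame({label: _summary_row(a - b)}).T
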