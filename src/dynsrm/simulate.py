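"""Synthetic clustered round-robin panel generator.

Emulates the design of intensive family-interaction studies: ~200 families
of 3-4 members with roles {M, F, S1, S2}, every within-family pair observed
in both directions over a variable number of snapshots (support 1..15, mean
9.7), a 4-category ordinal response obtained by thresholding a latent
continuous trajectory with AR(1) + cross-lagged residual dynamics, and ~1%
missingness injected at the undirected-dyad-snapshot level so that both
directions of a pair are always missing together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import COLUMNS, PanelDataset
from .params import CONTINUOUS, ORDINAL, FamilyEffects, SRMParams, cov2x2, require_valid
from .reparam import stationary_residual_cov
from .roles import DirectedDyad, UndirectedDyad, check_composition, undirected_dyads

FULL = ("M", "F", "S1", "S2")

#: family composition mix of the emulated study: 223 families, 65 without a
#: participating father, 2 with one child missing.
DEFAULT_COMPOSITION_PROBS: dict[tuple[str, ...], float] = {
    ("M", "F", "S1", "S2"): 156 / 223,
    ("M", "S1", "S2"): 65 / 223,
    ("M", "F", "S1"): 1 / 223,
    ("M", "F", "S2"): 1 / 223,
}


@dataclass
class SimDesign:
    """Study-design knobs of the simulator.

    Durations are drawn per undirected dyad (shared by both directions) as:
    the maximum ``duration_max`` with probability ``duration_p_max`` (dyads
    that use the full observation window), otherwise uniform on
    ``duration_lo..duration_hi``.  The defaults give mean 9.7 snapshots.
    """

    K: int = 200
    composition_probs: dict[tuple[str, ...], float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION_PROBS)
    )
    duration_p_max: float = 44 / 150  # mean = p*15 + (1-p)*7.5 = 9.7
    duration_max: int = 15
    duration_lo: int = 3
    duration_hi: int = 12
    missing_rate: float = 0.01
    seed: int = 0
    start_mode: str = "free_first"  # or "stationary"

    def __post_init__(self) -> None:
        total = sum(self.composition_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"composition probabilities sum to {total}, not 1")
        for comp in self.composition_probs:
            check_composition(comp)
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.duration_lo < 1 or self.duration_hi < self.duration_lo:
            raise ValueError("invalid duration range")
        if self.start_mode not in ("free_first", "stationary"):
            raise ValueError(f"unknown start_mode {self.start_mode!r}")

    def mean_duration(self) -> float:
        p = self.duration_p_max
        return p * self.duration_max + (1 - p) * (self.duration_lo + self.duration_hi) / 2


def draw_effects(
    params: SRMParams, composition: tuple[str, ...], rng: np.random.Generator
) -> FamilyEffects:
    """Draw one family's random effects from their generative distributions."""
    comp = check_composition(composition)
    f = rng.normal(0.0, np.sqrt(params.sigma2_f))
    a: dict[str, float] = {}
    p: dict[str, float] = {}
    for r in comp:
        S = np.asarray(params.Sigma_ap[r], float)
        if np.linalg.eigvalsh(S).min() < -1e-12:
            raise ValueError(f"Sigma_ap[{r}] is not positive semi-definite")
        ap = rng.multivariate_normal([0.0, 0.0], S, method="cholesky") if _pd(S) else _degenerate_mvn(S, rng)
        a[r], p[r] = float(ap[0]), float(ap[1])
    d: dict[DirectedDyad, float] = {}
    for u in undirected_dyads(comp):
        S = np.asarray(params.Sigma_d[u], float)
        dd = rng.multivariate_normal([0.0, 0.0], S, method="cholesky") if _pd(S) else _degenerate_mvn(S, rng)
        ij, ji = u.directed
        d[ij], d[ji] = float(dd[0]), float(dd[1])
    return FamilyEffects(f=float(f), a=a, p=p, d=d)


def _pd(S: np.ndarray) -> bool:
    return bool(np.linalg.eigvalsh(S).min() > 1e-12)


def _degenerate_mvn(S: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from a possibly rank-deficient bivariate normal (eigen route)."""
    w, V = np.linalg.eigh(S)
    w = np.clip(w, 0.0, None)
    return V @ (np.sqrt(w) * rng.normal(size=2))


def simulate_family(
    params: SRMParams,
    effects: FamilyEffects,
    durations: dict[UndirectedDyad, int],
    rng: np.random.Generator,
    start_mode: str = "free_first",
) -> dict[UndirectedDyad, np.ndarray]:
    """Latent continuous trajectories y*_t for one family.

    Returns, per undirected dyad, a (T, 2) array with columns in canonical
    direction order.  The first snapshot's residual pair is drawn from
    Sigma_e1 (``free_first``) or from the stationary VAR(1) covariance
    (``stationary``); later residuals follow e_t = Phi e_{t-1} + eta_t.
    """
    comp = effects.composition
    out: dict[UndirectedDyad, np.ndarray] = {}
    for u in undirected_dyads(comp):
        T = int(durations[u])
        ij, ji = u.directed
        Phi = params.dynamics_matrix(u)
        S1 = (
            stationary_residual_cov(Phi, params.Sigma_eta[u])
            if start_mode == "stationary"
            else np.asarray(params.Sigma_e1[u], float)
        )
        e = np.empty((T, 2))
        e[0] = np.linalg.cholesky(S1) @ rng.normal(size=2) if _pd(S1) else _degenerate_mvn(S1, rng)
        if T > 1:
            Se = np.asarray(params.Sigma_eta[u], float)
            L = np.linalg.cholesky(Se) if _pd(Se) else None
            eta = rng.normal(size=(T - 1, 2))
            for t in range(1, T):
                shock = L @ eta[t - 1] if L is not None else _degenerate_mvn(Se, rng)
                e[t] = Phi @ e[t - 1] + shock
        theta0 = np.array(
            [
                params.mu[ij] + effects.f + effects.a[ij.actor] + effects.p[ij.partner] + effects.d[ij],
                params.mu[ji] + effects.f + effects.a[ji.actor] + effects.p[ji.partner] + effects.d[ji],
            ]
        )
        y = theta0[None, :] + e
        if params.beta1 is not None:
            t_grid = np.arange(1, T + 1)[:, None]
            slopes = np.array([params.beta1_for(ij), params.beta1_for(ji)])
            y = y + slopes[None, :] * t_grid
        out[u] = y
    return out


def ordinalize(y_star: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Threshold latent values into categories 1..C (half-open intervals).

    Category c <=> y* in [tau_{c-1}, tau_c), with tau_0 = -inf, tau_C = +inf.
    """
    tau = np.asarray(thresholds, float)
    if np.any(np.diff(tau) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    return np.searchsorted(tau, np.asarray(y_star, float), side="right") + 1


def _draw_duration(design: SimDesign, rng: np.random.Generator) -> int:
    if rng.random() < design.duration_p_max:
        return design.duration_max
    return int(rng.integers(design.duration_lo, design.duration_hi + 1))


def simulate_dataset(params: SRMParams, design: SimDesign) -> PanelDataset:
    """Simulate a full panel of K families; reproducible from design.seed."""
    require_valid(params)
    rng = np.random.default_rng(design.seed)
    comps = list(design.composition_probs)
    probs = np.array([design.composition_probs[c] for c in comps])
    ordinal = params.response_kind == ORDINAL

    rows: list[tuple] = []
    width = max(4, len(str(design.K)))
    for k in range(design.K):
        fam = f"f{k + 1:0{width}d}"
        comp = comps[rng.choice(len(comps), p=probs)]
        durations = {u: _draw_duration(design, rng) for u in undirected_dyads(comp)}
        effects = draw_effects(params, comp, rng)
        traj = simulate_family(params, effects, durations, rng, design.start_mode)
        for u in undirected_dyads(comp):
            y = traj[u]
            if ordinal:
                y = ordinalize(y, params.thresholds).astype(float)
            ij, ji = u.directed
            T = durations[u]
            miss = rng.random(T) < design.missing_rate
            for t in range(T):
                for direction, dd in ((0, ij), (1, ji)):
                    obs = not miss[t]
                    rows.append(
                        (fam, dd.actor, dd.partner, t + 1, y[t, direction] if obs else np.nan, obs)
                    )
    df = pd.DataFrame(rows, columns=COLUMNS)
    return PanelDataset(
        df,
        response_kind=params.response_kind,
        n_categories=params.n_categories,
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_PHI1 = {
    "M.F": 0.068, "F.M": 0.202, "M.S1": 0.095, "S1.M": 0.224,
    "M.S2": 0.102, "S2.M": 0.237, "F.S1": 0.085, "S1.F": 0.208,
    "F.S2": 0.108, "S2.F": 0.120, "S1.S2": 0.143, "S2.S1": 0.164,
}
_PHI2 = {
    "M.F": -0.024, "F.M": 0.007, "M.S1": -0.054, "S1.M": -0.009,
    "M.S2": 0.056, "S2.M": 0.045, "F.S1": 0.016, "S1.F": 0.001,
    "F.S2": -0.016, "S2.F": 0.002, "S1.S2": 0.099, "S2.S1": 0.028,
}
_RHO_ETA = {
    "M:F": -0.021, "M:S1": 0.089, "M:S2": 0.104,
    "F:S1": 0.184, "F:S2": 0.108, "S1:S2": 0.326,
}
# observed per-dyad means of the motivating study's 4-point (2..5) scale,
# recoded 1..4; mapped to the latent scale via mu = 2 (mean - 2.5) given
# threshold gaps of 2.
_RAW_MEAN = {
    "M.F": 3.67, "F.M": 3.55, "M.S1": 3.79, "S1.M": 3.11,
    "M.S2": 3.78, "S2.M": 3.31, "F.S1": 3.89, "S1.F": 3.30,
    "F.S2": 3.72, "S2.F": 3.32, "S1.S2": 3.26, "S2.S1": 3.37,
}
_SIGMA2_A = {"M": 0.18, "F": 0.28, "S1": 0.16, "S2": 0.15}
_SIGMA2_P = {"M": 0.10, "F": 0.09, "S1": 0.09, "S2": 0.08}
_RHO_AP = {"M": 0.05, "F": 0.10, "S1": 0.10, "S2": 0.36}
_SIGMA2_D = {
    "M.F": 0.15, "F.M": 0.13, "M.S1": 0.30, "S1.M": 0.30,
    "M.S2": 0.28, "S2.M": 0.28, "F.S1": 0.26, "S1.F": 0.18,
    "F.S2": 0.22, "S2.F": 0.18, "S1.S2": 0.15, "S2.S1": 0.22,
}
_RHO_D = {"M:F": 0.20, "M:S1": 0.50, "M:S2": 0.25, "F:S1": 0.20, "F:S2": 0.15, "S1:S2": 0.20}


def paper_like_params(response_kind: str = ORDINAL) -> SRMParams:
    """Realistic preset: dynamics and correlations at the magnitudes reported
    for family conflict-discussion constructiveness; variance components with
    relationship shares dominating family shares.

    A preset, not ground truth; recovery tests use it as the generating truth.
    """
    ordinal = response_kind == ORDINAL
    dd = {DirectedDyad.parse(k): v for k, v in _PHI1.items()}
    mu = (
        {DirectedDyad.parse(k): 2.0 * (v - 2.5) for k, v in _RAW_MEAN.items()}
        if ordinal
        else {DirectedDyad.parse(k): v for k, v in _RAW_MEAN.items()}
    )
    rv = 1.0 if ordinal else 0.8
    return SRMParams(
        mu=mu,
        phi1=dd,
        phi2={DirectedDyad.parse(k): v for k, v in _PHI2.items()},
        sigma2_f=0.04,
        Sigma_ap={r: cov2x2(_SIGMA2_A[r], _SIGMA2_P[r], _RHO_AP[r]) for r in FULL},
        Sigma_d={
            u: cov2x2(_SIGMA2_D[str(u.directed[0])], _SIGMA2_D[str(u.directed[1])], _RHO_D[str(u)])
            for u in undirected_dyads(FULL)
        },
        Sigma_eta={u: cov2x2(rv, rv, _RHO_ETA[str(u)]) for u in undirected_dyads(FULL)},
        Sigma_e1={u: cov2x2(1.0 if ordinal else 0.9, 1.0 if ordinal else 0.9, _RHO_ETA[str(u)]) for u in undirected_dyads(FULL)},
        thresholds=np.array([0.0, 2.0, 4.0]) if ordinal else None,
        response_kind=response_kind,
    )


def headline_params(response_kind: str = ORDINAL) -> SRMParams:
    """paper_like_params with uniform mid-range dynamics (phi1 = 0.2,
    phi2 = 0.1, innovation correlations 0.2) for recovery benchmarking."""
    p = paper_like_params(response_kind)
    for d in p.phi1:
        p.phi1[d] = 0.2
        p.phi2[d] = 0.1
    rv = 1.0 if response_kind == ORDINAL else 0.8
    for u in p.Sigma_eta:
        p.Sigma_eta[u] = cov2x2(rv, rv, 0.2)
        e1v = 1.0 if response_kind == ORDINAL else 0.9
        p.Sigma_e1[u] = cov2x2(e1v, e1v, 0.2)
    return p


PRESETS = {
    "paper-like": paper_like_params,
    "headline": headline_params,
}
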