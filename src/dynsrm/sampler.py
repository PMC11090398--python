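"""Blocked Gibbs sampler for the dynamic social relations model.

The sampler targets the joint posterior of the unconditional parameters
(dyad-type means, AR and cross-lag coefficients, family/actor/partner/
relationship covariances, innovation and first-snapshot covariances,
thresholds), the realised random effects, and — for ordinal responses or
missing records — the latent continuous responses.

Blocks
------
* latent responses: single-site draws from Gaussian full conditionals
  truncated to the observed category's interval, scheduled in four
  conditionally independent colours (snapshot parity x direction) so each
  colour is one vectorised numpy operation;
* linear predictor components (means, family, actor/partner, relationship
  effects): conjugate Gaussian draws from bivariate sufficient statistics
  accumulated per undirected-dyad instance;
* AR/cross-lag matrix Phi per undirected dyad type: conjugate Gaussian
  (a seemingly-unrelated-regressions update with known error covariance);
* variance components: conjugate Wishart (2x2 blocks) and Gamma (family
  precision) updates;
* identified correlations (ordinal innovation and first-snapshot blocks):
  random-walk Metropolis on the Fisher-z (atanh) scale, step size adapted
  during the adaptation phase;
* thresholds: conditional draws on the feasible interval implied by the
  latents; with Exp(1) gap priors the interior conditionals are uniform and
  the top threshold's is a truncated exponential.

Priors follow the usual weakly informative choices for this model class:
N(0, precision 0.001) on fixed-part coefficients, Exp(1) on threshold gaps,
Wishart(identity, 2) on 2x2 precision blocks, Gamma(0.001, 0.001) on the
family precision, and a Normal on the atanh-correlation parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.special as sps
import scipy.stats

from .data import PanelDataset
from .params import CONTINUOUS, ORDINAL, FamilyEffects, SRMParams, cov2x2
from .roles import DirectedDyad, UndirectedDyad, undirected_dyads

I2 = np.eye(2)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class Priors:
    fixed_mean: float = 0.0
    fixed_prec: float = 0.001
    gap_rate: float = 1.0
    wishart_df: float = 2.0
    family_shape: float = 0.001
    family_rate: float = 0.001
    #: precision of the Normal prior on atanh-transformed correlations;
    #: the strict mode uses variance 0.001 (precision 1000) instead.
    corr_z_prec: float = 0.001

    def validate(self) -> None:
        for name in ("fixed_prec", "gap_rate", "wishart_df", "family_shape", "family_rate", "corr_z_prec"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior hyperparameter {name} must be > 0")


@dataclass
class FitConfig:
    """Response type, dynamics variant, chain settings and priors.

    ``n_iter`` is the number of monitored iterations per chain; every
    ``thin``-th draw is stored.  Defaults are desk-scale; the long-run
    configuration used for serious applications is available as
    :func:`longrun_chain_config`.
    """

    response_kind: str = ORDINAL
    dynamics: str = "ar_crosslag"  # none | ar | ar_crosslag
    trend: bool = False
    trend_scope: str = "undirected"  # or "directed"
    effects: str = "full"  # "none" reduces to an ordered-probit regression
    n_chains: int = 4
    n_adapt: int = 500
    n_burnin: int = 1000
    n_iter: int = 2500
    thin: int = 5
    seed: int = 0
    priors: Priors = field(default_factory=Priors)
    strict_correlation_prior: bool = False
    start_jitter: float = 0.1

    def __post_init__(self) -> None:
        if self.response_kind not in (CONTINUOUS, ORDINAL):
            raise ValueError(f"unknown response_kind {self.response_kind!r}")
        if self.dynamics not in ("none", "ar", "ar_crosslag"):
            raise ValueError(f"unknown dynamics {self.dynamics!r}")
        if self.effects not in ("full", "none"):
            raise ValueError(f"unknown effects mode {self.effects!r}")
        if self.trend_scope not in ("undirected", "directed"):
            raise ValueError(f"unknown trend_scope {self.trend_scope!r}")
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 (PSRF needs multiple chains)")
        if self.thin < 1 or self.n_iter < self.thin:
            raise ValueError("need n_iter >= thin >= 1")
        self.priors.validate()

    @property
    def corr_z_prec(self) -> float:
        return 1000.0 if self.strict_correlation_prior else self.priors.corr_z_prec

    @property
    def n_stored(self) -> int:
        return self.n_iter // self.thin


def longrun_chain_config(**kw) -> FitConfig:
    """The long-run chain settings used in serious applications of this
    model family: 5 chains, 1,000 adaptation, 200,000 burn-in, 50,000
    monitored iterations storing every 10th."""
    kw.setdefault("n_chains", 5)
    kw.setdefault("n_adapt", 1000)
    kw.setdefault("n_burnin", 200_000)
    kw.setdefault("n_iter", 50_000)
    kw.setdefault("thin", 10)
    return FitConfig(**kw)


# ---------------------------------------------------------------------------
# small numeric helpers
# ---------------------------------------------------------------------------

def truncnorm_draw(
    mean: np.ndarray,
    sd: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised truncated-normal draws on [lo, hi) via inverse CDF.

    Degenerate cases (zero width or vanishing probability mass) return the
    conditional mean clipped to the interval.
    """
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    a = sps.ndtr((lo - mean) / sd)
    b = sps.ndtr((hi - mean) / sd)
    width = b - a
    u = rng.uniform(size=mean.shape)
    safe = width > 1e-14
    q = np.where(safe, a + u * np.clip(width, 1e-300, None), 0.5)
    x = mean + sd * sps.ndtri(np.clip(q, 1e-16, 1 - 1e-16))
    fallback = np.clip(mean, lo, np.nextafter(hi, -np.inf))
    return np.where(safe, x, fallback)


def _inv2(S: np.ndarray) -> np.ndarray:
    det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
    return np.array([[S[1, 1], -S[0, 1]], [-S[1, 0], S[0, 0]]]) / det


def _draw_mvn2_batch(P: np.ndarray, h: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw x ~ N(P^{-1} h, P^{-1}) for stacked 2x2 precisions P (n,2,2)."""
    det = P[:, 0, 0] * P[:, 1, 1] - P[:, 0, 1] * P[:, 1, 0]
    Cov = np.empty_like(P)
    Cov[:, 0, 0] = P[:, 1, 1] / det
    Cov[:, 1, 1] = P[:, 0, 0] / det
    Cov[:, 0, 1] = Cov[:, 1, 0] = -P[:, 0, 1] / det
    mean = np.einsum("nij,nj->ni", Cov, h)
    L = np.linalg.cholesky(Cov)
    z = rng.normal(size=mean.shape)
    return mean + np.einsum("nij,nj->ni", L, z)


def _draw_mvn(P: np.ndarray, h: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from N(P^{-1} h, P^{-1}) for a single k x k precision."""
    L = np.linalg.cholesky(P)
    mean = np.linalg.solve(P, h)
    z = rng.normal(size=len(h))
    return mean + np.linalg.solve(L.T, z)


def _bvn_corr_suffstats_loglik(rho: float, S00: float, S11: float, S01: float, n: int) -> float:
    """Log-likelihood of n standard-bivariate-normal pairs with correlation rho."""
    om = 1.0 - rho * rho
    return -0.5 * n * np.log(om) - 0.5 * (S00 - 2.0 * rho * S01 + S11) / om


def _wishart2_rvs(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One 2x2 Wishart draw via the Bartlett decomposition."""
    L = np.linalg.cholesky(scale)
    A = np.zeros((2, 2))
    A[0, 0] = np.sqrt(rng.chisquare(df))
    A[1, 1] = np.sqrt(rng.chisquare(df - 1.0))
    A[1, 0] = rng.normal()
    LA = L @ A
    return LA @ LA.T


_LOG2PI = float(np.log(2.0 * np.pi))


def _mvn2_logpdf_sum(X: np.ndarray, S: np.ndarray) -> float:
    """Sum of bivariate normal log-densities N(x; 0, S) over rows of X."""
    n = len(X)
    if n == 0:
        return 0.0
    iS = _inv2(S)
    logdet = np.log(S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0])
    quad = np.einsum("ni,ij,nj->", X, iS, X)
    return -0.5 * (n * (2.0 * _LOG2PI + logdet) + quad)


# ---------------------------------------------------------------------------
# data plan: flat index arrays derived once from the panel
# ---------------------------------------------------------------------------

class _Plan:
    def __init__(self, data: PanelDataset, config: FitConfig):
        data.validate()
        if not data.satisfies_pair_rule():
            raise ValueError(
                "dataset violates the both-or-neither rule; run apply_pair_deletion first"
            )
        df = data.df
        if df.empty:
            raise ValueError("empty dataset")
        ordinal = config.response_kind == ORDINAL
        if ordinal:
            if data.response_kind != ORDINAL:
                raise ValueError("config asks for an ordinal fit on non-ordinal data")
            self.C = int(data.n_categories)
            n_seen = df.loc[df["observed"], "y"].nunique()
            if n_seen < 2:
                raise ValueError("ordinal fit requires at least two observed categories")

        self.families = data.families
        fam_idx = {f: i for i, f in enumerate(self.families)}
        self.K = len(self.families)

        roles_present = sorted(
            set(df["actor"]) | set(df["partner"]),
            key=["M", "F", "S1", "S2"].index,
        )
        self.roles = roles_present
        self.utypes: list[UndirectedDyad] = undirected_dyads(roles_present)
        u_idx = {u: i for i, u in enumerate(self.utypes)}
        self.U = len(self.utypes)
        self.directed: list[DirectedDyad] = [d for u in self.utypes for d in u.directed]

        # individuals = (family, role) pairs that actually appear
        pairs = sorted(
            {(f, r) for f, r in zip(df["family_id"], df["actor"])}
            | {(f, r) for f, r in zip(df["family_id"], df["partner"])}
        )
        ind_idx = {p: i for i, p in enumerate(pairs)}
        self.M = len(pairs)
        self.ind_family = np.array([fam_idx[f] for f, _ in pairs])
        self.ind_role = np.array([roles_present.index(r) for _, r in pairs])

        # dyad instances: one per (family, undirected dyad)
        inst_keys = sorted(
            {(f, str(UndirectedDyad.of(a, p))) for f, a, p in zip(df["family_id"], df["actor"], df["partner"])}
        )
        self.D = len(inst_keys)
        inst_idx = {k: i for i, k in enumerate(inst_keys)}
        self.dyad_family = np.empty(self.D, int)
        self.dyad_type = np.empty(self.D, int)
        self.dyad_m0 = np.empty(self.D, int)
        self.dyad_m1 = np.empty(self.D, int)
        for (f, us), i in inst_idx.items():
            u = UndirectedDyad.parse(us)
            self.dyad_family[i] = fam_idx[f]
            self.dyad_type[i] = u_idx[u]
            self.dyad_m0[i] = ind_idx[(f, u.first)]
            self.dyad_m1[i] = ind_idx[(f, u.second)]

        # durations per instance (validated equal across directions)
        durs = df.groupby(["family_id", "actor", "partner"])["snapshot"].max()
        self.T_d = np.zeros(self.D, int)
        for (f, a, p), T in durs.items():
            i = inst_idx[(f, str(UndirectedDyad.of(a, p)))]
            if self.T_d[i] not in (0, T):
                raise ValueError(f"directions of dyad {a}:{p} in family {f} have different durations")
            self.T_d[i] = T

        # flat slots: one per (instance, snapshot)
        self.offset = np.concatenate([[0], np.cumsum(self.T_d)])
        self.S = int(self.offset[-1])
        self.slot_dyad = np.repeat(np.arange(self.D), self.T_d)
        self.slot_t = np.concatenate([np.arange(1, T + 1) for T in self.T_d])
        self.slot_type = self.dyad_type[self.slot_dyad]
        self.is_first = self.slot_t == 1
        self.has_next = np.zeros(self.S, bool)
        self.has_next[:-1] = self.slot_dyad[:-1] == self.slot_dyad[1:]

        # responses: y[slot, dir], categories (0 = missing) / observed mask
        y = np.full((self.S, 2), np.nan)
        obs = np.zeros((self.S, 2), bool)
        for fam, a, p, t, yv, o in df.itertuples(index=False):
            u = UndirectedDyad.of(a, p)
            i = inst_idx[(fam, str(u))]
            s = self.offset[i] + t - 1
            direction = 0 if a == u.first else 1
            obs[s, direction] = o
            if o:
                y[s, direction] = yv
        self.y = y
        self.obs = obs
        if ordinal:
            self.cat = np.where(obs, np.nan_to_num(y, nan=0.0), 0.0).astype(int)

        # colour scheme for latent updates: (t parity, direction)
        self.colors = []
        for parity in (1, 0):
            mask = (self.slot_t % 2) == parity
            idx = np.where(mask)[0]
            for direction in (0, 1):
                self.colors.append((idx, direction))

        # per-type slot index lists
        self.type_slots = [np.where(self.slot_type == u)[0] for u in range(self.U)]
        self.type_first = [s[self.is_first[s]] for s in self.type_slots]
        self.type_later = [s[~self.is_first[s]] for s in self.type_slots]
        # individuals by role, dyads by (position, role)
        self.role_members = [np.where(self.ind_role == r)[0] for r in range(len(roles_present))]


# ---------------------------------------------------------------------------
# sampler state
# ---------------------------------------------------------------------------

class _State:
    """Current values of all unknowns, in flat array form."""

    def __init__(self, plan: _Plan, config: FitConfig, rng: np.random.Generator):
        P, cfg = plan, config
        self.mu = np.zeros((P.U, 2))
        self.beta = np.zeros((P.U, 2))  # per-direction slopes; tied if scope=undirected
        self.Phi = np.zeros((P.U, 2, 2))
        self.sigma2_f = 0.1
        self.Sigma_ap = np.tile(0.2 * I2, (len(P.roles), 1, 1))
        self.Sigma_d = np.tile(0.2 * I2, (P.U, 1, 1))
        self.Sigma_eta = np.tile(I2, (P.U, 1, 1))
        self.Sigma_e1 = np.tile(I2, (P.U, 1, 1))
        self.f = np.zeros(P.K)
        self.a = np.zeros(P.M)
        self.p = np.zeros(P.M)
        self.d = np.zeros((P.D, 2))
        ordinal = cfg.response_kind == ORDINAL

        if ordinal:
            C = P.C
            counts = np.bincount(P.cat[P.obs], minlength=C + 1)[1:].astype(float)
            counts = np.clip(counts, 0.5, None)
            cum = np.cumsum(counts)[:-1] / counts.sum()
            zq = sps.ndtri(np.clip(cum, 1e-4, 1 - 1e-4))
            self.tau = zq - zq[0]
            self.tau = np.maximum.accumulate(self.tau + np.arange(C - 1) * 1e-3)
            # latent responses initialised at interval midpoints
            edges_lo = np.concatenate([[self.tau[0] - 1.5], self.tau])
            edges_hi = np.concatenate([self.tau, [self.tau[-1] + 1.5]])
            mid = (edges_lo + edges_hi) / 2.0
            self.ystar = np.where(P.obs, mid[np.clip(P.cat, 1, C) - 1], 0.0)
            # dyad-type means from latent initialisation
            for u in range(P.U):
                sl = P.type_slots[u]
                for direction in (0, 1):
                    m = P.obs[sl, direction]
                    if m.any():
                        self.mu[u, direction] = self.ystar[sl, direction][m].mean()
        else:
            self.tau = None
            self.ystar = np.where(P.obs, np.nan_to_num(P.y), 0.0)
            for u in range(P.U):
                sl = P.type_slots[u]
                for direction in (0, 1):
                    m = P.obs[sl, direction]
                    if m.any():
                        vals = self.ystar[sl, direction][m]
                        self.mu[u, direction] = vals.mean()
                        v = max(vals.var(), 0.05)
                        self.Sigma_eta[u] = v * I2
                        self.Sigma_e1[u] = v * I2
            # fill unobserved slots at the dyad-type mean
            for u in range(P.U):
                sl = P.type_slots[u]
                for direction in (0, 1):
                    miss = ~P.obs[sl, direction]
                    self.ystar[sl[miss], direction] = self.mu[u, direction]

        # over-dispersed chain starts (tau_1 stays pinned at 0)
        j = cfg.start_jitter
        if j > 0:
            self.mu = self.mu + rng.normal(0, j, self.mu.shape)
            self.sigma2_f *= float(np.exp(rng.normal(0, j)))
            if ordinal and len(self.tau) > 1:
                gaps = np.diff(self.tau) * np.exp(rng.normal(0, j, len(self.tau) - 1))
                self.tau = np.concatenate([[0.0], np.cumsum(np.clip(gaps, 1e-3, None))])

    def rho_eta(self, u: int) -> float:
        S = self.Sigma_eta[u]
        return float(S[0, 1] / np.sqrt(S[0, 0] * S[1, 1]))

    def rho_e1(self, u: int) -> float:
        S = self.Sigma_e1[u]
        return float(S[0, 1] / np.sqrt(S[0, 0] * S[1, 1]))


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class GibbsSampler:
    def __init__(self, data: PanelDataset, config: FitConfig, prior_only: bool = False):
        self.config = config
        self.plan = _Plan(data, config)
        self.prior_only = prior_only
        self.ordinal = config.response_kind == ORDINAL
        # With one snapshot per dyad and no dynamics, a continuous model
        # cannot separate the relationship effect from a pair-level
        # residual: the model reduces to the cross-sectional SRM, where the
        # pair-level block IS the relationship covariance.  The sampler then
        # drops the explicit d-effects and reports the pair residual block
        # as the relationship covariance.
        self.cross_sectional = (
            config.dynamics == "none"
            and bool((self.plan.T_d == 1).all())
            and not self.ordinal
            and config.effects == "full"
        )
        self.mh_step = np.full((self.plan.U, 2), 0.3)  # (eta, e1) z-walk steps
        self.mh_accept = np.zeros((self.plan.U, 2))
        self.mh_tries = np.zeros((self.plan.U, 2))
        n_tau = (self.plan.C - 1) if self.ordinal else 0
        self.th_step = np.full(n_tau, 0.1)
        self.th_accept = np.zeros(n_tau)
        self.th_tries = np.zeros(n_tau)

    # -- per-sweep cached per-type matrices -------------------------------
    def _type_mats(self, st: _State):
        U = self.plan.U
        iSe = np.empty((U, 2, 2))
        iS1 = np.empty((U, 2, 2))
        G = np.empty((U, 2, 2))
        GtiSeG = np.empty((U, 2, 2))
        GtiSe = np.empty((U, 2, 2))
        for u in range(U):
            iSe[u] = _inv2(st.Sigma_eta[u])
            iS1[u] = _inv2(st.Sigma_e1[u])
            G[u] = I2 - st.Phi[u]
            GtiSe[u] = G[u].T @ iSe[u]
            GtiSeG[u] = GtiSe[u] @ G[u]
        return iSe, iS1, G, GtiSe, GtiSeG

    def _theta_dyad(self, st: _State) -> np.ndarray:
        P = self.plan
        th = np.empty((P.D, 2))
        th[:, 0] = st.mu[P.dyad_type, 0] + st.f[P.dyad_family] + st.a[P.dyad_m0] + st.p[P.dyad_m1] + st.d[:, 0]
        th[:, 1] = st.mu[P.dyad_type, 1] + st.f[P.dyad_family] + st.a[P.dyad_m1] + st.p[P.dyad_m0] + st.d[:, 1]
        if self.config.effects == "none":
            th[:, 0] = st.mu[P.dyad_type, 0]
            th[:, 1] = st.mu[P.dyad_type, 1]
        return th

    def _theta_slot(self, st: _State, theta_d: np.ndarray | None = None) -> np.ndarray:
        P = self.plan
        if theta_d is None:
            theta_d = self._theta_dyad(st)
        th = theta_d[P.slot_dyad].copy()
        if self.config.trend:
            th += st.beta[P.slot_type] * P.slot_t[:, None]
        return th

    # -- latent responses --------------------------------------------------
    def sample_latents(self, st: _State, rng: np.random.Generator) -> None:
        """Update latent responses (ordinal) / imputed values (missing)."""
        P, cfg = self.plan, self.config
        theta = self._theta_slot(st)
        e = st.ystar - theta
        iSe, iS1, G, GtiSe, GtiSeG = self._type_mats(st)
        Phi = st.Phi

        if self.ordinal:
            tau_ext = np.concatenate([[-np.inf], st.tau, [np.inf]])
        for idx, direction in P.colors:
            if self.ordinal:
                upd = idx  # every latent is resampled
            else:
                upd = idx[~P.obs[idx, direction]]
                if len(upd) == 0:
                    continue
            u = P.slot_type[upd]
            o = direction
            q = 1 - direction
            t_first = P.is_first[upd]
            # A-term (density of e_t)
            Pm = np.where(t_first[:, None, None], iS1[u], iSe[u])
            m = np.zeros((len(upd), 2))
            later = ~t_first
            m[later] = np.einsum("nij,nj->ni", Phi[u[later]], e[upd[later] - 1])
            prec = Pm[:, o, o].copy()
            lin = Pm[:, o, o] * m[:, o] - Pm[:, o, q] * (e[upd, q] - m[:, q])
            # B-term (density of e_{t+1})
            nxt = P.has_next[upd]
            if nxt.any():
                un = u[nxt]
                c = Phi[un][:, :, o]  # column `o` of Phi
                Pn = iSe[un]
                Pc = np.einsum("nij,nj->ni", Pn, c)
                uvec = e[upd[nxt] + 1] - Phi[un][:, :, q] * e[upd[nxt], q][:, None]
                prec[nxt] += np.einsum("ni,ni->n", c, Pc)
                lin[nxt] += np.einsum("ni,ni->n", Pc, uvec)
            mean = lin / prec
            sd = 1.0 / np.sqrt(prec)
            if self.ordinal:
                cat = P.cat[upd, o]
                lo = np.where(cat > 0, tau_ext[np.maximum(cat - 1, 0)], -np.inf) - theta[upd, o]
                hi = np.where(cat > 0, tau_ext[np.minimum(cat, len(tau_ext) - 1)], np.inf) - theta[upd, o]
                e[upd, o] = truncnorm_draw(mean, sd, lo, hi, rng)
            else:
                e[upd, o] = mean + sd * rng.normal(size=len(upd))
        st.ystar = theta + e

    # -- sufficient statistics for the linear predictor -------------------
    def _dyad_stats(self, st: _State):
        """(A_d, b_d): per-instance Gaussian sufficient statistics for the
        time-invariant linear predictor pair theta_d."""
        P, cfg = self.plan, self.config
        iSe, iS1, G, GtiSe, GtiSeG = self._type_mats(st)
        u_d = P.dyad_type
        A = iS1[u_d] + (P.T_d - 1)[:, None, None] * GtiSeG[u_d]

        b = np.zeros((P.D, 2))
        # t = 1 contribution
        first_slots = np.where(P.is_first)[0]
        z1 = st.ystar[first_slots].copy()
        if cfg.trend:
            z1 -= st.beta[P.slot_type[first_slots]] * 1.0
        d1 = P.slot_dyad[first_slots]
        np.add.at(b, d1, np.einsum("nij,nj->ni", iS1[u_d[d1]], z1))
        # t > 1 contributions
        later = np.where(~P.is_first)[0]
        if len(later):
            ul = P.slot_type[later]
            z = st.ystar[later] - np.einsum("nij,nj->ni", st.Phi[ul], st.ystar[later - 1])
            if cfg.trend:
                t = P.slot_t[later][:, None]
                # trend part of E z_t: beta*t - Phi (beta*(t-1))
                z -= st.beta[ul] * t - np.einsum("nij,nj->ni", st.Phi[ul], st.beta[ul] * (t - 1))
            dl = P.slot_dyad[later]
            np.add.at(b, dl, np.einsum("nij,nj->ni", GtiSe[ul], z))
        return A, b

    # -- linear predictor blocks ------------------------------------------
    def sample_linear_predictor(self, st: _State, rng: np.random.Generator) -> None:
        P, cfg = self.plan, self.config
        pri = cfg.priors
        if self.prior_only:
            st.mu = rng.normal(pri.fixed_mean, 1 / np.sqrt(pri.fixed_prec), st.mu.shape)
            if cfg.trend:
                st.beta = rng.normal(0, 1 / np.sqrt(pri.fixed_prec), st.beta.shape)
                if cfg.trend_scope == "undirected":
                    st.beta[:, 1] = st.beta[:, 0]
            if cfg.effects != "none":
                st.f = rng.normal(0, np.sqrt(st.sigma2_f), P.K)
                for r, members in enumerate(P.role_members):
                    L = np.linalg.cholesky(st.Sigma_ap[r])
                    ap = rng.normal(size=(len(members), 2)) @ L.T
                    st.a[members], st.p[members] = ap[:, 0], ap[:, 1]
                L = np.linalg.cholesky(st.Sigma_d)
                st.d = np.einsum("nij,nj->ni", L[P.dyad_type], rng.normal(size=(P.D, 2)))
            return

        A, b = self._dyad_stats(st)
        theta = self._theta_dyad(st)

        # dyad-type means, one bivariate block per undirected type
        for u in range(P.U):
            sel = np.where(P.dyad_type == u)[0]
            prec = pri.fixed_prec * I2 + A[sel].sum(axis=0)
            resid = b[sel] - np.einsum("nij,nj->ni", A[sel], theta[sel] - st.mu[u])
            h = resid.sum(axis=0) + pri.fixed_prec * pri.fixed_mean
            st.mu[u] = _draw_mvn(prec, h, rng)
        theta = self._theta_dyad(st)

        if cfg.effects == "none":
            if cfg.trend:
                self._sample_trend(st, rng)
            return

        # family effects (independent across families given the rest)
        ones = np.ones(2)
        A11 = A.sum(axis=(1, 2))
        resid = np.einsum("ni,ni->n", b - np.einsum("nij,nj->ni", A, theta - st.f[P.dyad_family][:, None]), np.ones((P.D, 2)))
        prec_f = np.full(P.K, 1.0 / st.sigma2_f)
        lin_f = np.zeros(P.K)
        np.add.at(prec_f, P.dyad_family, A11)
        np.add.at(lin_f, P.dyad_family, resid)
        st.f = lin_f / prec_f + rng.normal(size=P.K) / np.sqrt(prec_f)

        # actor/partner pairs, role by role (roles of one kind never share a dyad)
        J = np.array([[0.0, 1.0], [1.0, 0.0]])
        for r, members in enumerate(P.role_members):
            if len(members) == 0:
                continue
            theta = self._theta_dyad(st)
            iS = _inv2(st.Sigma_ap[r])
            prec = np.tile(iS, (len(members), 1, 1))
            lin = np.zeros((len(members), 2))
            mpos = {m: i for i, m in enumerate(members)}
            for pos, marr in ((0, P.dyad_m0), (1, P.dyad_m1)):
                sel = np.where(np.isin(marr, members))[0]
                if len(sel) == 0:
                    continue
                rows = np.array([mpos[m] for m in marr[sel]])
                x = np.stack([st.a[marr[sel]], st.p[marr[sel]]], axis=1)
                # C maps (a, p) into theta: identity at position 0, swap at 1
                Asel = A[sel]
                if pos == 1:
                    Asel = np.einsum("ij,njk,kl->nil", J, Asel, J)
                r_d = b[sel] - np.einsum("nij,nj->ni", A[sel], theta[sel])
                if pos == 1:
                    r_d = r_d[:, ::-1]
                cx = np.einsum("nij,nj->ni", Asel, x)
                np.add.at(prec, rows, Asel)
                np.add.at(lin, rows, r_d + cx)
            ap = _draw_mvn2_batch(prec, lin, rng)
            st.a[members], st.p[members] = ap[:, 0], ap[:, 1]

        # relationship pairs (independent across instances given the rest);
        # skipped in cross-sectional mode where the pair residual plays
        # this role
        if not self.cross_sectional:
            theta = self._theta_dyad(st)
            iSd = np.array([_inv2(S) for S in st.Sigma_d])
            prec = iSd[P.dyad_type] + A
            lin = b - np.einsum("nij,nj->ni", A, theta - st.d)
            st.d = _draw_mvn2_batch(prec, lin, rng)

        if cfg.trend:
            self._sample_trend(st, rng)

    def _sample_trend(self, st: _State, rng: np.random.Generator) -> None:
        """Conjugate update of the linear snapshot-trend slopes.

        The trend enters the first-snapshot mean as beta * 1 and the t > 1
        quasi-differenced mean as (t I - (t-1) Phi) beta; residuals are
        formed against the time-invariant part of the linear predictor.
        """
        P, cfg = self.plan, self.config
        pri = cfg.priors
        iSe, iS1, G, _, _ = self._type_mats(st)
        theta_d = self._theta_dyad(st)
        shared = cfg.trend_scope == "undirected"
        for u in range(P.U):
            first = P.type_first[u]
            later = P.type_later[u]
            designs: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
            if len(first):
                rho1 = st.ystar[first] - theta_d[P.slot_dyad[first]]
                W1 = np.broadcast_to(I2, (len(first), 2, 2))
                designs.append((W1, rho1, iS1[u]))
            if len(later):
                z = st.ystar[later] - np.einsum("ij,nj->ni", st.Phi[u], st.ystar[later - 1])
                rhol = z - np.einsum("ij,nj->ni", G[u], theta_d[P.slot_dyad[later]])
                t = P.slot_t[later].astype(float)
                Wl = t[:, None, None] * I2 - (t - 1)[:, None, None] * st.Phi[u]
                designs.append((Wl, rhol, iSe[u]))
            if shared:
                prec = pri.fixed_prec
                lin = 0.0
                for W, rho, Pm in designs:
                    w = W.sum(axis=2)  # W @ (1,1)'
                    prec += float(np.einsum("ni,ij,nj->", w, Pm, w))
                    lin += float(np.einsum("ni,ij,nj->", w, Pm, rho))
                st.beta[u] = lin / prec + rng.normal() / np.sqrt(prec)
            else:
                prec = pri.fixed_prec * np.eye(2)
                lin = np.zeros(2)
                for W, rho, Pm in designs:
                    prec += np.einsum("nij,ik,nkl->jl", W, Pm, W)
                    lin += np.einsum("nij,ik,nk->j", W, Pm, rho)
                st.beta[u] = _draw_mvn(prec, lin, rng)

    # -- dynamics ----------------------------------------------------------
    def sample_dynamics(self, st: _State, rng: np.random.Generator) -> None:
        P, cfg = self.plan, self.config
        if cfg.dynamics == "none":
            st.Phi[:] = 0.0
            return
        pri = cfg.priors
        theta = self._theta_slot(st)
        e = st.ystar - theta
        for u in range(P.U):
            later = P.type_later[u]
            iSe = _inv2(st.Sigma_eta[u])
            if self.prior_only or len(later) == 0:
                draw = rng.normal(pri.fixed_mean, 1 / np.sqrt(pri.fixed_prec), size=4)
                Phi_new = draw.reshape(2, 2)
                if cfg.dynamics == "ar":
                    Phi_new[0, 1] = Phi_new[1, 0] = 0.0
                st.Phi[u] = Phi_new
                continue
            x = e[later - 1]
            y = e[later]
            if cfg.dynamics == "ar_crosslag":
                Sxx = x.T @ x
                prec = np.kron(iSe, Sxx) + pri.fixed_prec * np.eye(4)
                Pe = y @ iSe.T
                lin = np.concatenate([x.T @ Pe[:, 0], x.T @ Pe[:, 1]])
                phi = _draw_mvn(prec, lin, rng)
                st.Phi[u] = phi.reshape(2, 2)
            else:  # ar: diagonal Phi only
                prec = np.empty((2, 2))
                prec[0, 0] = iSe[0, 0] * (x[:, 0] ** 2).sum() + pri.fixed_prec
                prec[1, 1] = iSe[1, 1] * (x[:, 1] ** 2).sum() + pri.fixed_prec
                prec[0, 1] = prec[1, 0] = iSe[0, 1] * (x[:, 0] * x[:, 1]).sum()
                Pe = y @ iSe.T
                lin = np.array([(Pe[:, 0] * x[:, 0]).sum(), (Pe[:, 1] * x[:, 1]).sum()])
                diag = _draw_mvn(prec, lin, rng)
                st.Phi[u] = np.diag(diag)

    # -- variance components ----------------------------------------------
    def _wishart_post(self, S: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw a covariance from the conjugate Wishart(identity, 2) posterior
        of the precision given scatter S over n bivariate observations."""
        df = self.config.priors.wishart_df + n
        scale = _inv2(I2 + S)
        W = _wishart2_rvs(df, scale, rng)
        return _inv2(W)

    def sample_variances(self, st: _State, rng: np.random.Generator) -> None:
        P, cfg = self.plan, self.config
        pri = cfg.priors
        if cfg.effects != "none":
            n = 0 if self.prior_only else P.K
            ss = 0.0 if self.prior_only else float((st.f ** 2).sum())
            lam = rng.gamma(pri.family_shape + n / 2.0, 1.0 / (pri.family_rate + ss / 2.0))
            # the diffuse Gamma(0.001, 0.001) prior can underflow to 0.0
            st.sigma2_f = 1.0 / max(lam, 1e-290)
            for r, members in enumerate(P.role_members):
                if self.prior_only or len(members) == 0:
                    st.Sigma_ap[r] = self._wishart_post(np.zeros((2, 2)), 0, rng)
                    continue
                X = np.stack([st.a[members], st.p[members]], axis=1)
                st.Sigma_ap[r] = self._wishart_post(X.T @ X, len(members), rng)
            if not self.cross_sectional:
                for u in range(P.U):
                    sel = np.where(P.dyad_type == u)[0]
                    if self.prior_only or len(sel) == 0:
                        st.Sigma_d[u] = self._wishart_post(np.zeros((2, 2)), 0, rng)
                        continue
                    X = st.d[sel]
                    st.Sigma_d[u] = self._wishart_post(X.T @ X, len(sel), rng)

        # residual / innovation blocks
        theta = self._theta_slot(st)
        e = st.ystar - theta
        for u in range(P.U):
            first = P.type_first[u]
            later = P.type_later[u]
            if len(later):
                eta = e[later] - np.einsum("ij,nj->ni", st.Phi[u], e[later - 1])
            else:
                eta = np.zeros((0, 2))
            e1 = e[first]
            if self.ordinal:
                self._mh_corr(st, u, 0, eta, rng)
                self._mh_corr(st, u, 1, e1, rng)
            else:
                st.Sigma_eta[u] = self._wishart_post(
                    np.zeros((2, 2)) if self.prior_only else eta.T @ eta,
                    0 if self.prior_only else len(eta),
                    rng,
                )
                st.Sigma_e1[u] = self._wishart_post(
                    np.zeros((2, 2)) if self.prior_only else e1.T @ e1,
                    0 if self.prior_only else len(e1),
                    rng,
                )

    def _mh_corr(self, st: _State, u: int, which: int, resid: np.ndarray, rng: np.random.Generator) -> None:
        """Fisher-z random-walk Metropolis for an identified correlation."""
        S = st.Sigma_eta[u] if which == 0 else st.Sigma_e1[u]
        rho = float(S[0, 1])
        z = np.arctanh(np.clip(rho, -0.999999, 0.999999))
        prec_z = self.config.corr_z_prec
        if self.prior_only or len(resid) == 0:
            z_new = rng.normal(0.0, 1.0 / np.sqrt(prec_z))
            # keep the matrix numerically invertible when the block has no data
            rho_new = float(np.clip(np.tanh(z_new), -0.999999, 0.999999))
        else:
            S00 = float((resid[:, 0] ** 2).sum())
            S11 = float((resid[:, 1] ** 2).sum())
            S01 = float((resid[:, 0] * resid[:, 1]).sum())
            n = len(resid)
            step = self.mh_step[u, which]
            z_prop = z + step * rng.normal()
            rho_prop = float(np.tanh(z_prop))
            # log posterior in z includes the tanh Jacobian log(1 - rho^2)
            def lp(zv, rv):
                return (
                    _bvn_corr_suffstats_loglik(rv, S00, S11, S01, n)
                    - 0.5 * prec_z * zv * zv
                    + np.log1p(-rv * rv)
                )
            self.mh_tries[u, which] += 1
            if np.log(rng.uniform()) < lp(z_prop, rho_prop) - lp(z, rho):
                rho_new = rho_prop
                self.mh_accept[u, which] += 1
            else:
                rho_new = rho
        M = np.array([[1.0, rho_new], [rho_new, 1.0]])
        if which == 0:
            st.Sigma_eta[u] = M
        else:
            st.Sigma_e1[u] = M

    # -- thresholds --------------------------------------------------------
    def sample_thresholds(self, st: _State, rng: np.random.Generator) -> None:
        """Conditional threshold draws on the feasible intervals.

        With Exp(1) priors on the gaps, interior thresholds are uniform on
        the feasible interval (the adjacent gap densities cancel); the top
        threshold follows a truncated Exp(1).  tau_1 stays fixed at 0.
        """
        P = self.plan
        C = P.C
        if C <= 2:
            return
        obs_cat = P.cat[P.obs]
        obs_y = st.ystar[P.obs]
        gap_rate = self.config.priors.gap_rate
        for c in range(2, C):  # tau_c, c = 2..C-1 (1-based), index c-1
            if self.prior_only:
                lo_lat, hi_lat = -np.inf, np.inf
            else:
                below = obs_y[obs_cat == c]
                above = obs_y[obs_cat == c + 1]
                lo_lat = below.max() if len(below) else -np.inf
                hi_lat = above.min() if len(above) else np.inf
            lo = max(lo_lat, st.tau[c - 2])
            hi = min(hi_lat, st.tau[c] if c < C - 1 else np.inf)
            if not lo < hi:
                continue  # numerically empty interval; keep current value
            if c < C - 1:
                if np.isinf(hi) or np.isinf(lo):
                    # only possible in prior-only runs: draw gap from Exp(1)
                    st.tau[c - 1] = lo + rng.exponential(1.0 / gap_rate) if np.isfinite(lo) else rng.exponential(1.0 / gap_rate)
                else:
                    st.tau[c - 1] = rng.uniform(lo, hi)
            else:
                # top threshold: density ∝ exp(-gap_rate * tau) on (lo, hi)
                if np.isinf(hi):
                    st.tau[c - 1] = lo + rng.exponential(1.0 / gap_rate)
                else:
                    u0 = rng.uniform()
                    a_, b_ = -gap_rate * lo, -gap_rate * hi
                    # inverse CDF of truncated exponential via logs
                    w = np.log1p(u0 * np.expm1(b_ - a_))
                    st.tau[c - 1] = lo - w / gap_rate

    def _latent_loglik(self, st: _State) -> float:
        """Joint Gaussian log-density of all latent residual sequences."""
        P = self.plan
        theta = self._theta_slot(st)
        e = st.ystar - theta
        total = 0.0
        for u in range(P.U):
            first = P.type_first[u]
            later = P.type_later[u]
            total += _mvn2_logpdf_sum(e[first], st.Sigma_e1[u])
            if len(later):
                eta = e[later] - e[later - 1] @ st.Phi[u].T
                total += _mvn2_logpdf_sum(eta, st.Sigma_eta[u])
        return total

    def threshold_stretch_moves(self, st: _State, rng: np.random.Generator) -> None:
        """Joint (threshold, latent) Metropolis moves.

        Single-site threshold conditionals can only crawl within the tiny
        feasible window left between adjacent order statistics of the
        latents, so the threshold scale mixes very slowly.  This move
        proposes tau_c -> tau_c + delta together with a piecewise-linear
        remapping of every latent response (stretching the two adjacent
        intervals, or shifting the upper tail for the top threshold) and
        accepts with the exact Metropolis–Hastings ratio including the
        transformation Jacobian.  Category memberships are preserved by
        construction.
        """
        P = self.plan
        C = P.C
        if C <= 2:
            return
        rate = self.config.priors.gap_rate
        ll_cur: float | None = None
        for c in range(2, C):  # tau_c, 1-based; index c-1
            i = c - 1
            step = self.th_step[i]
            delta = step * rng.normal()
            tau_c = st.tau[i]
            tau_lo = st.tau[i - 1]
            tau_hi = st.tau[i + 1] if c < C - 1 else np.inf
            tau_new = tau_c + delta
            self.th_tries[i] += 1
            if not (tau_lo < tau_new < tau_hi):
                continue
            if ll_cur is None:
                ll_cur = self._latent_loglik(st)
            ll_old = ll_cur
            y = st.ystar
            in_lower = (y >= tau_lo) & (y < tau_c)
            r1 = (tau_new - tau_lo) / (tau_c - tau_lo)
            log_jac = in_lower.sum() * np.log(r1)
            y_new = y.copy()
            y_new[in_lower] = tau_lo + (y[in_lower] - tau_lo) * r1
            if c < C - 1:
                in_upper = (y >= tau_c) & (y < tau_hi)
                r2 = (tau_hi - tau_new) / (tau_hi - tau_c)
                log_jac += in_upper.sum() * np.log(r2)
                y_new[in_upper] = tau_new + (y[in_upper] - tau_c) * r2
                log_prior = 0.0  # adjacent Exp gaps: delta cancels
            else:
                in_upper = y >= tau_c
                y_new[in_upper] = y[in_upper] + delta
                log_prior = -rate * delta
            old_y = st.ystar
            st.ystar = y_new
            st.tau[i] = tau_new
            ll_new = self._latent_loglik(st)
            if np.log(rng.uniform()) < ll_new - ll_old + log_jac + log_prior:
                self.th_accept[i] += 1
                ll_cur = ll_new
            else:
                st.ystar = old_y
                st.tau[i] = tau_c

    # -- one sweep ---------------------------------------------------------
    def sweep(self, st: _State, rng: np.random.Generator, adapt: bool = False) -> None:
        if not self.prior_only and (self.ordinal or not self.plan.obs.all()):
            self.sample_latents(st, rng)
        self.sample_linear_predictor(st, rng)
        if self.config.dynamics != "none":
            self.sample_dynamics(st, rng)
        self.sample_variances(st, rng)
        if self.ordinal:
            self.sample_thresholds(st, rng)
            if not self.prior_only:
                self.threshold_stretch_moves(st, rng)
        if adapt and self.ordinal:
            self._adapt_steps()

    def _adapt_steps(self) -> None:
        mask = self.mh_tries >= 50
        if mask.any():
            rate = np.where(self.mh_tries > 0, self.mh_accept / np.maximum(self.mh_tries, 1), 0.44)
            self.mh_step[mask] *= np.exp(np.clip(rate[mask] - 0.44, -0.5, 0.5))
            self.mh_accept[mask] = 0.0
            self.mh_tries[mask] = 0.0
        tmask = self.th_tries >= 50
        if tmask.any():
            rate = self.th_accept / np.maximum(self.th_tries, 1)
            self.th_step[tmask] *= np.exp(np.clip(rate[tmask] - 0.35, -0.5, 0.5))
            self.th_accept[tmask] = 0.0
            self.th_tries[tmask] = 0.0

    # -- chain driver ------------------------------------------------------
    def run_chain(self, chain: int) -> dict[str, np.ndarray]:
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919, chain]))
        st = _State(self.plan, cfg, rng)
        for it in range(cfg.n_adapt):
            self.sweep(st, rng, adapt=True)
        for it in range(cfg.n_burnin):
            self.sweep(st, rng)
        names = self.param_names()
        out = {nm: np.empty(cfg.n_stored) for nm in names}
        kept = 0
        for it in range(cfg.n_iter):
            self.sweep(st, rng)
            if (it + 1) % cfg.thin == 0 and kept < cfg.n_stored:
                for nm, val in self.extract(st).items():
                    out[nm][kept] = val
                kept += 1
        return out

    # -- naming / extraction ----------------------------------------------
    def param_names(self) -> list[str]:
        P, cfg = self.plan, self.config
        names: list[str] = []
        for u in P.utypes:
            ij, ji = u.directed
            names += [f"mu[{ij}]", f"mu[{ji}]"]
        if cfg.trend:
            for u in P.utypes:
                if cfg.trend_scope == "undirected":
                    names.append(f"beta1[{u}]")
                else:
                    ij, ji = u.directed
                    names += [f"beta1[{ij}]", f"beta1[{ji}]"]
        if cfg.dynamics != "none":
            for u in P.utypes:
                ij, ji = u.directed
                names += [f"phi1[{ij}]", f"phi1[{ji}]"]
                if cfg.dynamics == "ar_crosslag":
                    names += [f"phi2[{ij}]", f"phi2[{ji}]"]
        if cfg.effects != "none":
            names.append("sigma2_f")
            for r in P.roles:
                names += [f"sigma2_a[{r}]", f"sigma2_p[{r}]", f"rho_ap[{r}]"]
            for u in P.utypes:
                ij, ji = u.directed
                names += [f"sigma2_d[{ij}]", f"sigma2_d[{ji}]", f"rho_d[{u}]"]
        if not self.cross_sectional:
            for u in P.utypes:
                ij, ji = u.directed
                names += [f"sigma2_eta[{ij}]", f"sigma2_eta[{ji}]", f"rho_eta[{u}]"]
                names += [f"sigma2_e1[{ij}]", f"sigma2_e1[{ji}]", f"rho_e1[{u}]"]
        if self.ordinal:
            names += [f"tau[{c}]" for c in range(1, P.C)]
        return names

    def extract(self, st: _State) -> dict[str, float]:
        P, cfg = self.plan, self.config
        out: dict[str, float] = {}
        for ui, u in enumerate(P.utypes):
            ij, ji = u.directed
            out[f"mu[{ij}]"] = st.mu[ui, 0]
            out[f"mu[{ji}]"] = st.mu[ui, 1]
        if cfg.trend:
            for ui, u in enumerate(P.utypes):
                if cfg.trend_scope == "undirected":
                    out[f"beta1[{u}]"] = st.beta[ui, 0]
                else:
                    ij, ji = u.directed
                    out[f"beta1[{ij}]"] = st.beta[ui, 0]
                    out[f"beta1[{ji}]"] = st.beta[ui, 1]
        if cfg.dynamics != "none":
            for ui, u in enumerate(P.utypes):
                ij, ji = u.directed
                out[f"phi1[{ij}]"] = st.Phi[ui, 0, 0]
                out[f"phi1[{ji}]"] = st.Phi[ui, 1, 1]
                if cfg.dynamics == "ar_crosslag":
                    out[f"phi2[{ij}]"] = st.Phi[ui, 0, 1]
                    out[f"phi2[{ji}]"] = st.Phi[ui, 1, 0]
        if cfg.effects != "none":
            out["sigma2_f"] = st.sigma2_f
            for ri, r in enumerate(P.roles):
                S = st.Sigma_ap[ri]
                out[f"sigma2_a[{r}]"] = S[0, 0]
                out[f"sigma2_p[{r}]"] = S[1, 1]
                out[f"rho_ap[{r}]"] = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])
            for ui, u in enumerate(P.utypes):
                ij, ji = u.directed
                # in cross-sectional mode the pair residual block IS the
                # relationship covariance
                S = st.Sigma_e1[ui] if self.cross_sectional else st.Sigma_d[ui]
                out[f"sigma2_d[{ij}]"] = S[0, 0]
                out[f"sigma2_d[{ji}]"] = S[1, 1]
                out[f"rho_d[{u}]"] = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])
        if not self.cross_sectional:
            for ui, u in enumerate(P.utypes):
                ij, ji = u.directed
                out[f"sigma2_eta[{ij}]"] = st.Sigma_eta[ui, 0, 0]
                out[f"sigma2_eta[{ji}]"] = st.Sigma_eta[ui, 1, 1]
                out[f"rho_eta[{u}]"] = st.rho_eta(ui)
                out[f"sigma2_e1[{ij}]"] = st.Sigma_e1[ui, 0, 0]
                out[f"sigma2_e1[{ji}]"] = st.Sigma_e1[ui, 1, 1]
                out[f"rho_e1[{u}]"] = st.rho_e1(ui)
        if self.ordinal:
            for c in range(1, P.C):
                out[f"tau[{c}]"] = st.tau[c - 1]
        return out

# ---------------------------------------------------------------------------
# target density (exposed for testing)
# ---------------------------------------------------------------------------

def log_posterior(
    params: SRMParams,
    effects: dict[str, FamilyEffects],
    data: PanelDataset,
    config: FitConfig,
    latents: dict[str, dict[UndirectedDyad, np.ndarray]] | None = None,
) -> float:
    """Unnormalised log posterior of a full model state.

    ``effects`` maps family id -> FamilyEffects; ``latents`` maps family id
    -> {undirected dyad -> (T, 2) latent response array} and is required for
    ordinal responses (where every observed latent must lie inside its
    category's threshold interval) and for missing records.  Parameter
    priors are evaluated on the sampler's working scales (precision
    matrices, atanh correlations, threshold gaps).  Raises ValueError on
    invariant-violating states.
    """
    from .params import validate_params
    from .reparam import loglik_residual_form

    problems = validate_params(params)
    if problems:
        raise ValueError("invalid parameter state:\n  " + "\n  ".join(problems))
    pri = config.priors
    ordinal = config.response_kind == ORDINAL

    lp = 0.0
    # fixed-part priors
    for m in params.mu.values():
        lp += scipy.stats.norm.logpdf(m, pri.fixed_mean, 1 / np.sqrt(pri.fixed_prec))
    if config.dynamics != "none":
        for d in params.mu:
            lp += scipy.stats.norm.logpdf(params.phi1[d], pri.fixed_mean, 1 / np.sqrt(pri.fixed_prec))
            if config.dynamics == "ar_crosslag":
                lp += scipy.stats.norm.logpdf(params.phi2[d], pri.fixed_mean, 1 / np.sqrt(pri.fixed_prec))
    if params.beta1 is not None:
        for b in params.beta1.values():
            lp += scipy.stats.norm.logpdf(b, 0.0, 1 / np.sqrt(pri.fixed_prec))
    # threshold-gap priors
    if ordinal and params.thresholds is not None and len(params.thresholds) > 1:
        gaps = np.diff(params.thresholds)
        lp += float(np.sum(scipy.stats.expon.logpdf(gaps, scale=1.0 / pri.gap_rate)))
    # variance-component priors
    if config.effects != "none":
        lp += scipy.stats.gamma.logpdf(
            1.0 / params.sigma2_f, pri.family_shape, scale=1.0 / pri.family_rate
        )
        for S in list(params.Sigma_ap.values()) + list(params.Sigma_d.values()):
            lp += scipy.stats.wishart.logpdf(np.linalg.inv(S), df=pri.wishart_df, scale=I2)
    corr_prec = config.corr_z_prec
    for u in params.Sigma_eta:
        if ordinal:
            for S in (params.Sigma_eta[u], params.Sigma_e1[u]):
                z = np.arctanh(S[0, 1] / np.sqrt(S[0, 0] * S[1, 1]))
                lp += scipy.stats.norm.logpdf(z, 0.0, 1 / np.sqrt(corr_prec))
        else:
            for S in (params.Sigma_eta[u], params.Sigma_e1[u]):
                lp += scipy.stats.wishart.logpdf(np.linalg.inv(S), df=pri.wishart_df, scale=I2)

    # random-effect priors + likelihood, family by family
    tau_ext = None
    if ordinal:
        tau_ext = np.concatenate([[-np.inf], params.thresholds, [np.inf]])
    for fam in data.families:
        eff = effects[fam]
        if config.effects != "none":
            lp += scipy.stats.norm.logpdf(eff.f, 0.0, np.sqrt(params.sigma2_f))
            for r in eff.composition:
                lp += scipy.stats.multivariate_normal.logpdf(
                    [eff.a[r], eff.p[r]], mean=np.zeros(2), cov=params.Sigma_ap[r]
                )
            seen = set()
            for dd in eff.d:
                u = dd.undirected
                if u in seen:
                    continue
                seen.add(u)
                ij, ji = u.directed
                lp += scipy.stats.multivariate_normal.logpdf(
                    [eff.d[ij], eff.d[ji]], mean=np.zeros(2), cov=params.Sigma_d[u]
                )
        # assemble the working (latent) response arrays
        sub = data.df[data.df["family_id"] == fam]
        yfam: dict[UndirectedDyad, np.ndarray] = {}
        for (a, p), g in sub.groupby(["actor", "partner"]):
            u = UndirectedDyad.of(a, p)
            direction = 0 if a == u.first else 1
            T = int(g["snapshot"].max())
            arr = yfam.setdefault(u, np.full((T, 2), np.nan))
            g = g.sort_values("snapshot")
            if ordinal or not g["observed"].all():
                if latents is None or u not in latents.get(fam, {}):
                    raise ValueError(f"latent responses required for family {fam} dyad {u}")
                arr[:, direction] = latents[fam][u][:, direction]
                cats = g["y"].to_numpy()
                obs = g["observed"].to_numpy(bool)
                if ordinal:
                    lo = tau_ext[np.clip(cats[obs].astype(int) - 1, 0, None)]
                    hi = tau_ext[cats[obs].astype(int)]
                    vals = arr[obs, direction]
                    if np.any(vals < lo) or np.any(vals >= hi):
                        raise ValueError(
                            f"latent response outside its category interval (family {fam}, dyad {u})"
                        )
                else:
                    # observed continuous values are data, not free latents
                    arr[obs, direction] = g.loc[g["observed"], "y"].to_numpy()
            else:
                arr[:, direction] = g["y"].to_numpy()
        lp += loglik_residual_form(params, eff, yfam)
    return float(lp)
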