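"""Model parameters, realised random effects, and their validation.

Parameter containers follow the dynamic social relations model: directed
dyad-type means ``mu[ij]`` (optionally with a linear snapshot trend),
autoregressive and cross-lagged coefficients ``phi1[ij]``/``phi2[ij]``, a
family variance, per-role bivariate actor/partner covariances, per-undirected-
dyad bivariate relationship covariances, innovation covariances, a separate
first-snapshot residual covariance, and (for ordinal responses) strictly
increasing thresholds with ``tau_1 = 0``.

2x2 matrices keyed by an :class:`~dynsrm.roles.UndirectedDyad` are oriented
with index 0 = the canonical direction (``first -> second``) and index 1 =
the reverse direction.  Per-role actor/partner covariances are oriented
(actor, partner).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .roles import (
    ROLES,
    DirectedDyad,
    UndirectedDyad,
    check_composition,
    directed_dyads,
    undirected_dyads,
)

CONTINUOUS = "continuous"
ORDINAL = "ordinal"


def cov2x2(var1: float, var2: float, rho: float) -> np.ndarray:
    """Assemble a 2x2 covariance from variances and a correlation."""
    c = rho * np.sqrt(var1 * var2)
    return np.array([[var1, c], [c, var2]], float)


def corr_of(S: np.ndarray) -> float:
    return float(S[0, 1] / np.sqrt(S[0, 0] * S[1, 1]))


@dataclass
class SRMParams:
    """Full generative parameter set of the dynamic social relations model."""

    mu: dict[DirectedDyad, float]
    phi1: dict[DirectedDyad, float]
    phi2: dict[DirectedDyad, float]
    sigma2_f: float
    Sigma_ap: dict[str, np.ndarray]
    Sigma_d: dict[UndirectedDyad, np.ndarray]
    Sigma_eta: dict[UndirectedDyad, np.ndarray]
    Sigma_e1: dict[UndirectedDyad, np.ndarray]
    thresholds: np.ndarray | None = None
    response_kind: str = CONTINUOUS
    # Optional linear time trend in the latent mean; keys either all
    # UndirectedDyad (slope shared by both directions, the default reading)
    # or all DirectedDyad.
    beta1: dict | None = None

    # -- key sets ---------------------------------------------------------
    @property
    def directed(self) -> list[DirectedDyad]:
        return sorted(self.mu)

    @property
    def undirected(self) -> list[UndirectedDyad]:
        return sorted(self.Sigma_d)

    @property
    def roles(self) -> list[str]:
        present = {d.actor for d in self.mu} | {d.partner for d in self.mu}
        return [r for r in ROLES if r in present]

    @property
    def n_categories(self) -> int | None:
        if self.thresholds is None:
            return None
        return len(self.thresholds) + 1

    def beta1_for(self, dyad: DirectedDyad) -> float:
        """Trend slope for a directed dyad (0 when no trend is present)."""
        if self.beta1 is None:
            return 0.0
        if dyad in self.beta1:
            return float(self.beta1[dyad])
        return float(self.beta1[dyad.undirected])

    def dynamics_matrix(self, u: UndirectedDyad) -> np.ndarray:
        """Phi = [[phi1_ij, phi2_ij], [phi2_ji, phi1_ji]] for the stacked pair."""
        ij, ji = u.directed
        return np.array(
            [[self.phi1[ij], self.phi2[ij]], [self.phi2[ji], self.phi1[ji]]], float
        )

    def copy(self) -> "SRMParams":
        return replace(
            self,
            mu=dict(self.mu),
            phi1=dict(self.phi1),
            phi2=dict(self.phi2),
            Sigma_ap={k: v.copy() for k, v in self.Sigma_ap.items()},
            Sigma_d={k: v.copy() for k, v in self.Sigma_d.items()},
            Sigma_eta={k: v.copy() for k, v in self.Sigma_eta.items()},
            Sigma_e1={k: v.copy() for k, v in self.Sigma_e1.items()},
            thresholds=None if self.thresholds is None else self.thresholds.copy(),
            beta1=None if self.beta1 is None else dict(self.beta1),
        )


@dataclass
class FamilyEffects:
    """One family's realised random effects on the latent scale."""

    f: float
    a: dict[str, float]
    p: dict[str, float]
    d: dict[DirectedDyad, float]

    @property
    def composition(self) -> tuple[str, ...]:
        return check_composition(self.a)


def _check_spd(S: np.ndarray, name: str, unit_diag: bool, out: list[str]) -> None:
    S = np.asarray(S, float)
    if S.shape != (2, 2):
        out.append(f"{name}: expected 2x2 matrix, got shape {S.shape}")
        return
    if not np.allclose(S, S.T, atol=1e-10):
        out.append(f"{name}: not symmetric")
        return
    ev = np.linalg.eigvalsh(S)
    if ev.min() <= 0:
        out.append(f"{name}: not positive-definite (min eigenvalue {ev.min():.3g})")
        return
    rho = corr_of(S)
    if not (-1.0 < rho < 1.0):
        out.append(f"{name}: correlation {rho:.3g} outside (-1, 1)")
    if unit_diag and not np.allclose(np.diag(S), 1.0, atol=1e-10):
        out.append(f"{name}: ordinal identification requires unit variances, got diag {np.diag(S)}")


def validate_params(params: SRMParams) -> list[str]:
    """Return a list of human-readable invariant violations (empty iff valid)."""
    v: list[str] = []
    if params.response_kind not in (CONTINUOUS, ORDINAL):
        v.append(f"response_kind: unknown kind {params.response_kind!r}")

    dset = set(params.mu)
    for name, m in (("phi1", params.phi1), ("phi2", params.phi2)):
        if set(m) != dset:
            v.append(f"{name}: dyad keys differ from mu keys")
    uset = {d.undirected for d in dset}
    for name, m in (
        ("Sigma_d", params.Sigma_d),
        ("Sigma_eta", params.Sigma_eta),
        ("Sigma_e1", params.Sigma_e1),
    ):
        if set(m) != uset:
            v.append(f"{name}: undirected keys inconsistent with mu's dyads")

    if not np.isfinite(params.sigma2_f) or params.sigma2_f < 0:
        v.append(f"sigma2_f: must be >= 0, got {params.sigma2_f}")

    ordinal = params.response_kind == ORDINAL
    for r, S in params.Sigma_ap.items():
        _check_spd(S, f"Sigma_ap[{r}]", False, v)
    for u, S in params.Sigma_d.items():
        _check_spd(S, f"Sigma_d[{u}]", False, v)
    for u, S in params.Sigma_eta.items():
        _check_spd(S, f"Sigma_eta[{u}]", ordinal, v)
    for u, S in params.Sigma_e1.items():
        _check_spd(S, f"Sigma_e1[{u}]", ordinal, v)

    if ordinal:
        tau = params.thresholds
        if tau is None or len(tau) < 1:
            v.append("thresholds: ordinal response requires C-1 thresholds")
        else:
            tau = np.asarray(tau, float)
            if not np.all(np.diff(tau) > 0):
                v.append("thresholds: must be strictly increasing")
            if abs(tau[0]) > 1e-12:
                v.append(
                    f"thresholds: identification requires tau_1 = 0, got {tau[0]:.3g}"
                )
    elif params.thresholds is not None:
        v.append("thresholds: set for a continuous response")

    if params.beta1 is not None:
        keys = set(params.beta1)
        if not (keys == uset or keys == dset):
            v.append("beta1: keys must be all undirected or all directed dyad types")
    return v


def require_valid(params: SRMParams) -> None:
    problems = validate_params(params)
    if problems:
        raise ValueError("invalid SRMParams:\n  " + "\n  ".join(problems))


def linear_predictor(
    params: SRMParams, effects: FamilyEffects, dyad: DirectedDyad, t: int = 1
) -> float:
    """theta_ijk = mu_ij (+ beta1_ij t) + f_k + a_ik + p_jk + d_ijk."""
    comp = effects.composition
    if dyad.actor not in comp or dyad.partner not in comp:
        raise ValueError(f"dyad {dyad} not within family composition {comp}")
    theta = params.mu[dyad] + effects.f + effects.a[dyad.actor] + effects.p[dyad.partner]
    theta += effects.d[dyad]
    if params.beta1 is not None:
        theta += params.beta1_for(dyad) * t
    return float(theta)


def default_params(
    response_kind: str = CONTINUOUS,
    roles: tuple[str, ...] = ROLES,
    n_categories: int = 4,
) -> SRMParams:
    """A simple valid parameter set over `roles` (unit-ish scales, mild dynamics)."""
    dd = directed_dyads(roles)
    uu = undirected_dyads(roles)
    ordinal = response_kind == ORDINAL
    resid_var = 1.0 if ordinal else 0.8
    params = SRMParams(
        mu={d: (2.5 if ordinal else 3.5) for d in dd},
        phi1={d: 0.2 for d in dd},
        phi2={d: 0.1 for d in dd},
        sigma2_f=0.05,
        Sigma_ap={r: cov2x2(0.15, 0.08, 0.2) for r in roles},
        Sigma_d={u: cov2x2(0.2, 0.2, 0.3) for u in uu},
        Sigma_eta={u: cov2x2(resid_var, resid_var, 0.2) for u in uu},
        Sigma_e1={u: cov2x2(1.0 if ordinal else 0.9, 1.0 if ordinal else 0.9, 0.2) for u in uu},
        thresholds=np.arange(n_categories - 1, dtype=float) * 1.8 if ordinal else None,
        response_kind=response_kind,
    )
    return params
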