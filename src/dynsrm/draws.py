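"""Stored MCMC chains for every model parameter.

Draws are kept as a mapping from flat parameter names (``mu[M.F]``,
``phi1[S1.S2]``, ``rho_eta[M:F]``, ``tau[2]`` ...) to (n_chains, n_stored)
arrays, plus run metadata.  They serialise losslessly to a self-describing
CSV: '#'-prefixed JSON metadata lines, then one column per parameter with
17-significant-digit floats.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .params import SRMParams, cov2x2
from .roles import DirectedDyad, UndirectedDyad

_MAGIC = "# dynsrm-draws v1"


@dataclass
class PosteriorDraws:
    """Chain x stored-iteration arrays per parameter, plus sampler metadata."""

    values: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.values.values()}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent draw shapes: {shapes}")

    # -- access -----------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return list(self.values)

    @property
    def n_chains(self) -> int:
        return next(iter(self.values.values())).shape[0]

    @property
    def n_stored(self) -> int:
        return next(iter(self.values.values())).shape[1]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def chains(self, name: str) -> np.ndarray:
        """(n_chains, n_stored) array for one parameter."""
        try:
            return self.values[name]
        except KeyError:
            raise KeyError(
                f"unknown parameter {name!r}; available: {', '.join(self.names[:8])} ..."
            ) from None

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated into one vector."""
        return self.chains(name).reshape(-1)

    # -- reconstruction ---------------------------------------------------
    def to_params(self, chain: int, draw: int) -> SRMParams:
        """Rebuild a full SRMParams from one stored draw.

        Requires a fit with random effects (``effects='full'``); reduced
        ordered-probit fits carry no variance components to rebuild from.
        """
        if "sigma2_f" not in self.values:
            raise ValueError("draws carry no variance components (reduced fit?)")
        g = lambda name: float(self.values[name][chain, draw])
        roles = self.meta["roles"]
        utypes = [UndirectedDyad.parse(s) for s in self.meta["undirected"]]
        dynamics = self.meta.get("dynamics", "ar_crosslag")
        ordinal = self.meta.get("response_kind") == "ordinal"
        mu, phi1, phi2 = {}, {}, {}
        Sigma_d, Sigma_eta, Sigma_e1 = {}, {}, {}
        for u in utypes:
            ij, ji = u.directed
            for d in (ij, ji):
                mu[d] = g(f"mu[{d}]")
                phi1[d] = g(f"phi1[{d}]") if dynamics != "none" else 0.0
                phi2[d] = g(f"phi2[{d}]") if dynamics == "ar_crosslag" else 0.0
            Sigma_d[u] = cov2x2(g(f"sigma2_d[{ij}]"), g(f"sigma2_d[{ji}]"), g(f"rho_d[{u}]"))
            if f"sigma2_eta[{ij}]" in self.values:
                Sigma_eta[u] = cov2x2(g(f"sigma2_eta[{ij}]"), g(f"sigma2_eta[{ji}]"), g(f"rho_eta[{u}]"))
                Sigma_e1[u] = cov2x2(g(f"sigma2_e1[{ij}]"), g(f"sigma2_e1[{ji}]"), g(f"rho_e1[{u}]"))
            else:  # cross-sectional fit: pair residual absorbed into Sigma_d
                Sigma_eta[u] = np.eye(2)
                Sigma_e1[u] = 1e-8 * np.eye(2)
        Sigma_ap = {
            r: cov2x2(g(f"sigma2_a[{r}]"), g(f"sigma2_p[{r}]"), g(f"rho_ap[{r}]"))
            for r in roles
        }
        tau = None
        if ordinal:
            C = self.meta["n_categories"]
            tau = np.array([g(f"tau[{c}]") for c in range(1, C)])
        beta1 = None
        if self.meta.get("trend"):
            if self.meta.get("trend_scope") == "directed":
                beta1 = {d: g(f"beta1[{d}]") for u in utypes for d in u.directed}
            else:
                beta1 = {u: g(f"beta1[{u}]") for u in utypes}
        return SRMParams(
            mu=mu,
            phi1=phi1,
            phi2=phi2,
            sigma2_f=g("sigma2_f"),
            Sigma_ap=Sigma_ap,
            Sigma_d=Sigma_d,
            Sigma_eta=Sigma_eta,
            Sigma_e1=Sigma_e1,
            thresholds=tau,
            response_kind="ordinal" if ordinal else "continuous",
            beta1=beta1,
        )

    # -- serialisation ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        m, n = self.n_chains, self.n_stored
        cols = {
            "chain": np.repeat(np.arange(m), n),
            "draw": np.tile(np.arange(n), m),
        }
        for name, arr in self.values.items():
            cols[name] = arr.reshape(-1)
        return pd.DataFrame(cols)

    def save_csv(self, path) -> None:
        buf = io.StringIO()
        buf.write(_MAGIC + "\n")
        buf.write("# meta: " + json.dumps(self.meta, default=str) + "\n")
        self.to_frame().to_csv(buf, index=False, float_format="%.17g")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def load_csv(cls, path) -> "PosteriorDraws":
        with open(path) as fh:
            first = fh.readline().rstrip("\n")
            if first != _MAGIC:
                raise ValueError(f"{path}: not a dynsrm draws file")
            second = fh.readline().rstrip("\n")
            meta = json.loads(second.removeprefix("# meta: "))
            df = pd.read_csv(fh, float_precision="round_trip")
        m = int(df["chain"].max()) + 1
        n = int(df["draw"].max()) + 1
        values = {
            c: df[c].to_numpy().reshape(m, n)
            for c in df.columns
            if c not in ("chain", "draw")
        }
        return cls(values=values, meta=meta)
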