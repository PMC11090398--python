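"""Model and results objects for the dynamic social relations model.

Usage follows the familiar model/results pattern::

    model = DynamicSRM(panel, dynamics="ar_crosslag")
    res = model.fit(n_chains=4, n_burnin=1000, n_iter=2000, seed=1)
    print(res.summary())
    res.time_invariant_shares("M.F")

`DynamicSRM` owns the (pair-rule cleaned) data and the model variant;
`fit()` runs the blocked Gibbs sampler and returns a `DynamicSRMResults`
carrying the posterior draws, convergence diagnostics and the derived-
quantity methods (variance shares, extended VPCs, contrasts).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, replace

import numpy as np
import pandas as pd

from . import postprocess
from .data import PanelDataset, apply_pair_deletion
from .diagnostics import DEFAULT_MIN_ESS, DEFAULT_PSRF_TOL, DiagnosticsReport, diagnose
from .draws import PosteriorDraws
from .params import ORDINAL
from .roles import DirectedDyad
from .sampler import FitConfig, GibbsSampler

logger = logging.getLogger("dynsrm")


def fit(data: PanelDataset, config: FitConfig, prior_only: bool = False) -> PosteriorDraws:
    """Run the MCMC sampler and return the stored chains.

    ``prior_only`` drops every likelihood contribution, so the draws come
    from the prior (useful for prior-predictive checks).
    """
    sampler = GibbsSampler(data, config, prior_only=prior_only)
    per_chain = [sampler.run_chain(c) for c in range(config.n_chains)]
    names = sampler.param_names()
    values = {
        nm: np.stack([ch[nm] for ch in per_chain], axis=0) for nm in names
    }
    plan = sampler.plan
    meta = {
        "roles": plan.roles,
        "undirected": [str(u) for u in plan.utypes],
        "response_kind": config.response_kind,
        "n_categories": getattr(plan, "C", None),
        "dynamics": config.dynamics,
        "trend": config.trend,
        "trend_scope": config.trend_scope,
        "effects": config.effects,
        "seed": config.seed,
        "n_chains": config.n_chains,
        "n_stored": config.n_stored,
        "thin": config.thin,
        "prior_only": prior_only,
        "cross_sectional": sampler.cross_sectional,
        "config": {k: v for k, v in asdict(config).items()},
        "mh_acceptance": (
            (sampler.mh_accept / np.maximum(sampler.mh_tries, 1)).round(3).tolist()
            if config.response_kind == ORDINAL
            else None
        ),
    }
    return PosteriorDraws(values=values, meta=meta)


class DynamicSRM:
    """Dynamic social relations model for one panel dataset.

    Parameters
    ----------
    data : PanelDataset (the both-or-neither pair rule is applied on entry;
        the number of additionally removed records is logged and stored).
    dynamics : "none", "ar" (autoregressive only) or "ar_crosslag".
    trend : include a linear snapshot trend in the latent mean.
    trend_scope : "undirected" (slope shared by both directions, default)
        or "directed".
    effects : "full" SRM random effects, or "none" for the ordered-probit /
        Gaussian regression reduction.
    """

    def __init__(
        self,
        data: PanelDataset,
        response_kind: str | None = None,
        dynamics: str = "ar_crosslag",
        trend: bool = False,
        trend_scope: str = "undirected",
        effects: str = "full",
    ):
        data.validate()
        self.data, self.n_pair_deleted = apply_pair_deletion(data)
        if self.n_pair_deleted:
            logger.info(
                "pair deletion: flagged %d additional records missing", self.n_pair_deleted
            )
        self.response_kind = response_kind or data.response_kind
        self.dynamics = dynamics
        self.trend = trend
        self.trend_scope = trend_scope
        self.effects = effects

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        response_kind: str = "continuous",
        n_categories: int | None = None,
        **kwargs,
    ) -> "DynamicSRM":
        data = PanelDataset(df, response_kind=response_kind, n_categories=n_categories)
        return cls(data, **kwargs)

    def make_config(self, **overrides) -> FitConfig:
        base = dict(
            response_kind=self.response_kind,
            dynamics=self.dynamics,
            trend=self.trend,
            trend_scope=self.trend_scope,
            effects=self.effects,
        )
        base.update(overrides)
        return FitConfig(**base)

    def fit(self, config: FitConfig | None = None, **overrides) -> "DynamicSRMResults":
        if config is None:
            config = self.make_config(**overrides)
        elif overrides:
            config = replace(config, **overrides)
        draws = fit(self.data, config)
        return DynamicSRMResults(self, draws, config)

    def sample_prior(self, config: FitConfig | None = None, **overrides) -> PosteriorDraws:
        """Draws from the prior (empty-likelihood run) for predictive checks."""
        if config is None:
            config = self.make_config(**overrides)
        return fit(self.data, config, prior_only=True)


class DynamicSRMResults:
    """Posterior draws plus post-processing for a fitted dynamic SRM."""

    def __init__(self, model: DynamicSRM, draws: PosteriorDraws, config: FitConfig):
        self.model = model
        self.draws = draws
        self.config = config

    # -- summaries --------------------------------------------------------
    def summary(self, names: list[str] | None = None) -> pd.DataFrame:
        """Posterior mean, 95% interval and significance flag per parameter."""
        return postprocess.summarise(self.draws, names)

    def time_invariant_shares(self, dyad: DirectedDyad | str) -> pd.DataFrame:
        return postprocess.time_invariant_shares(self.draws, dyad)

    def share_table(self) -> pd.DataFrame:
        return postprocess.share_table(self.draws)

    def vpc_total(self, dyad: DirectedDyad | str) -> tuple[pd.DataFrame, int]:
        return postprocess.vpc_total(self.draws, dyad)

    def contrast(self, name_a: str, name_b: str, absolute: bool = False) -> pd.DataFrame:
        return postprocess.contrast(self.draws, name_a, name_b, absolute=absolute)

    def diagnostics(
        self,
        psrf_tol: float = DEFAULT_PSRF_TOL,
        min_ess: float = DEFAULT_MIN_ESS,
        split: bool = False,
    ) -> DiagnosticsReport:
        return diagnose(self.draws.values, psrf_tol=psrf_tol, min_ess=min_ess, split=split)

    # -- persistence / plotting ------------------------------------------
    def save(self, path) -> None:
        self.draws.save_csv(path)

    def plot_trace(self, names: list[str], path=None):
        """Minimal trace plots (one panel per parameter)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(len(names), 1, figsize=(8, 2 * len(names)), squeeze=False)
        for ax, nm in zip(axes[:, 0], names):
            for c in range(self.draws.n_chains):
                ax.plot(self.draws.chains(nm)[c], lw=0.5)
            ax.set_ylabel(nm)
        if path is not None:
            fig.savefig(path, dpi=100)
            plt.close(fig)
        return fig
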