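"""Convergence assessment for stored MCMC chains.

Implements the classic (non-split, non-rank-normalised) Gelman–Rubin
potential scale reduction factor and an autocorrelation-based effective
sample size with initial-monotone-sequence truncation — the estimators of
the generic Gibbs-sampling era this model class was developed with.  A
split-chain PSRF variant is available by flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default pass thresholds: PSRF within 0.05 of 1 and ESS of at least 1,500,
#: the run quality a long production chain is expected to reach.
DEFAULT_PSRF_TOL = 0.05
DEFAULT_MIN_ESS = 1500.0


def _as_chains(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2:
        raise ValueError("chains must be a (n_chains, n_draws) array")
    return x


def psrf(chains: np.ndarray, split: bool = False) -> float:
    """Gelman–Rubin potential scale reduction factor.

    Parameters
    ----------
    chains : (n_chains, n_draws) array, equal lengths, n_chains >= 2.
    split : split each chain in half first (halves treated as chains).
    """
    x = _as_chains(chains)
    if split:
        n = x.shape[1] // 2
        x = np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)
    m, n = x.shape
    if m < 2:
        raise ValueError("psrf requires at least 2 chains")
    if n < 2:
        raise ValueError("psrf requires chains of length >= 2")
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = x.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0 if B_over_n <= 0 else np.inf
    var_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_hat / W))


def _autocorr(y: np.ndarray) -> np.ndarray:
    """Biased sample autocorrelation of one chain via FFT."""
    n = len(y)
    y = y - y.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(y, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n] / n
    if acov[0] <= 0:
        return np.zeros(n)
    return acov / acov[0]


def ess(chains: np.ndarray) -> float:
    """Effective sample size with initial-monotone-sequence truncation.

    Autocorrelations are averaged across chains; successive pair sums
    rho_{2t} + rho_{2t+1} are kept while positive and monotonically
    non-increasing.  A constant chain is reported as fully efficient with a
    warning.
    """
    x = _as_chains(chains)
    m, n = x.shape
    total = m * n
    if total == 1:
        return 1.0
    if np.allclose(x, x.flat[0]):
        warnings.warn("constant chain: effective sample size set to the draw count")
        return float(total)
    rho = np.mean([_autocorr(c) for c in x], axis=0)
    # Geyer initial positive monotone sequence on pair sums
    # Gamma_k = rho_{2k} + rho_{2k+1}; tau = 2 * sum_k Gamma_k - 1
    gamma_sum = 0.0
    prev = np.inf
    t = 0
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev)
        gamma_sum += pair
        prev = pair
        t += 2
    tau = max(2.0 * gamma_sum - 1.0, 1.0 / total)
    return float(min(total, total / tau))


@dataclass
class DiagnosticsReport:
    """Per-parameter convergence table with pass/fail flags."""

    table: pd.DataFrame
    psrf_tol: float = DEFAULT_PSRF_TOL
    min_ess: float = DEFAULT_MIN_ESS

    @property
    def all_ok(self) -> bool:
        return bool(self.table["ok"].all())

    def __str__(self) -> str:
        lines = [
            f"convergence report (PSRF tolerance 1±{self.psrf_tol}, min ESS {self.min_ess:g})",
            self.table.to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        if not self.all_ok:
            bad = self.table.index[~self.table["ok"]]
            lines.append(f"flagged parameters: {', '.join(bad)}")
        return "\n".join(lines)


def diagnose(
    chains_by_name: dict[str, np.ndarray],
    psrf_tol: float = DEFAULT_PSRF_TOL,
    min_ess: float = DEFAULT_MIN_ESS,
    split: bool = False,
) -> DiagnosticsReport:
    rows = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, ch in chains_by_name.items():
            ch = _as_chains(ch)
            r = psrf(ch, split=split) if ch.shape[0] >= 2 else np.nan
            e = ess(ch)
            ok = (abs(r - 1.0) <= psrf_tol if np.isfinite(r) else False) and e >= min_ess
            rows[name] = {"psrf": r, "ess": e, "ok": ok}
    table = pd.DataFrame.from_dict(rows, orient="index")
    return DiagnosticsReport(table, psrf_tol=psrf_tol, min_ess=min_ess)
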