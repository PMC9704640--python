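"""Posterior summaries, correlations and model-adequacy diagnostics.

Credible intervals are central-mass intervals around the median: CI68
encloses 68.28% of the chain mass (the Gaussian 1-sigma mass) and CI95
encloses 95.45% (2-sigma), computed from empirical quantiles with linear
interpolation.  This keeps the reported interval inside the variable's
[0, 1] domain by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .sampler import MarkovChain

__all__ = [
    "PosteriorSummary",
    "DiagnosticsReport",
    "summarize",
    "correlation_matrix",
    "z_score",
    "z_to_probability",
    "two_chain_convergence",
]

CI68_MASS = 0.6828
CI95_MASS = 0.9545


@dataclass
class PosteriorSummary:
    """Per-variable posterior table and pairwise Pearson correlations.

    ``table`` rows are variables (``f_<source>`` then aux variables) with
    columns mean, median, sd, ci68_low/high, ci95_low/high.  Correlations
    of zero-variance variables are reported as NaN (undefined), never 0.
    """

    table: pd.DataFrame
    correlation: pd.DataFrame
    n_entries: int

    def __getitem__(self, variable: str) -> pd.Series:
        return self.table.loc[variable]


@dataclass
class DiagnosticsReport:
    """Model-adequacy diagnostics for one chain."""

    z: dict[str, float]
    rejection_probability: dict[str, float]
    z_n_free: dict[str, float] = field(default_factory=dict)
    acceptance_rate: float = float("nan")
    converged: bool | None = None


def _ci(values: np.ndarray, mass: float) -> tuple[float, float]:
    lo, hi = np.quantile(values, [0.5 - mass / 2.0, 0.5 + mass / 2.0])
    return float(lo), float(hi)


def summarize(chain: MarkovChain | dict[str, np.ndarray]) -> PosteriorSummary:
    """Posterior mean/median/sd and central credible intervals per variable."""
    variables = chain.variables() if isinstance(chain, MarkovChain) else dict(chain)
    if not variables or any(np.size(v) == 0 for v in variables.values()):
        raise ValueError("cannot summarize an empty chain")
    rows = {}
    for name, vals in variables.items():
        vals = np.asarray(vals, dtype=float)
        lo68, hi68 = _ci(vals, CI68_MASS)
        lo95, hi95 = _ci(vals, CI95_MASS)
        rows[name] = {
            "mean": float(vals.mean()),
            "median": float(np.median(vals)),
            "sd": float(vals.std(ddof=0)),
            "ci68_low": lo68,
            "ci68_high": hi68,
            "ci95_low": lo95,
            "ci95_high": hi95,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    corr = correlation_matrix(variables)
    n = len(next(iter(variables.values())))
    return PosteriorSummary(table=table, correlation=corr, n_entries=n)


def correlation_matrix(chain: MarkovChain | dict[str, np.ndarray]) -> pd.DataFrame:
    """Pearson correlation of every variable pair over chain entries.

    Zero-variance variables yield NaN off-diagonal entries (undefined
    correlation) rather than a misleading 0.
    """
    variables = chain.variables() if isinstance(chain, MarkovChain) else dict(chain)
    names = list(variables)
    X = np.column_stack([np.asarray(variables[n], dtype=float) for n in names])
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("correlation needs at least 2 entries and 2 variables")
    sd = X.std(axis=0)
    out = np.full((len(names), len(names)), np.nan)
    ok = sd > 0
    if ok.any():
        with np.errstate(invalid="ignore"):
            sub = np.corrcoef(X[:, ok], rowvar=False)
        out[np.ix_(ok, ok)] = np.atleast_2d(sub)
    np.fill_diagonal(out, 1.0)
    return pd.DataFrame(out, index=names, columns=names)


def z_score(x, mu_chain, spread=None) -> np.ndarray:
    """Standardised distance between measurement and chain-mean prediction.

    ``z_i = |x_i - mean(mu_i)| / (sd(mu_i)/sqrt(N))``, set to zero whenever
    the chain-mean prediction lies inside the band ``x_i ± spread_i``; when
    outside, the distance to the nearest band edge is used.  Scales with
    chain length N (a standard-error test of model adequacy).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    mu_chain = np.atleast_2d(np.asarray(mu_chain, dtype=float))
    n = mu_chain.shape[0]
    if n < 2:
        raise ValueError("z_score needs at least 2 chain entries")
    spread = np.zeros_like(x) if spread is None else np.atleast_1d(np.asarray(spread, float))
    mu_bar = mu_chain.mean(axis=0)
    se = mu_chain.std(axis=0, ddof=0) / np.sqrt(n)
    diff = np.abs(x - mu_bar)
    edge = np.minimum(np.abs(x - mu_bar - spread), np.abs(x - mu_bar + spread))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(diff <= spread, 0.0, edge / se)
    return z


def z_to_probability(z) -> np.ndarray:
    """Two-sided normal rejection probability 1 - P(x|model) = erf(z/sqrt(2));
    z = 2 gives 0.9545, z = 3 gives 0.9973."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("z must be >= 0")
    out = erf(z / np.sqrt(2.0))
    return float(out) if out.ndim == 0 else out


def diagnostics(chain: MarkovChain, measurement) -> DiagnosticsReport:
    """z-score adequacy report for one sampled measurement.

    Uses the chain of predicted signatures and the chain-mean spread as the
    ±Δ band.  Also reports the chain-length-free ratio |x - mean| / sd as
    supplementary context (labelled ``z_n_free``).
    """
    labels = chain.signature_labels
    spread_bar = chain.spread.mean(axis=0)
    z = z_score(measurement.x, chain.mu, spread_bar)
    mu_bar = chain.mu.mean(axis=0)
    sd = chain.mu.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nfree = np.where(sd > 0, np.abs(measurement.x - mu_bar) / sd, np.inf)
    return DiagnosticsReport(
        z={lab: float(z[i]) for i, lab in enumerate(labels)},
        rejection_probability={lab: float(z_to_probability(z[i])) for i, lab in enumerate(labels)},
        z_n_free={lab: float(nfree[i]) for i, lab in enumerate(labels)},
        acceptance_rate=chain.acceptance_rate,
    )


def _batch_se(values: np.ndarray, n_batches: int = 32) -> float:
    """Batch-means standard error of the chain mean.

    A Metropolis chain repeats its current state on rejection, so entries
    are autocorrelated and the naive sd/sqrt(N) understates the error of
    the mean; batch means absorb the correlation.
    """
    n = values.size
    if n < 2 * n_batches:
        return float(values.std(ddof=0) / np.sqrt(n))
    usable = n - n % n_batches
    means = values[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def two_chain_convergence(chain_a: MarkovChain, chain_b: MarkovChain,
                          threshold: float = 3.0) -> tuple[bool, dict[str, float]]:
    """Two-sample z-test comparing per-variable means of independent chains.

    ``z = |mean_a - mean_b| / sqrt(se_a² + se_b²)`` with batch-means
    standard errors (robust to the rejection-duplicate autocorrelation);
    the pair is flagged non-converged if any variable exceeds ``threshold``.
    """
    va, vb = chain_a.variables(), chain_b.variables()
    if set(va) != set(vb):
        raise ValueError("chains do not share the same variables")
    zs: dict[str, float] = {}
    for name in va:
        a, b = np.asarray(va[name], float), np.asarray(vb[name], float)
        denom = np.sqrt(_batch_se(a) ** 2 + _batch_se(b) ** 2)
        diff = abs(a.mean() - b.mean())
        zs[name] = 0.0 if diff == 0 else (float("inf") if denom == 0 else float(diff / denom))
    return all(z <= threshold for z in zs.values()), zs
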