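"""Independence Metropolis-Hastings sampler on the mixing simplex.

Proposals are drawn independently of the current state: mixing fractions
from a Dirichlet distribution (flat by default), auxiliary variables from
their uniform priors, and auxiliary parameters redrawn from their Gaussians
(so the chain marginalises over parameter uncertainty).  A proposal with
likelihood L is accepted when ``L >= alpha * T`` with ``alpha ~ U(0, 1)``
and ``T`` the likelihood of the current state, updated to ``L`` on
acceptance — exactly the textbook independence-Metropolis acceptance
probability ``min(1, L_new / L_current)`` realised through a running
threshold.  On rejection the current state is recorded again, which is what
makes the chain sample the posterior; ``accepted_only=True`` records only
distinct accepted states (a thinner, flatter chain kept for comparison with
implementations that drop rejections).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import mixed_likelihood
from .model_core import Measurement, MixingState, ModelSpec

__all__ = [
    "SamplerConfig",
    "SamplerState",
    "MarkovChain",
    "ChainError",
    "BatchItem",
    "propose_state",
    "metropolis_accept",
    "run_chain",
    "run_batch",
]


class ChainError(RuntimeError):
    """Sampling failed for a structural reason (e.g. unreachable data)."""


@dataclass
class SamplerConfig:
    """Sampler settings.

    chain_length : recorded post-burn-in entries to collect.
    burn_in : accepted states discarded before recording starts.
    max_iterations : hard cap on proposal draws.
    dirichlet_alpha : Dirichlet concentration for fraction proposals
        (all-ones = flat prior on the simplex).
    accepted_only : record only distinct accepted states instead of the
        full Metropolis chain (see module docstring).
    """

    chain_length: int = 10_000
    burn_in: int = 1_000
    max_iterations: int = 2_000_000
    dirichlet_alpha: np.ndarray | None = None
    seed: int | None = None
    accepted_only: bool = False
    block_size: int = 65_536

    def __post_init__(self):
        if self.chain_length < 1:
            raise ValueError("chain_length must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.max_iterations <= self.chain_length:
            raise ValueError("max_iterations must exceed chain_length")
        if self.dirichlet_alpha is not None:
            self.dirichlet_alpha = np.atleast_1d(np.asarray(self.dirichlet_alpha, dtype=float))
            if np.any(self.dirichlet_alpha <= 0):
                raise ValueError("dirichlet_alpha must be > 0 elementwise")

    def alpha_for(self, m: int) -> np.ndarray:
        if self.dirichlet_alpha is None:
            return np.ones(m)
        if self.dirichlet_alpha.size != m:
            raise ValueError(
                f"dirichlet_alpha has length {self.dirichlet_alpha.size}, expected {m}"
            )
        return self.dirichlet_alpha


@dataclass
class SamplerState:
    """Running acceptance state: current threshold T (last accepted
    likelihood, initialised at 0 so the first positive proposal is always
    accepted) and the iteration counter."""

    T: float = 0.0
    iteration: int = 0

    def __post_init__(self):
        if self.T < 0:
            raise ValueError("threshold T must be >= 0")


@dataclass
class MarkovChain:
    """Recorded chain over (f, r) with per-entry model predictions."""

    f: np.ndarray                      # (N, m)
    r: np.ndarray                      # (N, k)
    likelihood: np.ndarray             # (N,)
    mu: np.ndarray                     # (N, n) predicted signatures
    spread: np.ndarray                 # (N, n) predicted band half-widths
    source_names: list[str]
    var_names: list[str]
    signature_labels: list[str]
    burn_in: int = 0
    n_iterations: int = 0
    n_accepted: int = 0
    complete: bool = True
    seed: int | None = None

    def __len__(self) -> int:
        return self.f.shape[0]

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_iterations if self.n_iterations else float("nan")

    def variables(self) -> dict[str, np.ndarray]:
        """Chain per named variable: fractions then auxiliary variables."""
        out = {f"f_{name}": self.f[:, j] for j, name in enumerate(self.source_names)}
        out.update({name: self.r[:, k] for k, name in enumerate(self.var_names)})
        return out

    def to_dataframe(self) -> pd.DataFrame:
        data = {"entry": np.arange(len(self))}
        data.update(self.variables())
        data["likelihood"] = self.likelihood
        for i, lab in enumerate(self.signature_labels):
            data[f"mu_{lab}"] = self.mu[:, i]
        return pd.DataFrame(data)

    def states(self):
        """Iterate entries as MixingState objects (mainly for inspection)."""
        for i in range(len(self)):
            yield MixingState(f=self.f[i], r=self.r[i], likelihood=float(self.likelihood[i]))


@dataclass
class BatchItem:
    """Per-sample result of a batch run; exactly one of chain/error is set."""

    sample_id: str
    chain: MarkovChain | None = None
    error: Exception | None = None

    @property
    def ok(self) -> bool:
        return self.chain is not None


def propose_state(model: ModelSpec, config: SamplerConfig, rng: np.random.Generator,
                  measurement: Measurement | None = None) -> MixingState:
    """Draw one independent proposal (f from Dirichlet, r from its priors)."""
    f = np.ones(1) if model.m == 1 else rng.dirichlet(config.alpha_for(model.m))
    r = np.array([rng.uniform(v.prior_low, v.prior_high) for v in model.aux_vars])
    like = 0.0
    if measurement is not None:
        rd = {v.name: np.array([r[k]]) for k, v in enumerate(model.aux_vars)}
        like = float(model.likelihood_of(measurement, f[None, :], r=rd,
                                         params=model.draw_params(rng, 1))[0])
    return MixingState(f=f, r=r, likelihood=like)


def metropolis_accept(L: float, state: SamplerState, alpha: float) -> tuple[bool, float]:
    """Threshold acceptance: accept iff ``L >= alpha * T``; T := L on
    acceptance (equivalent to independence-MH acceptance min(1, L/T))."""
    if L < 0:
        raise ValueError("likelihood must be nonnegative")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if L >= alpha * state.T:
        return True, float(L)
    return False, state.T


def run_chain(model: ModelSpec, measurement: Measurement, config: SamplerConfig | None = None,
              rng: np.random.Generator | None = None) -> MarkovChain:
    """Sample the posterior over (f, r) for one measurement.

    Proposals are evaluated in vectorised blocks; the sequential acceptance
    scan preserves the exact Markov dependence.  Deterministic for a given
    seed.  Raises :class:`ChainError` if no proposal is ever accepted
    within ``max_iterations`` (the measurement is unreachable under the
    model — check the z-score diagnostic / mixing polygon).
    """
    config = config or SamplerConfig()
    if measurement.n != model.n:
        raise ValueError(
            f"measurement {measurement.id!r} has {measurement.n} signatures, "
            f"model expects {model.n}"
        )
    rng = rng or np.random.default_rng(config.seed)
    alpha_dir = config.alpha_for(model.m)
    k = len(model.aux_vars)
    lows = np.array([v.prior_low for v in model.aux_vars])
    highs = np.array([v.prior_high for v in model.aux_vars])

    # all accepted states (including burn-in) stored once; recorded entries
    # reference them by index so rejection-duplicates cost no memory
    acc_f, acc_r, acc_L, acc_mu, acc_spread = [], [], [], [], []
    entry_ids: list[int] = []

    T = 0.0
    n_acc = 0
    it = 0
    cur = -1  # index of current state in accepted store
    target = config.chain_length
    while len(entry_ids) < target and it < config.max_iterations:
        B = min(config.block_size, config.max_iterations - it)
        F = np.ones((B, 1)) if model.m == 1 else rng.dirichlet(alpha_dir, size=B)
        R = rng.uniform(lows, highs, size=(B, k)) if k else np.empty((B, 0))
        r_dict = {v.name: R[:, j] for j, v in enumerate(model.aux_vars)}
        params = model.draw_params(rng, B)
        ev = model.evaluate(F, r=r_dict, params=params)
        sigma_tot = np.sqrt(ev.sigma**2 + measurement.sigma_x**2)
        L = mixed_likelihood(measurement.x, ev.mu, sigma_tot, ev.spread)
        alphas = rng.uniform(size=B)
        record_rejections = not config.accepted_only
        for i in range(B):
            it += 1
            Li = L[i]
            if Li >= alphas[i] * T and Li > 0.0:
                T = Li
                n_acc += 1
                acc_f.append(F[i]); acc_r.append(R[i]); acc_L.append(Li)
                acc_mu.append(ev.mu[i]); acc_spread.append(ev.spread[i])
                cur = len(acc_f) - 1
                if n_acc > config.burn_in:
                    entry_ids.append(cur)
            elif record_rejections and n_acc > config.burn_in and cur >= 0:
                entry_ids.append(cur)
            if len(entry_ids) >= target:
                break

    if n_acc == 0:
        raise ChainError(
            f"no proposal accepted in {it} iterations for sample {measurement.id!r}: "
            "the model cannot reach the measurement (zero likelihood everywhere "
            "probed); check the mixing polygon and the z-score diagnostic"
        )

    ids = np.asarray(entry_ids, dtype=int)
    store_f = np.asarray(acc_f)
    store_r = np.asarray(acc_r) if k else np.empty((len(acc_f), 0))
    chain = MarkovChain(
        f=store_f[ids],
        r=store_r[ids],
        likelihood=np.asarray(acc_L)[ids],
        mu=np.asarray(acc_mu)[ids],
        spread=np.asarray(acc_spread)[ids],
        source_names=model.source_names,
        var_names=model.var_names,
        signature_labels=list(model.signatures.labels),
        burn_in=min(n_acc, config.burn_in),
        n_iterations=it,
        n_accepted=n_acc,
        complete=len(entry_ids) >= target,
        seed=config.seed,
    )
    return chain


def run_batch(model: ModelSpec, measurements: list[Measurement],
              config: SamplerConfig | None = None) -> list[BatchItem]:
    """Run independent chains for several measurements of one model.

    Per-sample seeds derive deterministically from the base seed and the
    sample index, so a batch is reproducible and order-stable.  Failures are
    reported per sample, never aborting the batch.
    """
    config = config or SamplerConfig()
    results: list[BatchItem] = []
    base = np.random.SeedSequence(config.seed)
    for i, meas in enumerate(measurements):
        child = np.random.SeedSequence(entropy=base.entropy, spawn_key=(i,))
        rng = np.random.default_rng(child)
        try:
            chain = run_chain(model, meas, config, rng=rng)
            results.append(BatchItem(sample_id=meas.id or str(i), chain=chain))
        except (ChainError, ValueError) as e:
            results.append(BatchItem(sample_id=meas.id or str(i), error=e))
    return results
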