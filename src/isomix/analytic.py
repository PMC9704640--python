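"""Closed-form mixing solvers and error propagation.

These are exact solutions for the algebraically solvable cases (m sources,
n signatures, m = n + 1): two sources on one signature, and the general
square linear system.  They double as independent oracles for validating
the MCMC sampler in the small-uncertainty limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AnalyticSolution",
    "solve_two_source_1d",
    "propagate_sigma_1d",
    "range_bounds_1d",
    "solve_n_sources",
    "invert_evaporation",
]


@dataclass
class AnalyticSolution:
    """Closed-form result: fractions, optional propagated sd, optional
    per-fraction (lo, hi) bounds for range-mode inputs, feasibility flag."""

    fractions: np.ndarray
    sigma: np.ndarray | None = None
    bounds: list[tuple[float, float]] | None = None
    feasible: bool = True


def solve_two_source_1d(x: float, S1: float, S2: float) -> tuple[float, float]:
    """Exact two-source mass balance on one signature.

    ``f1 = (S2 - x)/(S2 - S1)``, ``f2 = (x - S1)/(S2 - S1)``; f1 + f2 = 1.
    """
    if S1 == S2:
        raise ZeroDivisionError("sources have identical signatures: system is singular")
    f1 = (S2 - x) / (S2 - S1)
    return f1, 1.0 - f1


def propagate_sigma_1d(x, S1, S2, sigma_x, dS1, dS2) -> tuple[float, float]:
    """First-order (delta-method) sd of the two-source fractions.

    ``sigma_f1² = (∂f1/∂x)² σx² + (∂f1/∂S1)² dS1² + (∂f1/∂S2)² dS2²`` with
    ``∂f1/∂x = -1/(S2-S1)``, ``∂f1/∂S1 = (S2-x)/(S2-S1)²``,
    ``∂f1/∂S2 = (x-S1)/(S2-S1)²``.  f1 + f2 = 1 forces σf1 = σf2.
    """
    if S1 == S2:
        raise ZeroDivisionError("sources have identical signatures: system is singular")
    if min(sigma_x, dS1, dS2) < 0:
        raise ValueError("uncertainties must be >= 0")
    den = S2 - S1
    var = (sigma_x / den) ** 2 + ((S2 - x) / den**2) ** 2 * dS1**2 \
        + ((x - S1) / den**2) ** 2 * dS2**2
    s = float(np.sqrt(var))
    return s, s


def range_bounds_1d(x, S1, dS1, S2, dS2) -> AnalyticSolution:
    """Feasible f1/f2 intervals when both sources are uniform ranges.

    The extreme fractions are attained at the range corners: f1 is smallest
    when S2 sits at its low edge and S1 at its low edge, and largest at the
    opposite corner (assuming x between the ranges); the returned intervals
    are clipped to [0, 1].  ``feasible=False`` marks a measurement outside
    the attainable envelope.
    """
    if min(dS1, dS2) < 0:
        raise ValueError("half-ranges must be >= 0")
    lo_den = S2 - dS2 - S1 + dS1
    hi_den = S2 + dS2 - S1 - dS1
    if lo_den == 0 or hi_den == 0:
        raise ZeroDivisionError("source ranges touch: interval bounds are singular")
    f1_lo = (S2 - dS2 - x) / lo_den
    f1_hi = (S2 + dS2 - x) / hi_den
    f2_lo = (x - S1 - dS1) / hi_den
    f2_hi = (x - S1 + dS1) / lo_den
    f1_lo, f1_hi = sorted((f1_lo, f1_hi))
    f2_lo, f2_hi = sorted((f2_lo, f2_hi))
    feasible = f1_hi >= 0 and f1_lo <= 1 and f2_hi >= 0 and f2_lo <= 1
    clip = lambda v: float(min(1.0, max(0.0, v)))
    point = solve_two_source_1d(x, S1, S2)
    return AnalyticSolution(
        fractions=np.asarray(point),
        bounds=[(clip(f1_lo), clip(f1_hi)), (clip(f2_lo), clip(f2_hi))],
        feasible=feasible,
    )


def solve_n_sources(x, S) -> AnalyticSolution:
    """Solve the square mass-balance system for m = n + 1 sources.

    Stacks the signature equations with the closure ``sum f = 1`` and solves
    ``[S^T; 1] f = [x; 1]``.  A solution with any fraction outside [0, 1]
    (measurement outside the mixing polygon) is returned with
    ``feasible=False`` but still sums to 1.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    S = np.atleast_2d(np.asarray(S, dtype=float))  # (m, n)
    m, n = S.shape
    if m > n + 1:
        raise ValueError(
            f"{m} sources with {n} signatures admit no unique solution; use the sampler"
        )
    if m < n + 1:
        raise ValueError(f"system is overdetermined ({m} sources, {n} signatures)")
    A = np.vstack([S.T, np.ones(m)])
    b = np.concatenate([x, [1.0]])
    try:
        f = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("sources are collinear: mixing system is singular") from None
    feasible = bool(np.all((f >= -1e-12) & (f <= 1 + 1e-12)))
    return AnalyticSolution(fractions=f, feasible=feasible)


def invert_evaporation(mu, mu0, A, D) -> float:
    """Closed-form evaporation-to-inflow ratio from the Craig-Gordon form.

    Inverts ``mu = (r A D + mu0)/(r A + 1)`` to ``r = (mu - mu0)/(A (D - mu))``;
    round-trips with the forward model to machine precision.
    """
    den = A * (D - mu)
    if den == 0:
        raise ZeroDivisionError("A*(D - mu) = 0: evaporation model not invertible here")
    return (mu - mu0) / den
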