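"""Likelihood of a measurement given a model prediction.

Point-mode sources yield a Gaussian likelihood whose width combines the
sample sd with the fraction-weighted source sds.  Range-mode sources yield
an erf-shaped plateau: the convolution of the analytical Gaussian with the
uniform band of predicted values ``mu ± spread``.  Sampling uses the
un-normalised forms (constant factors cancel in the acceptance ratio);
``normalized=True`` exposes proper densities for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

__all__ = [
    "ModelEvaluation",
    "gaussian_likelihood",
    "range_likelihood",
    "mixed_likelihood",
    "combine_sigma",
    "compute_spread",
]

_SQRT2 = np.sqrt(2.0)
_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass
class ModelEvaluation:
    """Forward-model output per state: predicted delta vector ``mu``,
    effective sd ``sigma`` and uniform-band half-width ``spread`` (all ‰,
    per signature, batched on the leading axis)."""

    mu: np.ndarray
    sigma: np.ndarray
    spread: np.ndarray


def _check_sigma(sigma) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0 elementwise")
    return sigma


def gaussian_likelihood(x, mu, sigma) -> np.ndarray:
    """Product over signatures of normal densities N(x; mu, sigma).

    ``x`` is the measured delta vector ``(n,)``; ``mu``/``sigma`` may carry a
    leading batch axis.  Returns a scalar or ``(N,)`` array.
    """
    sigma = _check_sigma(sigma)
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    dens = np.exp(-((x - mu) ** 2) / (2.0 * sigma**2)) / (sigma * _SQRT2PI)
    return dens.prod(axis=-1) if dens.ndim else float(dens)


def range_likelihood(x, mu, sigma, spread, normalized=False) -> np.ndarray:
    """Uniform-band likelihood: Gaussian analytics convolved with the band
    ``mu ± spread``.

    Per signature the un-normalised value is
    ``erf((x - mu + Δ)/(σ√2)) - erf((x - mu - Δ)/(σ√2))`` — the upper
    argument uses ``+Δ`` so the difference is nonnegative.  With
    ``normalized=True`` the value is divided by ``4Δ`` giving a proper
    density (and the Gaussian density in the ``Δ = 0`` limit).
    """
    sigma = _check_sigma(sigma)
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    spread = np.asarray(spread, dtype=float)
    if np.any(spread < 0):
        raise ValueError("spread must be >= 0")
    z = (x - mu) / (sigma * _SQRT2)
    d = spread / (sigma * _SQRT2)
    val = erf(z + d) - erf(z - d)
    if normalized:
        dens = np.where(
            spread > 0,
            val / np.where(spread > 0, 4.0 * spread, 1.0),
            np.exp(-((x - mu) ** 2) / (2.0 * sigma**2)) / (sigma * _SQRT2PI),
        )
        return dens.prod(axis=-1) if dens.ndim else float(dens)
    return val.prod(axis=-1) if val.ndim else float(val)


def mixed_likelihood(x, mu, sigma, spread) -> np.ndarray:
    """Per-signature automatic form: erf band where ``spread > 0`` (range
    sources present on that signature), Gaussian density otherwise.
    Un-normalised, as used in the acceptance ratio."""
    sigma = _check_sigma(sigma)
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    spread = np.asarray(spread, dtype=float)
    z = (x - mu) / (sigma * _SQRT2)
    d = spread / (sigma * _SQRT2)
    gauss = np.exp(-(z**2)) / (sigma * _SQRT2PI)  # z^2 = (x-mu)^2 / (2 sigma^2)
    band = erf(z + d) - erf(z - d)
    per_sig = np.where(spread > 0, band, gauss)
    return per_sig.prod(axis=-1) if per_sig.ndim else float(per_sig)


def combine_sigma(sigma_x, f, source_sigmas, partials=None,
                  aux_partials=None, aux_sigmas=None, check_degenerate=True) -> np.ndarray:
    """Effective per-signature sd by first-order quadrature propagation.

    ``sigma_i² = sigma_x_i² + Σ_j (∂mu_i/∂S_{j,i})² σ_{S_j,i}²`` plus
    optional analytic auxiliary-parameter terms.  For plain mixing
    ``∂mu_i/∂S_{j,i} = f_j``, which is used when ``partials`` is omitted.
    Range-mode sources must carry zero rows in ``source_sigmas`` — their
    variability enters through :func:`compute_spread`.
    """
    sigma_x = np.asarray(sigma_x, dtype=float)
    f = np.asarray(f, dtype=float)
    src = np.atleast_2d(np.asarray(source_sigmas, dtype=float))  # (m, n)
    squeeze = f.ndim == 1
    F = np.atleast_2d(f)  # (N, m)
    if partials is None:
        partials = np.repeat(F[:, :, None], src.shape[1], axis=2)
    var = sigma_x**2 + np.einsum("njs,js->ns", partials**2, src**2)
    if aux_partials is not None and aux_sigmas is not None:
        aux_partials = np.asarray(aux_partials, dtype=float)
        aux_sigmas = np.asarray(aux_sigmas, dtype=float)
        var = var + np.einsum("nks,ks->ns", aux_partials**2, np.atleast_2d(aux_sigmas) ** 2)
    if check_degenerate and np.all(var == 0):
        raise ValueError("degenerate likelihood: total sd is zero on every signature")
    out = np.sqrt(var)
    return out[0] if squeeze else out


def compute_spread(f, half_ranges, partials=None, aux_terms=None) -> np.ndarray:
    """Predicted-band half-width ``Δ_i = Σ_j |∂mu_i/∂S_{j,i}| ΔS_{j,i}``.

    For plain mixing the sensitivities are the fractions themselves, so
    ``Δ_i = Σ_j f_j ΔS_{j,i}``.  Point-mode sources must carry zero rows in
    ``half_ranges``.  ``aux_terms`` adds extra per-signature half-widths.
    """
    f = np.asarray(f, dtype=float)
    hr = np.atleast_2d(np.asarray(half_ranges, dtype=float))  # (m, n)
    if np.any(hr < 0):
        raise ValueError("half_ranges must be >= 0")
    squeeze = f.ndim == 1
    F = np.atleast_2d(f)
    if partials is None:
        partials = np.repeat(F[:, :, None], hr.shape[1], axis=2)
    out = np.einsum("njs,js->ns", np.abs(partials), hr)
    if aux_terms is not None:
        out = out + np.asarray(aux_terms, dtype=float)
    return out[0] if squeeze else out
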