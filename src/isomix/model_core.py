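"""Domain types and forward models for isotope mixing with fractionation.

A mixture's predicted isotope composition is a convex combination of the
source signatures, ``mu0 = sum_j f_j * S_j`` (one value per measured
signature), optionally shifted by a fractionation term built from auxiliary
parameters (fractionation factors, equilibrium endpoints, ...) and auxiliary
variables such as the residual unreacted fraction ``r``.

All delta values are in permil (‰). Vectorised evaluation uses a leading
batch axis: ``f`` has shape ``(N, m)`` for ``m`` sources, auxiliary
variables are ``(N,)`` arrays, auxiliary parameter draws are ``(N, n)`` for
``n`` signatures, and predictions come back as ``(N, n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SignatureSet",
    "Measurement",
    "SourceSpec",
    "AuxParam",
    "AuxVariableSpec",
    "MixingState",
    "ModelSpec",
    "ModelEquation",
    "mix_mu0",
    "open_system_shift",
    "open_system_reduced_shift",
    "rayleigh_shift",
    "equilibrium_shift",
    "craig_gordon_mu",
    "nitrite_model",
    "n2o_model",
    "recalc_nitrification_source",
    "build_model_from_expression",
    "builtin_equation",
    "BUILTIN_EQUATIONS",
]

SIMPLEX_TOL = 1e-12


def _per_signature(r, mu0) -> np.ndarray:
    """Broadcast a scalar/batch aux variable against per-signature arrays."""
    r = np.asarray(r, dtype=float)
    mu0 = np.asarray(mu0, dtype=float)
    if mu0.ndim > r.ndim:
        return r[..., None]
    return r


def _as_vector(v, n: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(v, dtype=float))
    if arr.shape != (n,):
        raise ValueError(f"{name} must have length {n}, got shape {arr.shape}")
    return arr


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignatureSet:
    """The 1-3 measured isotope signatures spanning the model space."""

    labels: tuple[str, ...]

    def __post_init__(self):
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if not 1 <= len(labels) <= 3:
            raise ValueError("between 1 and 3 isotope signatures are supported")
        if len(set(labels)) != len(labels):
            raise ValueError(f"signature labels must be unique: {labels}")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class Measurement:
    """A sample's measured delta vector with per-signature analytical sd."""

    x: np.ndarray
    sigma_x: np.ndarray
    id: str = ""

    def __post_init__(self):
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.sigma_x = _as_vector(self.sigma_x, self.x.size, "sigma_x")
        if np.any(self.sigma_x < 0):
            raise ValueError(f"sigma_x must be >= 0 (sample {self.id!r})")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass
class SourceSpec:
    """One mixing end-member.

    ``mode="point"`` describes the source as mean ± sd (Gaussian); its sd
    enters the likelihood width.  ``mode="range"`` describes it as a uniform
    band mean ± half_range; the half-range enters the predicted spread
    instead.  An optional ``analytical_margin`` widens a range at its edges
    by the analytical sd of the source determination.
    """

    name: str
    mode: str
    mean: np.ndarray
    sigma: np.ndarray | None = None
    half_range: np.ndarray | None = None
    analytical_margin: np.ndarray | None = None

    def __post_init__(self):
        if self.mode not in ("point", "range"):
            raise ValueError(f"source {self.name!r}: mode must be 'point' or 'range'")
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        n = self.mean.size
        if self.mode == "point":
            if self.sigma is None or self.half_range is not None:
                raise ValueError(
                    f"source {self.name!r}: point mode requires sigma and no half_range"
                )
            self.sigma = _as_vector(self.sigma, n, "sigma")
            if np.any(self.sigma < 0):
                raise ValueError(f"source {self.name!r}: sigma must be >= 0")
        else:
            if self.half_range is None or self.sigma is not None:
                raise ValueError(
                    f"source {self.name!r}: range mode requires half_range and no sigma"
                )
            self.half_range = _as_vector(self.half_range, n, "half_range")
            if np.any(self.half_range < 0):
                raise ValueError(f"source {self.name!r}: half_range must be >= 0")
        if self.analytical_margin is not None:
            self.analytical_margin = _as_vector(self.analytical_margin, n, "analytical_margin")
            if np.any(self.analytical_margin < 0):
                raise ValueError(f"source {self.name!r}: analytical_margin must be >= 0")

    @classmethod
    def from_range(cls, name, low, high, analytical_margin=None) -> "SourceSpec":
        """Build a range-mode source from from/to bounds (as tables print them)."""
        low = np.atleast_1d(np.asarray(low, dtype=float))
        high = np.atleast_1d(np.asarray(high, dtype=float))
        return cls(
            name=name,
            mode="range",
            mean=(low + high) / 2.0,
            half_range=(high - low) / 2.0,
            analytical_margin=analytical_margin,
        )


@dataclass
class AuxParam:
    """Auxiliary model parameter (per-signature) with Gaussian uncertainty.

    Typical roles: fractionation factor (A, eps), equilibrium endpoint (E),
    limiting enrichment (D), exchange fraction (C).  During sampling the
    parameter is redrawn from N(mean, sigma) at every proposal, so the chain
    marginalises over its uncertainty.  Optional bounds clip the draws
    (e.g. an exchange fraction must stay in [0, 1]).
    """

    name: str
    mean: np.ndarray
    sigma: np.ndarray
    role: str = ""
    low: float | None = None
    high: float | None = None

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.sigma = _as_vector(self.sigma, self.mean.size, f"sigma of {self.name!r}")
        if np.any(self.sigma < 0):
            raise ValueError(f"aux param {self.name!r}: sigma must be >= 0")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        out = rng.normal(self.mean, self.sigma, size=(size, self.mean.size))
        if self.low is not None or self.high is not None:
            out = np.clip(out, self.low, self.high)
        return out


@dataclass
class AuxVariableSpec:
    """A model variable estimated by the sampler (uniform prior on bounds)."""

    name: str
    prior_low: float = 0.0
    prior_high: float = 1.0

    def __post_init__(self):
        if not np.isfinite([self.prior_low, self.prior_high]).all():
            raise ValueError(f"aux variable {self.name!r}: bounds must be finite")
        if not self.prior_low < self.prior_high:
            raise ValueError(f"aux variable {self.name!r}: prior_low must be < prior_high")


@dataclass
class MixingState:
    """One accepted sampler state: fractions, aux variables, its likelihood."""

    f: np.ndarray
    r: np.ndarray
    likelihood: float

    def __post_init__(self):
        self.f = np.atleast_1d(np.asarray(self.f, dtype=float))
        self.r = np.atleast_1d(np.asarray(self.r, dtype=float)) if np.size(self.r) else np.empty(0)
        if abs(self.f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if np.any((self.f < -SIMPLEX_TOL) | (self.f > 1 + SIMPLEX_TOL)):
            raise ValueError("fractions must lie in [0, 1]")
        if self.likelihood < 0:
            raise ValueError("likelihood must be nonnegative")


# ---------------------------------------------------------------------------
# Forward-model building blocks
# ---------------------------------------------------------------------------


def mix_mu0(f, sources) -> np.ndarray:
    """Pure-mixing prediction ``mu0_i = sum_j f_j S_{j,i}``.

    ``f``: fractions, shape ``(m,)`` or ``(N, m)``.  ``sources``: source mean
    matrix, shape ``(m, n)``.  Returns ``(n,)`` or ``(N, n)``.
    """
    f = np.asarray(f, dtype=float)
    S = np.atleast_2d(np.asarray(sources, dtype=float))
    if f.shape[-1] != S.shape[0]:
        raise ValueError(
            f"fraction vector length {f.shape[-1]} does not match {S.shape[0]} sources"
        )
    return f @ S


def open_system_shift(mu0, A, r) -> np.ndarray:
    """Open-system (steady-state) fractionation, residual-fraction form.

    ``mu = mu0 - A (1 - r)`` with ``r`` the residual unreacted fraction;
    ``r = 1`` means no reaction and returns ``mu0`` unchanged.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("residual fraction r must lie in [0, 1]")
    mu0 = np.asarray(mu0, dtype=float)
    A = np.asarray(A, dtype=float)
    return mu0 - A * (1.0 - _per_signature(r, mu0))


def open_system_reduced_shift(mu0, E, r) -> np.ndarray:
    """Open-system fractionation written against the reduced fraction.

    ``mu = mu0 - E r`` with ``r`` the fraction already removed by the
    reaction (``r = 0`` means no reaction).  ``E`` is the fractionation
    factor (product minus substrate), typically negative.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("reduced fraction r must lie in [0, 1]")
    mu0 = np.asarray(mu0, dtype=float)
    E = np.asarray(E, dtype=float)
    return mu0 - E * _per_signature(r, mu0)


def rayleigh_shift(mu0, A, r) -> np.ndarray:
    """Closed-system (Rayleigh) fractionation of the residual pool.

    ``mu = mu0 + A ln(r)`` with residual fraction ``r`` in (0, 1];
    ``r = 1`` returns ``mu0``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or np.any(r > 1):
        raise ValueError("residual fraction r must lie in (0, 1]")
    mu0 = np.asarray(mu0, dtype=float)
    A = np.asarray(A, dtype=float)
    return mu0 + A * _per_signature(np.log(r), mu0)


def equilibrium_shift(mu0, E, r, per_signature_multiplier=1.0) -> np.ndarray:
    """Abiotic equilibrium exchange toward endpoint ``E``.

    ``mu_i = mu0_i (1 - r m_i) + E_i r m_i`` with equilibrated fraction
    ``r`` in [0, 1] and an optional per-signature multiplier ``m_i`` (for
    compounds whose elements equilibrate at different rates).  ``r = 0``
    returns ``mu0``; ``r m = 1`` returns ``E``.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("equilibrated fraction r must lie in [0, 1]")
    mult = np.asarray(per_signature_multiplier, dtype=float)
    if np.any(mult < 0):
        raise ValueError("per-signature multiplier must be >= 0")
    mu0 = np.asarray(mu0, dtype=float)
    E = np.asarray(E, dtype=float)
    w = _per_signature(r, mu0) * mult
    if np.any(w > 1 + 1e-12):
        raise ValueError("r times multiplier must not exceed 1")
    return mu0 * (1.0 - w) + E * w


def craig_gordon_mu(mu0, A, D, r) -> np.ndarray:
    """Evaporative enrichment of surface water (Craig-Gordon steady state).

    ``mu = (r A D + mu0) / (r A + 1)`` with evaporation-to-inflow ratio
    ``r >= 0``, humidity/temperature slope parameter ``A`` and limiting
    enrichment ``D``.  ``r = 0`` returns the inflow composition ``mu0``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("evaporated fraction r must be >= 0")
    mu0 = np.asarray(mu0, dtype=float)
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    rb = _per_signature(r, mu0 if mu0.ndim >= A.ndim else A)
    denom = rb * A + 1.0
    if np.any(np.abs(denom) < 1e-300):
        raise ZeroDivisionError("singular evaporation model: r*A = -1")
    return (rb * A * D + mu0) / denom


def nitrite_model(f, S, A, B, C, equil_value=8.6) -> np.ndarray:
    """Nitrite source partitioning with consumption and O equilibration.

    ``mu = (sum_j f_j S_j - 0.7 A - 0.3 B)(1 - C) + equil_value * C``

    The three production pathways (nitrate reduction NAR, ammonium oxidation
    AOX, organic-N oxidation ORG) mix; nitrite consumption splits 0.7:0.3
    between reduction (factor ``A``) and oxidation (factor ``B``, inverse
    fractionation) in an open system; oxygen isotopes additionally exchange
    toward the water-equilibrated value (``equil_value``, ‰) with exchanged
    fraction ``C`` per signature (zero on the nitrogen signature).
    """
    C = np.asarray(C, dtype=float)
    if np.any((C < 0) | (C > 1)):
        raise ValueError("exchanged fraction C must lie in [0, 1]")
    mu0 = mix_mu0(f, S)
    return (mu0 - 0.7 * np.asarray(A, float) - 0.3 * np.asarray(B, float)) * (1.0 - C) \
        + equil_value * C


def n2o_model(f, S, A, r) -> np.ndarray:
    """N2O pathway mixing followed by Rayleigh reduction to N2.

    Mixes the four production pathways (bacterial denitrification, nitrifier
    denitrification, fungal denitrification, nitrification) and shifts the
    residual N2O by ``A ln(r)``, ``r`` being the unreduced fraction.
    """
    return rayleigh_shift(mix_mu0(f, S), A, r)


def recalc_nitrification_source(d15N_NH4, eps_nit, d18O_H2O, d18O_O2=23.5):
    """Recalculate an ammonium source into its nitrate signature.

    Nitrification shifts nitrogen by the fractionation factor
    (``d15N_NO3 = d15N_NH4 + eps_nit``) and assembles nitrate oxygen from
    ambient water and atmospheric O2 in a 2:1 ratio
    (``d18O_NO3 = (2/3) d18O_H2O + (1/3) d18O_O2``).
    """
    vals = np.asarray([d15N_NH4, eps_nit, d18O_H2O, d18O_O2], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("inputs must be finite")
    d15N_NO3 = float(d15N_NH4) + float(eps_nit)
    d18O_NO3 = (2.0 / 3.0) * float(d18O_H2O) + (1.0 / 3.0) * float(d18O_O2)
    return d15N_NO3, d18O_NO3


# ---------------------------------------------------------------------------
# Model equations
# ---------------------------------------------------------------------------


class ModelEquation:
    """Evaluable forward model ``(f, r, S, params) -> mu``.

    ``f``: ``(N, m)`` fractions; ``r``: dict of ``(N,)`` aux-variable draws;
    ``S``: ``(m, n)`` source means; ``params``: dict of ``(N, n)`` parameter
    draws.  ``dmu_dS`` returns the per-signature sensitivities
    ``d mu_i / d S_{j,i}`` with shape ``(N, m, n)``, used to propagate source
    sd into the likelihood width and source half-ranges into the spread.
    """

    name = "custom"
    param_names: tuple[str, ...] = ()
    var_names: tuple[str, ...] = ()

    def mu(self, f, r, S, params):  # pragma: no cover - interface
        raise NotImplementedError

    def dmu_dS(self, f, r, S, params):
        """Central finite differences in S (relative step 1e-6)."""
        S = np.asarray(S, dtype=float)
        m, n = S.shape
        N = np.asarray(f).shape[0]
        out = np.empty((N, m, n))
        for j in range(m):
            h = 1e-6 * np.maximum(1.0, np.abs(S[j]))
            Sp, Sm = S.copy(), S.copy()
            Sp[j] = S[j] + h
            Sm[j] = S[j] - h
            out[:, j, :] = (self.mu(f, r, Sp, params) - self.mu(f, r, Sm, params)) / (2 * h)
        return out

    def _get_var(self, r, name=None):
        name = name or self.var_names[0]
        try:
            return np.asarray(r[name], dtype=float)
        except KeyError:
            raise KeyError(f"equation {self.name!r} needs aux variable {name!r}") from None

    def _get_param(self, params, name):
        try:
            return np.asarray(params[name], dtype=float)
        except KeyError:
            raise KeyError(f"equation {self.name!r} needs aux parameter {name!r}") from None


class MixingEquation(ModelEquation):
    """Pure mixing: ``mu = sum_j f_j S_j``."""

    name = "mixing"

    def mu(self, f, r, S, params):
        return mix_mu0(f, S)

    def dmu_dS(self, f, r, S, params):
        f = np.asarray(f, dtype=float)
        n = np.asarray(S).shape[1]
        return np.repeat(f[:, :, None], n, axis=2)


class RayleighEquation(ModelEquation):
    """Post-mixing closed-system fractionation: ``mu = mu0 + A ln(r)``."""

    name = "rayleigh"
    param_names = ("A",)
    var_names = ("r",)

    def __init__(self, param="A", var="r"):
        self.param_names = (param,)
        self.var_names = (var,)

    def mu(self, f, r, S, params):
        return rayleigh_shift(mix_mu0(f, S), self._get_param(params, self.param_names[0]),
                              self._get_var(r))

    def dmu_dS(self, f, r, S, params):
        f = np.asarray(f, dtype=float)
        n = np.asarray(S).shape[1]
        return np.repeat(f[:, :, None], n, axis=2)


class PreMixRayleighEquation(ModelEquation):
    """Source-1-only closed-system fractionation before mixing.

    ``mu = f_1 (S_1 + A ln r) + f_2 S_2 + ...``
    """

    name = "rayleigh_premix"
    param_names = ("A",)
    var_names = ("r",)

    def __init__(self, param="A", var="r", fractionated_source=0):
        self.param_names = (param,)
        self.var_names = (var,)
        self.fractionated_source = fractionated_source

    def mu(self, f, r, S, params):
        f = np.asarray(f, dtype=float)
        rr = self._get_var(r)
        if np.any(rr <= 0) or np.any(rr > 1):
            raise ValueError("residual fraction r must lie in (0, 1]")
        A = self._get_param(params, self.param_names[0])
        shift = f[:, self.fractionated_source, None] * A * np.log(rr)[:, None]
        return mix_mu0(f, S) + shift

    def dmu_dS(self, f, r, S, params):
        f = np.asarray(f, dtype=float)
        n = np.asarray(S).shape[1]
        return np.repeat(f[:, :, None], n, axis=2)


class OpenSystemEquation(ModelEquation):
    """Post-mixing open-system fractionation, residual form: ``mu = mu0 - A(1-r)``."""

    name = "open_system"
    param_names = ("A",)
    var_names = ("r",)

    def __init__(self, param="A", var="r"):
        self.param_names = (param,)
        self.var_names = (var,)

    def mu(self, f, r, S, params):
        return open_system_shift(mix_mu0(f, S), self._get_param(params, self.param_names[0]),
                                 self._get_var(r))

    def dmu_dS(self, f, r, S, params):
        f = np.asarray(f, dtype=float)
        n = np.asarray(S).shape[1]
        return np.repeat(f[:, :, None], n, axis=2)


class OpenSystemReducedEquation(ModelEquation):
    """Post-mixing open-system fractionation, reduced form: ``mu = mu0 - E r``."""

    name = "open_system_reduced"
    param_names = ("E",)
    var_names = ("r",)

    def __init__(self, param="E", var="r"):
        self.param_names = (param,)
        self.var_names = (var,)

    def mu(self, f, r, S, params):
        return open_system_reduced_shift(mix_mu0(f, S),
                                         self._get_param(params, self.param_names[0]),
                                         self._get_var(r))

    def dmu_dS(self, f, r, S, params):
        f = np.asarray(f, dtype=float)
        n = np.asarray(S).shape[1]
        return np.repeat(f[:, :, None], n, axis=2)


class EquilibriumEquation(ModelEquation):
    """Post-mixing equilibrium exchange: ``mu = mu0 (1 - r m) + E r m``."""

    name = "equilibrium"
    param_names = ("E",)
    var_names = ("r",)

    def __init__(self, param="E", var="r", per_signature_multiplier=1.0):
        self.param_names = (param,)
        self.var_names = (var,)
        self.multiplier = np.atleast_1d(np.asarray(per_signature_multiplier, dtype=float))

    def mu(self, f, r, S, params):
        return equilibrium_shift(mix_mu0(f, S), self._get_param(params, self.param_names[0]),
                                 self._get_var(r), self.multiplier)

    def dmu_dS(self, f, r, S, params):
        f = np.asarray(f, dtype=float)
        rr = self._get_var(r)
        w = 1.0 - rr[:, None] * self.multiplier  # (N, n)
        return f[:, :, None] * w[:, None, :]


class CraigGordonEquation(ModelEquation):
    """Evaporation of (mixed) inflow water: ``mu = (r A D + mu0)/(r A + 1)``."""

    name = "craig_gordon"
    param_names = ("A", "D")
    var_names = ("r",)

    def mu(self, f, r, S, params):
        return craig_gordon_mu(mix_mu0(f, S), self._get_param(params, "A"),
                               self._get_param(params, "D"), self._get_var(r))

    def dmu_dS(self, f, r, S, params):
        f = np.asarray(f, dtype=float)
        A = self._get_param(params, "A")
        rr = self._get_var(r)
        w = 1.0 / (rr[:, None] * A + 1.0)  # (N, n)
        return f[:, :, None] * w[:, None, :]


class NitriteEquation(ModelEquation):
    """Nitrite pathway partitioning with consumption and O equilibration."""

    name = "nitrite"
    param_names = ("A", "B", "C")
    var_names = ()

    def __init__(self, equil_value=8.6):
        self.equil_value = float(equil_value)

    def mu(self, f, r, S, params):
        return nitrite_model(f, S, self._get_param(params, "A"),
                             self._get_param(params, "B"), self._get_param(params, "C"),
                             self.equil_value)

    def dmu_dS(self, f, r, S, params):
        f = np.asarray(f, dtype=float)
        C = self._get_param(params, "C")
        return f[:, :, None] * (1.0 - C)[:, None, :]


class N2OEquation(RayleighEquation):
    """N2O pathway mixing + Rayleigh reduction (same algebra as ``rayleigh``)."""

    name = "n2o"


BUILTIN_EQUATIONS = {
    "mixing": MixingEquation,
    "rayleigh": RayleighEquation,
    "rayleigh_premix": PreMixRayleighEquation,
    "open_system": OpenSystemEquation,
    "open_system_reduced": OpenSystemReducedEquation,
    "equilibrium": EquilibriumEquation,
    "craig_gordon": CraigGordonEquation,
    "nitrite": NitriteEquation,
    "n2o": N2OEquation,
}


def builtin_equation(name: str, **kwargs) -> ModelEquation:
    """Instantiate a built-in model equation by name."""
    try:
        cls = BUILTIN_EQUATIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown equation {name!r}; available: {', '.join(sorted(BUILTIN_EQUATIONS))}"
        ) from None
    return cls(**kwargs)


# ---------------------------------------------------------------------------
# Expression-defined equations
# ---------------------------------------------------------------------------


def build_model_from_expression(expr: str, m: int, param_names=(), var_names=()):
    """Compile a user model equation from an arithmetic expression.

    The expression may reference fractions ``f1..fm``, source signatures
    ``S1..Sm``, declared auxiliary parameter names, declared auxiliary
    variable names, numeric literals, ``+ - * / **``, parentheses, and the
    functions ``ln``/``log``, ``exp`` and ``sqrt``.  It is evaluated
    per-signature with numpy broadcasting; sensitivities to the source
    signatures are obtained by central finite differences.
    """
    from .expressions import ExpressionEquation

    return ExpressionEquation(expr, m, param_names=param_names, var_names=var_names)


# ---------------------------------------------------------------------------
# The full model specification
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Sources + auxiliary parameters/variables + model equation.

    ``margin_mode`` controls where a range source's analytical margin goes:
    ``"spread"`` (default) widens the half-range; ``"sigma"`` adds it in
    quadrature to the likelihood sd instead.
    """

    signatures: SignatureSet
    sources: list[SourceSpec]
    aux_params: list[AuxParam] = field(default_factory=list)
    aux_vars: list[AuxVariableSpec] = field(default_factory=list)
    equation: ModelEquation = field(default_factory=MixingEquation)
    margin_mode: str = "spread"

    def __post_init__(self):
        n = self.signatures.n
        if len(self.sources) < 1:
            raise ValueError("at least one source is required")
        names = [s.name for s in self.sources]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate source names: {names}")
        for s in self.sources:
            if s.mean.size != n:
                raise ValueError(f"source {s.name!r} has {s.mean.size} signatures, expected {n}")
        for p in self.aux_params:
            if p.mean.size != n:
                raise ValueError(f"aux param {p.name!r} has {p.mean.size} signatures, expected {n}")
        if self.margin_mode not in ("spread", "sigma"):
            raise ValueError("margin_mode must be 'spread' or 'sigma'")
        declared_p = {p.name for p in self.aux_params}
        declared_v = {v.name for v in self.aux_vars}
        missing_p = set(self.equation.param_names) - declared_p
        missing_v = set(self.equation.var_names) - declared_v
        if missing_p or missing_v:
            raise ValueError(
                f"equation {self.equation.name!r} references undeclared symbols: "
                f"{sorted(missing_p | missing_v)}"
            )

    # -- convenience views ---------------------------------------------------

    @property
    def m(self) -> int:
        return len(self.sources)

    @property
    def n(self) -> int:
        return self.signatures.n

    @property
    def source_names(self) -> list[str]:
        return [s.name for s in self.sources]

    @property
    def var_names(self) -> list[str]:
        return [v.name for v in self.aux_vars]

    def source_means(self) -> np.ndarray:
        return np.vstack([s.mean for s in self.sources])

    def source_sigmas(self) -> np.ndarray:
        """Per-source likelihood sd: point-mode sd, range sources contribute 0
        (plus the analytical margin when margin_mode='sigma')."""
        rows = []
        for s in self.sources:
            if s.mode == "point":
                rows.append(s.sigma)
            elif self.margin_mode == "sigma" and s.analytical_margin is not None:
                rows.append(s.analytical_margin)
            else:
                rows.append(np.zeros(self.n))
        return np.vstack(rows)

    def source_half_ranges(self) -> np.ndarray:
        """Per-source spread half-width: range-mode half-range (widened by the
        margin when margin_mode='spread'), point sources contribute 0."""
        rows = []
        for s in self.sources:
            if s.mode == "range":
                hr = s.half_range
                if self.margin_mode == "spread" and s.analytical_margin is not None:
                    hr = hr + s.analytical_margin
                rows.append(hr)
            else:
                rows.append(np.zeros(self.n))
        return np.vstack(rows)

    # -- evaluation -----------------------------------------------------------

    def draw_params(self, rng: np.random.Generator, size: int) -> dict[str, np.ndarray]:
        return {p.name: p.draw(rng, size) for p in self.aux_params}

    def mean_params(self, size: int = 1) -> dict[str, np.ndarray]:
        return {p.name: np.broadcast_to(p.mean, (size, self.n)).copy() for p in self.aux_params}

    def evaluate(self, f, r=None, params=None):
        """Forward-evaluate a batch: returns a ``likelihood.ModelEvaluation``
        holding mu (N, n), sigma (N, n) and spread (N, n)."""
        from .likelihood import ModelEvaluation, combine_sigma, compute_spread

        f = np.atleast_2d(np.asarray(f, dtype=float))
        N = f.shape[0]
        r = {} if r is None else {k: np.atleast_1d(np.asarray(v, float)) for k, v in r.items()}
        params = self.mean_params(N) if params is None else params
        S = self.source_means()
        mu = self.equation.mu(f, r, S, params)
        partials = self.equation.dmu_dS(f, r, S, params)
        sigma = combine_sigma(np.zeros(self.n), f, self.source_sigmas(), partials=partials,
                              check_degenerate=False)
        spread = compute_spread(f, self.source_half_ranges(), partials=partials)
        return ModelEvaluation(mu=mu, sigma=sigma, spread=spread)

    def likelihood_of(self, measurement: Measurement, f, r=None, params=None) -> np.ndarray:
        """Likelihood of ``measurement`` for a batch of states.

        Per signature: where the propagated spread is positive, the
        erf-convolved uniform-range likelihood; otherwise the Gaussian
        density.  Sample sd is added to the propagated source sd in
        quadrature.  Returns a ``(N,)`` array.
        """
        from .likelihood import mixed_likelihood

        if measurement.n != self.n:
            raise ValueError(
                f"measurement {measurement.id!r} has {measurement.n} signatures, "
                f"model expects {self.n}"
            )
        ev = self.evaluate(f, r=r, params=params)
        sigma = np.sqrt(ev.sigma**2 + measurement.sigma_x**2)
        return mixed_likelihood(measurement.x, ev.mu, sigma, ev.spread)
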