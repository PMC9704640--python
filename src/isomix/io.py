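"""File formats: sources/samples/parameter CSV tables, YAML/JSON run
configuration, and result export.

CSV dialect: comma-separated, UTF-8, ``.`` decimal separator, header
required; delta values stored as plain numbers in permil.  Summaries are
printed at 4 decimal places; chain dumps keep full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_core import (
    AuxParam,
    AuxVariableSpec,
    Measurement,
    ModelSpec,
    SignatureSet,
    SourceSpec,
    build_model_from_expression,
    builtin_equation,
)
from .sampler import SamplerConfig

__all__ = [
    "RunConfig",
    "read_sources",
    "read_samples",
    "read_aux_params",
    "read_config",
    "model_from_dict",
    "model_to_dict",
    "write_summary",
    "write_correlation",
    "write_chain",
    "write_diagnostics",
]


class FormatError(ValueError):
    """A user input file violates the expected schema."""


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------


def _signature_labels_from_columns(columns, suffixes) -> list[str]:
    """Infer signature labels from '<label>_mean'-style columns, preserving order."""
    labels = []
    for col in columns:
        for suf in suffixes:
            if col.endswith(suf):
                lab = col[: -len(suf)]
                if lab and lab not in labels:
                    labels.append(lab)
    return labels


def read_sources(path) -> list[SourceSpec]:
    """Read end-member definitions from CSV.

    Header: ``name, mode`` then per signature ``<label>_mean`` plus
    ``<label>_sd`` (point mode) or ``<label>_halfrange`` (range mode);
    optional ``<label>_margin`` for range-edge analytical margins.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError(f"{path}: no sources defined")
    for col in ("name", "mode"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    labels = _signature_labels_from_columns(df.columns, ("_mean",))
    if not labels:
        raise FormatError(f"{path}: no '<signature>_mean' columns found")
    sources = []
    for idx, row in df.iterrows():
        name, mode = str(row["name"]), str(row["mode"])
        mean = [row.get(f"{lab}_mean") for lab in labels]
        sds = [row.get(f"{lab}_sd", np.nan) for lab in labels]
        hrs = [row.get(f"{lab}_halfrange", np.nan) for lab in labels]
        margins = [row.get(f"{lab}_margin", np.nan) for lab in labels]
        if any(pd.isna(mean)):
            raise FormatError(f"{path} row {idx} ({name}): missing mean value")
        try:
            if mode == "point":
                if not all(pd.isna(hrs)):
                    raise FormatError(
                        f"{path} row {idx} ({name}): point-mode source must not fill halfrange"
                    )
                if any(pd.isna(sds)):
                    raise FormatError(f"{path} row {idx} ({name}): missing '<label>_sd' value")
                src = SourceSpec(name=name, mode="point", mean=mean, sigma=sds)
            elif mode == "range":
                if not all(pd.isna(sds)):
                    raise FormatError(
                        f"{path} row {idx} ({name}): range-mode source must not fill sd"
                    )
                if any(pd.isna(hrs)):
                    raise FormatError(
                        f"{path} row {idx} ({name}): missing '<label>_halfrange' value"
                    )
                margin = None if all(pd.isna(margins)) else np.nan_to_num(margins)
                src = SourceSpec(name=name, mode="range", mean=mean, half_range=hrs,
                                 analytical_margin=margin)
            else:
                raise FormatError(f"{path} row {idx} ({name}): unknown mode {mode!r}")
        except ValueError as e:
            raise FormatError(f"{path} row {idx} ({name}): {e}") from None
        sources.append(src)
    names = [s.name for s in sources]
    if len(set(names)) != len(names):
        raise FormatError(f"{path}: duplicate source names {names}")
    return sources


def read_samples(path, expected_labels=None) -> list[Measurement]:
    """Read measurements from CSV: ``id`` then ``<label>`` and ``<label>_sd``."""
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError(f"{path}: no samples defined")
    if "id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'id'")
    labels = [c for c in df.columns if c != "id" and not c.endswith("_sd")]
    if expected_labels is not None and list(expected_labels) != labels:
        raise FormatError(
            f"{path}: sample signatures {labels} do not match sources {list(expected_labels)}"
        )
    for lab in labels:
        if f"{lab}_sd" not in df.columns:
            raise FormatError(f"{path}: missing column '{lab}_sd'")
    out = []
    for idx, row in df.iterrows():
        x = [row[lab] for lab in labels]
        sd = [row[f"{lab}_sd"] for lab in labels]
        if any(pd.isna(x)) or any(pd.isna(sd)):
            raise FormatError(f"{path} row {idx}: missing value")
        if any(s <= 0 for s in sd):
            raise FormatError(f"{path} row {idx}: sample sd must be > 0")
        out.append(Measurement(x=x, sigma_x=sd, id=str(row["id"])))
    return out


def read_aux_params(path) -> list[AuxParam]:
    """Read auxiliary parameters from CSV: ``name`` then ``<label>_mean``,
    ``<label>_sd``; optional ``low``/``high`` clip bounds and ``role``."""
    df = pd.read_csv(path)
    if "name" not in df.columns:
        raise FormatError(f"{path}: missing required column 'name'")
    labels = _signature_labels_from_columns(df.columns, ("_mean",))
    out = []
    for idx, row in df.iterrows():
        mean = [row[f"{lab}_mean"] for lab in labels]
        sd = [row.get(f"{lab}_sd", 0.0) for lab in labels]
        if any(pd.isna(mean)):
            raise FormatError(f"{path} row {idx}: missing mean value")
        low = row.get("low")
        high = row.get("high")
        out.append(AuxParam(
            name=str(row["name"]), mean=mean, sigma=np.nan_to_num(sd),
            role=str(row.get("role", "") or ""),
            low=None if pd.isna(low) else float(low),
            high=None if pd.isna(high) else float(high),
        ))
    return out


# ---------------------------------------------------------------------------
# Model <-> dict (YAML/JSON)
# ---------------------------------------------------------------------------


def _source_from_dict(d: dict) -> SourceSpec:
    d = dict(d)
    if "low" in d and "high" in d:
        return SourceSpec.from_range(d["name"], d["low"], d["high"],
                                     analytical_margin=d.get("analytical_margin"))
    return SourceSpec(
        name=d["name"], mode=d["mode"], mean=d["mean"], sigma=d.get("sigma"),
        half_range=d.get("half_range"), analytical_margin=d.get("analytical_margin"),
    )


def _source_to_dict(s: SourceSpec) -> dict:
    d = {"name": s.name, "mode": s.mode, "mean": s.mean.tolist()}
    if s.sigma is not None:
        d["sigma"] = s.sigma.tolist()
    if s.half_range is not None:
        d["half_range"] = s.half_range.tolist()
    if s.analytical_margin is not None:
        d["analytical_margin"] = s.analytical_margin.tolist()
    return d


def model_from_dict(d: dict) -> ModelSpec:
    """Build a ModelSpec from its YAML/JSON dictionary form."""
    signatures = SignatureSet(tuple(d["signatures"]))
    sources = [_source_from_dict(s) for s in d["sources"]]
    aux_params = [
        AuxParam(name=p["name"], mean=p["mean"], sigma=p.get("sigma", 0.0),
                 role=p.get("role", ""), low=p.get("low"), high=p.get("high"))
        for p in d.get("aux_params", [])
    ]
    aux_vars = [
        AuxVariableSpec(name=v["name"], prior_low=v.get("prior_low", 0.0),
                        prior_high=v.get("prior_high", 1.0))
        for v in d.get("aux_vars", [])
    ]
    eq = d.get("equation", {"kind": "mixing"})
    if isinstance(eq, str):
        eq = {"kind": eq}
    kind = eq.get("kind", "mixing")
    options = {k: v for k, v in eq.items() if k != "kind"}
    if kind == "expression":
        equation = build_model_from_expression(
            options["expr"], m=len(sources),
            param_names=[p.name for p in aux_params],
            var_names=[v.name for v in aux_vars],
        )
    else:
        equation = builtin_equation(kind, **options)
    return ModelSpec(
        signatures=signatures, sources=sources, aux_params=aux_params,
        aux_vars=aux_vars, equation=equation,
        margin_mode=d.get("margin_mode", "spread"),
    )


def model_to_dict(model: ModelSpec) -> dict:
    """Serialise a ModelSpec to a YAML/JSON-ready dictionary."""
    eq = model.equation
    if eq.__class__.__name__ == "ExpressionEquation":
        eq_d = {"kind": "expression", "expr": eq.expr}
    else:
        eq_d = {"kind": eq.name}
        if eq.name in ("rayleigh", "rayleigh_premix", "open_system", "n2o"):
            eq_d["param"] = eq.param_names[0]
            eq_d["var"] = eq.var_names[0]
        if eq.name == "open_system_reduced":
            eq_d["param"] = eq.param_names[0]
            eq_d["var"] = eq.var_names[0]
        if eq.name == "nitrite":
            eq_d["equil_value"] = eq.equil_value
        if eq.name == "equilibrium":
            eq_d["param"] = eq.param_names[0]
            eq_d["var"] = eq.var_names[0]
            eq_d["per_signature_multiplier"] = eq.multiplier.tolist()
    return {
        "signatures": list(model.signatures.labels),
        "sources": [_source_to_dict(s) for s in model.sources],
        "aux_params": [
            {k: v for k, v in dict(
                name=p.name, mean=p.mean.tolist(), sigma=p.sigma.tolist(),
                role=p.role or None, low=p.low, high=p.high).items() if v is not None}
            for p in model.aux_params
        ],
        "aux_vars": [
            {"name": v.name, "prior_low": v.prior_low, "prior_high": v.prior_high}
            for v in model.aux_vars
        ],
        "equation": eq_d,
        "margin_mode": model.margin_mode,
    }


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """A full run: model + measurements + sampler settings + output options."""

    model: ModelSpec
    measurements: list[Measurement]
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    output_dir: Path = Path("isomix_output")
    plots: bool = False


def read_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration.

    The file either embeds the model inline (keys ``signatures``,
    ``sources``, ...) or points at CSV tables (``sources_csv``,
    ``samples_csv``, ``aux_params_csv``) relative to the config file.
    """
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    base = path.parent

    if "sources_csv" in d:
        sources = read_sources(base / d["sources_csv"])
        labels = d.get("signatures")
        if labels is None:
            raise FormatError(f"{path}: 'signatures' must list the signature labels")
        aux_params = read_aux_params(base / d["aux_params_csv"]) if d.get("aux_params_csv") else []
        model = model_from_dict({
            "signatures": labels,
            "sources": [_source_to_dict(s) for s in sources],
            "aux_params": [
                {"name": p.name, "mean": p.mean.tolist(), "sigma": p.sigma.tolist(),
                 "role": p.role, "low": p.low, "high": p.high}
                for p in aux_params
            ],
            "aux_vars": d.get("aux_vars", []),
            "equation": d.get("equation", "mixing"),
            "margin_mode": d.get("margin_mode", "spread"),
        })
        measurements = read_samples(base / d["samples_csv"], expected_labels=labels)
    else:
        model = model_from_dict(d)
        measurements = [
            Measurement(x=s["x"], sigma_x=s["sigma_x"], id=str(s.get("id", i)))
            for i, s in enumerate(d.get("samples", []))
        ]

    sampler_d = d.get("sampler", {})
    sampler = SamplerConfig(**sampler_d)
    return RunConfig(
        model=model,
        measurements=measurements,
        sampler=sampler,
        output_dir=Path(d.get("output_dir", "isomix_output")),
        plots=bool(d.get("plots", False)),
    )


# ---------------------------------------------------------------------------
# Result export
# ---------------------------------------------------------------------------


def write_summary(summary, path) -> None:
    """Summary CSV: one row per variable, 4-decimal fixed format."""
    df = summary.table.copy()
    df.insert(0, "variable", df.index)
    df.to_csv(path, index=False, float_format="%.4f")


def write_correlation(summary, path) -> None:
    df = summary.correlation.copy()
    df.insert(0, "variable", df.index)
    df.to_csv(path, index=False, float_format="%.4f")


def write_chain(chain, path) -> None:
    """Full-precision tidy chain dump (entry, f_<source>..., r..., likelihood)."""
    chain.to_dataframe().to_csv(path, index=False)


def write_diagnostics(report, path) -> None:
    payload = {
        "z": report.z,
        "rejection_probability": report.rejection_probability,
        "z_n_free": report.z_n_free,
        "acceptance_rate": report.acceptance_rate,
        "converged": report.converged,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
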