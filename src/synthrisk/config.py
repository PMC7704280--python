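"""Configuration documents: variable metadata plus risk parameters.

One YAML (or JSON — YAML is a superset) document holds two blocks::

    variables:
      - {name: Origin, role: quasi_identifier, kind: nominal}
      - {name: Age, role: quasi_identifier, kind: continuous,
         hierarchy: [{type: bands, width: 5}, {type: bands, width: 10},
                     {type: suppress}]}
      - {name: Income, role: sensitive, kind: continuous}
    parameters:
      threshold: 0.09
      L: 5
      error_rate: {min: 0.0, mean: 0.0426, max: 0.0852}
      verification_rate: {min: 0.0, mean: 0.23, max: 0.46}
      correlation: 0.3
      mad_multiplier: 1.48
      seed: 1
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .data_model import RiskParameters, VariableMeta


class ConfigError(ValueError):
    pass


def parse_variables(entries: list[dict]) -> list[VariableMeta]:
    out = []
    for e in entries:
        try:
            out.append(
                VariableMeta(
                    name=e["name"],
                    role=e.get("role", "quasi_identifier"),
                    kind=e.get("kind", "nominal"),
                    hierarchy=e.get("hierarchy"),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"bad variable entry {e!r}: {exc}") from exc
    return out


def parse_parameters(block: dict) -> RiskParameters:
    kw: dict = {}
    for key in ("threshold", "L", "correlation", "mad_multiplier", "kmeans_max_k", "seed"):
        if key in block:
            kw[key] = block[key]
    for key, prefix in (("error_rate", "error_rate"), ("verification_rate", "verification_rate")):
        if key in block:
            tri = block[key]
            if "mean" in tri:
                kw[f"{prefix}_mean"] = float(tri["mean"])
            if "min" in tri or "max" in tri:
                base = RiskParameters()
                lo = float(tri.get("min", getattr(base, f"{prefix}_range")[0]))
                hi = float(tri.get("max", getattr(base, f"{prefix}_range")[1]))
                kw[f"{prefix}_range"] = (lo, hi)
    try:
        return RiskParameters(**kw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad parameters block: {exc}") from exc


def load_config(path: str | Path) -> tuple[list[VariableMeta], RiskParameters]:
    """Load a metadata + parameters document; parameters block optional."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "variables" not in doc:
        raise ConfigError(f"{path}: config must contain a 'variables:' block")
    meta = parse_variables(doc["variables"])
    params = parse_parameters(doc.get("parameters") or {})
    return meta, params
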