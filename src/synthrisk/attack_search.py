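"""Comprehensive search over attack modalities.

An adversary need not match on the raw values of every quasi-identifier:
they may generalize values (age to 10-year bands, ZIP to a prefix, a date
to its month) or match on a subset of the quasi-identifiers.  The overall
meaningful identity disclosure risk of a dataset is therefore the maximum
risk over all combinations of quasi-identifier subsets and generalization
levels.  Risk is not monotone in the subset (dropping a variable gains
synthetic matches but also inflates class sizes), so the search is
exhaustive up to a configurable cap.

Sensitive variables are never generalized — after a match the adversary
reads them at the granularity of the released sample.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adjustment import sample_adjustments
from .attribution import build_sensitive_context
from .data_model import Dataset, KIND_CONTINUOUS, RiskParameters, VariableMeta
from .risk_engine import RiskReport, assess_config


class AttackSearchError(ValueError):
    pass


@dataclass(frozen=True)
class AttackConfig:
    """One attack modality: which QIs to match on and how coarsely."""

    qi_subset: tuple[str, ...]
    levels: tuple[int, ...]  # generalization level per included QI, 0 = raw

    def __post_init__(self) -> None:
        if not self.qi_subset:
            raise AttackSearchError("attack configuration needs a non-empty QI subset")
        if len(self.levels) != len(self.qi_subset):
            raise AttackSearchError("one level per included quasi-identifier required")

    def as_dict(self) -> dict:
        return {"qi_subset": list(self.qi_subset), "levels": dict(zip(self.qi_subset, self.levels))}


# ---------------------------------------------------------------------------
# generalization operators

def _band_label(v: float, width: float, origin: float) -> str:
    lo = origin + math.floor((v - origin) / width) * width
    if float(width).is_integer() and float(lo).is_integer():
        return f"{int(lo)}-{int(lo + width - 1)}"
    return f"[{lo:g},{lo + width:g})"


def _apply_level(col: pd.Series, spec: dict, name: str) -> pd.Series:
    kind = spec.get("type")
    if kind == "bands":
        width = float(spec["width"])
        origin = float(spec.get("origin", 0.0))
        num = pd.to_numeric(col, errors="coerce")
        out = num.map(lambda v: _band_label(v, width, origin) if pd.notna(v) else np.nan)
        return out
    if kind == "prefix":
        length = int(spec["length"])
        return col.map(lambda v: str(v)[:length] + "*" * max(0, len(str(v)) - length)
                       if pd.notna(v) else np.nan)
    if kind == "suppress":
        return col.map(lambda v: "*" if pd.notna(v) else np.nan)
    if kind == "map":
        mapping = spec["mapping"]
        return col.map(lambda v: mapping.get(v, mapping.get(str(v), v)) if pd.notna(v) else np.nan)
    if kind == "bin":
        edges = [float(e) for e in spec["edges"]]
        num = pd.to_numeric(col, errors="coerce")
        lab = pd.cut(num, bins=edges, right=False)
        return lab.astype(object).map(lambda v: str(v) if pd.notna(v) else np.nan)
    raise AttackSearchError(f"unknown generalization type {kind!r} on {name!r}")


def apply_generalization(ds: Dataset, config: AttackConfig) -> Dataset:
    """Recode each included QI to its configured level; level 0 is identity.

    Recoded columns become nominal (band/prefix labels), so binned
    continuous quasi-identifiers are matchable by exact equality.
    """
    df = ds.records.copy()
    new_meta = list(ds.meta)
    lv = dict(zip(config.qi_subset, config.levels))
    for i, m in enumerate(ds.meta):
        if m.name not in lv:
            continue
        level = lv[m.name]
        if level == 0:
            continue
        if m.hierarchy is None or level > len(m.hierarchy):
            raise AttackSearchError(
                f"level {level} exceeds hierarchy depth for {m.name!r} "
                f"(depth {0 if m.hierarchy is None else len(m.hierarchy)})"
            )
        df[m.name] = _apply_level(df[m.name], m.hierarchy[level - 1], m.name)
        new_meta[i] = VariableMeta(m.name, role=m.role, kind="nominal", hierarchy=None)
    return Dataset(df, new_meta, ds.label)


# ---------------------------------------------------------------------------
# enumeration

@dataclass(frozen=True)
class SearchLimits:
    max_configs: int = 10_000
    truncate: bool = False  # if true, keep guaranteed configs + fill; else error


def _level_range(m: VariableMeta) -> list[int]:
    depth = 0 if m.hierarchy is None else len(m.hierarchy)
    lo = 0
    if m.kind == KIND_CONTINUOUS:
        if depth == 0:
            raise AttackSearchError(
                f"continuous quasi-identifier {m.name!r} needs a binning hierarchy "
                "to participate in matching"
            )
        lo = 1  # raw floating-point equality is degenerate
    return list(range(lo, depth + 1))


def enumerate_configs(
    meta: list[VariableMeta],
    limits: SearchLimits | None = None,
) -> list[AttackConfig]:
    """All non-empty QI subsets crossed with all level combinations.

    Deterministic lexicographic order (subsets by size then name, levels in
    product order).  If the projected count exceeds ``limits.max_configs``:
    with ``truncate`` the all-raw configuration and every single-QI
    configuration are kept and the rest filled in order up to the cap;
    otherwise an error instructs lowering ``--max-configs`` or the
    hierarchy depth.
    """
    limits = limits or SearchLimits()
    qis = sorted([m for m in meta if m.role == "quasi_identifier"], key=lambda m: m.name)
    if not qis:
        raise AttackSearchError("at least one quasi-identifier is required")
    ranges = {m.name: _level_range(m) for m in qis}
    names = [m.name for m in qis]

    projected = 0
    for r in range(1, len(names) + 1):
        for sub in itertools.combinations(names, r):
            projected += math.prod(len(ranges[q]) for q in sub)

    def gen():
        for r in range(1, len(names) + 1):
            for sub in itertools.combinations(names, r):
                for lv in itertools.product(*(ranges[q] for q in sub)):
                    yield AttackConfig(tuple(sub), tuple(lv))

    if projected <= limits.max_configs:
        return list(gen())
    if not limits.truncate:
        raise AttackSearchError(
            f"search space has {projected} configurations, above the cap "
            f"{limits.max_configs}; raise --max-configs, enable truncation, "
            "or reduce hierarchy depth"
        )
    # guaranteed configs: all-QIs at rawest admissible levels, each single QI
    guaranteed: list[AttackConfig] = [
        AttackConfig(tuple(names), tuple(min(ranges[q]) for q in names))
    ]
    for q in names:
        for lv in ranges[q]:
            guaranteed.append(AttackConfig((q,), (lv,)))
    seen = set(guaranteed)
    out = list(guaranteed)
    for cfg in gen():
        if len(out) >= limits.max_configs:
            break
        if cfg not in seen:
            seen.add(cfg)
            out.append(cfg)
    return out[: max(limits.max_configs, len(guaranteed))]


def max_risk_search(
    real: Dataset,
    synthetic: Dataset,
    population: Dataset,
    params: RiskParameters | None = None,
    limits: SearchLimits | None = None,
    mode: str = "synthetic_vs_real",
    with_audit: bool = False,
) -> RiskReport:
    """Evaluate every attack configuration and report the riskiest one.

    One set of per-record (error, verification) draws is sampled up front
    and reused across configurations (only the QI count k changes), so the
    argmax reflects the attack surface rather than sampling noise.
    """
    params = params or RiskParameters()
    configs = enumerate_configs(real.meta, limits)
    base_adj = sample_adjustments(real.n, k=1, params=params,
                                  rng=np.random.default_rng(params.seed))
    ctx = build_sensitive_context(real, max_k=params.kmeans_max_k)

    best: RiskReport | None = None
    best_cfg: AttackConfig | None = None
    for cfg in configs:
        r = apply_generalization(real, cfg)
        s = apply_generalization(synthetic, cfg)
        p = apply_generalization(population, cfg)
        rep = assess_config(
            r, s, p, list(cfg.qi_subset), params,
            adj=base_adj, mode=mode, with_audit=with_audit, ctx=ctx,
        )
        if best is None or rep.overall > best.overall:
            best, best_cfg = rep, cfg
    assert best is not None and best_cfg is not None
    best.winning_config = best_cfg.as_dict()
    return best
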