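"""Dataset and metadata representations for disclosure risk assessment.

A risk assessment involves three rectangular tables: the real sample ``R``
(size ``n``), a fully synthetic sample ``S`` generated from it, and the
population ``P`` (size ``N``) from which the real sample was drawn.  Each
variable is designated either a *quasi-identifier* (knowable to an adversary
and used for matching) or a *sensitive variable* (the object of the
"learning something new" test), and is typed as nominal, binary or
continuous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

ROLE_QI = "quasi_identifier"
ROLE_SENSITIVE = "sensitive"
ROLE_IGNORED = "ignored"
ROLES = (ROLE_QI, ROLE_SENSITIVE, ROLE_IGNORED)

KIND_NOMINAL = "nominal"
KIND_BINARY = "binary"
KIND_CONTINUOUS = "continuous"
KINDS = (KIND_NOMINAL, KIND_BINARY, KIND_CONTINUOUS)

LABELS = ("real_sample", "synthetic_sample", "population")


class DataModelError(ValueError):
    """Structural or value error in datasets or metadata."""


@dataclass(frozen=True)
class VariableMeta:
    """Metadata for one variable: its role, kind and optional hierarchy.

    ``hierarchy`` is an ordered list of generalization level specifications;
    level 0 is always the raw values and is implicit (the list holds levels
    1..depth).  Each entry is a dict understood by
    :mod:`synthrisk.attack_search` (e.g. ``{"type": "bands", "width": 10}``).
    """

    name: str
    role: str = ROLE_QI
    kind: str = KIND_NOMINAL
    hierarchy: tuple[dict, ...] | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise DataModelError(f"unknown role {self.role!r} for {self.name!r}")
        if self.kind not in KINDS:
            raise DataModelError(f"unknown kind {self.kind!r} for {self.name!r}")
        if self.hierarchy is not None:
            if self.role != ROLE_QI:
                raise DataModelError(
                    f"hierarchy only allowed on quasi-identifiers, not {self.name!r}"
                )
            object.__setattr__(self, "hierarchy", tuple(dict(h) for h in self.hierarchy))

    @property
    def n_levels(self) -> int:
        """Number of generalization levels including raw level 0."""
        return 1 + (len(self.hierarchy) if self.hierarchy else 0)

    @property
    def is_categorical(self) -> bool:
        return self.kind in (KIND_NOMINAL, KIND_BINARY)


@dataclass
class Dataset:
    """A table of records plus per-variable metadata.

    Column order follows ``meta``; columns present in the file but absent
    from the declared metadata are carried along with role ``ignored``.
    """

    records: pd.DataFrame
    meta: list[VariableMeta]
    label: str = "real_sample"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise DataModelError(f"unknown dataset label {self.label!r}")
        names = [m.name for m in self.meta]
        if len(set(names)) != len(names):
            raise DataModelError("duplicate variable names in metadata")
        missing = [nm for nm in names if nm not in self.records.columns]
        if missing:
            raise DataModelError(f"declared column(s) missing from data: {missing}")
        if len(self.records) < 1:
            raise DataModelError("dataset has no records")
        dup = self.records.columns[self.records.columns.duplicated()]
        if len(dup):
            raise DataModelError(f"duplicate column names in data: {list(dup)}")

    @property
    def n(self) -> int:
        return len(self.records)

    def meta_for(self, name: str) -> VariableMeta:
        for m in self.meta:
            if m.name == name:
                return m
        raise KeyError(name)

    def variables(self, role: str | None = None) -> list[VariableMeta]:
        return [m for m in self.meta if role is None or m.role == role]

    @property
    def quasi_identifiers(self) -> list[str]:
        return [m.name for m in self.meta if m.role == ROLE_QI]

    @property
    def sensitive_variables(self) -> list[str]:
        return [m.name for m in self.meta if m.role == ROLE_SENSITIVE]

    def with_label(self, label: str) -> "Dataset":
        return Dataset(self.records, self.meta, label)


@dataclass(frozen=True)
class RiskParameters:
    """Tunable parameters of the risk model.

    threshold
        Acceptable-risk boundary on the overall probability; the commonly
        used release threshold 0.09 by default.  A risk equal to the
        threshold is acceptable.
    L
        Minimal percentage of sensitive variables that must pass the
        learning-something-new test for a matched record to count (default
        5, i.e. 5%).
    error_rate_*, verification_rate_*
        Triangular distributions for the per-variable data error rate
        (mode 0.0426) and the adversary's match verification rate
        (mode 0.23); ranges default to symmetric about the mode.
    correlation
        Magnitude of the rank correlation induced between error and
        verification draws (negative sign applied internally: errors make
        verification less likely).  0.3 is a medium effect per Cohen.
    mad_multiplier
        Scale factor on the median absolute deviation in the continuous
        learning test; 1.48 makes the MAD match one standard deviation
        under normality.
    """

    threshold: float = 0.09
    L: float = 5.0
    error_rate_mean: float = 0.0426
    error_rate_range: tuple[float, float] = (0.0, 0.0852)
    verification_rate_mean: float = 0.23
    verification_rate_range: tuple[float, float] = (0.0, 0.46)
    correlation: float = 0.3
    mad_multiplier: float = 1.48
    kmeans_max_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for nm in ("threshold", "error_rate_mean", "verification_rate_mean"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise DataModelError(f"{nm} must be a probability, got {v}")
        for nm in ("error_rate_range", "verification_rate_range"):
            lo, hi = getattr(self, nm)
            mean = getattr(self, nm.replace("_range", "_mean"))
            if not (0.0 <= lo <= mean <= hi <= 1.0):
                raise DataModelError(f"{nm}={lo, hi} must bracket its mean {mean} in [0,1]")
        if not 0.0 <= self.L <= 100.0:
            raise DataModelError(f"L must be in [0, 100], got {self.L}")
        if self.mad_multiplier <= 0:
            raise DataModelError("mad_multiplier must be positive")
        if not 0.0 <= self.correlation <= 1.0:
            raise DataModelError("correlation magnitude must be in [0, 1]")


def _coerce(df: pd.DataFrame, meta: Sequence[VariableMeta], path: str) -> pd.DataFrame:
    out = df.copy()
    for m in meta:
        if m.name not in out.columns:
            raise DataModelError(f"{path}: declared column {m.name!r} not found in file")
        col = out[m.name]
        if m.kind == KIND_CONTINUOUS:
            coerced = pd.to_numeric(col, errors="coerce")
            bad = coerced.isna() & col.notna() & (col.astype(str).str.strip() != "")
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise DataModelError(
                    f"{path}: unparseable continuous value {col.iloc[row]!r} "
                    f"in column {m.name!r}, row {row}"
                )
            out[m.name] = coerced.astype(float)
        else:
            # keep categorical tokens as strings; true NaN stays missing
            out[m.name] = col.where(col.isna(), col.astype(str))
    return out


def load_dataset(
    path: str | Path,
    meta: Sequence[VariableMeta],
    label: str = "real_sample",
) -> Dataset:
    """Read a CSV file into a :class:`Dataset`, coercing declared kinds.

    Columns in the file that are not declared in ``meta`` are kept with role
    ``ignored`` (nominal kind) so a load/write round trip preserves every
    cell.  Raises :class:`DataModelError` for a missing declared column, an
    unparseable continuous value, or an empty table.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=object, keep_default_na=True)
    if len(df) == 0:
        raise DataModelError(f"{path}: dataset has no records")
    full_meta = list(meta)
    declared = {m.name for m in full_meta}
    for col in df.columns:
        if col not in declared:
            full_meta.append(VariableMeta(col, role=ROLE_IGNORED, kind=KIND_NOMINAL))
    df = _coerce(df, full_meta, str(path))
    ordered = [m.name for m in full_meta]
    return Dataset(df[ordered].reset_index(drop=True), full_meta, label)


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write the dataset as CSV (UTF-8, header row), preserving column order."""
    ds.records.to_csv(path, index=False)


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``severity`` is ``error`` or ``warning``."""

    severity: str
    message: str


def validate(real: Dataset, synthetic: Dataset, population: Dataset) -> list[Finding]:
    """Cross-dataset consistency checks; returns findings, raises nothing.

    Errors: differing quasi-identifier sets; real sample larger than the
    population.  Warnings: synthetic quasi-identifier categories absent from
    the population (such records can never match anyone real).
    """
    findings: list[Finding] = []
    qis = {ds.label: set(ds.quasi_identifiers) for ds in (real, synthetic, population)}
    if len({frozenset(v) for v in qis.values()}) != 1:
        findings.append(Finding("error", f"quasi-identifier sets differ across datasets: {qis}"))
        return findings
    if real.n > population.n:
        findings.append(
            Finding("error", f"sample larger than population (n={real.n} > N={population.n})")
        )
    for q in real.quasi_identifiers:
        syn_vals = set(synthetic.records[q].dropna().unique())
        pop_vals = set(population.records[q].dropna().unique())
        extra = syn_vals - pop_vals
        if extra:
            findings.append(
                Finding(
                    "warning",
                    f"synthetic categories absent from population in {q!r}: {sorted(map(str, extra))}",
                )
            )
    return findings
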