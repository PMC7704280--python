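"""Equivalence-class matching between real, synthetic and population tables.

Matching is exact equality on the tuple of (possibly generalized) active
quasi-identifier values.  For each real-sample record *s* we compute

* ``f_s`` — size of its equivalence class in the real sample,
* ``F_s`` — size of the class with the same quasi-identifier tuple in the
  population (the population table supplies these sizes exactly),
* ``I_s`` — 1 iff at least one synthetic record carries the identical tuple,

together with the list of matched synthetic partner indices, which the
attribution stage uses.  Adversary imperfection (data errors, verification)
is handled separately by the λ adjustment, not by fuzzy matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import Dataset, KIND_CONTINUOUS, ROLE_QI


class MatchingError(ValueError):
    pass


@dataclass
class MatchState:
    """Per-real-record match quantities on one active QI configuration."""

    f: np.ndarray  # real-sample equivalence class sizes, len n
    F: np.ndarray  # population equivalence class sizes, len n
    I: np.ndarray  # binary synthetic-match indicator, len n
    partners: list[list[int]]  # synthetic record indices matching each s
    active_qi: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.f)


def _check_qi(ds: Dataset, qi: list[str]) -> None:
    if not qi:
        raise MatchingError("active quasi-identifier set must be non-empty")
    for name in qi:
        m = ds.meta_for(name)
        if m.role != ROLE_QI:
            raise MatchingError(f"{name!r} has role {m.role!r}; matching requires quasi_identifier")
        if m.kind == KIND_CONTINUOUS:
            raise MatchingError(
                f"continuous quasi-identifier {name!r} must be generalized (binned) "
                "before matching; exact equality on raw continuous values is refused"
            )


def _keys(ds: Dataset, qi: list[str], tag: str) -> pd.Series:
    """Tuple keys per record; rows missing any active QI get a unique sentinel."""
    sub = ds.records[qi]
    keys = pd.Series(list(zip(*(sub[c].astype(object) for c in qi))), index=sub.index, dtype=object)
    miss = sub.isna().any(axis=1)
    if miss.any():
        keys = keys.astype(object)
        for i in np.flatnonzero(miss.to_numpy()):
            keys.iloc[i] = ("__missing__", tag, int(i))
    return keys


def equivalence_classes(ds: Dataset, qi: list[str]) -> dict[tuple, set[int]]:
    """Group record indices by their active quasi-identifier value tuple.

    Every record appears in exactly one class; class sizes sum to ``n``.
    """
    _check_qi(ds, qi)
    keys = _keys(ds, qi, ds.label)
    out: dict[tuple, set[int]] = {}
    for i, k in enumerate(keys):
        out.setdefault(k, set()).add(i)
    return out


def compute_match_state(
    real: Dataset,
    synthetic: Dataset,
    population: Dataset,
    qi: list[str],
) -> MatchState:
    """Compute f_s, F_s, I_s and matched synthetic partners per real record.

    A record whose quasi-identifier tuple is missing in part matches nothing
    (unique sentinel): it gets f_s = F_s = 1 and I_s = 0.  A complete real
    tuple absent from the population is an error — the real sample must be a
    subset of the population on the quasi-identifiers.
    """
    _check_qi(real, qi)
    _check_qi(synthetic, qi)
    _check_qi(population, qi)

    rk = _keys(real, qi, "real")
    sk = _keys(synthetic, qi, "syn")
    pk = _keys(population, qi, "pop")
    r_miss = real.records[qi].isna().any(axis=1).to_numpy()

    f = rk.map(rk.value_counts()).to_numpy(dtype=np.int64)
    pop_counts = pk.value_counts()
    F_ser = rk.map(pop_counts)
    syn_index: dict[tuple, list[int]] = {}
    for t, k in enumerate(sk):
        syn_index.setdefault(k, []).append(t)

    n = real.n
    F = np.empty(n, dtype=np.int64)
    I = np.zeros(n, dtype=np.int64)
    partners: list[list[int]] = [[] for _ in range(n)]
    for s in range(n):
        if r_miss[s]:
            f[s] = 1
            F[s] = 1
            continue
        Fv = F_ser.iloc[s]
        if pd.isna(Fv):
            raise MatchingError(
                "real sample is not a subset of population on quasi-identifiers: "
                f"tuple {rk.iloc[s]!r} (record {s}) absent from population"
            )
        F[s] = int(Fv)
        hits = syn_index.get(rk.iloc[s], [])
        if hits:
            I[s] = 1
            partners[s] = list(hits)
    return MatchState(f=f, F=F, I=I, partners=partners, active_qi=tuple(qi))
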