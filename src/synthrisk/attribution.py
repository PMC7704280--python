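"""Does the adversary learn something new about a matched individual?

Identity disclosure is only meaningful if the sensitive values attached to
the matched synthetic record teach the adversary something both *new*
(the individual stands out from the rest of the real sample) and *correct*
(the synthetic value is close to the real one).  Each sensitive variable is
tested per matched (real s, synthetic t) pair:

* nominal/binary — with p_j the real-sample proportion of the record's
  value j, the weighted agreement (1 − p_j)·[X_s = Y_t] must exceed one
  Bernoulli standard deviation sqrt(p_j (1 − p_j)).  For an exact value
  match this reduces algebraically to p_j < 1/2: only minority values can
  be learned.
* continuous — values are discretized by univariate k-means (cluster count
  by majority rule over a panel of indices); with p_s the record's cluster
  proportion and the MAD taken over the variable in the real sample,
  learning occurs when p_s·|X_s − Y_t| < 1.48·MAD.

A real record learns-new (R_s = 1) iff for at least one matched partner, at
least L% of the applicable sensitive variables pass their test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .data_model import Dataset, RiskParameters, KIND_CONTINUOUS
from .matching import MatchState

LEARNED = "learned"
NOT_LEARNED = "not_learned"
SKIPPED_MISSING = "skipped_missing"


def nominal_learn_new(x, y, p_j: float) -> str:
    """Nominal/binary learning test for one matched pair.

    Learned iff the values agree and (1 − p_j) > sqrt(p_j (1 − p_j)).
    """
    if not 0.0 < p_j <= 1.0:
        raise ValueError(f"p_j must be in (0, 1] (value must occur in the real sample), got {p_j}")
    if x != y:
        return NOT_LEARNED
    d_j = 1.0 - p_j
    return LEARNED if d_j > np.sqrt(p_j * (1.0 - p_j)) else NOT_LEARNED


def mad(values) -> float:
    """Median absolute deviation about the median (unscaled)."""
    a = np.asarray(values, dtype=float)
    a = a[~np.isnan(a)]
    if a.size == 0:
        raise ValueError("mad requires at least one value")
    return float(np.median(np.abs(a - np.median(a))))


def continuous_learn_new(x: float, y: float, p_s: float, mad_x: float, multiplier: float = 1.48) -> str:
    """Continuous learning test: p_s·|x − y| < multiplier·MAD."""
    if not 0.0 < p_s <= 1.0:
        raise ValueError(f"p_s must be in (0, 1], got {p_s}")
    if mad_x < 0:
        raise ValueError("mad must be nonnegative")
    return LEARNED if p_s * abs(x - y) < multiplier * mad_x else NOT_LEARNED


@dataclass
class Clustering:
    """Univariate k-means partition of a continuous variable."""

    labels: np.ndarray  # cluster label per input value
    k: int
    proportions: np.ndarray  # per input value: its cluster's share of n
    centers: np.ndarray


def _quantile_init(x: np.ndarray, k: int) -> np.ndarray:
    qs = (np.arange(k) + 0.5) / k
    return np.quantile(x, qs).reshape(-1, 1)


def _fit_kmeans(x: np.ndarray, k: int) -> KMeans:
    # deterministic sorted-quantile seeding: reproducible without a seed
    init = _quantile_init(x, k)
    # collapse duplicate initial centers to keep k-means well posed
    init = np.unique(init, axis=0)
    km = KMeans(n_clusters=len(init), init=init, n_init=1, random_state=0)
    km.fit(x.reshape(-1, 1))
    return km


def discretize_continuous(values, max_k: int = 10) -> Clustering:
    """Discretize a continuous variable by 1-D k-means, k via majority rule.

    Candidate counts k ∈ [2, min(max_k, #distinct)] are scored by four
    voters — within-SS elbow (maximum curvature), silhouette (max),
    Calinski–Harabasz (max) and Davies–Bouldin (min) — and the count with
    the most votes wins, ties broken toward smaller k.  All-identical
    input yields a single cluster with proportion 1.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("discretize_continuous requires non-missing values")
    n = x.size
    distinct = np.unique(x)
    if distinct.size == 1:
        return Clustering(np.zeros(n, int), 1, np.ones(n), distinct.reshape(1))

    # silhouette & co. need 2 <= k <= n-1; with fewer points just use k=2
    k_max = min(max_k, distinct.size, n - 1)
    if k_max < 2:
        km = _fit_kmeans(x, 2)
        labels = km.labels_
        sizes = np.bincount(labels, minlength=km.n_clusters)
        return Clustering(labels, km.n_clusters, sizes[labels] / n,
                          km.cluster_centers_.ravel())
    ks = list(range(2, k_max + 1))
    fits = {k: _fit_kmeans(x, k) for k in ks}
    ks = sorted({fits[k].n_clusters for k in ks})  # dedupe collapsed inits
    fits = {k: f for k, f in ((f.n_clusters, f) for f in fits.values())}

    if len(ks) == 1:
        best = ks[0]
    else:
        X = x.reshape(-1, 1)
        inertia = {k: fits[k].inertia_ for k in ks}
        tss = float(np.sum((x - x.mean()) ** 2))  # within-SS at k=1
        w = {1: tss, **inertia}
        votes: list[int] = []
        # elbow voter: maximum curvature of the within-SS curve
        curv = {}
        for i, k in enumerate(ks):
            prev = w[1] if i == 0 else w[ks[i - 1]]
            if i + 1 < len(ks):
                curv[k] = (prev - w[k]) - (w[k] - w[ks[i + 1]])
        if curv:
            votes.append(min(curv, key=lambda k: (-curv[k], k)))
        sil = {k: silhouette_score(X, fits[k].labels_) for k in ks}
        votes.append(min(sil, key=lambda k: (-sil[k], k)))
        ch = {k: calinski_harabasz_score(X, fits[k].labels_) for k in ks}
        votes.append(min(ch, key=lambda k: (-ch[k], k)))
        db = {k: davies_bouldin_score(X, fits[k].labels_) for k in ks}
        votes.append(min(db, key=lambda k: (db[k], k)))
        counts = pd.Series(votes).value_counts()
        top = counts[counts == counts.max()].index
        best = int(min(top))

    km = fits[best]
    labels = km.labels_
    sizes = np.bincount(labels, minlength=km.n_clusters)
    props = sizes[labels] / n
    return Clustering(labels, km.n_clusters, props, km.cluster_centers_.ravel())


@dataclass
class SensitiveContext:
    """Real-sample statistics for every sensitive variable, precomputed once."""

    nominal_p: dict[str, pd.Series] = field(default_factory=dict)  # value -> p_j
    cont_props: dict[str, np.ndarray] = field(default_factory=dict)  # p_s per real record
    cont_mad: dict[str, float] = field(default_factory=dict)


def build_sensitive_context(real: Dataset, max_k: int = 10) -> SensitiveContext:
    ctx = SensitiveContext()
    for m in real.variables("sensitive"):
        col = real.records[m.name]
        if m.kind == KIND_CONTINUOUS:
            vals = col.to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            props = np.full(len(vals), np.nan)
            if ok.sum() >= 1:
                cl = discretize_continuous(vals[ok], max_k=max_k)
                props[ok] = cl.proportions
                ctx.cont_mad[m.name] = mad(vals[ok])
            else:
                ctx.cont_mad[m.name] = np.nan
            ctx.cont_props[m.name] = props
        else:
            ctx.nominal_p[m.name] = col.value_counts(dropna=True) / col.notna().sum()
    return ctx


@dataclass
class AttributionResult:
    """R_s per real record (0 where I_s = 0) plus audit detail."""

    R: np.ndarray
    detail: list[dict] = field(default_factory=list)
    no_sensitive_variables: bool = False


def pair_verdicts(
    real: Dataset,
    synthetic: Dataset,
    s: int,
    t: int,
    ctx: SensitiveContext,
    params: RiskParameters,
) -> dict[str, str]:
    """Verdict per sensitive variable for one matched (real, synthetic) pair."""
    verdicts: dict[str, str] = {}
    for m in real.variables("sensitive"):
        x = real.records[m.name].iloc[s]
        y = synthetic.records[m.name].iloc[t]
        if pd.isna(x) or pd.isna(y):
            verdicts[m.name] = SKIPPED_MISSING
            continue
        if m.kind == KIND_CONTINUOUS:
            p_s = ctx.cont_props[m.name][s]
            if np.isnan(p_s):
                verdicts[m.name] = SKIPPED_MISSING
                continue
            verdicts[m.name] = continuous_learn_new(
                float(x), float(y), float(p_s), ctx.cont_mad[m.name], params.mad_multiplier
            )
        else:
            p_j = float(ctx.nominal_p[m.name].get(x, 0.0))
            if p_j == 0.0:
                # value absent from the real sample cannot occur for x drawn
                # from it; guard for ignored-column edge cases
                verdicts[m.name] = SKIPPED_MISSING
            else:
                verdicts[m.name] = nominal_learn_new(x, y, p_j)
    return verdicts


def record_learns_new(fractions: list[float], L: float) -> int:
    """R_s from per-partner learned fractions: 1 iff any fraction ≥ L/100."""
    if not 0.0 <= L <= 100.0:
        raise ValueError("L must be in [0, 100]")
    return int(any(f >= L / 100.0 for f in fractions))


def attribute(
    real: Dataset,
    synthetic: Dataset,
    ms: MatchState,
    params: RiskParameters | None = None,
    ctx: SensitiveContext | None = None,
) -> AttributionResult:
    """Compute R_s for every real record with a synthetic match.

    A partner pair with zero applicable (non-missing) sensitive variables —
    in particular a dataset with no sensitive variables at all — counts as
    learned (R_s = 1): the assessment degrades conservatively to pure
    identity disclosure and the result is flagged.
    """
    params = params or RiskParameters()
    ctx = ctx or build_sensitive_context(real, max_k=params.kmeans_max_k)
    n = real.n
    R = np.zeros(n, dtype=np.int64)
    detail: list[dict] = []
    no_sens = len(real.sensitive_variables) == 0
    for s in range(n):
        if not ms.I[s]:
            continue
        fractions: list[float] = []
        per_partner = []
        for t in ms.partners[s]:
            verdicts = pair_verdicts(real, synthetic, s, t, ctx, params)
            applicable = [v for v in verdicts.values() if v != SKIPPED_MISSING]
            if not applicable:
                frac = 1.0  # conservative: no testable sensitive variable
            else:
                frac = sum(v == LEARNED for v in applicable) / len(applicable)
            fractions.append(frac)
            per_partner.append({"t": t, "verdicts": verdicts, "fraction": frac})
        R[s] = record_learns_new(fractions, params.L)
        detail.append({"s": s, "partners": per_partner, "R": int(R[s])})
    return AttributionResult(R=R, detail=detail, no_sensitive_variables=no_sens)
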