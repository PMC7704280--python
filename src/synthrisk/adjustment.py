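"""Adjustment of match probabilities for data errors and verification.

A suspected match only succeeds if (a) the record holds no data errors on
the k matching variables and (b) the adversary can verify the match.  Both
rates are uncertain; they are modelled as triangular distributions — error
rate with mode 0.0426 per variable, verification rate with mode 0.23 — and
sampled with a negative rank correlation (data errors depress the ability
to verify).  The point form of the attenuation is

    λ = 0.23 × (1 − 0.0426)^k

and per record s, with sampled rates (e_s, v_s),

    λ_s = v_s × (1 − e_s)^k,       λ_c = (λ_s + 1) / 2,

where λ_c is the conservative variant: the midpoint between λ_s and 1, so
the adjustment can never attenuate the risk by more than half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import RiskParameters


@dataclass
class AdjustmentDraws:
    """Per-record sampled rates and the derived λ factors (all length n)."""

    e: np.ndarray  # per-variable data error rate draws
    v: np.ndarray  # verification rate draws
    k: int  # number of active quasi-identifiers

    @property
    def lambda_s(self) -> np.ndarray:
        return self.v * (1.0 - self.e) ** self.k

    @property
    def lambda_c(self) -> np.ndarray:
        return conservative_lambda(self.lambda_s)

    def with_k(self, k: int) -> "AdjustmentDraws":
        """Same underlying rate draws, recomputed for a different QI count.

        The attack search reuses one set of per-record draws across
        configurations so the maximization is not inflated by sampling
        noise; only k changes between configurations.
        """
        return AdjustmentDraws(self.e, self.v, k)


def lambda_point(k: int, params: RiskParameters | None = None) -> float:
    """Point attenuation v̄ × (1 − ē)^k at the distribution modes."""
    if k < 0:
        raise ValueError("k must be >= 0")
    p = params or RiskParameters()
    return p.verification_rate_mean * (1.0 - p.error_rate_mean) ** k


def conservative_lambda(lambda_s):
    """Midpoint between λ_s and the maximum value 1."""
    return (np.asarray(lambda_s, dtype=float) + 1.0) / 2.0


def _triangular_ppf(u: np.ndarray, lo: float, mode: float, hi: float) -> np.ndarray:
    if hi == lo:  # degenerate range: deterministic draws
        return np.full_like(u, mode, dtype=float)
    c = (mode - lo) / (hi - lo)
    return stats.triang.ppf(u, c, loc=lo, scale=hi - lo)


def sample_adjustments(
    n_records: int,
    k: int,
    params: RiskParameters | None = None,
    rng: np.random.Generator | None = None,
) -> AdjustmentDraws:
    """Draw correlated (e_s, v_s) pairs, one per real-sample record.

    The dependence is induced through a Gaussian copula over independently
    specified triangular marginals.  The normal correlation is set to
    2·sin(π·ρ/6) so that the induced Spearman rank correlation equals −ρ
    (−0.3 by default) exactly in distribution; the marginals are untouched.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    p = params or RiskParameters()
    rng = rng if rng is not None else np.random.default_rng(p.seed)

    rho_s = -abs(p.correlation)
    r = 2.0 * np.sin(np.pi * rho_s / 6.0)  # Pearson corr of the copula normals
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n_records, method="cholesky")
    u = stats.norm.cdf(z)

    e_lo, e_hi = p.error_rate_range
    v_lo, v_hi = p.verification_rate_range
    e = _triangular_ppf(u[:, 0], e_lo, p.error_rate_mean, e_hi)
    v = _triangular_ppf(u[:, 1], v_lo, p.verification_rate_mean, v_hi)
    return AdjustmentDraws(e=e, v=v, k=k)
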