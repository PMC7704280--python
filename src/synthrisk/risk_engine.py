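"""Directional and overall meaningful identity disclosure risk.

Two attack directions are modelled.  In the population-to-sample attack the
adversary picks a random person from the population and tries to find them
in the synthetic data through the real sample; in the sample-to-population
attack they pick a synthetic-matched real record and look the person up in
a population registry.  With per-record attenuation λ_c,s, synthetic-match
indicator I_s and learning indicator R_s:

    A = (1/N) Σ_s λ_c,s · (1/f_s) · I_s · R_s      (population → sample)
    B = (1/n) Σ_s λ_c,s · (1/F_s) · I_s · R_s      (sample → population)

    overall = max(A, B)

The overall value is compared with an acceptable-risk threshold (0.09 by
default); equality is acceptable.  Running the pipeline with the real
sample standing in for the synthetic sample (all I_s = 1) gives the
real-data baseline against which the synthesis benefit is judged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .adjustment import AdjustmentDraws, sample_adjustments
from .attribution import AttributionResult, attribute, build_sensitive_context
from .data_model import Dataset, RiskParameters
from .matching import MatchState, compute_match_state


@dataclass
class RiskReport:
    """Result of one assessment: directional risks, verdict, provenance."""

    risk_pop_to_sample: float
    risk_sample_to_pop: float
    overall: float
    n: int
    N: int
    k: int
    threshold: float
    verdict: str  # acceptable | too_high
    mode: str = "synthetic_vs_real"  # or real_baseline
    winning_config: dict | None = None
    seed: int | None = None
    no_sensitive_variables: bool = False
    audit: dict | None = None

    def to_dict(self) -> dict[str, Any]:
        d = {
            "risk_pop_to_sample": self.risk_pop_to_sample,
            "risk_sample_to_pop": self.risk_sample_to_pop,
            "overall": self.overall,
            "n": self.n,
            "N": self.N,
            "k": self.k,
            "threshold": self.threshold,
            "verdict": self.verdict,
            "mode": self.mode,
            "winning_config": self.winning_config,
            "seed": self.seed,
            "no_sensitive_variables": self.no_sensitive_variables,
        }
        if self.audit is not None:
            d["audit"] = self.audit
        return d


def population_to_sample_risk(
    ms: MatchState, adj: AdjustmentDraws, attr: AttributionResult, N: int
) -> float:
    """A = (1/N) Σ λ_c,s (1/f_s) I_s R_s."""
    if np.any(ms.f < 1):
        raise ValueError("every real record belongs to its own class: f_s >= 1")
    return float(np.sum(adj.lambda_c * (1.0 / ms.f) * ms.I * attr.R) / N)


def sample_to_population_risk(
    ms: MatchState, adj: AdjustmentDraws, attr: AttributionResult, n: int
) -> float:
    """B = (1/n) Σ λ_c,s (1/F_s) I_s R_s."""
    if np.any(ms.F < 1):
        raise ValueError("population must contain each real record's class: F_s >= 1")
    return float(np.sum(adj.lambda_c * (1.0 / ms.F) * ms.I * attr.R) / n)


def overall_risk(A: float, B: float) -> float:
    """The adversary attempts one direction; take the worse case."""
    return max(A, B)


def _verdict(overall: float, threshold: float) -> str:
    return "acceptable" if overall <= threshold else "too_high"


def assess_config(
    real: Dataset,
    synthetic: Dataset,
    population: Dataset,
    qi: list[str],
    params: RiskParameters | None = None,
    adj: AdjustmentDraws | None = None,
    mode: str = "synthetic_vs_real",
    with_audit: bool = False,
    ctx=None,
) -> RiskReport:
    """Run the full pipeline for one fixed quasi-identifier configuration."""
    params = params or RiskParameters()
    ms = compute_match_state(real, synthetic, population, qi)
    k = len(qi)
    if adj is None:
        adj = sample_adjustments(real.n, k, params, np.random.default_rng(params.seed))
    else:
        adj = adj.with_k(k)
    attr = attribute(real, synthetic, ms, params, ctx=ctx)
    A = population_to_sample_risk(ms, adj, attr, population.n)
    B = sample_to_population_risk(ms, adj, attr, real.n)
    ov = overall_risk(A, B)
    audit = None
    if with_audit:
        audit = {
            "f": ms.f.tolist(),
            "F": ms.F.tolist(),
            "I": ms.I.tolist(),
            "R": attr.R.tolist(),
            "lambda_c": adj.lambda_c.tolist(),
        }
    return RiskReport(
        risk_pop_to_sample=A,
        risk_sample_to_pop=B,
        overall=ov,
        n=real.n,
        N=population.n,
        k=k,
        threshold=params.threshold,
        verdict=_verdict(ov, params.threshold),
        mode=mode,
        winning_config={"qi_subset": list(qi), "levels": {q: 0 for q in qi}},
        seed=params.seed,
        no_sensitive_variables=attr.no_sensitive_variables,
        audit=audit,
    )


def baseline_real_risk(
    real: Dataset,
    population: Dataset,
    params: RiskParameters | None = None,
    qi: list[str] | None = None,
    adj: AdjustmentDraws | None = None,
) -> RiskReport:
    """Real-data baseline: the real sample plays the synthetic sample's role.

    Every record matches itself, so all I_s = 1 by construction; the result
    bounds what synthesis can be compared against.
    """
    synthetic = Dataset(real.records.copy(), real.meta, "synthetic_sample")
    qi = qi or real.quasi_identifiers
    rep = assess_config(real, synthetic, population, qi, params, adj, mode="real_baseline")
    return rep
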