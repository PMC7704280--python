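"""Synthesize a sample with sequential trees and measure its disclosure risk.

Builds a simulated population, draws a 20% real sample, fits the sequential
decision-tree generator, then runs the full attack search on the synthetic
output and on the real-data baseline (real sample standing in for the
synthetic one).  The ratio of the two overall risks is the privacy benefit
attributable to synthesis.
"""

import numpy as np

from synthrisk import (
    FixtureSpec,
    RiskParameters,
    control_synthetics,
    draw_real_sample,
    generate_population,
    max_risk_search,
    synthesize,
)

spec = FixtureSpec(
    N=2000,
    qi_specs={
        "region": {"categories": [f"r{i}" for i in range(12)]},
        "ageband": {"categories": [f"a{i}" for i in range(10)]},
        "sex": {"categories": ["f", "m"], "probs": [0.5, 0.5]},
    },
    sensitive_specs={
        "status": {"categories": ["active", "recovered", "deceased"],
                   "probs": [0.3, 0.6, 0.1]},
        "cost": {"gaussian_mixture": {"means": [100.0, 400.0], "sds": [30.0, 80.0],
                                      "weights": [0.7, 0.3]}},
    },
    sampling_fraction=0.2,
    seed=7,
)
population = generate_population(spec)
real = draw_real_sample(population, 0.2, np.random.default_rng(8))
synthetic = synthesize(real, min_leaf=5, seed=9)

params = RiskParameters(seed=7)
rep = max_risk_search(real, synthetic, population, params)
base = max_risk_search(real, control_synthetics(real, "copy"), population,
                       params, mode="real_baseline")

print(f"population N={population.n}, real sample n={real.n}")
print(f"synthetic overall risk      {rep.overall:.4f}  ({rep.verdict}, "
      f"threshold {params.threshold})")
print(f"  pop->sample {rep.risk_pop_to_sample:.4f}  "
      f"sample->pop {rep.risk_sample_to_pop:.4f}")
print(f"  winning attack config: {rep.winning_config}")
print(f"real-data baseline risk     {base.overall:.4f}")
if rep.overall > 0:
    print(f"synthesis reduced the meaningful identity disclosure risk "
          f"{base.overall / rep.overall:.1f}x")
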