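import numpy as np
import pytest

from synthrisk import (
    FixtureSpec,
    control_synthetics,
    draw_real_sample,
    generate_population,
    worked_example,
)


@pytest.fixture(scope="session")
def worked():
    """(population, real, synthetic) didactic triple."""
    return worked_example()


def make_triplet(seed, N=200, fraction=0.25, syn_mode="independent",
                 n_qi=3, cats=(4, 3, 5)):
    """Random population / real sample / control synthetic triple."""
    rng = np.random.default_rng(seed)
    qi_specs = {
        f"q{i}": {"categories": [f"c{j}" for j in range(cats[i % len(cats)])]}
        for i in range(n_qi)
    }
    spec = FixtureSpec(
        N=N,
        qi_specs=qi_specs,
        sensitive_specs={
            "snom": {"categories": ["x", "y", "z"], "probs": [0.5, 0.3, 0.2]},
            "scont": {"gaussian_mixture": {"means": [0.0, 10.0], "sds": [1.0, 1.0],
                                           "weights": [0.5, 0.5]}},
        },
        sampling_fraction=fraction,
        seed=seed,
    )
    pop = generate_population(spec)
    real = draw_real_sample(pop, fraction, rng)
    syn = control_synthetics(real, syn_mode, rng)
    return pop, real, syn
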