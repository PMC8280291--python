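import numpy as np
import pytest
from hypothesis import settings

import cmapcv as c

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template():
    return c.synthetic_smup(peak_amplitude_mv=0.1, onset_ms=4.0, seed=0)


@pytest.fixture(scope="session")
def small_corpus(template):
    """12 groups x 5 sets — enough structure for plumbing tests."""
    cfg = c.SimConfig(n_per_group=5)
    return c.build_corpus(template, cfg, seed=11), cfg


@pytest.fixture(scope="session")
def normal_population():
    return c.population_from_histogram(c.normal_histogram())


def brute_force_cmap(template, pop, cfg):
    """Independent superposition oracle: explicit per-axon loop with
    per-sample placement (no vectorized slicing)."""
    out = np.zeros(cfg.n_samples)
    for axon in pop.axons:
        if axon.blocked:
            continue
        tau = (
            cfg.distal_distance / axon.normal_cv
            + cfg.forearm_distance / axon.forearm_cv
            - (cfg.distal_distance + cfg.forearm_distance) / cfg.reference_cv
        )
        k = int(np.floor(tau / cfg.dt + 0.5))
        for j, amp in enumerate(template.amplitudes):
            if 0 <= k + j < cfg.n_samples:
                out[k + j] += amp
    return out
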