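import numpy as np
import pytest

from pmrgwas.simulate import GwasSimulator, SimulationConfig


@pytest.fixture(scope="session")
def small_study():
    """One modest LD-structured case/control study with ground truth."""
    cfg = SimulationConfig(n_cases=300, n_controls=300, n_markers=2000,
                           n_causal=5, h2=0.5, seed=42)
    sim = GwasSimulator(cfg)
    truth = sim.assign_effects()
    g, y = sim.simulate_case_control(truth)
    return g, y, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_dosages(rng, n, p, maf_low=0.1, maf_high=0.5):
    """Independent binomial(2, f) dosage columns (no LD)."""
    f = rng.uniform(maf_low, maf_high, p)
    return rng.binomial(2, f, size=(n, p)).astype(float)
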