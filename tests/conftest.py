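import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import riskcline as rc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_world():
    """A modest serial-founder world shared by unit tests.

    30 populations x 1,500 SNPs keeps every stage fast while leaving all
    frequency bins populated.
    """
    cfg = rc.SimulationConfig(n_populations=30, n_snps=1500, effective_size=500, seed=42)
    matrix, panel = rc.simulate_serial_founder(cfg)
    climate = rc.generate_climate(panel, seed=43)
    predictors = climate.copy()
    predictors.insert(0, "distance_km", panel.distances_km)
    return {"matrix": matrix, "panel": panel, "climate": climate, "predictors": predictors}


@pytest.fixture
def tiny_matrix():
    """Hand-sized matrix for formula spot checks."""
    return rc.FrequencyMatrix(
        snp_ids=np.array(["rs1", "rs2", "rs3", "rs4"], dtype=object),
        populations=["p1", "p2"],
        freq=np.array([[0.2, 0.5], [0.4, 0.1], [0.3, 0.9], [0.9, 0.5]]),
        designated_allele=np.array(["A", "C", "G", "T"], dtype=object),
    )
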