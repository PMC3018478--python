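import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from methgex.simulate import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """One modest seeded cohort shared by read-only tests."""
    cfg = GeneratorConfig(n_probes=900, n_genes=500, n_dm_hyper=50,
                          n_dm_hypo=20, n_regulated=25, n_linked=8,
                          n_de_up=25, n_de_down=25)
    return generate_dataset(cfg, seed=42)
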