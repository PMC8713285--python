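import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

# no example database: keeps runs deterministic and the tree clean
settings.register_profile("cystmine", database=None, deadline=None)
settings.load_profile("cystmine")

from cystmine.known import BARRETTIDE_C
from cystmine.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def barrettide_c():
    return BARRETTIDE_C


@pytest.fixture
def sim_config():
    """Small, fast default simulation config."""

    def make(**kwargs):
        defaults = dict(seed=7, n_decoys=15, n_precursors=2,
                        peak_noise_count=50)
        defaults.update(kwargs)
        return SimConfig(**defaults)

    return make


@pytest.fixture(scope="session")
def default_bundle():
    """A shared clean bundle (mutation 0, jitter 0) for read-only tests."""
    return simulate(
        SimConfig(seed=11, n_decoys=15, n_precursors=3, peak_noise_count=50)
    )


@pytest.fixture
def query_fasta(tmp_path, barrettide_c):
    path = tmp_path / "queries.fasta"
    path.write_text(f">{barrettide_c.name}\n{barrettide_c.sequence}\n")
    return path
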