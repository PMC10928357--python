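import numpy as np
import pandas as pd
import pytest

from terrsub.mixing import MixingParameters
from terrsub.synth import SynthConfig, generate_all


@pytest.fixture(scope="session")
def default_params() -> MixingParameters:
    return MixingParameters()


@pytest.fixture(scope="session")
def synth_tables() -> dict[str, pd.DataFrame]:
    """One default synthetic study shared across tests (seed 7)."""
    return generate_all(SynthConfig(seed=7))


@pytest.fixture()
def toy_gut() -> pd.DataFrame:
    """Tiny two-fish gut table covering kept/dropped replicate patterns."""
    rows = [
        # fish f1: kept (both replicates), dropped (one replicate)
        ("f1", "aqua_a", 1, 10), ("f1", "aqua_a", 2, 5),
        ("f1", "terr_b", 1, 10), ("f1", "terr_b", 2, 0),
        # fish f2: kept terrestrial, bat contamination
        ("f2", "terr_c", 1, 3), ("f2", "terr_c", 2, 7),
        ("f2", "Myotis daubentonii", 1, 4), ("f2", "Myotis daubentonii", 2, 4),
    ]
    return pd.DataFrame(
        rows, columns=["fish_id", "species_detected", "technical_replicate", "read_count"]
    )
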