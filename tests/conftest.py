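import numpy as np
import pandas as pd
import pytest

from tritroph.webgen import CommunityConfig, InteractionTable, generate_community


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return CommunityConfig(r1=12, r2=10, r3=8, a1=80, a2=60, a3=40,
                           alpha2=1.5, alpha3=2.0, seed=42)


@pytest.fixture(scope="session")
def small_community(small_config):
    return generate_community(small_config)


@pytest.fixture(scope="session")
def community_batch():
    """A batch of communities spanning the default parameter ranges."""
    from tritroph.experiment import generate_webs

    communities, _, _ = generate_webs(60, seed=2024)
    return communities


def make_table(rows):
    """Build an InteractionTable from (plant_sp, herb_sp, enemy_sp) triples."""
    frame = pd.DataFrame(
        {
            "plant_id": np.arange(1, len(rows) + 1),
            "plant_sp": [r[0] for r in rows],
            "herb_sp": [r[1] for r in rows],
            "enemy_sp": [r[2] for r in rows],
        }
    )
    return InteractionTable(frame=frame)
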