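import numpy as np
import pytest

from soilvirome import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def small_cfg():
    return simulate.SimConfig(
        seed=11,
        genome_length_range=(2_000, 4_000),
        planted_clusters=[(3, 97.0, 85.0), (3, 97.0, 85.0)],
    )


@pytest.fixture
def spacer_setup(small_cfg):
    db, lineages = simulate.make_host_db(
        n_hosts=4, spacers_per_host=2, cfg=small_cfg, hosts_per_genus=2
    )
    return db, lineages
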