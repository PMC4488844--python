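import numpy as np
import pytest

from lqtex import curated
from lqtex.synthetic_cohort import SimulationConfig, simulate_cohort
from lqtex.variant_model import Genotype, GenotypeTable


@pytest.fixture(scope="session")
def small_cohort():
    """Seven-family synthetic cohort (4 trios, 3 multiplex), small background."""
    config = SimulationConfig(
        seed=11, n_trio_families=4, n_multiplex_families=3, n_background_sites=300
    )
    return config, simulate_cohort(config)


@pytest.fixture(scope="session")
def unrelated_panel_table():
    """Genotype table of 138 singleton cases carrying the curated panel mutations."""
    sample_ids = [f"U{i:02d}" for i in range(1, 16)] + [
        f"N{i:03d}" for i in range(138 - 15)
    ]
    sites = [curated.to_variant_site(m) for m in curated.UNRELATED_CANDIDATES]
    gt = np.zeros((len(sample_ids), len(sites)), dtype=np.int8)
    for j, mut in enumerate(curated.UNRELATED_CANDIDATES):
        gt[sample_ids.index(mut.individual), j] = Genotype.het
    table = GenotypeTable(sample_ids=sample_ids, sites=sites, gt=gt)
    annotations = {
        curated.to_variant_site(m).key: curated.to_annotation(m)
        for m in curated.UNRELATED_CANDIDATES
    }
    return table, annotations
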