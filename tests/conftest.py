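import numpy as np
import pytest

from phosphorescue.differential_phospho import call_sites
from phosphorescue.phospho_io import compute_site_quant
from phosphorescue.synthetic_data import (
    PhosphoSimConfig,
    RnaseqSimConfig,
    simulate_phospho_dataset,
    simulate_rnaseq_dataset,
)

TIMEPOINTS = ("15min", "0.5h", "2h", "4h")


@pytest.fixture(scope="session")
def default_phospho():
    """Default-condition phosphoproteome simulation: 2000 sites, 6
    replicates, 4 timepoints, CV 0.15, 1.0 log2 effect, 0.8 rescue depth."""
    config = PhosphoSimConfig(seed=11)
    records, truth = simulate_phospho_dataset(config)
    return config, records, truth


@pytest.fixture(scope="session")
def default_phospho_calls(default_phospho):
    config, records, truth = default_phospho
    quants = [compute_site_quant(r) for r in records]
    calls = call_sites(quants, config.timepoints)
    by_site = {}
    for c in calls:
        by_site.setdefault(c.site_id, []).append(c)
    return calls, by_site


@pytest.fixture(scope="session")
def small_phospho():
    config = PhosphoSimConfig(n_sites=150, seed=7)
    records, truth = simulate_phospho_dataset(config)
    return config, records, truth


@pytest.fixture(scope="session")
def default_rnaseq():
    config = RnaseqSimConfig(seed=13)
    counts, sheet, truth = simulate_rnaseq_dataset(config)
    return config, counts, sheet, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
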