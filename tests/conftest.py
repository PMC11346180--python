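"""Shared fixtures: synthetic datasets generated once per session."""

import numpy as np
import pytest

from micropept.homology import ProteomeIndex
from micropept.synthetic_data import SimSpec, make_proteomes, make_taxonomy, simulate_psm_table


@pytest.fixture(scope="session")
def recovery_dataset():
    """5000-spectrum dataset with planted look-alikes, for parameter
    recovery checks: (spec, tree, proteomes, psm, denovo, truth)."""
    spec = SimSpec(
        seed=101,
        n_spectra=5000,
        fraction_human=0.5,
        fraction_planted_lookalikes=0.1,
    )
    tree = make_taxonomy(spec)
    proteomes = make_proteomes(tree, spec)
    psm, denovo, truth = simulate_psm_table(proteomes, tree, spec)
    return spec, tree, proteomes, psm, denovo, truth


@pytest.fixture(scope="session")
def recovery_indexes(recovery_dataset):
    _spec, _tree, proteomes, _psm, _denovo, _truth = recovery_dataset
    human = [e for e in proteomes if e.origin == "human"]
    microbiota = [e for e in proteomes if e.origin == "microbiota"]
    return ProteomeIndex(human, "human"), ProteomeIndex(microbiota, "microbiota")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240826)
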