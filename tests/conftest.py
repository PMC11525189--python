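"""Shared fixtures: simulated MPRA libraries at two scales.

The session-scoped full-scale library (1,000 genes -> 3,000 fragments,
8 barcodes each, 3 replicates) backs the end-to-end recovery tests; the
small library keeps unit tests fast.
"""

import pytest

from tssreg import quantify, synthio


@pytest.fixture(scope="session")
def mpra_config() -> synthio.SynthConfig:
    return synthio.SynthConfig(n_genes=1000, rng_seed=0)


@pytest.fixture(scope="session")
def mpra_lib(mpra_config) -> synthio.SimulatedLibrary:
    return synthio.simulate_library(mpra_config, "downstream")


@pytest.fixture(scope="session")
def mpra_activity(mpra_lib):
    props = quantify.dna_proportions(mpra_lib.dna_counts)
    return quantify.quantify_expression(mpra_lib.rna_counts, mpra_lib.barcode_map, props)


@pytest.fixture(scope="session")
def small_config() -> synthio.SynthConfig:
    return synthio.SynthConfig(n_genes=100, rng_seed=7)


@pytest.fixture(scope="session")
def small_lib(small_config) -> synthio.SimulatedLibrary:
    return synthio.simulate_library(small_config, "downstream")


@pytest.fixture(scope="session")
def small_activity(small_lib):
    props = quantify.dna_proportions(small_lib.dna_counts)
    return quantify.quantify_expression(small_lib.rna_counts, small_lib.barcode_map, props)
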