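"""Shared fixtures: a miniature allopolyploid system with known truth."""

import numpy as np
import pandas as pd
import pytest

from polyhomeo import synthdata


@pytest.fixture(scope="session")
def params():
    return synthdata.SynthParams(n_genes_per_subgenome=200, seed=11)


@pytest.fixture(scope="session")
def reference(params):
    return synthdata.generate_reference(params)


@pytest.fixture(scope="session")
def annotation(reference):
    return reference[0]


@pytest.fixture(scope="session")
def hmap(reference):
    return reference[1]


@pytest.fixture(scope="session")
def expression(reference, params):
    annotation, hmap = reference
    return synthdata.simulate_expression(annotation, hmap, None, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
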