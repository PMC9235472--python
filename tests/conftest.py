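"""Shared fixtures: synthetic tables, a demo word-vector file, and a small
trained model reused across test modules."""

import numpy as np
import pytest

from mlpathway.dataset_io import generate_fixture, write_demo_wordvec_file
from mlpathway.model import MetabolicPathwayClassifier, small_layout


@pytest.fixture(scope="session")
def wordvec_file(tmp_path_factory):
    path = tmp_path_factory.mktemp("wordvec") / "demo_vectors.txt"
    return str(write_demo_wordvec_file(path, r=50))


@pytest.fixture(scope="session")
def fixture_table():
    """200-compound, 6-label synthetic table with planted structure."""
    return generate_fixture(200, n_pathways=6, seed=7)


@pytest.fixture(scope="session")
def trained_model(fixture_table, wordvec_file):
    """A small model trained briefly on the fixture (for prediction-path and
    interpretation tests, not for performance assertions)."""
    est = MetabolicPathwayClassifier(
        **small_layout(), epochs=15, random_state=0,
        pathway_names=fixture_table.pathway_names, wordvec_file=wordvec_file)
    est.fit(fixture_table.smiles, fixture_table.Y)
    return est
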