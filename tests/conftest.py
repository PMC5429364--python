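"""Shared fixtures: synthetic corpora generated once per session."""

import numpy as np
import pytest

from proteus.dataset_folds import build_folds
from proteus.forest_model import ForestConfig, cross_validate
from proteus.synthetic_fixtures import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def corpus_small():
    """60-protein corpus: enough signal for fast end-to-end checks."""
    return generate_corpus(GeneratorConfig(n_proteins=60, seed=11))


@pytest.fixture(scope="session")
def corpus_tiny():
    """15 short proteins for smoke tests of expensive routines."""
    return generate_corpus(
        GeneratorConfig(
            n_proteins=15,
            length_range=(60, 120),
            protean_protein_fraction=0.6,
            seed=23,
        )
    )


@pytest.fixture(scope="session")
def corpus200():
    """The default study-condition corpus: 200 proteins, ~2% protean residues."""
    return generate_corpus(GeneratorConfig(seed=5))


@pytest.fixture(scope="session")
def folds_small(corpus_small):
    return build_folds(corpus_small.clusters, k=5, seed=11)


@pytest.fixture(scope="session")
def cv_tracks_small(corpus_small, folds_small):
    """Out-of-fold score tracks on the small corpus (50 trees)."""
    return cross_validate(
        corpus_small.proteins,
        folds_small,
        ForestConfig(n_trees=50, seed=11),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
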