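"""Shared fixtures: synthetic corpora and fitted estimators.

The expensive objects (a generated corpus, a predictor trained to
convergence, a fitted marker-set estimator) are session-scoped so the
whole suite trains each of them once.
"""

import pytest

from geval.degrade import (
    SyntheticCorpusSpec,
    generate_synthetic_corpus,
    train_validation_split,
)
from geval.genome import AnnotatedGenome, Contig, Feature
from geval.markers import MarkerSetEstimator
from geval.matrix import build_training_matrix
from geval.training import ConsistencyPredictor

#: corpus used by the training/scoring/degradation tests; small enough to
#: train in seconds but structured like the full study corpus
SMALL_SPEC = SyntheticCorpusSpec(
    n_genomes=150,
    n_subsystems=8,
    roles_per_subsystem=6,
    n_noise_roles=30,
    n_universal_roles=10,
    grouping_sizes=(50, 50, 50),
    seed=2,
)

#: fast random-forest settings used throughout the suite
FAST_RF = {"n_estimators": 20}


@pytest.fixture(scope="session")
def small_corpus():
    return generate_synthetic_corpus(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_matrix(small_corpus):
    genomes, labels = small_corpus
    return build_training_matrix(genomes, labels.role_set)


@pytest.fixture(scope="session")
def split(small_matrix):
    return train_validation_split(small_matrix, validation_fraction=0.20, seed=2)


@pytest.fixture(scope="session")
def fitted_predictor(split):
    train, _ = split
    return ConsistencyPredictor(model_params=FAST_RF, seed=2).fit(train)


@pytest.fixture(scope="session")
def marker_estimator(small_corpus):
    genomes, _ = small_corpus
    return MarkerSetEstimator().fit(genomes)


@pytest.fixture
def tiny_genome():
    """A hand-built genome: 2 contigs, 3 features."""
    return AnnotatedGenome(
        genome_id="toy.1",
        name="Toyobacter exemplaris",
        domain="bacteria",
        lineage=["Toyaceae", "Toyobacter", "Toyobacter exemplaris"],
        contigs=[
            Contig(contig_id="c1", length=10000),
            Contig(contig_id="c2", length=5000),
        ],
        features=[
            Feature("toy.1.peg.1", "c1", 100, 1299, "+", "Role A"),
            Feature("toy.1.peg.2", "c1", 2000, 3199, "-", "Role A"),
            Feature("toy.1.peg.3", "c2", 500, 1699, "+", "Role A / Role B"),
        ],
    )
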