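"""Shared fixtures: a synthetic dataset generated once per session.

The default planted-module fixture (300 genes, a 20-gene disease
module, seed 42) exercises every pipeline stage; the leave-one-out
evaluation over it is expensive enough (~20 s) to be computed once and
shared.
"""

from types import SimpleNamespace

import numpy as np
import pytest

from gcngp import (
    FixtureConfig,
    ModelConfig,
    build_feature_matrices,
    generate_fixture,
    load_ppi,
    read_annotations,
)
from gcngp.prioritizer import loocv_evaluate
from gcngp.synthetic import read_coordinates, read_gmt

PIPELINE_MODEL_SEED = 7


def load_dataset(fixture_path):
    network = load_ppi(fixture_path / "ppi_edges.tsv")
    annotations = read_annotations(fixture_path / "annotations.tsv")
    matrices = build_feature_matrices(annotations, network.gene_order)
    coordinates = read_coordinates(fixture_path / "coordinates.tsv")
    gene_sets = read_gmt(fixture_path / "diseases.gmt")
    disease = [
        g for g in gene_sets["planted_module"] if g in network.index()
    ]
    return SimpleNamespace(
        path=fixture_path,
        network=network,
        annotations=annotations,
        matrices=matrices,
        coordinates=coordinates,
        disease=disease,
    )


@pytest.fixture(scope="session")
def planted_dataset(tmp_path_factory):
    """Default planted-module fixture (both signal channels on)."""
    path = tmp_path_factory.mktemp("planted_fixture")
    generate_fixture(FixtureConfig(), path)
    return load_dataset(path)


@pytest.fixture(scope="session")
def null_dataset(tmp_path_factory):
    """Both signals ablated: p_in = p_out, equal term probabilities."""
    path = tmp_path_factory.mktemp("null_fixture")
    generate_fixture(
        FixtureConfig(
            p_in=0.01, p_out=0.01, p_term_disease=0.05, p_term_background=0.05
        ),
        path,
    )
    return load_dataset(path)


@pytest.fixture(scope="session")
def planted_rank_lists(planted_dataset):
    """Full LOOCV of the planted disease with the default model."""
    return loocv_evaluate(
        planted_dataset.disease,
        planted_dataset.matrices,
        planted_dataset.network,
        planted_dataset.coordinates,
        ModelConfig(seed=PIPELINE_MODEL_SEED),
        disease_id="planted_module",
    )


@pytest.fixture(scope="session")
def null_rank_lists(null_dataset):
    return loocv_evaluate(
        null_dataset.disease,
        null_dataset.matrices,
        null_dataset.network,
        null_dataset.coordinates,
        ModelConfig(seed=PIPELINE_MODEL_SEED),
        disease_id="null_module",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
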