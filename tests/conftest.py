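"""Shared fixtures: all data is generated programmatically and seeded."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import fragilib as fl


@pytest.fixture(scope="session")
def sim_genome():
    """200 kb i.i.d. synthetic genome at human-like GC."""
    return fl.simulate_genome(200_000, gc=0.41, seed=11)


@dataclass
class PlantedBundle:
    genome: object
    truth: object
    breaks: object
    table: object
    extractor: object
    matrix: object
    model: object
    test_matrix: object
    thresholds: list


@pytest.fixture(scope="session")
def planted_bundle(sim_genome):
    """End-to-end fixture: planted octamer fragility (short-range limit,
    log-normal propensities sd 2.5, baseline 0.1), scored from paired
    multinomial count tables, assembled into features and trained with
    a gradient-boosted classifier."""
    seed = 11
    truth = fl.FragilityGroundTruth.random(
        seed, effect_sd=2.5, sigmas=(0.0,), weights=(1.0,), baseline=0.1
    )
    breaks = fl.simulate_breakpoints(sim_genome, truth, 2000, seed=seed + 1)
    bg = fl.background_octamer_frequencies(sim_genome)
    case, ctrl = fl.simulate_count_tables(
        truth, 5_000_000, 50_000_000, seed=seed + 2, background=bg
    )
    table = fl.impute_sparse_kmers(fl.fragility_zscores(case, ctrl))
    extractor = fl.FeatureExtractor(score_tables={"planted": table})
    matrix = fl.assemble_feature_matrix(sim_genome, breaks, extractor, seed=seed + 3)
    model = fl.train_classifier(
        matrix, kind="gbm", search_budget=3, cv_folds=2, seed=seed, extractor=extractor
    )
    test_matrix = matrix.iloc[model.test_index]
    thresholds = fl.thresholds_from_fpr(model, test_matrix, [0.01, 0.05, 0.1, 0.2])
    return PlantedBundle(
        sim_genome, truth, breaks, table, extractor, matrix, model, test_matrix, thresholds
    )


@pytest.fixture()
def tiny_genome():
    return fl.GenomeSequence({"chr1": "ACGTACGTACGTACGTACGT"})
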