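import numpy as np
import pytest

from promscope.fishquant import quantify_field, summarize_culture
from promscope.reads import ReadClassifier
from promscope.simulate import (
    SimulationConfig,
    default_locus,
    default_transcripts,
    simulate_drs_reads,
    simulate_fish_images,
)


@pytest.fixture(scope="session")
def ann():
    return default_locus()


@pytest.fixture(scope="session")
def transcripts():
    return default_transcripts(seed=0)


@pytest.fixture(scope="session")
def classifier(ann):
    return ReadClassifier(ann)


@pytest.fixture(scope="session")
def drs_run(ann, classifier):
    """A 4-replicate long-read experiment at the default mixture with decay,
    classified once and shared across tests."""
    config = SimulationConfig(n_reads=4000, n_replicates=4, decay_fraction=0.3)
    reads, truth = simulate_drs_reads(ann, config, seed=20240)
    classified = classifier.classify_reads(reads)
    return {"config": config, "reads": reads, "truth": truth, "classified": classified}


@pytest.fixture(scope="session")
def fish_run():
    """Four default-condition fields (>= 100 cells each), simulated and
    quantified once; shared by the imaging recovery tests."""
    results = []
    for seed in (300, 301, 302, 303):
        config = SimulationConfig(n_fields=1, n_cells_per_field=100)
        field = simulate_fish_images(config, seed=seed)[0]
        cell_df, spots = quantify_field(field.image)
        results.append(
            {
                "field": field,
                "cells": cell_df,
                "spots": spots,
                "summary": summarize_culture(cell_df),
            }
        )
    return results


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
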