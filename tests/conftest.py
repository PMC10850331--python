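"""Shared fixtures: one seeded synthetic study run reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from somscape import preprocess, segment, simulate, som

STUDY_SEED = 11
SOM_SEED = 7
KMEANS_SEED = 3


@pytest.fixture(scope="session")
def paper_truth() -> simulate.SimulationTruth:
    design = simulate.make_design("paper")
    return simulate.make_truth(design, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def paper_data(paper_truth) -> tuple[pd.DataFrame, pd.DataFrame]:
    return simulate.simulate_counts(paper_truth)


@pytest.fixture(scope="session")
def paper_expr(paper_data) -> pd.DataFrame:
    counts, metadata = paper_data
    expr, _ = preprocess.preprocess_counts(counts, metadata)
    return expr


@pytest.fixture(scope="session")
def paper_cond(paper_expr, paper_data) -> pd.DataFrame:
    _, metadata = paper_data
    return preprocess.average_replicates(paper_expr, metadata)


@pytest.fixture(scope="session")
def paper_som(paper_expr) -> som.SOMModel:
    return som.train_som(paper_expr, som.SOMConfig(seed=SOM_SEED))


@pytest.fixture(scope="session")
def paper_grid(paper_som, paper_expr) -> som.MetageneGrid:
    return som.metagene_grid(paper_som, paper_expr)


@pytest.fixture(scope="session")
def paper_seg(paper_grid) -> segment.GridSegmentation:
    seg = segment.kmeans_grid(paper_grid, 20, seed=KMEANS_SEED)
    return segment.significance_filter(seg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
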