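"""Shared fixtures: seeded synthetic datasets and cached analysis runs."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
import pytest

from lncmodnet import (
    SimulationConfig,
    WGCNA,
    generate_design,
    simulate_dataset,
)
from lncmodnet.preprocess import TMMNormalizer, filter_low_expression


@pytest.fixture(scope="session")
def design():
    return generate_design()


@dataclass
class AnalysisRun:
    """One seeded fixture taken through normalization and module detection."""

    seed: int
    counts: pd.DataFrame
    truth: object
    norm: pd.DataFrame
    wgcna: WGCNA

    def truth_labels(self) -> pd.Series:
        return pd.Series(self.truth.modules).reindex(self.norm.index)

    def match_detected_to_planted(self) -> dict[int, int]:
        """Detected module -> planted module with maximal gene overlap."""
        planted = {
            m: set(self.truth.module_genes(m))
            for m in range(1, self.truth.n_modules + 1)
        }
        out = {}
        for m in self.wgcna.modules_.module_ids:
            genes = set(self.wgcna.modules_.genes_in(m))
            out[m] = max(planted, key=lambda t: len(genes & planted[t]))
        return out


def _run_seed(design, seed: int) -> AnalysisRun:
    counts, truth = simulate_dataset(SimulationConfig(seed=seed), design)
    norm = TMMNormalizer().fit_transform(filter_low_expression(counts, design))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wgcna = WGCNA().fit(norm)
    return AnalysisRun(seed=seed, counts=counts, truth=truth, norm=norm, wgcna=wgcna)


@pytest.fixture(scope="session")
def run_factory(design):
    cache: dict[int, AnalysisRun] = {}

    def get(seed: int) -> AnalysisRun:
        if seed not in cache:
            cache[seed] = _run_seed(design, seed)
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def default_run(run_factory) -> AnalysisRun:
    """The default study fixture (seed 1) through module detection."""
    return run_factory(1)


@pytest.fixture(scope="session")
def multi_seed_runs(run_factory) -> list[AnalysisRun]:
    """Ten replicate fixtures (seeds 1..10) for power/recovery checks."""
    return [run_factory(seed) for seed in range(1, 11)]
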