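"""Shared fixtures: a small bundle for unit-level integration tests and one
session-scoped full-scale benchmark run shared by the end-to-end tests."""

from __future__ import annotations

import pytest

from glypsearch import (
    SearchConfig,
    build_library,
    estimate_fdr,
    search_all,
)
from glypsearch.simulate import FixtureConfig, evaluate_identifications, generate_benchmark


@pytest.fixture(scope="session")
def small_bundle():
    """A cheap fixture set: 20 peptides, 40 true + 40 noise queries."""
    return generate_benchmark(FixtureConfig(n_peptides=20, n_true_queries=40, seed=7))


@pytest.fixture(scope="session")
def small_library(small_bundle):
    return build_library(small_bundle.identifications, small_bundle.library_spectra)


@pytest.fixture(scope="session")
def benchmark():
    """The full desk-scale benchmark: 200 peptides x 85 glycans, 500 true +
    500 pure-noise queries, searched at default settings and filtered at the
    1% FDR level."""
    config = SearchConfig()
    bundle = generate_benchmark(FixtureConfig(seed=42))
    library = build_library(bundle.identifications, bundle.library_spectra)
    result = search_all(bundle.queries, library, bundle.glycans, config)
    fdr_result, accepted = estimate_fdr(result.best, level=config.fdr_level)
    metrics = evaluate_identifications(accepted, bundle.truth)
    return {
        "config": config,
        "bundle": bundle,
        "library": library,
        "result": result,
        "fdr_result": fdr_result,
        "accepted": accepted,
        "metrics": metrics,
    }
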