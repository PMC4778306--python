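"""Shared fixtures: small simulated populations reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from binqtl import (
    GenomeSpec,
    breed_ril_population,
    filter_segregation,
    observe_gbs,
)
from binqtl.binmap import build_bins, build_genetic_map
from binqtl.calling import call_population, extract_breakpoints


@pytest.fixture(scope="session")
def small_spec() -> GenomeSpec:
    """Three 100-Mb chromosomes of 120 cM with 3000 SNPs each."""
    return GenomeSpec.uniform(3, 100_000_000, 120.0, 3000, seed=1)


@pytest.fixture(scope="session")
def population(small_spec):
    """300 F11 RILs bred by single-seed descent (fixed seed)."""
    return breed_ril_population(small_spec, n_rils=300, n_selfing_generations=10, seed=42)


@pytest.fixture(scope="session")
def clean_pipeline(small_spec, population):
    """Error-free, fully observed calls pushed through filter/call/bin/map."""
    matrix = observe_gbs(population, small_spec, observe_rate=1.0, allele_error_rate=0.0, seed=7)
    filtered, report = filter_segregation(matrix)
    blocks = call_population(filtered)
    breakpoints = extract_breakpoints(blocks)
    binmap = build_bins(blocks, breakpoints, small_spec)
    gmap = build_genetic_map(binmap)
    return {
        "matrix": matrix,
        "filtered": filtered,
        "filter_report": report,
        "blocks": blocks,
        "breakpoints": breakpoints,
        "binmap": binmap,
        "gmap": gmap,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
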