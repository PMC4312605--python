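"""Shared fixtures: a small simulated four-library dataset.

The desk-scale dataset (20k reads/library, 50 kb genome) is generated once
per session; tests needing the full-scale study conditions build their own.
"""

from __future__ import annotations

import pytest

from droughtmir.preprocess import collapse, process_library
from droughtmir.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_reads_per_library=20_000,
                            genome_length=50_000)


@pytest.fixture(scope="session")
def small_dataset(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("smallsim")
    bundle, counts, paths = simulate_dataset(small_config, outdir)
    return {"config": small_config, "bundle": bundle,
            "counts": counts, "paths": paths, "outdir": outdir}


@pytest.fixture(scope="session")
def small_clean_sets(small_dataset):
    cfg = small_dataset["config"]
    return [
        process_library(small_dataset["paths"][lib], cfg.adapter_sequence,
                        library=lib)
        for lib in ("C1", "T1", "C2", "T2")
    ]


@pytest.fixture(scope="session")
def small_tags(small_clean_sets):
    return collapse(small_clean_sets)
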