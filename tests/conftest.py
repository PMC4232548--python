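"""Shared fixtures: a desk-scale synthetic dataset with planted truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from genomescan.sim import (
    SimulationConfig,
    generate_reference,
    plant_variants,
    simulate_dataset,
)


def small_config(seed: int = 11) -> SimulationConfig:
    """A compact genome exercising every planted signal class."""
    return SimulationConfig(
        chromosome_lengths=[
            ("chr1", 600_000),
            ("chr2", 400_000),
            ("chr3", 300_000),
            ("chrW", 200_000),
        ],
        loh_tracts=[("chr1", 100_000, 400_000)],
        ploidy_map={"chr1": 2, "chr2": 3, "chr3": 4, "chrW": 1},
        viral_sites=[
            ("chr1", 450_000, "forward", "all_alleles"),
            ("chr3", 150_000, "reverse", "partial"),
        ],
        seed=seed,
    )


@pytest.fixture(scope="session")
def config() -> SimulationConfig:
    return small_config()


@pytest.fixture(scope="session")
def reference(config):
    return generate_reference(config)


@pytest.fixture(scope="session")
def planted(config, reference):
    """Single-sample planted variants: (records, truth frame)."""
    rng = np.random.default_rng(config.seed + 7)
    return plant_variants(reference, config, rng)


@pytest.fixture(scope="session")
def dataset(config, tmp_path_factory):
    """Full on-disk bundle: VCFs, coverage, scaffolds, read pairs, truth."""
    out = tmp_path_factory.mktemp("dataset")
    return simulate_dataset(config, out)


@pytest.fixture(scope="session")
def truth_variants(dataset) -> dict[str, pd.DataFrame]:
    return {
        s: pd.read_csv(dataset["truth_dir"] / f"truth_variants_{s}.tsv", sep="\t")
        for s in dataset["samples"]
    }
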