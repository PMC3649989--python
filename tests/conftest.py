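"""Shared fixtures: small simulated studies and hand-built genotype tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from introscan.io_formats import GenotypeMatrix
from introscan.synthetic_data import (
    SharedTract,
    SimConfig,
    simulate_admixed_population,
    simulate_ancestral_panels,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A fast, single-chromosome study configuration."""
    return SimConfig(
        n_chromosomes=1,
        chromosome_length_bp=40_000_000,
        n_populations=3,
        n_individuals=8,
        n_reference_haplotypes=12,
        shared_tract_spec=[
            SharedTract("chr1", 10_000_000, 18_000_000, 0.95, "mexicana")
        ],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_panels(small_cfg):
    return simulate_ancestral_panels(small_cfg)


@pytest.fixture(scope="session")
def small_population(small_cfg, small_panels):
    return simulate_admixed_population(small_panels, small_cfg, 0, "maize")


@pytest.fixture()
def toy_genotypes() -> GenotypeMatrix:
    """Hand-built 3-site, 4-individual matrix over two populations."""
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * 3,
            "bp": [100, 5000, 9000],
            "cM": [0.0001, 0.005, 0.009],
            "ref": ["A", "C", "G"],
            "alt": ["G", "T", "A"],
        }
    )
    dosages = np.array(
        [
            [0, 1, 2, 2],
            [1, 1, 0, 0],
            [2, 2, 0, 1],
        ]
    )
    individuals = ["m1", "m2", "x1", "x2"]
    populations = {"m1": "popA", "m2": "popA", "x1": "popB", "x2": "popB"}
    roles = {"popA": "admixed_maize", "popB": "admixed_mexicana"}
    return GenotypeMatrix(sites, dosages, individuals, populations, roles)
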