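"""Shared fixtures: hand-built matrices and session-scoped simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from swampx.genotype_data import GenotypeMatrix, allele_counts_by_population


def build_matrix(sites_rows, samples_rows, dosage) -> GenotypeMatrix:
    sites = pd.DataFrame(sites_rows,
                         columns=["chrom", "pos", "ref", "alt", "chrom_class"])
    samples = pd.DataFrame(samples_rows,
                           columns=["sample_id", "population", "sex"])
    return GenotypeMatrix(sites, samples, np.asarray(dosage, dtype=np.int16))


@pytest.fixture
def small_gm() -> GenotypeMatrix:
    """4 samples (2 populations, mixed sexes), autosome + X + mito sites."""
    sites = [
        ("chr1", 100, "A", "G", "autosome"),
        ("chr1", 200, "C", "T", "autosome"),
        ("chr2", 150, "G", "A", "autosome"),
        ("chrX", 500, "T", "C", "X"),
        ("chrX", 200_000, "A", "C", "X"),
        ("chrM", 10, "G", "T", "mito"),
    ]
    samples = [
        ("P1_F", "P1", "female"),
        ("P1_M", "P1", "male"),
        ("P2_F", "P2", "female"),
        ("P2_M", "P2", "male"),
    ]
    dosage = [
        [0, 1, 2, 1],   # autosomal
        [1, 1, 0, 0],
        [2, 2, 1, 0],
        [2, 1, 0, 0],   # X: males carry 0 or 1 copies
        [1, 0, 2, 1],
        [1, 0, 1, 1],   # mito: everyone haploid
    ]
    return build_matrix(sites, samples, dosage)


@pytest.fixture(scope="session")
def swamping_run():
    """One nuclear-swamping simulation shared across tests."""
    from swampx.synthetic_data import nuclear_swamping_scenario

    model, gm, truth = nuclear_swamping_scenario(seed=11)
    return model, gm, truth


@pytest.fixture(scope="session")
def swamping_table(swamping_run):
    from swampx.genotype_data import filter_complete_cases

    _, gm, _ = swamping_run
    return allele_counts_by_population(filter_complete_cases(gm))
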