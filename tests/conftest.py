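"""Shared fixtures: tiny hand-built tables and a small simulated pair."""

import numpy as np
import pandas as pd
import pytest

from gwasdecomp import SimConfig, SummaryStatsTable, simulate_pair


def make_table(trait_id, rows):
    """Build a SummaryStatsTable from (snp, chrom, pos, ea, oa, beta, se, p) rows."""
    df = pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pval"],
    )
    df["chrom"] = df["chrom"].astype(str)
    return SummaryStatsTable(trait_id=trait_id, data=df)


@pytest.fixture
def toy_tables():
    """Two traits x three SNPs, consistent alleles."""
    t1 = make_table(
        "t1",
        [
            ("rs1", "1", 1000, "A", "G", 0.10, 0.05, 0.04),
            ("rs2", "1", 2000, "C", "T", -0.20, 0.10, 0.01),
            ("rs3", "2", 1500, "A", "C", 0.05, 0.05, 0.30),
        ],
    )
    t2 = make_table(
        "t2",
        [
            ("rs1", "1", 1000, "A", "G", 0.30, 0.10, 0.002),
            ("rs2", "1", 2000, "C", "T", 0.10, 0.10, 0.35),
            ("rs3", "2", 1500, "A", "C", -0.15, 0.05, 0.003),
        ],
    )
    return [t1, t2]


SMALL_CFG = SimConfig(
    m_traits=48,
    n_snps=400,
    k_true=3,
    sparsity=0.05,
    factor_scale=0.05,
    n_modality_blocks=4,
    n_sample_a=5000,
    n_sample_b=2500,
    seed=11,
)


@pytest.fixture(scope="session")
def small_pair():
    """A quick, strongly-identified simulated pair for unit tests."""
    return simulate_pair(SMALL_CFG)


@pytest.fixture(scope="session")
def small_matrices(small_pair):
    return (
        small_pair.effect_matrix("a", "z_value"),
        small_pair.effect_matrix("b", "z_value"),
    )
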