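"""Pruning, clumping, lead augmentation and the effective-SNP count."""

import numpy as np
import pandas as pd
import pytest

from gwasdecomp import (
    ClumpConfig,
    MatrixLd,
    augment_lead_snps,
    clump,
    effective_n_snps,
    ld_prune,
    min_p_across_traits,
)
from gwasdecomp.exceptions import ValidationError
from conftest import make_table
from oracles import brute_clump, brute_prune, m_eff_eigen


def block_ld_instance(rng, n_snps=60, max_block=6):
    """Random block-LD toy: equicorrelated blocks, random r2 per block."""
    sizes = []
    while sum(sizes) < n_snps:
        sizes.append(int(rng.integers(1, max_block + 1)))
    sizes[-1] -= sum(sizes) - n_snps
    if sizes[-1] == 0:
        sizes.pop()
    ids, chroms, positions, block_of = [], [], [], []
    R = np.eye(n_snps)
    start = 0
    pos = 1
    for bi, size in enumerate(sizes):
        r2 = float(rng.uniform(0, 0.95))
        r = np.sqrt(r2)
        for j in range(size):
            ids.append(f"s{start + j}")
            chroms.append(str(1 + bi % 3))
            positions.append(pos)
            pos += int(rng.integers(1_000, 300_000))
            block_of.append(bi)
        blk = slice(start, start + size)
        R[blk, blk] = r
        np.fill_diagonal(R[blk, blk], 1.0)
        start += size
        if bi % 3 == 2:
            pos = 1
    df = pd.DataFrame({"snp_id": ids, "chrom": chroms, "pos": positions})
    return df, MatrixLd(R, ids, signed=True), block_of


class TestPrune:
    def test_high_r2_pair_keeps_first_by_position(self):
        df = pd.DataFrame({"snp_id": ["b", "a"], "chrom": ["1", "1"], "pos": [2000, 1000]})
        ld = MatrixLd([[1, np.sqrt(0.9)], [np.sqrt(0.9), 1]], ["b", "a"])
        assert ld_prune(df, ld, r2_max=0.3) == ["a"]

    def test_independent_snps_all_kept(self):
        df = pd.DataFrame({"snp_id": list("abc"), "chrom": "1", "pos": [1, 2, 3]})
        ld = MatrixLd(np.eye(3), list("abc"))
        assert ld_prune(df, ld, r2_max=0.3) == ["a", "b", "c"]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        df, ld, _ = block_ld_instance(rng)
        got = ld_prune(df, ld, r2_max=0.3, window_bp=1_000_000)
        want = brute_prune(
            list(zip(df["snp_id"], df["chrom"], df["pos"])), ld.r2, 0.3, 1_000_000
        )
        assert got == want


class TestClump:
    def test_forced_three_snp_example(self):
        pmin = pd.DataFrame(
            {
                "snp_id": ["s1", "s2", "s3"],
                "chrom": ["1", "1", "1"],
                "pos": [1000, 2000, 3000],
                "p_min": [1e-8, 1e-6, 0.5],
            }
        )
        R = np.eye(3)
        R[0, 1] = R[1, 0] = np.sqrt(0.5)
        ld = MatrixLd(R, ["s1", "s2", "s3"])
        clumps = clump(pmin, ld, ClumpConfig())
        assert [c.lead for c in clumps] == ["s1"]
        assert clumps[0].members == ["s2"]  # s3: p too large to lead, r2 too low to claim

    def test_different_chromosomes_both_lead(self):
        pmin = pd.DataFrame(
            {"snp_id": ["a", "b"], "chrom": ["1", "2"], "pos": [1, 1], "p_min": [1e-8, 1e-7]}
        )
        ld = MatrixLd(np.eye(2), ["a", "b"])
        assert sorted(c.lead for c in clump(pmin, ld)) == ["a", "b"]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        df, ld, _ = block_ld_instance(rng, n_snps=100)
        df = df.copy()
        df["p_min"] = 10.0 ** rng.uniform(-9, 0, len(df))
        cfg = ClumpConfig()
        got = [(c.lead, c.members) for c in clump(df, ld, cfg)]
        want = brute_clump(
            list(zip(df["snp_id"], df["chrom"], df["pos"], df["p_min"])),
            ld.r2, cfg.lead_p_max, cfg.clump_r2_max, cfg.clump_window_bp,
        )
        assert got == [(l, m) for l, m in want]

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(42)
        df, ld, _ = block_ld_instance(rng, n_snps=50)
        df["p_min"] = 10.0 ** rng.uniform(-9, 0, len(df))
        base = [(c.lead, c.members) for c in clump(df, ld)]
        shuffled = df.sample(frac=1.0, random_state=3)
        assert [(c.lead, c.members) for c in clump(shuffled, ld)] == base


def test_min_p_across_traits(toy_tables):
    out = min_p_across_traits(toy_tables)
    np.testing.assert_allclose(out["p_min"], [0.002, 0.01, 0.003])
    single = min_p_across_traits(toy_tables[:1])
    np.testing.assert_allclose(single["p_min"], [0.04, 0.01, 0.30])


def test_min_p_all_ones():
    t = make_table("t", [("rs1", "1", 1, "A", "G", 0.0, 1.0, 1.0)])
    out = min_p_across_traits([t, t, t])
    assert out["p_min"].iloc[0] == 1.0


class TestAugment:
    def test_union_preserves_order_and_counts(self):
        snps, added = augment_lead_snps(["a", "b"], [["b", "c"]])
        assert snps == ["a", "b", "c"] and added == 1

    def test_empty_external_is_identity(self):
        assert augment_lead_snps(["a", "b"], []) == (["a", "b"], 0)

    def test_shared_external_snp_dedup(self):
        snps, added = augment_lead_snps(["a"], [["d"], ["d", "e"]])
        assert snps == ["a", "d", "e"] and added == 2


class TestEffectiveN:
    def test_identity_correlation(self):
        ld = MatrixLd(np.eye(10), [f"s{i}" for i in range(10)])
        assert effective_n_snps(ld, [f"s{i}" for i in range(10)]) == pytest.approx(10.0)

    def test_perfect_dependence(self):
        ld = MatrixLd([[1.0, 1.0], [1.0, 1.0]], ["a", "b"])
        assert effective_n_snps(ld, ["a", "b"]) == pytest.approx(1.0)

    def test_exchangeable_matches_eigen_oracle(self):
        R = np.full((5, 5), 0.3)
        np.fill_diagonal(R, 1.0)
        ld = MatrixLd(R, list("abcde"))
        assert effective_n_snps(ld, list("abcde")) == pytest.approx(m_eff_eigen(R), abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_shrinkage_property(self, seed):
        """M_eff <= M, equality iff identity correlation."""
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(40, 8))  # 40 observations of 8 SNPs
        snps = [f"s{i}" for i in range(8)]
        ld = MatrixLd(np.corrcoef(A.T), snps)
        meff = effective_n_snps(ld, snps)
        assert meff <= 8 + 1e-9
        assert meff < 8  # random correlations never exactly identity

    def test_non_psd_rejected(self):
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        ld = MatrixLd(R, list("abc"))
        with pytest.raises(ValidationError):
            effective_n_snps(ld, list("abc"))


def test_one_lead_per_causal_block(small_pair):
    """Prune + clump at field defaults keeps exactly one lead per planted
    causal LD block (within-block r2 > 0.1, between-block r2 = 0)."""
    truth = small_pair.truth
    pmin = min_p_across_traits(small_pair.tables_a)
    ld = truth.ld_source()
    kept = ld_prune(pmin, ld, r2_max=0.3, window_bp=1_000_000)
    pruned = pmin[pmin["snp_id"].isin(set(kept))].reset_index(drop=True)
    clumps = clump(pruned, ld, ClumpConfig())
    # every lead sits in a distinct block
    block_of = dict(zip(truth.snp_registry["snp_id"], truth.block_of_snp))
    lead_blocks = [block_of[c.lead] for c in clumps]
    assert len(lead_blocks) == len(set(lead_blocks))
    # causal blocks with genome-wide-suggestive signal are all represented
    strong = set()
    sig = pmin[pmin["p_min"] < 1e-7]
    strong = {block_of[s] for s in sig["snp_id"]} & set(truth.causal_blocks.tolist())
    assert strong <= set(lead_blocks)
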