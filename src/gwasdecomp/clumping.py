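"""LD pruning and p-value clumping of multi-trait GWAS SNP sets.

Nearby variants are correlated through linkage disequilibrium, so the raw
SNP dimension of a multi-trait effect matrix is massively redundant.  The
reduction pipeline is:

1. *prune* — greedy scan in genomic order keeping a SNP only if its r2 with
   every previously kept SNP within the window (same chromosome) stays
   below a ceiling (default 0.3);
2. *clump* — take each SNP's smallest p-value across all traits, walk
   candidates with p below a lead threshold (default 1e-5) in ascending p,
   promote each unclaimed candidate to a lead, and claim every unclaimed
   SNP within the window whose r2 with the lead exceeds the clump threshold
   (default 0.1);
3. optionally *augment* the lead list with externally derived lead SNPs
   (e.g. disease-GWAS leads) so downstream components stay sensitive to
   those loci.

An eigenvalue-based count of effectively independent SNPs (Li–Ji family)
is provided to quantify the residual dependence left at the clump
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import SummaryStatsTable
from .ld import LdSource
from .utils import chrom_rank

__all__ = [
    "ClumpConfig",
    "Clump",
    "min_p_across_traits",
    "ld_prune",
    "clump",
    "augment_lead_snps",
    "effective_n_snps",
]


@dataclass(frozen=True)
class ClumpConfig:
    """Thresholds of the prune/clump procedure.

    prune_r2_max : r2 ceiling for the pruning pass (default 0.3).
    clump_window_bp : genomic window, base pairs (default 1 Mb).
    lead_p_max : lead-variant p-value threshold (default 1e-5).
    clump_r2_max : r2 above which a neighbour is claimed by a lead
        (default 0.1).
    """

    prune_r2_max: float = 0.3
    clump_window_bp: int = 1_000_000
    lead_p_max: float = 1e-5
    clump_r2_max: float = 0.1

    def __post_init__(self):
        if not 0 < self.prune_r2_max <= 1:
            raise ValidationError("prune_r2_max must be in (0, 1]")
        if not 0 < self.clump_r2_max < 1:
            raise ValidationError("clump_r2_max must be in (0, 1)")
        if self.clump_window_bp <= 0:
            raise ValidationError("clump_window_bp must be positive")
        if not 0 < self.lead_p_max <= 1:
            raise ValidationError("lead_p_max must be in (0, 1]")


@dataclass
class Clump:
    """One lead SNP and the neighbours it claimed."""

    lead: str
    members: list[str] = field(default_factory=list)


def min_p_across_traits(tables: Sequence[SummaryStatsTable]) -> pd.DataFrame:
    """Per-SNP minimum p-value across all trait GWAS.

    Returns a DataFrame (snp_id, chrom, pos, p_min) over the SNPs shared by
    every table, preserving the first table's SNP order.
    """
    tables = list(tables)
    if not tables:
        raise ValidationError("need at least one summary-stats table")
    base = tables[0].data[["snp_id", "chrom", "pos"]].copy()
    shared = set(base["snp_id"])
    for t in tables[1:]:
        shared &= set(t.snp_ids)
    base = base[base["snp_id"].isin(shared)].reset_index(drop=True)
    pmin = None
    for t in tables:
        p = t.data.set_index("snp_id")["pval"].reindex(base["snp_id"]).to_numpy()
        pmin = p if pmin is None else np.minimum(pmin, p)
    base["p_min"] = pmin
    return base


def _genomic_sort(df: pd.DataFrame) -> pd.DataFrame:
    key = [(*chrom_rank(c), int(p)) for c, p in zip(df["chrom"], df["pos"])]
    order = sorted(range(len(key)), key=key.__getitem__)
    return df.iloc[order].reset_index(drop=True)


def ld_prune(
    snps: pd.DataFrame,
    ld: LdSource,
    r2_max: float = 0.3,
    window_bp: int = 1_000_000,
) -> list[str]:
    """Greedy windowed LD pruning in genomic order.

    ``snps`` needs columns (snp_id, chrom, pos).  Scanning by (chromosome,
    position), a SNP is kept iff its r2 with *every* previously kept SNP on
    the same chromosome within ``window_bp`` is strictly below ``r2_max``.
    Deterministic; result is independent of the input row order.
    """
    df = _genomic_sort(snps[["snp_id", "chrom", "pos"]])
    kept: list[tuple[str, str, int]] = []  # (snp_id, chrom, pos)
    for s, c, p in zip(df["snp_id"], df["chrom"], df["pos"]):
        ok = True
        for ks, kc, kp in reversed(kept):
            if kc != c:
                break  # sorted: earlier chromosomes only
            if p - kp > window_bp:
                break
            if ld.r2(s, ks) >= r2_max:
                ok = False
                break
        if ok:
            kept.append((s, str(c), int(p)))
    return [s for s, _, _ in kept]


def clump(
    p_min: pd.DataFrame,
    ld: LdSource,
    cfg: ClumpConfig | None = None,
) -> list[Clump]:
    """Greedy p-value clumping.

    ``p_min`` needs columns (snp_id, chrom, pos, p_min).  Candidates with
    ``p_min < cfg.lead_p_max`` are visited in ascending p_min (ties broken
    by (chromosome, position)); each still-unclaimed candidate becomes a
    lead and claims every unclaimed SNP on its chromosome within
    ``cfg.clump_window_bp`` whose r2 with it exceeds ``cfg.clump_r2_max``.
    SNPs at or above the lead threshold are never leads (but can be
    claimed).  Invariant to input row order.
    """
    cfg = cfg or ClumpConfig()
    df = p_min[["snp_id", "chrom", "pos", "p_min"]].copy()
    df["chrom"] = df["chrom"].astype(str)
    order = sorted(
        range(len(df)),
        key=lambda i: (df["p_min"].iat[i], *chrom_rank(df["chrom"].iat[i]), df["pos"].iat[i]),
    )
    by_chrom: dict[str, list[int]] = {}
    for i in sorted(range(len(df)), key=lambda i: int(df["pos"].iat[i])):
        by_chrom.setdefault(df["chrom"].iat[i], []).append(i)  # members in position order

    claimed: set[int] = set()
    clumps: list[Clump] = []
    for i in order:
        if df["p_min"].iat[i] >= cfg.lead_p_max:
            break  # sorted ascending: no further candidates
        if i in claimed:
            continue
        lead_id = df["snp_id"].iat[i]
        lead_pos = int(df["pos"].iat[i])
        claimed.add(i)
        cl = Clump(lead=lead_id)
        for j in by_chrom[df["chrom"].iat[i]]:
            if j in claimed:
                continue
            if abs(int(df["pos"].iat[j]) - lead_pos) > cfg.clump_window_bp:
                continue
            if ld.r2(lead_id, df["snp_id"].iat[j]) > cfg.clump_r2_max:
                claimed.add(j)
                cl.members.append(df["snp_id"].iat[j])
        clumps.append(cl)
    return clumps


def augment_lead_snps(
    leads: Sequence[str], external: Sequence[Sequence[str]]
) -> tuple[list[str], int]:
    """Union of the clumped leads with external lead-SNP lists.

    Original lead order is preserved; novel external SNPs are appended in
    input order, de-duplicated across lists.  Returns (snp list, number of
    novel additions).
    """
    seen = set(leads)
    out = list(leads)
    added = 0
    for lst in external:
        for s in lst:
            if s not in seen:
                seen.add(s)
                out.append(s)
                added += 1
    return out, added


def effective_n_snps(
    ld: LdSource,
    snps: Sequence[str],
    blocks: Sequence[Sequence[str]] | None = None,
) -> float:
    """Effective number of independent SNPs (Li–Ji eigenvalue family).

    For each LD block (default: one block over the full set), take the
    eigenvalues ``lam_i`` of the signed correlation matrix and compute
    ``M_eff = M - sum_i (lam_i - 1) * 1[lam_i > 1]``; blocks are summed.
    M_eff <= M, with equality iff the correlation matrix is the identity.
    """
    if blocks is None:
        blocks = [list(snps)]
    total = 0.0
    for block in blocks:
        if not block:
            continue
        R = np.asarray(ld.r_matrix(list(block)), dtype=float)
        lam = np.linalg.eigvalsh((R + R.T) / 2.0)
        if lam.min() < -1e-6:
            raise ValidationError(
                f"correlation matrix not positive semidefinite (min eigenvalue {lam.min():.3g})"
            )
        excess = lam - 1.0
        total += len(block) - float(excess[excess > 0].sum())
    return total
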