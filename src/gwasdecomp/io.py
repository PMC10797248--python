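"""Reading, harmonising and stacking per-trait GWAS summary statistics.

A GWAS of one trait yields, for every SNP, an estimated per-allele effect
(beta), its standard error and a p-value.  This module ingests such tables
(one per trait), harmonises effect alleles across traits, and stacks them
into the traits x SNPs *effect matrix* that the decomposition operates on,
either as raw betas or as standard-error-scaled z-values (z = beta / se).

Design notes
------------
* Allele harmonisation: the first table encountered defines the reference
  effect allele per SNP; a later table whose effect/other alleles are
  swapped relative to that reference contributes ``-beta``.  Any other
  combination is treated as a strand-ambiguous mismatch and is an error.
* SNPs absent from some trait are an error in strict mode (default) and are
  dropped with a record in lenient mode.
* Coordinates are 1-based; chromosomes are stored as strings so X/MT work.
* p-values may be supplied as -log10(p) (as some consortium releases
  distribute them); they are converted back at read time.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AlleleMismatchError,
    EmptyInputError,
    FormatError,
    MissingSnpError,
    ValidationError,
)

__all__ = [
    "SummaryStatsTable",
    "EffectMatrix",
    "read_summary_stats",
    "z_transform",
    "assemble_effect_matrix",
    "write_effect_matrix",
    "read_effect_matrix",
]

REQUIRED_COLUMNS = ("snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pval")


@dataclass
class SummaryStatsTable:
    """One trait's per-SNP GWAS results.

    ``data`` holds columns ``snp_id, chrom, pos, effect_allele,
    other_allele, beta, se, pval``; rows are unique by ``snp_id``, ``se`` is
    strictly positive and ``pval`` lies in (0, 1].
    """

    trait_id: str
    data: pd.DataFrame
    n_dropped: int = 0
    drop_reasons: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"summary-stats table missing column(s): {', '.join(missing)}")
        if self.data["snp_id"].duplicated().any():
            dups = self.data.loc[self.data["snp_id"].duplicated(), "snp_id"].tolist()[:5]
            raise ValidationError(f"duplicate snp_id in trait {self.trait_id!r}: {dups}")
        if len(self.data) == 0:
            raise EmptyInputError(f"trait {self.trait_id!r}: no rows survived validation")
        if (self.data["se"] <= 0).any():
            raise ValidationError(f"trait {self.trait_id!r}: non-positive standard errors present")
        p = self.data["pval"].to_numpy()
        if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
            raise ValidationError(f"trait {self.trait_id!r}: p-values outside (0, 1]")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def snp_ids(self) -> pd.Series:
        return self.data["snp_id"]

    def z_values(self) -> np.ndarray:
        """Standard-error-scaled effects, beta / se."""
        return self.data["beta"].to_numpy() / self.data["se"].to_numpy()


def z_transform(beta: float, se: float) -> float:
    """z = beta / se; the standard-error-standardised effect size.

    Raises
    ------
    ValidationError
        If ``se`` is not strictly positive.
    """
    if not se > 0:
        raise ValidationError(f"standard error must be > 0, got {se}")
    return beta / se


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    pval_scale: Literal["p", "neglog10p"] = "p",
    trait_id: str | None = None,
) -> SummaryStatsTable:
    """Read one trait's GWAS summary statistics from a delimited text file.

    Parameters
    ----------
    path
        Tab- or whitespace-delimited file with a header; ``.gz`` accepted.
    column_map
        Maps canonical names (``snp_id``, ``chrom``, ``pos``,
        ``effect_allele``, ``other_allele``, ``beta``, ``se``, ``pval``) to
        the column names present in the file.  Identity by default.
    pval_scale
        ``"p"`` for plain p-values, ``"neglog10p"`` when the file stores
        -log10(p) (converted back via ``10**-x``).
    trait_id
        Defaults to the file's stem.

    Rows with missing beta or non-positive se are dropped; the count and
    reasons are recorded on the returned table.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    column_map = dict(column_map or {})
    with _open_maybe_gzip(path) as fh:
        df = pd.read_csv(fh, sep=r"\s+")

    rename = {}
    for canonical in REQUIRED_COLUMNS:
        src = column_map.get(canonical, canonical)
        if src not in df.columns:
            raise FormatError(
                f"{path.name}: mandatory column {src!r} (for {canonical!r}) not in header"
            )
        rename[src] = canonical
    df = df.rename(columns=rename)[list(REQUIRED_COLUMNS)].copy()

    if pval_scale == "neglog10p":
        df["pval"] = np.power(10.0, -df["pval"].astype(float))
    elif pval_scale != "p":
        raise ValidationError(f"unknown pval_scale {pval_scale!r}")

    reasons: dict[str, int] = {}
    bad_beta = df["beta"].isna()
    bad_se = df["se"].isna() | (df["se"] <= 0)
    bad_p = df["pval"].isna() | (df["pval"] <= 0) | (df["pval"] > 1)
    reasons["missing_beta"] = int(bad_beta.sum())
    reasons["nonpositive_se"] = int(bad_se.sum())
    reasons["invalid_pval"] = int((bad_p & ~bad_beta & ~bad_se).sum())
    keep = ~(bad_beta | bad_se | bad_p)
    dropped = int((~keep).sum())
    df = df.loc[keep].reset_index(drop=True)
    if len(df) == 0:
        raise EmptyInputError(f"{path.name}: zero rows survived validation")

    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(int)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    return SummaryStatsTable(
        trait_id=trait_id or path.name.removesuffix(".gz").rsplit(".", 1)[0],
        data=df,
        n_dropped=dropped,
        drop_reasons=reasons,
    )


@dataclass
class EffectMatrix:
    """The m x n traits-by-SNPs matrix of GWAS effects.

    ``values[i, j]`` is trait i's (allele-harmonised) effect at SNP j, in
    ``mode`` ``"raw_beta"`` or ``"z_value"`` units.  ``snp_registry`` is a
    DataFrame with columns ``snp_id, chrom, pos, effect_allele`` aligned to
    the columns of ``values``.
    """

    values: np.ndarray
    trait_ids: list[str]
    snp_registry: pd.DataFrame
    mode: Literal["raw_beta", "z_value"]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("effect matrix must be 2-D")
        m, n = self.values.shape
        if len(self.trait_ids) != m:
            raise ValidationError("trait_ids length does not match number of rows")
        if len(self.snp_registry) != n:
            raise ValidationError("snp_registry length does not match number of columns")
        if len(set(self.trait_ids)) != m:
            raise ValidationError("trait_ids are not unique")
        if self.snp_registry["snp_id"].duplicated().any():
            raise ValidationError("snp_registry snp_ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("effect matrix contains non-finite entries")
        if self.mode not in ("raw_beta", "z_value"):
            raise ValidationError(f"unknown mode {self.mode!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def snp_ids(self) -> list[str]:
        return self.snp_registry["snp_id"].tolist()

    def same_registry(self, other: "EffectMatrix") -> bool:
        return self.snp_ids == other.snp_ids


def _harmonised_signs(ea, oa, ref_ea, ref_oa, snps, trait) -> np.ndarray:
    """+1 where alleles match the registry, -1 where swapped; error otherwise."""
    match = (ea == ref_ea) & (oa == ref_oa)
    swap = (ea == ref_oa) & (oa == ref_ea)
    bad = ~(match | swap)
    if bad.any():
        j = int(np.argmax(bad))
        raise AlleleMismatchError(
            f"trait {trait!r}, SNP {snps[j]!r}: alleles {ea[j]}/{oa[j]} neither match "
            f"nor swap against registry {ref_ea[j]}/{ref_oa[j]}"
        )
    return np.where(swap, -1.0, 1.0)


def assemble_effect_matrix(
    tables: Sequence[SummaryStatsTable],
    snp_subset: Iterable[str] | None = None,
    mode: Literal["raw_beta", "z_value"] = "raw_beta",
    missing: Literal["strict", "lenient"] = "strict",
) -> EffectMatrix:
    """Stack per-trait summary statistics into an :class:`EffectMatrix`.

    Row order follows the input table order; column order follows
    ``snp_subset`` (default: the first table's SNP order).  The first table
    defines the reference effect allele per SNP; later tables with swapped
    alleles contribute sign-flipped effects.

    ``missing="strict"`` raises if any requested SNP is absent from any
    trait; ``"lenient"`` drops such columns (the drop count is not part of
    the returned object's invariants but columns are silently consistent).
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValidationError("need at least 2 traits to assemble an effect matrix")

    first = tables[0].data.set_index("snp_id")
    if snp_subset is None:
        snp_subset = list(tables[0].snp_ids)
    else:
        snp_subset = list(snp_subset)

    # registry from the first table
    unknown = [s for s in snp_subset if s not in first.index]
    if unknown:
        raise MissingSnpError(
            f"trait {tables[0].trait_id!r} lacks SNP(s) required for the registry: "
            f"{unknown[:5]}{'...' if len(unknown) > 5 else ''}"
        )

    indexed = [t.data.set_index("snp_id") for t in tables]
    id_sets = [set(t.snp_ids) for t in tables]
    offenders: list[str] = []
    keep: list[str] = []
    for s in snp_subset:
        missing_in = [t.trait_id for t, ids in zip(tables, id_sets) if s not in ids]
        if missing_in:
            if missing == "strict":
                offenders.append(f"SNP {s!r} missing in trait(s) {missing_in}")
            # lenient: drop column
        else:
            keep.append(s)
    if offenders and missing == "strict":
        raise MissingSnpError("; ".join(offenders[:10]))
    if not keep:
        raise EmptyInputError("no SNPs shared by all traits")

    reg = first.loc[keep, ["chrom", "pos", "effect_allele", "other_allele"]]
    ref_ea = reg["effect_allele"].to_numpy()
    ref_oa = reg["other_allele"].to_numpy()

    m, n = len(tables), len(keep)
    out = np.empty((m, n), dtype=float)
    for i, (tab, ix) in enumerate(zip(tables, indexed)):
        sub = ix.loc[keep]
        ea = sub["effect_allele"].to_numpy()
        oa = sub["other_allele"].to_numpy()
        vals = sub["beta"].to_numpy().astype(float)
        if mode == "z_value":
            vals = vals / sub["se"].to_numpy().astype(float)
        signs = _harmonised_signs(ea, oa, ref_ea, ref_oa, keep, tab.trait_id)
        out[i] = signs * vals

    registry = pd.DataFrame(
        {
            "snp_id": keep,
            "chrom": reg["chrom"].to_numpy(),
            "pos": reg["pos"].to_numpy(),
            "effect_allele": ref_ea,
        }
    )
    return EffectMatrix(
        values=out,
        trait_ids=[t.trait_id for t in tables],
        snp_registry=registry,
        mode=mode,
    )


def write_effect_matrix(em: EffectMatrix, prefix) -> tuple[Path, Path]:
    """Write an EffectMatrix as ``<prefix>.tsv`` + ``<prefix>.json`` sidecar.

    The TSV has one row per trait (first column ``trait_id``, remaining
    columns one per SNP); floats are written with 17 significant digits so a
    round trip is bit-identical.
    """
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    meta = prefix.with_suffix(".json")
    with open(tsv, "w") as fh:
        fh.write("trait_id\t" + "\t".join(em.snp_ids) + "\n")
        for tid, row in zip(em.trait_ids, em.values):
            fh.write(tid + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")
    with open(meta, "w") as fh:
        json.dump(
            {
                "mode": em.mode,
                "snp_registry": em.snp_registry.to_dict(orient="list"),
            },
            fh,
            indent=1,
        )
    return tsv, meta


def read_effect_matrix(prefix) -> EffectMatrix:
    """Inverse of :func:`write_effect_matrix`."""
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", dtype={"trait_id": str}, float_precision="round_trip")
    with open(prefix.with_suffix(".json")) as fh:
        meta = json.load(fh)
    registry = pd.DataFrame(meta["snp_registry"])
    registry["chrom"] = registry["chrom"].astype(str)
    registry["pos"] = registry["pos"].astype(int)
    return EffectMatrix(
        values=df.drop(columns="trait_id").to_numpy(dtype=float),
        trait_ids=df["trait_id"].tolist(),
        snp_registry=registry,
        mode=meta["mode"],
    )
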