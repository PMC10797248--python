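"""Linkage-disequilibrium (LD) sources.

Pruning and clumping need pairwise r2 between SNPs.  Three interchangeable
providers are supported:

* :class:`MatrixLd` — a square correlation matrix over an ordered SNP list
  (signed r or r2; signs are kept when available because the effective-test
  count uses the signed correlation matrix);
* :class:`TableLd` — a long table of (snp_a, snp_b, r2) pairs, the dialect
  PLINK's ``--ld-window`` reports emit.  Pairs absent from the table are
  r2 = 0 only when the two SNPs are on different chromosomes or farther
  apart than the declared window; otherwise the pair is *unknown* and an
  error in strict mode;
* :class:`DosageLd` — a genotype dosage matrix (individuals x SNPs); r is
  the Pearson correlation of dosages.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import LdCoverageError, ValidationError

__all__ = ["LdSource", "MatrixLd", "TableLd", "DosageLd", "read_ld_table", "read_ld_matrix"]


class LdSource:
    """Interface: pairwise r2 (and, when known, signed r) between SNPs."""

    def r2(self, a: str, b: str) -> float:
        """r2 between two SNPs; may raise :class:`LdCoverageError` if unknown."""
        raise NotImplementedError

    def knows(self, a: str, b: str) -> bool:
        raise NotImplementedError

    def r_matrix(self, snps: Sequence[str]) -> np.ndarray:
        """Signed correlation matrix over ``snps`` (sqrt(r2) if unsigned)."""
        raise NotImplementedError


class MatrixLd(LdSource):
    def __init__(self, matrix, snp_ids: Sequence[str], signed: bool = True):
        """``matrix`` holds signed r when ``signed`` else r2."""
        mat = np.asarray(matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValidationError("LD matrix must be square")
        if mat.shape[0] != len(snp_ids):
            raise ValidationError("LD matrix size does not match snp_ids")
        if not np.allclose(mat, mat.T, atol=1e-8):
            raise ValidationError("LD matrix must be symmetric")
        vals = mat**2 if signed else mat
        if np.any(vals < -1e-9) or np.any(vals > 1 + 1e-9):
            raise ValidationError("r2 values outside [0, 1]")
        if not np.allclose(np.diag(vals), 1.0, atol=1e-6):
            raise ValidationError("diagonal r2 must be 1")
        self._mat = mat
        self._signed = signed
        self._idx = {s: i for i, s in enumerate(snp_ids)}
        self.snp_ids = list(snp_ids)

    def knows(self, a, b):
        return a in self._idx and b in self._idx

    def r2(self, a, b):
        try:
            v = self._mat[self._idx[a], self._idx[b]]
        except KeyError as e:
            raise LdCoverageError(f"SNP {e.args[0]!r} not in LD matrix") from None
        return v * v if self._signed else float(v)

    def r_matrix(self, snps):
        ix = [self._idx[s] for s in snps]
        sub = self._mat[np.ix_(ix, ix)]
        return sub if self._signed else np.sqrt(np.clip(sub, 0.0, 1.0))


class TableLd(LdSource):
    def __init__(
        self,
        pairs: Mapping[tuple[str, str], float] | Iterable[tuple[str, str, float]],
        registry: pd.DataFrame | None = None,
        window_bp: int | None = None,
    ):
        """``registry`` (snp_id, chrom, pos) + ``window_bp`` let absent pairs
        be resolved as r2=0 when they are out of range of each other."""
        if isinstance(pairs, Mapping):
            items = pairs.items()
        else:
            items = [((a, b), float(v)) for a, b, v in pairs]
        self._r2: dict[tuple[str, str], float] = {}
        for (a, b), v in items:
            if not 0.0 <= v <= 1.0 + 1e-9:
                raise ValidationError(f"r2({a},{b})={v} outside [0,1]")
            self._r2[(a, b)] = min(v, 1.0)
            self._r2[(b, a)] = min(v, 1.0)
        self._coords = None
        if registry is not None:
            self._coords = {
                s: (str(c), int(p))
                for s, c, p in zip(registry["snp_id"], registry["chrom"], registry["pos"])
            }
        self.window_bp = window_bp

    def _resolvable_as_zero(self, a, b) -> bool:
        if self._coords is None or self.window_bp is None:
            return False
        if a not in self._coords or b not in self._coords:
            return False
        (ca, pa), (cb, pb) = self._coords[a], self._coords[b]
        return ca != cb or abs(pa - pb) > self.window_bp

    def knows(self, a, b):
        return a == b or (a, b) in self._r2 or self._resolvable_as_zero(a, b)

    def r2(self, a, b):
        if a == b:
            return 1.0
        if (a, b) in self._r2:
            return self._r2[(a, b)]
        if self._resolvable_as_zero(a, b):
            return 0.0
        raise LdCoverageError(f"r2 unknown for within-window pair ({a}, {b})")

    def r_matrix(self, snps):
        n = len(snps)
        out = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = np.sqrt(self.r2(snps[i], snps[j]))
        return out


class DosageLd(LdSource):
    def __init__(self, dosages, snp_ids: Sequence[str]):
        """``dosages``: individuals x SNPs numeric matrix (0..2 per allele count)."""
        d = np.asarray(dosages, dtype=float)
        if d.ndim != 2 or d.shape[1] != len(snp_ids):
            raise ValidationError("dosage matrix must be individuals x SNPs")
        if d.shape[0] < 2:
            raise ValidationError("need >= 2 individuals to estimate LD")
        sd = d.std(axis=0)
        if np.any(sd == 0):
            raise ValidationError("monomorphic SNP (zero dosage variance) in LD panel")
        self._z = (d - d.mean(axis=0)) / sd
        self._n = d.shape[0]
        self._idx = {s: i for i, s in enumerate(snp_ids)}
        self.snp_ids = list(snp_ids)

    def knows(self, a, b):
        return a in self._idx and b in self._idx

    def _r(self, a, b) -> float:
        i, j = self._idx[a], self._idx[b]
        return float(self._z[:, i] @ self._z[:, j] / self._n)

    def r2(self, a, b):
        if not self.knows(a, b):
            raise LdCoverageError(f"SNP not in dosage panel: {a if a not in self._idx else b}")
        r = self._r(a, b)
        return min(r * r, 1.0)

    def r_matrix(self, snps):
        ix = [self._idx[s] for s in snps]
        z = self._z[:, ix]
        return np.clip(z.T @ z / self._n, -1.0, 1.0)


def read_ld_table(path, registry: pd.DataFrame | None = None, window_bp: int | None = None) -> TableLd:
    """Read a whitespace-delimited SNP_A SNP_B R2 long table (PLINK dialect).

    A header line is detected by a non-numeric third field and skipped;
    extra columns (CHR_A, BP_A, ... as in PLINK ``.ld`` files) are accepted
    when named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+")
    cols = {c.upper(): c for c in df.columns}
    if {"SNP_A", "SNP_B", "R2"} <= set(cols):
        a, b, v = cols["SNP_A"], cols["SNP_B"], cols["R2"]
    elif len(df.columns) == 3:
        a, b, v = df.columns
    else:
        raise ValidationError(f"{path.name}: cannot identify SNP_A/SNP_B/R2 columns")
    pairs = [(str(x), str(y), float(r)) for x, y, r in zip(df[a], df[b], df[v])]
    return TableLd(pairs, registry=registry, window_bp=window_bp)


def read_ld_matrix(path, signed: bool = False) -> MatrixLd:
    """Read a square LD matrix TSV with SNP ids as header row and first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError("LD matrix row and column SNP ids differ")
    return MatrixLd(df.to_numpy(dtype=float), [str(s) for s in df.columns], signed=signed)
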