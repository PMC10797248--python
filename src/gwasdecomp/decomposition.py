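"""Genomic PCA and ICA of a traits x SNPs effect matrix.

The effect matrix X (m traits x n SNPs) of GWAS betas or z-values is
decomposed along the SNP dimension into K components.  Each component is a
*genomic factor*: a loading vector over SNPs (one row of ``snp_loadings``,
the source/"spatial" map S) paired with a vector of per-trait weights (one
column of ``trait_loadings``, the mixing matrix A), such that

    X  ~=  A @ S        (the rank-K approximation of X).

PCA takes the top-K right singular vectors of X; ICA rotates the K-
dimensional PCA subspace with a FastICA fixed-point iteration (log-cosh
contrast, symmetric decorrelation) so that the SNP-loading rows become
maximally non-Gaussian, i.e. statistically independent sparse sources.

Two conventions mirror how the method is applied to GWAS effects and both
are asserted by tests:

* **no demeaning** — SNP effect sizes are centred on zero under the null
  (effect-allele direction is arbitrary), so neither rows nor columns are
  centred by default (an opt-in flag exists for sensitivity analysis);
* **no per-SNP variance normalisation** — the magnitude of allelic effects
  carries biological information and is preserved.

Determinism: the SVD is deterministic; ICA is bit-reproducible for a fixed
seed.  Components are ordered by the energy they carry in X and each SNP-
loading row's sign is fixed so its skewness is positive (falling back to
making the largest-magnitude entry positive when skewness is ~0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import skew

from .exceptions import ConvergenceError, RegistryMismatchError, ValidationError
from .io import EffectMatrix

__all__ = [
    "GenomicPCA",
    "GenomicICA",
    "DecompositionResult",
    "pca_decompose",
    "ica_decompose",
    "scree_table",
    "align_components",
    "load_result",
]


def _fix_signs(S: np.ndarray, A: np.ndarray) -> None:
    """Flip (row of S, column of A) pairs so each source row has positive
    skewness; near-zero skewness falls back to the largest-|entry| sign."""
    for k in range(S.shape[0]):
        sk = skew(S[k])
        if abs(sk) > 1e-8:
            sgn = np.sign(sk)
        else:
            sgn = np.sign(S[k][np.argmax(np.abs(S[k]))])
            if sgn == 0:
                sgn = 1.0
        if sgn < 0:
            S[k] *= -1.0
            A[:, k] *= -1.0


@dataclass
class DecompositionResult:
    """K genomic components extracted from an effect matrix.

    Attributes
    ----------
    method : ``"pca"`` or ``"ica"``.
    k : number of components.
    snp_loadings : (K, n) source matrix S; for PCA the rows are orthonormal
        right singular vectors, for ICA they have unit root-mean-square.
    trait_loadings : (m, K) mixing matrix A; ``A @ S`` reconstructs the
        rank-K approximation of the input.
    singular_spectrum : all min(m, n) singular values of the input.
    variance_explained : sigma_k^2 / sum(sigma^2) for the K-dimensional PCA
        subspace (shared by PCA and ICA, which is a rotation within it).
    config : fingerprint of the fit (mode, centering, seed, tolerance, ...).
    """

    method: str
    k: int
    snp_loadings: np.ndarray
    trait_loadings: np.ndarray
    singular_spectrum: np.ndarray
    variance_explained: np.ndarray
    trait_ids: list[str]
    snp_registry: pd.DataFrame
    config: dict = field(default_factory=dict)
    n_iter: int | None = None

    @property
    def snp_ids(self) -> list[str]:
        return self.snp_registry["snp_id"].tolist()

    def reconstruct(self) -> np.ndarray:
        """Rank-K approximation A @ S of the decomposed matrix."""
        return self.trait_loadings @ self.snp_loadings

    def scree_table(self, dims: Sequence[int]) -> pd.DataFrame:
        """Cumulative variance fraction at each requested dimension."""
        return scree_table(self, dims)

    def standardized_snp_loadings(self) -> np.ndarray:
        """Rows standardised to zero mean, unit SD (for thresholding)."""
        S = self.snp_loadings
        sd = S.std(axis=1, ddof=0, keepdims=True)
        if np.any(sd == 0):
            raise ValidationError("constant SNP-loading row cannot be standardised")
        return (S - S.mean(axis=1, keepdims=True)) / sd

    def summary(self) -> str:
        m, K = self.trait_loadings.shape
        n = self.snp_loadings.shape[1]
        lines = [
            f"Genomic {self.method.upper()} decomposition",
            "=" * 44,
            f"traits (m): {m:>8}    SNPs (n): {n:>8}    components (K): {K}",
            f"input mode: {self.config.get('mode', '?')}    "
            f"column centering: {self.config.get('center_columns', False)}",
        ]
        if self.n_iter is not None:
            lines.append(f"ICA iterations: {self.n_iter} (seed={self.config.get('seed')})")
        lines.append("-" * 44)
        lines.append(f"{'comp':>4} {'var_explained':>14} {'cum_var':>9} {'|A_k|':>9}")
        cum = 0.0
        for i in range(K):
            cum += self.variance_explained[i]
            anorm = float(np.linalg.norm(self.trait_loadings[:, i]))
            lines.append(f"{i + 1:>4} {self.variance_explained[i]:>14.5f} {cum:>9.4f} {anorm:>9.4f}")
        lines.append("-" * 44)
        tot = float(np.sum(self.variance_explained))
        lines.append(f"variance explained by K={K} subspace: {tot:.4f}")
        return "\n".join(lines)

    def save(self, prefix) -> dict[str, str]:
        """Write ``<prefix>_snp_loadings.tsv``, ``_trait_loadings.tsv``,
        ``_spectrum.tsv`` and ``_meta.json``; returns the file map."""
        prefix = str(prefix)
        comp_cols = [f"C{i + 1}" for i in range(self.k)]
        snp_df = self.snp_registry[["snp_id", "chrom", "pos"]].copy()
        for i, c in enumerate(comp_cols):
            snp_df[c] = self.snp_loadings[i]
        trait_df = pd.DataFrame({"trait_id": self.trait_ids})
        for i, c in enumerate(comp_cols):
            trait_df[c] = self.trait_loadings[:, i]
        spec_df = pd.DataFrame(
            {
                "component": np.arange(1, len(self.singular_spectrum) + 1),
                "singular_value": self.singular_spectrum,
            }
        )
        files = {
            "snp_loadings": f"{prefix}_snp_loadings.tsv",
            "trait_loadings": f"{prefix}_trait_loadings.tsv",
            "spectrum": f"{prefix}_spectrum.tsv",
            "meta": f"{prefix}_meta.json",
        }
        snp_df.to_csv(files["snp_loadings"], sep="\t", index=False, float_format="%.17g")
        trait_df.to_csv(files["trait_loadings"], sep="\t", index=False, float_format="%.17g")
        spec_df.to_csv(files["spectrum"], sep="\t", index=False, float_format="%.17g")
        with open(files["meta"], "w") as fh:
            json.dump(
                {
                    "method": self.method,
                    "k": self.k,
                    "config": self.config,
                    "n_iter": self.n_iter,
                    "variance_explained": [float(v) for v in self.variance_explained],
                    "snp_registry": self.snp_registry.to_dict(orient="list"),
                },
                fh,
                indent=1,
            )
        return files


def load_result(prefix) -> DecompositionResult:
    """Re-read a decomposition written by :meth:`DecompositionResult.save`."""
    prefix = str(prefix)
    with open(f"{prefix}_meta.json") as fh:
        meta = json.load(fh)
    snp_df = pd.read_csv(f"{prefix}_snp_loadings.tsv", sep="\t", float_precision="round_trip")
    trait_df = pd.read_csv(f"{prefix}_trait_loadings.tsv", sep="\t", float_precision="round_trip")
    spec_df = pd.read_csv(f"{prefix}_spectrum.tsv", sep="\t", float_precision="round_trip")
    comp_cols = [f"C{i + 1}" for i in range(meta["k"])]
    registry = pd.DataFrame(meta["snp_registry"])
    registry["chrom"] = registry["chrom"].astype(str)
    return DecompositionResult(
        method=meta["method"],
        k=meta["k"],
        snp_loadings=snp_df[comp_cols].to_numpy(dtype=float).T,
        trait_loadings=trait_df[comp_cols].to_numpy(dtype=float),
        singular_spectrum=spec_df["singular_value"].to_numpy(dtype=float),
        variance_explained=np.asarray(meta["variance_explained"], dtype=float),
        trait_ids=trait_df["trait_id"].astype(str).tolist(),
        snp_registry=registry,
        config=meta["config"],
        n_iter=meta.get("n_iter"),
    )


class _BaseDecomposer:
    """Shared validation + SVD for the PCA/ICA models."""

    def __init__(self, effects: EffectMatrix, center_columns: bool = False):
        if not isinstance(effects, EffectMatrix):
            raise ValidationError("expected an EffectMatrix; use from_array() for raw arrays")
        self.effects = effects
        self.center_columns = bool(center_columns)
        X = effects.values
        if self.center_columns:
            X = X - X.mean(axis=0, keepdims=True)
        self._X = X
        # economy SVD; deterministic
        self._U, self._s, self._Vt = np.linalg.svd(X, full_matrices=False)

    @classmethod
    def from_array(
        cls,
        values,
        trait_ids: Sequence[str] | None = None,
        snp_ids: Sequence[str] | None = None,
        mode: str = "raw_beta",
        **kwargs,
    ):
        """Build the model from a bare array, with an autogenerated registry."""
        values = np.asarray(values, dtype=float)
        m, n = values.shape
        trait_ids = list(trait_ids) if trait_ids is not None else [f"trait{i}" for i in range(m)]
        snp_ids = list(snp_ids) if snp_ids is not None else [f"snp{j}" for j in range(n)]
        registry = pd.DataFrame(
            {"snp_id": snp_ids, "chrom": "1", "pos": np.arange(1, n + 1), "effect_allele": "A"}
        )
        em = EffectMatrix(values=values, trait_ids=trait_ids, snp_registry=registry, mode=mode)
        return cls(em, **kwargs)

    def _check_k(self, k: int) -> None:
        m, n = self._X.shape
        if not 1 <= k <= min(m, n):
            raise ValidationError(f"K={k} out of range 1..{min(m, n)}")

    def _variance_explained(self, k: int) -> np.ndarray:
        tot = float(np.sum(self._s**2))
        if tot == 0:
            raise ValidationError("zero matrix has no variance to explain")
        return self._s[:k] ** 2 / tot

    def _base_config(self) -> dict:
        return {
            "mode": self.effects.mode,
            "center_columns": self.center_columns,
            "demean_rows": False,
            "variance_normalize": False,
        }


class GenomicPCA(_BaseDecomposer):
    """Principal-component model of a GWAS effect matrix.

    ``GenomicPCA(effects).fit(k)`` returns a :class:`DecompositionResult`
    whose SNP loadings are the top-K right singular vectors of the
    (uncentred) matrix and whose trait loadings are ``U_K @ diag(s_K)``.
    """

    def fit(self, k: int) -> DecompositionResult:
        self._check_k(k)
        S = self._Vt[:k].copy()
        A = self._U[:, :k] * self._s[:k]
        _fix_signs(S, A)
        cfg = self._base_config() | {"method": "pca"}
        return DecompositionResult(
            method="pca",
            k=k,
            snp_loadings=S,
            trait_loadings=A,
            singular_spectrum=self._s.copy(),
            variance_explained=self._variance_explained(k),
            trait_ids=list(self.effects.trait_ids),
            snp_registry=self.effects.snp_registry.copy(),
            config=cfg,
        )


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    """W <- (W W^T)^(-1/2) W, the symmetric orthogonalisation step."""
    lam, E = np.linalg.eigh(W @ W.T)
    return E @ np.diag(1.0 / np.sqrt(np.maximum(lam, 1e-300))) @ E.T @ W


class GenomicICA(_BaseDecomposer):
    """Independent-component model of a GWAS effect matrix.

    The K-dimensional PCA subspace is used as the (uncentred) whitening
    basis; a FastICA fixed-point iteration with the log-cosh contrast and
    symmetric decorrelation then rotates it so the SNP-loading rows are
    maximally non-Gaussian.  ``fit`` is bit-reproducible for a fixed seed
    and retries from fresh random rotations on non-convergence.
    """

    def fit(
        self,
        k: int,
        seed: int = 0,
        tol: float = 1e-6,
        max_iter: int = 1000,
        restarts: int = 5,
    ) -> DecompositionResult:
        self._check_k(k)
        if k < 2:
            raise ValidationError("ICA needs K >= 2 (a single component cannot be unmixed)")
        n = self._X.shape[1]
        Z = np.sqrt(n) * self._Vt[:k]  # K x n, Z Z^T = n I: already white, uncentred
        rng = np.random.default_rng(seed)

        diagnostics = []
        W_final = None
        n_iter_total = None
        for attempt in range(max(1, restarts)):
            W = _sym_decorrelate(rng.standard_normal((k, k)))
            converged = False
            for it in range(1, max_iter + 1):
                WZ = W @ Z
                G = np.tanh(WZ)
                gprime_mean = (1.0 - G**2).mean(axis=1)
                W_new = (G @ Z.T) / n - gprime_mean[:, None] * W
                W_new = _sym_decorrelate(W_new)
                delta = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1.0)))
                W = W_new
                if delta < tol:
                    converged = True
                    break
            diagnostics.append({"restart": attempt, "iterations": it, "last_delta": delta})
            if converged:
                W_final = W
                n_iter_total = it
                break
        if W_final is None:
            raise ConvergenceError(
                f"FastICA did not converge in {max_iter} iterations over "
                f"{max(1, restarts)} restarts (tol={tol})",
                diagnostics=diagnostics,
            )

        S = W_final @ Z  # rows have unit root-mean-square
        A = (self._U[:, :k] * self._s[:k]) @ W_final.T / np.sqrt(n)
        # order components by the energy they carry in X (||A_k||, rows of S
        # all have unit RMS); deterministic tie-break by original index
        energy = np.linalg.norm(A, axis=0)
        order = np.argsort(-energy, kind="stable")
        S = S[order]
        A = A[:, order]
        _fix_signs(S, A)

        cfg = self._base_config() | {
            "method": "ica",
            "seed": int(seed),
            "tol": float(tol),
            "max_iter": int(max_iter),
            "restarts": int(restarts),
        }
        return DecompositionResult(
            method="ica",
            k=k,
            snp_loadings=S,
            trait_loadings=A,
            singular_spectrum=self._s.copy(),
            variance_explained=self._variance_explained(k),
            trait_ids=list(self.effects.trait_ids),
            snp_registry=self.effects.snp_registry.copy(),
            config=cfg,
            n_iter=n_iter_total,
        )


def pca_decompose(effects: EffectMatrix, k: int, center_columns: bool = False) -> DecompositionResult:
    """Functional shorthand for ``GenomicPCA(effects, center_columns).fit(k)``."""
    return GenomicPCA(effects, center_columns=center_columns).fit(k)


def ica_decompose(
    effects: EffectMatrix,
    k: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    restarts: int = 5,
    center_columns: bool = False,
) -> DecompositionResult:
    """Functional shorthand for ``GenomicICA(effects, ...).fit(...)``."""
    return GenomicICA(effects, center_columns=center_columns).fit(
        k, seed=seed, tol=tol, max_iter=max_iter, restarts=restarts
    )


def scree_table(source, dims: Sequence[int]) -> pd.DataFrame:
    """Cumulative variance fraction at the requested dimensionalities.

    ``source`` is a :class:`DecompositionResult` (its full singular
    spectrum is used) or a 1-D array of singular values.
    """
    if isinstance(source, DecompositionResult):
        s = np.asarray(source.singular_spectrum, dtype=float)
    else:
        s = np.asarray(source, dtype=float)
    dims = [int(d) for d in dims]
    if any(d < 1 or d > len(s) for d in dims):
        raise ValidationError(f"requested dimension outside 1..{len(s)}")
    frac = s**2 / float(np.sum(s**2))
    cum = np.cumsum(frac)
    return pd.DataFrame({"K": dims, "cumulative_variance": [float(cum[d - 1]) for d in dims]})


def align_components(a: DecompositionResult, b: DecompositionResult) -> pd.DataFrame:
    """Optimal one-to-one matching of two decompositions' components.

    Pairs SNP-loading rows of ``a`` with rows of ``b`` so the summed
    absolute Pearson correlation is maximal (linear assignment).  Returns a
    DataFrame (index_a, index_b, r, sign) sorted by index_a; when K
    differs, min(K_a, K_b) pairs are returned.
    """
    if a.snp_ids != b.snp_ids:
        raise RegistryMismatchError("decompositions do not share a SNP registry")
    Sa, Sb = a.snp_loadings, b.snp_loadings
    Ka, Kb = Sa.shape[0], Sb.shape[0]
    C = np.empty((Ka, Kb))
    for i in range(Ka):
        for j in range(Kb):
            C[i, j] = np.corrcoef(Sa[i], Sb[j])[0, 1]
    rows, cols = linear_sum_assignment(-np.abs(C))
    recs = [
        {"index_a": int(i), "index_b": int(j), "r": float(C[i, j]), "sign": int(np.sign(C[i, j]) or 1)}
        for i, j in zip(rows, cols)
    ]
    return pd.DataFrame(recs).sort_values("index_a").reset_index(drop=True)
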