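"""Inter-sample reproducibility of genomic components and of univariate GWAS.

Given two decompositions of the *same* SNP set estimated in non-overlapping
samples (a discovery/replication pair), this module quantifies how well the
components replicate and benchmarks them against the reproducibility of the
raw per-trait GWAS they were built from:

* global signal: Pearson correlation of SNP-loading rows across samples,
  Bonferroni-adjusted for all K_a x K_b unique comparisons;
* sparse signal: loadings are standardised, thresholded (default > 1) and
  binarized; the overlap of the surviving SNP sets is tested with Fisher's
  exact test (valid because clumped lead SNPs at r2 < 0.1 are treated as
  independent draws);
* benchmark: the per-trait correlation of effect sizes across samples
  (r_SNP) — its mean is the bar a useful component should clear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import DecompositionResult, align_components
from .exceptions import (
    RegistryMismatchError,
    UndefinedCorrelationError,
    ValidationError,
)
from .io import EffectMatrix

__all__ = [
    "ReproReport",
    "component_correlations",
    "binarize_loadings",
    "overlap_fisher",
    "univariate_reproducibility",
    "benchmark_report",
    "loading_vs_reproducibility",
]


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the exact two-sided t-transform p-value."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def component_correlations(
    a: DecompositionResult, b: DecompositionResult
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Pearson correlations of SNP-loading rows across samples.

    Returns ``(corr, p_adj)`` as K_a x K_b DataFrames; p-values are
    two-sided and Bonferroni-adjusted by the number of unique comparisons,
    K_a * K_b.  A constant loading row raises
    :class:`UndefinedCorrelationError` naming the offending component.
    """
    if a.snp_ids != b.snp_ids:
        raise RegistryMismatchError("decompositions do not share a SNP registry")
    Sa, Sb = a.snp_loadings, b.snp_loadings
    Ka, Kb = Sa.shape[0], Sb.shape[0]
    for name, S in (("a", Sa), ("b", Sb)):
        const = np.where(np.ptp(S, axis=1) == 0)[0]
        if const.size:
            raise UndefinedCorrelationError(
                f"constant SNP-loading row(s) in decomposition {name}: {const.tolist()}"
            )
    bonf = Ka * Kb
    R = np.empty((Ka, Kb))
    P = np.empty((Ka, Kb))
    for i in range(Ka):
        for j in range(Kb):
            r, p = _pearson_with_p(Sa[i], Sb[j])
            R[i, j] = r
            P[i, j] = min(1.0, p * bonf)
    idx = [f"a{i + 1}" for i in range(Ka)]
    cols = [f"b{j + 1}" for j in range(Kb)]
    return pd.DataFrame(R, index=idx, columns=cols), pd.DataFrame(P, index=idx, columns=cols)


def binarize_loadings(
    d: DecompositionResult, threshold: float = 1.0, absolute: bool = False
) -> np.ndarray:
    """Standardise each SNP-loading row and threshold it.

    An entry is True iff its standardised loading exceeds ``threshold``
    (one-sided, the printed convention); ``absolute=True`` thresholds
    |loading| instead, the two-sided reading.
    """
    Z = d.standardized_snp_loadings()
    return (np.abs(Z) if absolute else Z) > threshold


def overlap_fisher(
    bin_a: np.ndarray, bin_b: np.ndarray, n: int | None = None, bonferroni: int = 1
) -> dict:
    """Fisher's exact test of the overlap between two binarized loadings.

    Builds the 2x2 table {both, a-only, b-only, neither} over the ``n``
    SNPs and returns the two-sided hypergeometric p with
    ``p_adj = min(1, p * bonferroni)`` (callers pass the number of
    contingency tables generated).  The odds ratio is ``inf`` when a
    margin makes the denominator zero.
    """
    bin_a = np.asarray(bin_a, dtype=bool).ravel()
    bin_b = np.asarray(bin_b, dtype=bool).ravel()
    if bin_a.shape != bin_b.shape:
        raise ValidationError("binarized rows differ in length")
    if n is None:
        n = bin_a.size
    if n == 0:
        raise ValidationError("cannot test overlap over zero SNPs")
    if n != bin_a.size:
        raise ValidationError(f"n={n} does not match row length {bin_a.size}")
    both = int(np.sum(bin_a & bin_b))
    a_only = int(np.sum(bin_a & ~bin_b))
    b_only = int(np.sum(~bin_a & bin_b))
    neither = int(np.sum(~bin_a & ~bin_b))
    table = np.array([[both, a_only], [b_only, neither]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "table": table,
        "odds_ratio": float(odds),
        "p": float(p),
        "p_adj": min(1.0, float(p) * bonferroni),
    }


def univariate_reproducibility(Xa: EffectMatrix, Xb: EffectMatrix) -> pd.DataFrame:
    """Per-trait Pearson correlation of effect sizes across samples (r_SNP).

    Both matrices must share trait and SNP registries.  Returns a DataFrame
    (trait_id, r, p) in trait order; use ``df["r"].agg(["max","mean","std"])``
    for the summary the benchmark uses.
    """
    if Xa.trait_ids != Xb.trait_ids:
        raise RegistryMismatchError("effect matrices do not share trait registries")
    if not Xa.same_registry(Xb):
        raise RegistryMismatchError("effect matrices do not share SNP registries")
    recs = []
    for i, tid in enumerate(Xa.trait_ids):
        r, p = _pearson_with_p(Xa.values[i], Xb.values[i])
        recs.append({"trait_id": tid, "r": r, "p": p})
    return pd.DataFrame(recs)


def loading_vs_reproducibility(
    trait_loadings_column, univariate_r, signed: bool = False
) -> tuple[float, float]:
    """Correlate one component's trait loadings with per-trait univariate r.

    By default the absolute loading is used (a component can weight a trait
    in either direction); ``signed=True`` keeps the sign.  Returns (r, p).
    """
    x = np.asarray(trait_loadings_column, dtype=float)
    y = np.asarray(univariate_r, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors differ in length")
    if not signed:
        x = np.abs(x)
    return _pearson_with_p(x, y)


@dataclass
class ReproReport:
    """Full discovery/replication comparison for one decomposition pair."""

    corr_matrix: pd.DataFrame
    pvals_adj: pd.DataFrame
    matched_pairs: pd.DataFrame  # from align_components, + |r| and beats_univariate_mean
    fisher_results: pd.DataFrame
    univariate: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def summary_text(self) -> str:
        s = self.summary
        lines = [
            "Inter-sample reproducibility report",
            "=" * 46,
            f"components: {len(self.matched_pairs)} matched pairs",
            f"  matched |r|: max {s['comp_r_max']:.4f}  mean {s['comp_r_mean']:.4f}",
            f"univariate GWAS (n traits = {len(self.univariate)}):",
            f"  r: max {s['uni_r_max']:.4f}  mean {s['uni_r_mean']:.4f}  sd {s['uni_r_sd']:.4f}",
            f"components beating mean univariate r: "
            f"{int(self.matched_pairs['beats_univariate_mean'].sum())}/{len(self.matched_pairs)}",
        ]
        return "\n".join(lines)


def benchmark_report(
    a: DecompositionResult,
    b: DecompositionResult,
    Xa: EffectMatrix,
    Xb: EffectMatrix,
    threshold: float = 1.0,
    absolute: bool = False,
) -> ReproReport:
    """Assemble the component-vs-univariate reproducibility benchmark.

    Combines all-pairs loading correlations, optimal component matching,
    Fisher overlap tests of the thresholded loadings, and the per-trait
    univariate benchmark; flags, per matched component, whether its |r|
    exceeds the mean univariate r.
    """
    corr, padj = component_correlations(a, b)
    pairs = align_components(a, b)
    uni = univariate_reproducibility(Xa, Xb)

    bin_a = binarize_loadings(a, threshold=threshold, absolute=absolute)
    bin_b = binarize_loadings(b, threshold=threshold, absolute=absolute)
    n = bin_a.shape[1]
    bonf = bin_a.shape[0] * bin_b.shape[0]
    fisher_recs = []
    for _, row in pairs.iterrows():
        i, j = int(row["index_a"]), int(row["index_b"])
        res = overlap_fisher(bin_a[i], bin_b[j], n=n, bonferroni=bonf)
        fisher_recs.append(
            {
                "index_a": i,
                "index_b": j,
                "both": int(res["table"][0, 0]),
                "a_only": int(res["table"][0, 1]),
                "b_only": int(res["table"][1, 0]),
                "neither": int(res["table"][1, 1]),
                "odds_ratio": res["odds_ratio"],
                "p": res["p"],
                "p_adj": res["p_adj"],
            }
        )
    fisher_df = pd.DataFrame(fisher_recs)

    uni_mean = float(uni["r"].mean())
    pairs = pairs.copy()
    pairs["abs_r"] = pairs["r"].abs()
    pairs["beats_univariate_mean"] = pairs["abs_r"] > uni_mean

    summary = {
        "comp_r_max": float(pairs["abs_r"].max()),
        "comp_r_mean": float(pairs["abs_r"].mean()),
        "uni_r_max": float(uni["r"].max()),
        "uni_r_mean": uni_mean,
        "uni_r_sd": float(uni["r"].std(ddof=1)),
    }
    return ReproReport(
        corr_matrix=corr,
        pvals_adj=padj,
        matched_pairs=pairs,
        fisher_results=fisher_df,
        univariate=uni,
        summary=summary,
    )
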