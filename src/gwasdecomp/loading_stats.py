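"""Per-SNP significance of component loadings; Manhattan-style tables.

Within one genomic component the bulk of SNP loadings is approximately
Gaussian noise; a SNP's significance is therefore referred to the normal
CDF parameterised by the component's own loading mean and SD.  The result
is a plot-ready table analogous to a GWAS Manhattan plot, one per
component.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import DecompositionResult
from .exceptions import ValidationError
from .utils import genomic_order

__all__ = ["loading_significance", "manhattan_table"]


def loading_significance(
    loadings, tails: Literal["one", "two"] = "two"
) -> np.ndarray:
    """Normal-reference p-values for one component's SNP loadings.

    With mu, sigma the loading vector's mean and SD, the one-tailed (upper)
    p is ``1 - Phi((x - mu)/sigma)`` and the two-tailed p is
    ``2 * Phi(-|x - mu|/sigma)``.  Invariant to affine rescaling of the
    whole vector.
    """
    x = np.asarray(loadings, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValidationError("need a 1-D vector of at least 3 loadings")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite loadings")
    mu = x.mean()
    sigma = x.std(ddof=0)
    if sigma == 0:
        raise ValidationError("degenerate loading vector (zero SD)")
    z = (x - mu) / sigma
    if tails == "one":
        return stats.norm.sf(z)
    if tails == "two":
        return 2.0 * stats.norm.sf(np.abs(z))
    raise ValidationError(f"tails must be 'one' or 'two', got {tails!r}")


def manhattan_table(
    d: DecompositionResult, component: int, tails: Literal["one", "two"] = "two"
) -> pd.DataFrame:
    """Plot-ready per-SNP significance table for one component.

    ``component`` is 0-based.  Joins the component's loadings to the SNP
    registry coordinates, attaches the CDF-based p and -log10(p), and sorts
    by (chromosome, position).
    """
    if not 0 <= component < d.k:
        raise ValidationError(f"component {component} out of range 0..{d.k - 1}")
    reg = d.snp_registry
    for col in ("chrom", "pos"):
        if col not in reg.columns or reg[col].isna().any():
            bad = reg.loc[reg[col].isna(), "snp_id"].tolist()[:5] if col in reg.columns else "all"
            raise ValidationError(f"missing {col} coordinates in registry: {bad}")
    p = loading_significance(d.snp_loadings[component], tails=tails)
    out = pd.DataFrame(
        {
            "snp_id": reg["snp_id"].to_numpy(),
            "chrom": reg["chrom"].astype(str).to_numpy(),
            "pos": reg["pos"].astype(int).to_numpy(),
            "component": component + 1,
            "loading": d.snp_loadings[component],
            "p": p,
            "neglog10_p": -np.log10(np.maximum(p, np.finfo(float).tiny)),
        }
    )
    order = genomic_order(out["chrom"], out["pos"])
    return out.iloc[order].reset_index(drop=True)
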