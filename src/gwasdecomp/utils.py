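"""Small shared helpers."""

from __future__ import annotations

import numpy as np

_SPECIAL_CHROMS = {"X": 23, "Y": 24, "XY": 25, "MT": 26, "M": 26}


def chrom_rank(chrom: str) -> tuple[int, str]:
    """Sortable key for a chromosome label.

    Autosomes sort numerically (``"1" < "2" < ... < "22"``), then X, Y, XY,
    MT; anything else sorts after those, alphabetically.  ``chr`` prefixes
    are tolerated.
    """
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    cu = c.upper()
    if cu.isdigit():
        return (int(cu), "")
    if cu in _SPECIAL_CHROMS:
        return (_SPECIAL_CHROMS[cu], "")
    return (99, cu)


def genomic_order(chroms, positions) -> np.ndarray:
    """Indices that sort SNPs by (chromosome, position)."""
    keys = [(*chrom_rank(c), int(p)) for c, p in zip(chroms, positions)]
    return np.array(sorted(range(len(keys)), key=keys.__getitem__), dtype=int)
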