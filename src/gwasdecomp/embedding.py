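"""2-D embedding of trait loadings (visualising modality clustering).

Traits whose loading profiles across components are similar — typically
traits from the same imaging modality — end up close in the embedding.
t-SNE is used as the stochastic-neighbour method; determinism is
guaranteed for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .exceptions import ValidationError

__all__ = ["EmbeddingResult", "embed_trait_loadings"]


@dataclass
class EmbeddingResult:
    coords: np.ndarray  # m x 2
    trait_ids: list[str]
    modality_labels: list[str] | None
    perplexity: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"trait_id": self.trait_ids, "x": self.coords[:, 0], "y": self.coords[:, 1]}
        )
        if self.modality_labels is not None:
            df["modality"] = self.modality_labels
        return df


def embed_trait_loadings(
    trait_loadings,
    perplexity: float = 30.0,
    seed: int = 0,
    trait_ids: Sequence[str] | None = None,
    modality_labels: Sequence[str] | None = None,
) -> EmbeddingResult:
    """t-SNE embedding of an m x K trait-loading matrix into 2-D.

    Requires ``m > 3 * perplexity`` (the neighbourhood size must be
    resolvable) and K >= 2.  Deterministic for a fixed seed.
    """
    A = np.asarray(trait_loadings, dtype=float)
    if A.ndim != 2 or A.shape[1] < 2:
        raise ValidationError("trait loadings must be m x K with K >= 2")
    m = A.shape[0]
    if not m > 3 * perplexity:
        raise ValidationError(f"perplexity {perplexity} too large for m={m} (need m > 3*perplexity)")
    if not np.all(np.isfinite(A)):
        raise ValidationError("non-finite trait loadings")
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=int(seed),
        init="pca",
        method="exact" if m < 1000 else "barnes_hut",
    )
    coords = tsne.fit_transform(A)
    if not np.all(np.isfinite(coords)):
        raise ValidationError("embedding produced non-finite coordinates")
    tids = list(trait_ids) if trait_ids is not None else [f"trait{i}" for i in range(m)]
    if len(tids) != m:
        raise ValidationError("trait_ids length mismatch")
    labels = list(modality_labels) if modality_labels is not None else None
    if labels is not None and len(labels) != m:
        raise ValidationError("modality_labels length mismatch")
    return EmbeddingResult(
        coords=np.asarray(coords, dtype=float),
        trait_ids=tids,
        modality_labels=labels,
        perplexity=float(perplexity),
        seed=int(seed),
    )
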