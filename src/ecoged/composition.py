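"""Compositional (species-occurrence) similarity between webs."""

from __future__ import annotations

from dataclasses import dataclass

from .foodweb import FoodWeb, composition_counts

__all__ = ["CompositionScore", "jaccard_dissimilarity", "jaccard_similarity", "composition_score"]


@dataclass(frozen=True)
class CompositionScore:
    jaccard_dissimilarity: float
    jaccard_similarity: float


def jaccard_dissimilarity(w1: FoodWeb, w2: FoodWeb) -> float:
    """Jaccard dissimilarity (a+b)/(a+b+c) over taxon occurrences.

    a and b are taxa unique to each web, c the shared taxa.  Two empty webs
    compare as identical (0), consistent with the equal-sets limit.
    """
    a, b, c = composition_counts(w1, w2)
    if a + b + c == 0:
        return 0.0
    return (a + b) / (a + b + c)


def jaccard_similarity(w1: FoodWeb, w2: FoodWeb) -> float:
    return 1.0 - jaccard_dissimilarity(w1, w2)


def composition_score(w1: FoodWeb, w2: FoodWeb) -> CompositionScore:
    d = jaccard_dissimilarity(w1, w2)
    return CompositionScore(jaccard_dissimilarity=d, jaccard_similarity=1.0 - d)
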