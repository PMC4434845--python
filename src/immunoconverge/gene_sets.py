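"""Overlap accounting among disease gene sets.

The focal disease (ankylosing spondylitis in the motivating study) is compared
against every other catalog entry: pairwise intersection counts, a per-gene
sharing classification (unique / shared with at most two others / shared with
more than two others), and construction of the disjoint seed/test pair used by
the network stage, where genes shared with the focal set are excluded so the
connectivity signal is not confounded by literal gene overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import DiseaseGeneCatalog

__all__ = [
    "OverlapSummary",
    "DegenerateComparisonError",
    "pairwise_overlap",
    "sharing_classes",
    "deconfounded_pair",
]


class DegenerateComparisonError(ValueError):
    """Raised when excluding focal-shared genes empties the comparison set."""


@dataclass(frozen=True)
class OverlapSummary:
    """Sharing structure of a focal disease's gene set.

    ``unique_to_focal + shared_at_most_two + shared_more_than_two`` partitions
    the focal set: each focal gene is classified by the number of *other*
    diseases whose sets contain it (0 / 1–2 / ≥3).
    """

    focal: str
    per_disease_overlap: dict[str, int]
    unique_to_focal: int
    shared_at_most_two: int
    shared_more_than_two: int

    @property
    def focal_size(self) -> int:
        return self.unique_to_focal + self.shared_at_most_two + self.shared_more_than_two


def pairwise_overlap(catalog: DiseaseGeneCatalog, focal: str) -> dict[str, int]:
    """Count |focal ∩ d| for every other disease d in the catalog."""
    focal_genes = catalog.genes(focal)
    return {
        d: len(focal_genes & catalog.entries[d])
        for d in catalog.diseases
        if d != focal
    }


def sharing_classes(
    catalog: DiseaseGeneCatalog, focal: str, count_focal: bool = False
) -> OverlapSummary:
    """Classify each focal gene by how many disease sets share it.

    By default a gene's sharing count is the number of *other* diseases whose
    sets contain it; ``count_focal=True`` additionally counts the focal set
    itself (shifting every gene's count up by one).
    """
    focal_genes = catalog.genes(focal)
    others = [d for d in catalog.diseases if d != focal]
    unique = at_most_two = more_than_two = 0
    for gene in focal_genes:
        n = sum(1 for d in others if gene in catalog.entries[d])
        if count_focal:
            n += 1
        if n == 0:
            unique += 1
        elif n <= 2:
            at_most_two += 1
        else:
            more_than_two += 1
    return OverlapSummary(
        focal=focal,
        per_disease_overlap=pairwise_overlap(catalog, focal),
        unique_to_focal=unique,
        shared_at_most_two=at_most_two,
        shared_more_than_two=more_than_two,
    )


def deconfounded_pair(
    catalog: DiseaseGeneCatalog, a: str, b: str
) -> tuple[frozenset[str], frozenset[str]]:
    """Return (A, B \\ A): disease b's genes with those shared with a removed.

    The two returned sets are disjoint by construction. Raises
    :class:`DegenerateComparisonError` when b ⊆ a leaves nothing to test.
    """
    if a == b:
        raise ValueError("a and b must be different diseases")
    set_a = catalog.genes(a)
    set_b = catalog.genes(b) - set_a
    if not set_b:
        raise DegenerateComparisonError(
            f"every gene of {b!r} is shared with {a!r}; nothing left to compare"
        )
    return set_a, frozenset(set_b)
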