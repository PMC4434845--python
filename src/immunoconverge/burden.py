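"""Exon-level deleterious-mutation burden as a measure of purifying selection.

A gene's exons from all isoforms are merged into a *compound exon model*
(maximal non-overlapping blocks; touching blocks merge). Rare missense and
loss-of-function variants are counted per compound exon and normalized by exon
length in bp. Genes under purifying selection are depleted of such variants
relative to genes known to tolerate loss of function, and the two burden
distributions are compared with a two-sample Kolmogorov–Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import kolmogorov

from .io_formats import LOF_CONSEQUENCES, GenomicInterval, VariantRecord

__all__ = [
    "CompoundExonModel",
    "BurdenProfile",
    "KSResult",
    "build_compound_exons",
    "classify_deleterious",
    "exon_burden",
    "set_burdens",
    "ks_compare",
]


@dataclass(frozen=True)
class CompoundExonModel:
    """Merged, sorted, non-overlapping exon blocks of one gene."""

    gene: str
    intervals: tuple[GenomicInterval, ...]

    def __post_init__(self):
        if not self.intervals:
            raise ValueError(f"compound exon model for {self.gene} has no intervals")
        for prev, cur in zip(self.intervals, self.intervals[1:]):
            if prev.chrom == cur.chrom and cur.start <= prev.end:
                raise ValueError(f"intervals of {self.gene} overlap or touch after merging")

    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)


@dataclass(frozen=True)
class BurdenProfile:
    """Per-compound-exon deleterious counts and length-normalized burdens."""

    gene: str
    per_exon: tuple[tuple[GenomicInterval, int, float], ...]
    n_outside: int = 0  # deleterious variants falling outside every compound exon

    @property
    def burdens(self) -> list[float]:
        return [b for _, _, b in self.per_exon]


@dataclass(frozen=True)
class KSResult:
    D: float
    p_value: float
    n_a: int
    n_b: int


def build_compound_exons(
    intervals: Iterable[GenomicInterval],
) -> dict[str, CompoundExonModel]:
    """Merge each gene's exon intervals into maximal non-overlapping blocks.

    Intervals are half-open; blocks that touch (end == next start) merge into
    a single breakpoint. Duplicated isoform annotations therefore never change
    the model.
    """
    by_gene: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_gene.setdefault(iv.gene, []).append(iv)
    models: dict[str, CompoundExonModel] = {}
    for gene, ivs in by_gene.items():
        merged: list[GenomicInterval] = []
        for iv in sorted(ivs, key=lambda x: (x.chrom, x.start, x.end)):
            if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
                last = merged[-1]
                if iv.end > last.end:
                    merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, gene)
            else:
                merged.append(GenomicInterval(iv.chrom, iv.start, iv.end, gene))
        models[gene] = CompoundExonModel(gene=gene, intervals=tuple(merged))
    return models


def classify_deleterious(
    variants: Iterable[VariantRecord], maf_threshold: float = 0.01
) -> list[VariantRecord]:
    """Keep rare missense (AF < threshold) and all loss-of-function variants."""
    if not 0.0 < maf_threshold < 1.0:
        raise ValueError(f"maf_threshold must be in (0, 1), got {maf_threshold}")
    return [
        v
        for v in variants
        if (v.consequence == "missense" and v.allele_frequency < maf_threshold)
        or v.consequence in LOF_CONSEQUENCES
    ]


def exon_burden(
    model: CompoundExonModel, deleterious: Sequence[VariantRecord]
) -> BurdenProfile:
    """Assign pre-filtered deleterious variants to compound exons of one gene.

    Variant positions are 1-based and converted to 0-based before the
    half-open containment test. Variants landing outside every compound exon
    are counted in ``n_outside`` but assigned to no exon.
    """
    counts = [0] * len(model.intervals)
    outside = 0
    # per chromosome, binary search over sorted block starts
    tmp: dict[str, list[tuple[int, int, int]]] = {}
    for idx, iv in enumerate(model.intervals):
        tmp.setdefault(iv.chrom, []).append((iv.start, iv.end, idx))
    lookup = {
        chrom: (
            np.array([s for s, _, _ in blocks]),
            np.array([e for _, e, _ in blocks]),
            [i for _, _, i in blocks],
        )
        for chrom, blocks in tmp.items()
    }
    for v in deleterious:
        if v.gene != model.gene:
            continue
        pos0 = v.pos - 1
        hit = False
        if v.chrom in lookup:
            starts, ends, idxs = lookup[v.chrom]
            j = int(np.searchsorted(starts, pos0, side="right")) - 1
            if j >= 0 and pos0 < ends[j]:
                counts[idxs[j]] += 1
                hit = True
        if not hit:
            outside += 1
    per_exon = tuple(
        (iv, c, c / iv.length) for iv, c in zip(model.intervals, counts)
    )
    return BurdenProfile(gene=model.gene, per_exon=per_exon, n_outside=outside)


def set_burdens(
    models: Mapping[str, CompoundExonModel],
    deleterious: Sequence[VariantRecord],
    genes: Iterable[str],
    per_gene: bool = False,
) -> list[float]:
    """Pooled burden observations for a gene set.

    Default pooling unit is the per-compound-exon normalized burden across all
    genes of the set; ``per_gene=True`` instead yields one mean burden per
    gene. Genes without an exon model are skipped.
    """
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in deleterious:
        by_gene.setdefault(v.gene, []).append(v)
    out: list[float] = []
    for gene in sorted(set(genes)):
        model = models.get(gene)
        if model is None:
            continue
        profile = exon_burden(model, by_gene.get(gene, []))
        if per_gene:
            out.append(float(np.mean(profile.burdens)))
        else:
            out.extend(profile.burdens)
    return out


def ks_compare(burdens_a: Sequence[float], burdens_b: Sequence[float]) -> KSResult:
    """Two-sided two-sample KS test with the asymptotic Kolmogorov p-value.

    D is the supremum ECDF distance; the p-value is the Kolmogorov survival
    function evaluated at sqrt(n_eff)·D with n_eff = n_a·n_b/(n_a+n_b).
    """
    a = np.sort(np.asarray(burdens_a, dtype=float))
    b = np.sort(np.asarray(burdens_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both burden samples must be non-empty")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    n_eff = a.size * b.size / (a.size + b.size)
    p = float(kolmogorov(np.sqrt(n_eff) * d))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return KSResult(D=d, p_value=p, n_a=int(a.size), n_b=int(b.size))
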