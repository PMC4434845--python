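"""Percentile-threshold expression profiling.

Two read-outs, both anchored on the genome-wide 75th-percentile cutoff:

* transcript abundance — how many of a gene's transcripts sit above the
  genome-wide cutoff of population-mean FPKM, averaged over a risk-gene set
  versus all annotated genes;
* tissue protein profile — per tissue, the mean spectral count over set genes
  and the fraction of set genes above the cutoff of the pooled gene×tissue
  matrix, from which a hematopoietic-versus-rest fold is derived.

Also carries the comparative-threshold-cycle (ΔCT/ΔΔCT) arithmetic used to
summarize qPCR runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, normalize_symbol

__all__ = [
    "TissueExpressionSummary",
    "percentile_threshold",
    "transcript_abundance",
    "tissue_profile",
    "hematopoietic_fold",
    "delta_delta_ct",
]


@dataclass(frozen=True)
class TissueExpressionSummary:
    """Per-tissue mean expression and above-cutoff ratios for one gene set."""

    per_tissue_mean: dict[str, float]
    per_tissue_ratio: dict[str, float]  # each in [0, 1]
    cutoff: float
    n_set_genes: int
    col_groups: dict[str, str] | None = None


def percentile_threshold(values: Sequence[float], q: float = 75.0) -> float:
    """Linear-interpolation percentile (index (q/100)·(n−1) on sorted values)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take a percentile of an empty sample")
    if not 0.0 < q < 100.0:
        raise ValueError(f"q must be in (0, 100), got {q}")
    return float(np.percentile(arr, q, method="linear"))


def transcript_abundance(
    fpkm: ExpressionMatrix,
    gene_set: Iterable[str],
    q: float = 75.0,
    per_sample: bool = False,
) -> tuple[float, float]:
    """Mean number of highly expressed transcripts per gene: set vs genome.

    A transcript is *highly expressed* when its mean FPKM across samples
    exceeds the genome-wide q-th percentile of transcript mean FPKM (strict
    ``>``). With ``per_sample=True`` the threshold crossing is instead decided
    per sample (against the per-sample genome percentile) and the per-sample
    counts are averaged afterwards.

    Returns ``(set_mean, genome_mean)``.
    """
    if fpkm.row_to_gene is None:
        raise ValueError("FPKM matrix needs a row_to_gene annotation")
    genes = pd.Series(fpkm.row_to_gene).reindex(fpkm.values.index)
    query = {normalize_symbol(g) for g in gene_set}
    annotated = set(genes)
    missing = query - annotated
    if missing == query:
        raise ValueError(
            f"no query gene is annotated in the matrix; missing: {sorted(missing)}"
        )
    if per_sample:
        counts = pd.Series(0.0, index=pd.unique(genes))
        n_samples = fpkm.values.shape[1]
        for col in fpkm.values.columns:
            vals = fpkm.values[col]
            cutoff = percentile_threshold(vals.to_numpy(), q)
            high = vals > cutoff
            counts = counts.add(high.groupby(genes).sum() / n_samples, fill_value=0.0)
        per_gene = counts
    else:
        mean_fpkm = fpkm.values.mean(axis=1)
        cutoff = percentile_threshold(mean_fpkm.to_numpy(), q)
        high = mean_fpkm > cutoff
        per_gene = high.groupby(genes).sum().astype(float)
        per_gene = per_gene.reindex(pd.unique(genes), fill_value=0.0)
    set_genes = sorted(query & annotated)
    return float(per_gene.loc[set_genes].mean()), float(per_gene.mean())


def tissue_profile(
    spectra: ExpressionMatrix,
    gene_set: Iterable[str],
    q: float = 75.0,
    per_tissue_cutoff: bool = False,
) -> TissueExpressionSummary:
    """Per-tissue mean spectral counts and above-cutoff gene ratios for a set.

    The cutoff defaults to the q-th percentile of the pooled gene×tissue value
    matrix (one global cutoff); ``per_tissue_cutoff=True`` recomputes it per
    tissue column. Ratios divide by the number of set genes present as matrix
    rows.
    """
    query = {normalize_symbol(g) for g in gene_set}
    rows = sorted(query & set(spectra.values.index))
    if not rows:
        raise ValueError("gene set has no overlap with the matrix rows")
    sub = spectra.values.loc[rows]
    global_cutoff = percentile_threshold(spectra.values.to_numpy().ravel(), q)
    means: dict[str, float] = {}
    ratios: dict[str, float] = {}
    for col in spectra.values.columns:
        cutoff = (
            percentile_threshold(spectra.values[col].to_numpy(), q)
            if per_tissue_cutoff
            else global_cutoff
        )
        means[col] = float(sub[col].mean())
        ratios[col] = float((sub[col] > cutoff).mean())
    return TissueExpressionSummary(
        per_tissue_mean=means,
        per_tissue_ratio=ratios,
        cutoff=global_cutoff,
        n_set_genes=len(rows),
        col_groups=spectra.col_groups,
    )


def hematopoietic_fold(
    summary: TissueExpressionSummary, hematopoietic_labels: Iterable[str]
) -> float:
    """Mean above-cutoff ratio over hematopoietic tissues ÷ over all others.

    Returns ``inf`` when only the hematopoietic ratios are non-zero and NaN
    (with a warning) when both group means are zero.
    """
    hema = {str(t) for t in hematopoietic_labels}
    tissues = set(summary.per_tissue_ratio)
    if not hema & tissues or not tissues - hema:
        raise ValueError("both tissue groups must be non-empty")
    num = float(np.mean([summary.per_tissue_ratio[t] for t in sorted(hema & tissues)]))
    den = float(np.mean([summary.per_tissue_ratio[t] for t in sorted(tissues - hema)]))
    if den == 0.0:
        if num == 0.0:
            warnings.warn("all above-cutoff ratios are zero; fold undefined", stacklevel=2)
            return float("nan")
        return float("inf")
    return num / den


def delta_delta_ct(
    ct_target: float, ct_reference: float, calibrator_delta: float = 0.0
) -> tuple[float, float, float]:
    """Comparative threshold cycle arithmetic.

    ``delta = CT_target − CT_reference``; ``ddct = delta − calibrator_delta``;
    relative quantity ``rq = 2^(−ddct)``. Returns ``(delta, ddct, rq)``.
    """
    for name, v in (("ct_target", ct_target), ("ct_reference", ct_reference),
                    ("calibrator_delta", calibrator_delta)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    delta = ct_target - ct_reference
    ddct = delta - calibrator_delta
    return delta, ddct, float(2.0 ** (-ddct))
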