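"""Seeded generators emulating every input dataset with planted structure.

Each generator plants a parameterized effect so the corresponding pipeline
stage has a ground-truth recovery test:

* catalog — membership patterns realise exact pairwise overlaps and sharing
  classes between disease gene sets;
* exome — per-gene compound exons with deleterious variants placed by a
  Poisson process whose rate is halved in "constrained" genes (purifying
  selection);
* expression — log-normal FPKM / spectral-count baselines with a
  multiplicative boost of the risk genes in flagged tissues;
* gene sets — uniform decoy pathways plus one planted pathway holding a
  configured fraction of a disease's genes;
* network — Erdős–Rényi background with extra cross-set bipartite edges at a
  planted density.

All generators are deterministic functions of the configuration (seed
included); identical configurations yield byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    DiseaseGeneCatalog,
    EdgeList,
    ExpressionMatrix,
    GeneSetDB,
    GenomicInterval,
    VariantRecord,
    write_edge_list,
    write_exon_bed,
    write_expression_matrix,
    write_gene_file,
    write_gene_lists,
    write_gmt,
    write_variant_table,
)

__all__ = [
    "BurdenRates",
    "ExpressionBoost",
    "PlantedPathway",
    "NetworkParams",
    "SyntheticConfig",
    "default_config",
    "load_scenario",
    "gen_catalog",
    "gen_exome_and_variants",
    "gen_expression",
    "gen_genesets",
    "gen_network",
    "generate_all",
    "PLANTED_SET_NAME",
]

#: Tissue panel mirroring a developmental proteome: 6 fetal organs, 18 adult
#: tissues and 6 purified hematopoietic cell types.
FETAL_TISSUES = (
    "fetal_heart", "fetal_liver", "fetal_gut", "fetal_ovary", "fetal_testis", "fetal_brain",
)
ADULT_TISSUES = (
    "frontal_cortex", "spinal_cord", "retina", "heart", "liver", "ovary", "testis",
    "lung", "adrenal", "gallbladder", "pancreas", "kidney", "esophagus", "colon",
    "rectum", "urinary_bladder", "prostate", "placenta",
)
HEMATOPOIETIC_CELLS = ("b_cell", "cd4_cell", "cd8_cell", "nk_cell", "monocyte", "platelet")

PLANTED_SET_NAME = "SET_PLANTED"

_LOF_TYPES = ("stop_gained", "frameshift", "splice_donor", "splice_acceptor")


@dataclass(frozen=True)
class BurdenRates:
    """Deleterious-variant placement rates and allele-frequency shape.

    ``lambda_*`` are per-bp Poisson rates of deleterious-class variants
    (missense + LOF). A ``rare_fraction`` of missense allele frequencies fall
    below ``rare_cutoff``; AFs follow a rare-skewed Beta(alpha, beta).
    """

    lambda_tolerated: float = 0.02
    lambda_constrained: float = 0.01
    missense_fraction: float = 0.75
    rare_fraction: float = 0.9
    synonymous_rate: float = 0.03
    rare_cutoff: float = 0.01
    maf_alpha: float = 0.2
    maf_beta: float = 5.0


@dataclass(frozen=True)
class ExpressionBoost:
    """Multiplicative expression boost of risk genes in flagged tissues."""

    tissues: tuple[str, ...] = HEMATOPOIETIC_CELLS
    factor: float = 3.0


@dataclass(frozen=True)
class PlantedPathway:
    size: int = 50
    query_fraction: float = 0.5
    n_decoys: int = 400
    n_background: int = 5000


@dataclass(frozen=True)
class NetworkParams:
    n_nodes: int = 2000
    p_background: float = 0.02
    p_planted: float = 0.1
    planted_pairs: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class SyntheticConfig:
    """Full scenario description; the seed is part of the scenario."""

    seed: int
    diseases: tuple[str, ...]
    set_sizes: dict[str, int]
    membership_patterns: tuple[tuple[frozenset[str], int], ...]
    focal: str = "AS"
    n_tolerated: int = 98
    burden_rates: BurdenRates = field(default_factory=BurdenRates)
    expression_boost: ExpressionBoost = field(default_factory=ExpressionBoost)
    planted_pathway: PlantedPathway = field(default_factory=PlantedPathway)
    network_params: NetworkParams = field(default_factory=NetworkParams)
    n_fpkm_samples: int = 45
    log_mu: float = 1.0
    log_sigma: float = 1.0

    def __post_init__(self):
        for (pattern, count) in self.membership_patterns:
            if count < 0:
                raise ValueError("pattern counts must be >= 0")
            unknown = pattern - set(self.diseases)
            if unknown:
                raise ValueError(f"pattern names unknown diseases {sorted(unknown)}")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent deterministic stream per generator stage."""
        return np.random.default_rng([self.seed, stage])


def default_config(seed: int = 0) -> SyntheticConfig:
    """Desk-scale default scenario mirroring the motivating study's design.

    Nine diseases, 407 distinct genes, focal-set pairwise overlaps
    CD 11 / UC 8 / CeD 5 / PS 5 / T1D 4 / MS 4 / PBC 1 / RA 0 with sharing
    classes 8 unique, 17 shared with at most two others, 5 shared with more
    than two.
    """
    diseases = ("AS", "CD", "UC", "PS", "CeD", "MS", "PBC", "RA", "T1D")
    set_sizes = {
        "AS": 30, "CD": 110, "UC": 75, "PS": 40, "CeD": 40,
        "MS": 50, "PBC": 20, "RA": 45, "T1D": 35,
    }
    triples = [("CD", "UC", "PS"), ("CD", "UC", "CeD"), ("CD", "UC", "T1D"),
               ("CD", "PS", "MS"), ("CD", "CeD", "T1D")]
    pairs = [("CD", "UC"), ("CD", "PS"), ("CD", "CeD"), ("UC", "T1D"),
             ("UC", "MS"), ("PS", "CeD")]
    singles = [("CD", 3), ("UC", 2), ("PS", 1), ("CeD", 1), ("T1D", 1), ("MS", 2), ("PBC", 1)]
    patterns: list[tuple[frozenset[str], int]] = []
    for t in triples:
        patterns.append((frozenset({"AS", *t}), 1))
    for p in pairs:
        patterns.append((frozenset({"AS", *p}), 1))
    for d, n in singles:
        patterns.append((frozenset({"AS", d}), n))
    return SyntheticConfig(
        seed=seed,
        diseases=diseases,
        set_sizes=set_sizes,
        membership_patterns=tuple(patterns),
        network_params=NetworkParams(
            planted_pairs=tuple(("AS", d) for d in diseases if d != "AS")
        ),
    )


def load_scenario(path, seed: int | None = None) -> SyntheticConfig:
    """Load a scenario YAML; ``seed`` overrides the file's seed when given."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    patterns = tuple(
        (frozenset(p["diseases"]), int(p["count"]))
        for p in raw.get("membership_patterns", [])
    )
    cfg = SyntheticConfig(
        seed=int(raw["seed"]) if seed is None else int(seed),
        diseases=tuple(raw["diseases"]),
        set_sizes={str(k): int(v) for k, v in raw["set_sizes"].items()},
        membership_patterns=patterns,
        focal=str(raw.get("focal", "AS")),
        n_tolerated=int(raw.get("n_tolerated", 98)),
        burden_rates=BurdenRates(**raw.get("burden_rates", {})),
        expression_boost=ExpressionBoost(
            tissues=tuple(raw.get("expression_boost", {}).get("tissues", HEMATOPOIETIC_CELLS)),
            factor=float(raw.get("expression_boost", {}).get("factor", 3.0)),
        ),
        planted_pathway=PlantedPathway(**raw.get("planted_pathway", {})),
        network_params=NetworkParams(
            n_nodes=int(raw.get("network_params", {}).get("n_nodes", 2000)),
            p_background=float(raw.get("network_params", {}).get("p_background", 0.02)),
            p_planted=float(raw.get("network_params", {}).get("p_planted", 0.1)),
            planted_pairs=tuple(
                (a, b) for a, b in raw.get("network_params", {}).get("planted_pairs", [])
            ),
        ),
        n_fpkm_samples=int(raw.get("n_fpkm_samples", 45)),
        log_mu=float(raw.get("log_mu", 1.0)),
        log_sigma=float(raw.get("log_sigma", 1.0)),
    )
    return cfg


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------


def gen_catalog(config: SyntheticConfig) -> DiseaseGeneCatalog:
    """Catalog whose pairwise overlaps equal the membership design exactly.

    Each membership pattern (a set of diseases, a count) contributes that many
    genes belonging to exactly those diseases; remaining slots are filled with
    genes unique to each disease. Symbols are synthetic ("G000001"...).
    """
    used: dict[str, int] = {d: 0 for d in config.diseases}
    for pattern, count in config.membership_patterns:
        for d in pattern:
            used[d] += count
    for d in config.diseases:
        if d not in config.set_sizes:
            raise ValueError(f"no set size for disease {d!r}")
        if used[d] > config.set_sizes[d]:
            raise ValueError(
                f"infeasible design: disease {d!r} needs {used[d]} pattern genes "
                f"but its set size is {config.set_sizes[d]}"
            )
    entries: dict[str, set[str]] = {d: set() for d in config.diseases}
    counter = 0

    def next_gene() -> str:
        nonlocal counter
        counter += 1
        return f"G{counter:06d}"

    for pattern, count in config.membership_patterns:
        for _ in range(count):
            g = next_gene()
            for d in sorted(pattern):
                entries[d].add(g)
    for d in config.diseases:
        while len(entries[d]) < config.set_sizes[d]:
            entries[d].add(next_gene())
    return DiseaseGeneCatalog({d: frozenset(v) for d, v in entries.items()})


# ---------------------------------------------------------------------------
# Exome + variants
# ---------------------------------------------------------------------------


def _draw_af_rare(rng: np.random.Generator, rates: BurdenRates) -> float:
    return float(rates.rare_cutoff * rng.beta(rates.maf_alpha, rates.maf_beta))


def gen_exome_and_variants(
    config: SyntheticConfig,
    genes: Iterable[str],
    group_labels: Mapping[str, str],
) -> tuple[list[GenomicInterval], list[VariantRecord]]:
    """Per-gene exons plus Poisson-placed deleterious and synonymous variants.

    ``group_labels`` maps each gene to ``"tolerated"`` or ``"constrained"``,
    selecting the per-bp deleterious rate. Each gene receives 3–8 exons of
    80–400 bp on its own synthetic chromosome; some genes additionally emit a
    redundant contained isoform exon, which the compound model must absorb.
    """
    rng = config.rng(stage=2)
    rates = config.burden_rates
    intervals: list[GenomicInterval] = []
    variants: list[VariantRecord] = []
    for gene in sorted(set(genes)):
        group = group_labels[gene]
        if group not in ("tolerated", "constrained"):
            raise ValueError(f"unknown group {group!r} for gene {gene}")
        lam = rates.lambda_tolerated if group == "tolerated" else rates.lambda_constrained
        chrom = f"chr_{gene}"
        n_exons = int(rng.integers(3, 9))
        lengths = rng.integers(80, 401, size=n_exons)
        gaps = rng.integers(100, 1001, size=n_exons)
        pos = 0
        exons: list[tuple[int, int]] = []
        for ln, gp in zip(lengths, gaps):
            start = pos + int(gp)
            end = start + int(ln)
            exons.append((start, end))
            pos = end
        for start, end in exons:
            intervals.append(GenomicInterval(chrom, start, end, gene))
        # redundant isoform annotation, fully contained in an existing exon
        if rng.random() < 0.3:
            s, e = exons[int(rng.integers(0, n_exons))]
            if e - s > 20:
                off = int(rng.integers(0, (e - s) // 2))
                intervals.append(GenomicInterval(chrom, s + off, e - (e - s) // 4, gene))
        for start, end in exons:
            length = end - start
            n_del = int(rng.poisson(lam * length))
            for _ in range(n_del):
                p = start + int(rng.integers(0, length)) + 1  # 1-based
                if rng.random() < rates.missense_fraction:
                    cons = "missense"
                    if rng.random() < rates.rare_fraction:
                        af = _draw_af_rare(rng, rates)
                    else:
                        af = float(rng.uniform(rates.rare_cutoff, 0.5))
                else:
                    cons = _LOF_TYPES[int(rng.integers(0, len(_LOF_TYPES)))]
                    af = _draw_af_rare(rng, rates)
                variants.append(VariantRecord(gene, chrom, p, cons, af))
            n_syn = int(rng.poisson(rates.synonymous_rate * length))
            for _ in range(n_syn):
                p = start + int(rng.integers(0, length)) + 1
                af = float(rng.beta(rates.maf_alpha, rates.maf_beta))
                variants.append(VariantRecord(gene, chrom, p, "synonymous", af))
    return intervals, variants


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def gen_expression(
    config: SyntheticConfig,
    genes: Iterable[str],
    boosted_genes: Iterable[str] = (),
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Log-normal FPKM (transcript×sample) and spectra (gene×tissue) matrices.

    ``boosted_genes`` (typically the focal risk set) are multiplied by the
    configured boost factor in the flagged tissues of the spectra matrix.
    """
    rng = config.rng(stage=3)
    gene_list = sorted(set(genes))
    boosted = set(boosted_genes)
    # FPKM: 1-5 transcripts per gene over n_fpkm_samples LCL-like samples
    n_tx = rng.integers(1, 6, size=len(gene_list))
    row_ids: list[str] = []
    row_to_gene: dict[str, str] = {}
    t = 0
    for gene, k in zip(gene_list, n_tx):
        for _ in range(int(k)):
            t += 1
            rid = f"T{t:06d}"
            row_ids.append(rid)
            row_to_gene[rid] = gene
    samples = [f"S{i + 1:02d}" for i in range(config.n_fpkm_samples)]
    fpkm_vals = rng.lognormal(config.log_mu, config.log_sigma, size=(len(row_ids), len(samples)))
    fpkm = ExpressionMatrix(
        pd.DataFrame(fpkm_vals, index=row_ids, columns=samples),
        row_to_gene=row_to_gene,
    )
    # spectra: genes x (fetal + adult + hematopoietic) tissues
    tissues = [*FETAL_TISSUES, *ADULT_TISSUES, *HEMATOPOIETIC_CELLS]
    groups = {
        **{c: "fetal" for c in FETAL_TISSUES},
        **{c: "adult" for c in ADULT_TISSUES},
        **{c: "hematopoietic" for c in HEMATOPOIETIC_CELLS},
    }
    if config.log_sigma == 0.0:
        spectra_vals = np.full((len(gene_list), len(tissues)), math.exp(config.log_mu))
    else:
        spectra_vals = rng.lognormal(config.log_mu, config.log_sigma,
                                     size=(len(gene_list), len(tissues)))
    boost_cols = [i for i, c in enumerate(tissues) if c in set(config.expression_boost.tissues)]
    boost_rows = [i for i, g in enumerate(gene_list) if g in boosted]
    if boost_rows and boost_cols:
        spectra_vals[np.ix_(boost_rows, boost_cols)] *= config.expression_boost.factor
    spectra = ExpressionMatrix(
        pd.DataFrame(spectra_vals, index=gene_list, columns=tissues),
        col_groups=groups,
    )
    return fpkm, spectra


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


def gen_genesets(
    config: SyntheticConfig,
    genes: Iterable[str],
    planted_from: Iterable[str],
) -> tuple[GeneSetDB, frozenset[str]]:
    """Decoy pathways plus one planted pathway over a synthetic background.

    The background universe contains every provided gene plus filler symbols
    up to ``n_background``. The planted set holds ``query_fraction`` of the
    ``planted_from`` genes (rounded down), topped up with random background
    genes to ``size``. Returns ``(db, background_universe)``.
    """
    pp = config.planted_pathway
    if not 15 <= pp.size <= 1000:
        raise ValueError("planted pathway size must be within [15, 1000]")
    rng = config.rng(stage=4)
    base = sorted(set(genes))
    universe = list(base)
    i = 0
    while len(universe) < pp.n_background:
        i += 1
        universe.append(f"B{i:06d}")
    universe_arr = np.array(sorted(universe))
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    sources = ("GO", "NCI", "KEGG", "REACTOME")
    for j in range(pp.n_decoys):
        size = int(rng.integers(15, 401))
        members = rng.choice(universe_arr, size=size, replace=False)
        sets[f"SET_{j + 1:04d}"] = (sources[j % 4], frozenset(str(m) for m in members))
    planted_pool = sorted(set(planted_from))
    k = int(pp.query_fraction * len(planted_pool))
    chosen = list(rng.choice(np.array(planted_pool), size=k, replace=False)) if k else []
    rest_pool = np.array([g for g in universe_arr if g not in set(chosen)])
    fill = rng.choice(rest_pool, size=pp.size - len(chosen), replace=False)
    sets[PLANTED_SET_NAME] = ("SYN", frozenset(str(g) for g in [*chosen, *fill]))
    return GeneSetDB(sets), frozenset(str(g) for g in universe_arr)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


def gen_network(config: SyntheticConfig, catalog: DiseaseGeneCatalog) -> EdgeList:
    """Erdős–Rényi background plus planted cross-set bipartite edges.

    Nodes are all catalog genes plus filler symbols up to ``n_nodes``. For
    every planted disease pair (a, b), each A×(B\\A) gene pair receives an
    extra edge independently at ``p_planted``.
    """
    params = config.network_params
    if params.p_planted < params.p_background:
        raise ValueError("p_planted must be >= p_background")
    rng = config.rng(stage=5)
    nodes = sorted(catalog.all_genes())
    i = 0
    while len(nodes) < params.n_nodes:
        i += 1
        nodes.append(f"N{i:06d}")
    nodes = sorted(nodes[: max(params.n_nodes, len(nodes))])
    n = len(nodes)
    pairs: list[tuple[str, str]] = []
    if params.p_background > 0:
        # vectorized upper-triangle Bernoulli draw
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(iu.size) < params.p_background
        for a, b in zip(iu[mask], ju[mask]):
            pairs.append((nodes[a], nodes[b]))
    for a_lab, b_lab in params.planted_pairs:
        set_a = sorted(catalog.genes(a_lab))
        set_b = sorted(catalog.genes(b_lab) - catalog.genes(a_lab))
        for ga in set_a:
            draws = rng.random(len(set_b)) < params.p_planted
            for gb, hit in zip(set_b, draws):
                if hit:
                    pairs.append((ga, gb))
    return EdgeList.from_raw(pairs)


# ---------------------------------------------------------------------------
# Full scenario emission
# ---------------------------------------------------------------------------


def generate_all(config: SyntheticConfig, outdir) -> dict[str, Path]:
    """Emit every input file of the pipeline into ``outdir``.

    All files are written through the package's own writers so generated
    fixtures exercise the readers. Returns a name → path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog = gen_catalog(config)
    risk_genes = catalog.all_genes()
    tolerated = frozenset(f"TOL{i + 1:04d}" for i in range(config.n_tolerated))
    labels = {g: "constrained" for g in risk_genes}
    labels.update({g: "tolerated" for g in tolerated})
    intervals, variants = gen_exome_and_variants(config, risk_genes | tolerated, labels)
    fpkm, spectra = gen_expression(
        config, risk_genes | tolerated, boosted_genes=catalog.genes(config.focal)
    )
    db, universe = gen_genesets(config, risk_genes, planted_from=catalog.genes(config.focal))
    edges = gen_network(config, catalog)
    background = sorted(set(n for p in edges.pairs for n in p) | risk_genes)
    paths = {
        "gene_lists": outdir / "gene_lists.tsv",
        "tolerated": outdir / "tolerated_genes.txt",
        "exons": outdir / "exons.bed",
        "variants": outdir / "variants.tsv",
        "fpkm": outdir / "fpkm.tsv",
        "fpkm_gene_map": outdir / "fpkm_gene_map.tsv",
        "spectra": outdir / "spectra.tsv",
        "tissue_groups": outdir / "tissue_groups.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "enrichment_background": outdir / "enrichment_background.txt",
        "edges": outdir / "edges.tsv",
        "network_background": outdir / "network_background.txt",
    }
    write_gene_lists(catalog, paths["gene_lists"])
    write_gene_file(tolerated, paths["tolerated"])
    write_exon_bed(intervals, paths["exons"])
    write_variant_table(variants, paths["variants"])
    write_expression_matrix(fpkm, paths["fpkm"], gene_map=paths["fpkm_gene_map"])
    write_expression_matrix(spectra, paths["spectra"], col_groups=paths["tissue_groups"])
    write_gmt(db, paths["gene_sets"])
    write_gene_file(universe, paths["enrichment_background"])
    write_edge_list(edges, paths["edges"])
    write_gene_file(background, paths["network_background"])
    return paths
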