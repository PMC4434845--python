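"""Readers and writers for every file the pipeline touches.

File dialects
-------------
All tabular files are strict TSV: UTF-8, tab-separated, no quoting. Gene
identity is the uppercased HGNC-style symbol; symbols are uppercased at read
time and never alias-resolved. Exon files follow the BED convention (0-based,
half-open intervals); variant tables carry 1-based positions. Conversion
between the two conventions happens only where a variant is assigned to an
exon, never at read time.

Every reader is total on the corresponding writer's output (read ∘ write is
the identity on the in-memory object), and readers never silently drop rows:
the only cleaning performed is the documented edge-list dedup/self-loop
removal, which is counted and reported.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "normalize_symbol",
    "DiseaseGeneCatalog",
    "GenomicInterval",
    "VariantRecord",
    "CONSEQUENCES",
    "LOF_CONSEQUENCES",
    "ExpressionMatrix",
    "GeneSetDB",
    "EdgeList",
    "read_gene_lists",
    "write_gene_lists",
    "read_gene_file",
    "write_gene_file",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_exon_bed",
    "write_exon_bed",
    "read_variant_table",
    "write_variant_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_mapping",
    "write_mapping",
]


class FormatError(ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


def normalize_symbol(token: str) -> str:
    """Uppercase a gene symbol token; reject empty or whitespace-bearing ones."""
    token = token.strip()
    if not token:
        raise ValueError("empty gene symbol")
    if any(ch.isspace() for ch in token):
        raise ValueError(f"gene symbol contains whitespace: {token!r}")
    return token.upper()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiseaseGeneCatalog:
    """Named disease → set of (uppercased) gene symbols.

    Disease labels are unique by construction of the mapping; every set must
    be non-empty.
    """

    entries: Mapping[str, frozenset[str]]

    def __post_init__(self):
        for disease, genes in self.entries.items():
            if not genes:
                raise ValueError(f"disease {disease!r} has an empty gene set")

    @property
    def diseases(self) -> list[str]:
        return list(self.entries)

    def genes(self, disease: str) -> frozenset[str]:
        if disease not in self.entries:
            raise KeyError(f"unknown disease {disease!r}; have {sorted(self.entries)}")
        return self.entries[disease]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.entries.values():
            out |= genes
        return frozenset(out)

    def n_distinct_genes(self) -> int:
        return len(self.all_genes())


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """0-based, half-open genomic interval attached to a gene."""

    chrom: str
    start: int
    end: int
    gene: str

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


CONSEQUENCES = frozenset(
    {"missense", "stop_gained", "frameshift", "splice_donor", "splice_acceptor",
     "synonymous", "other"}
)
#: Consequence classes treated as loss of function.
LOF_CONSEQUENCES = frozenset({"stop_gained", "frameshift", "splice_donor", "splice_acceptor"})


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """Single exome variant with a 1-based position and a closed consequence vocabulary."""

    gene: str
    chrom: str
    pos: int
    consequence: str
    allele_frequency: float

    def __post_init__(self):
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"unknown consequence {self.consequence!r}; allowed: {sorted(CONSEQUENCES)}"
            )
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError(f"allele frequency {self.allele_frequency} outside [0, 1]")


class ExpressionMatrix:
    """Non-negative expression values over (transcript|gene) × (sample|tissue).

    Thin wrapper around a pandas DataFrame that also carries the optional
    transcript→gene annotation (``row_to_gene``) and column group labels
    (``col_groups``, e.g. developmental period or "hematopoietic").
    """

    def __init__(
        self,
        values: pd.DataFrame,
        row_to_gene: Mapping[str, str] | None = None,
        col_groups: Mapping[str, str] | None = None,
    ):
        if values.index.has_duplicates:
            raise ValueError("duplicate row identifiers")
        if values.columns.has_duplicates:
            raise ValueError("duplicate column identifiers")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        self.values = values
        if row_to_gene is not None:
            missing = set(values.index) - set(row_to_gene)
            if missing:
                raise ValueError(
                    f"row_to_gene does not cover {len(missing)} rows, e.g. {sorted(missing)[:3]}"
                )
            row_to_gene = {r: normalize_symbol(g) for r, g in row_to_gene.items()}
        self.row_to_gene = dict(row_to_gene) if row_to_gene is not None else None
        self.col_groups = dict(col_groups) if col_groups is not None else None

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ExpressionMatrix)
            and self.values.equals(other.values)
            and self.row_to_gene == other.row_to_gene
            and self.col_groups == other.col_groups
        )


@dataclass(frozen=True)
class GeneSetDB:
    """Pathway name → (source label, gene set)."""

    sets: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self):
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def genes_of(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def source_of(self, name: str) -> str:
        return self.sets[name][0]


@dataclass(frozen=True)
class EdgeList:
    """Cleaned undirected gene–gene pairs.

    Pairs are stored with sorted endpoints, so ``(a, b)`` and ``(b, a)`` have
    one identity. ``n_dropped`` counts self-loops and duplicate (symmetric)
    pairs removed during cleaning.
    """

    pairs: tuple[tuple[str, str], ...]
    weights: tuple[float, ...] | None = None
    n_dropped: int = 0

    def __post_init__(self):
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self pair {a!r} survived cleaning")
        if self.weights is not None and len(self.weights) != len(self.pairs):
            raise ValueError("weights length mismatch")

    def __len__(self) -> int:
        return len(self.pairs)

    @staticmethod
    def from_raw(
        raw: Iterable[tuple[str, str] | tuple[str, str, float]],
    ) -> "EdgeList":
        """Clean raw pairs: uppercase, drop self-loops, collapse symmetric duplicates.

        The first occurrence of an unordered pair wins (its weight, if any,
        is kept); every dropped row is counted.
        """
        seen: dict[tuple[str, str], float | None] = {}
        order: list[tuple[str, str]] = []
        dropped = 0
        any_weight = False
        for row in raw:
            a = normalize_symbol(row[0])
            b = normalize_symbol(row[1])
            w = float(row[2]) if len(row) > 2 else None
            if w is not None:
                any_weight = True
            if a == b:
                dropped += 1
                continue
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                dropped += 1
                continue
            seen[key] = w
            order.append(key)
        weights = tuple(seen[k] if seen[k] is not None else 1.0 for k in order) if any_weight else None
        return EdgeList(pairs=tuple(order), weights=weights, n_dropped=dropped)


# ---------------------------------------------------------------------------
# Line-oriented helpers
# ---------------------------------------------------------------------------


def _iter_lines(path) -> Iterable[tuple[int, str]]:
    text = Path(path).read_text(encoding="utf-8")
    for i, line in enumerate(text.splitlines(), start=1):
        if line.strip() == "":
            continue
        yield i, line


# ---------------------------------------------------------------------------
# Disease gene lists (2-column TSV: disease, gene)
# ---------------------------------------------------------------------------

_GENE_LIST_HEADER = {"disease", "gene"}


def read_gene_lists(path, strict: bool = True) -> DiseaseGeneCatalog:
    """Read a 2-column ``disease<TAB>gene`` TSV into a catalog.

    A header row is auto-detected by the reserved tokens ``disease``/``gene``.
    Symbols are uppercased; duplicates within a disease collapse. With
    ``strict=False`` malformed rows are skipped instead of raising.
    """
    entries: dict[str, set[str]] = {}
    n_rows = 0
    for lineno, line in _iter_lines(path):
        fields = line.split("\t")
        if n_rows == 0 and {f.strip().lower() for f in fields} == _GENE_LIST_HEADER:
            continue
        if len(fields) != 2:
            if strict:
                raise FormatError(
                    f"expected 2 tab-separated columns, found {len(fields)}", path, lineno
                )
            continue
        disease, gene = fields[0].strip(), fields[1]
        try:
            symbol = normalize_symbol(gene)
        except ValueError as exc:
            if strict:
                raise FormatError(str(exc), path, lineno) from exc
            continue
        if not disease:
            if strict:
                raise FormatError("empty disease label", path, lineno)
            continue
        entries.setdefault(disease, set()).add(symbol)
        n_rows += 1
    if not entries:
        raise FormatError("no gene-list rows found", path)
    return DiseaseGeneCatalog({d: frozenset(g) for d, g in entries.items()})


def write_gene_lists(catalog: DiseaseGeneCatalog, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease\tgene\n")
        for disease in sorted(catalog.entries):
            for gene in sorted(catalog.entries[disease]):
                fh.write(f"{disease}\t{gene}\n")


def read_gene_file(path) -> frozenset[str]:
    """Read a plain one-symbol-per-line gene list (e.g. tolerated-LOF genes)."""
    genes: set[str] = set()
    for lineno, line in _iter_lines(path):
        try:
            genes.add(normalize_symbol(line))
        except ValueError as exc:
            raise FormatError(str(exc), path, lineno) from exc
    if not genes:
        raise FormatError("no genes found", path)
    return frozenset(genes)


def write_gene_file(genes: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(genes):
            fh.write(f"{gene}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path) -> GeneSetDB:
    """Read GMT: ``name<TAB>source<TAB>gene...``; duplicate names are an error."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in _iter_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"GMT line needs >=3 tab-separated fields, found {len(fields)}", path, lineno
            )
        name, source = fields[0].strip(), fields[1].strip()
        if not name:
            raise FormatError("empty pathway name", path, lineno)
        if name in sets:
            raise FormatError(f"duplicate pathway name {name!r}", path, lineno)
        try:
            genes = frozenset(normalize_symbol(g) for g in fields[2:])
        except ValueError as exc:
            raise FormatError(str(exc), path, lineno) from exc
        sets[name] = (source, genes)
    if not sets:
        raise FormatError("no gene sets found", path)
    return GeneSetDB(sets)


def write_gmt(db: GeneSetDB, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in db.names():
            source, genes = db.sets[name]
            fh.write("\t".join([name, source, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------


def read_edge_list(path) -> EdgeList:
    """Read a 2/3-column TSV of undirected interactions and clean it.

    Self-loops are dropped and symmetric duplicates collapsed; the number of
    dropped rows is reported on the returned object.
    """
    raw: list[tuple] = []
    for lineno, line in _iter_lines(path):
        fields = line.split("\t")
        if len(fields) not in (2, 3):
            raise FormatError(
                f"expected 2 or 3 tab-separated columns, found {len(fields)}", path, lineno
            )
        if len(fields) == 3:
            try:
                w = float(fields[2])
            except ValueError:
                raise FormatError(f"non-numeric weight {fields[2]!r}", path, lineno) from None
            raw.append((fields[0], fields[1], w))
        else:
            raw.append((fields[0], fields[1]))
    try:
        return EdgeList.from_raw(raw)
    except ValueError as exc:
        raise FormatError(str(exc), path) from exc


def write_edge_list(edges: EdgeList, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, (a, b) in enumerate(edges.pairs):
            if edges.weights is not None:
                fh.write(f"{a}\t{b}\t{edges.weights[i]:g}\n")
            else:
                fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Exon BED (BED4: chrom, start, end, gene) — 0-based half-open
# ---------------------------------------------------------------------------


def read_exon_bed(path) -> list[GenomicInterval]:
    intervals: list[GenomicInterval] = []
    for lineno, line in _iter_lines(path):
        fields = line.split("\t")
        if len(fields) != 4:
            raise FormatError(f"expected 4 BED columns, found {len(fields)}", path, lineno)
        chrom, start_s, end_s, gene = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(f"non-integer coordinates {start_s!r}/{end_s!r}", path, lineno) from None
        try:
            intervals.append(GenomicInterval(chrom.strip(), start, end, normalize_symbol(gene)))
        except ValueError as exc:
            raise FormatError(str(exc), path, lineno) from exc
    if not intervals:
        raise FormatError("no exon intervals found", path)
    return intervals


def write_exon_bed(intervals: Sequence[GenomicInterval], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.gene}\n")


# ---------------------------------------------------------------------------
# Variant tables (TSV with header: gene, chrom, pos, consequence, allele_frequency)
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = ["gene", "chrom", "pos", "consequence", "allele_frequency"]


def read_variant_table(path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    saw_header = False
    for lineno, line in _iter_lines(path):
        fields = line.split("\t")
        if not saw_header:
            if [f.strip().lower() for f in fields] != _VARIANT_COLUMNS:
                raise FormatError(
                    f"expected header {_VARIANT_COLUMNS}, found {fields}", path, lineno
                )
            saw_header = True
            continue
        if len(fields) != 5:
            raise FormatError(f"expected 5 columns, found {len(fields)}", path, lineno)
        gene, chrom, pos_s, consequence, af_s = fields
        try:
            records.append(
                VariantRecord(
                    gene=normalize_symbol(gene),
                    chrom=chrom.strip(),
                    pos=int(pos_s),
                    consequence=consequence.strip(),
                    allele_frequency=float(af_s),
                )
            )
        except ValueError as exc:
            raise FormatError(str(exc), path, lineno) from exc
    if not saw_header:
        raise FormatError("empty variant table", path)
    return records


def write_variant_table(records: Sequence[VariantRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_VARIANT_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.gene}\t{r.chrom}\t{r.pos}\t{r.consequence}\t{r.allele_frequency:.6g}\n")


# ---------------------------------------------------------------------------
# Expression matrices (+ sidecar two-column maps)
# ---------------------------------------------------------------------------


def read_expression_matrix(path, gene_map=None, col_groups=None) -> ExpressionMatrix:
    """Read a TSV matrix (first column = row ids, header = column ids).

    ``gene_map`` and ``col_groups`` are optional paths to two-column TSV
    sidecar files mapping row→gene and column→group label respectively.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, quoting=3)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse matrix: {exc}", path) from exc
    if df.empty:
        raise FormatError("empty expression matrix", path)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric matrix values: {exc}", path) from exc
    row_to_gene = read_mapping(gene_map) if gene_map is not None else None
    groups = read_mapping(col_groups) if col_groups is not None else None
    try:
        return ExpressionMatrix(df, row_to_gene=row_to_gene, col_groups=groups)
    except ValueError as exc:
        raise FormatError(str(exc), path) from exc


def write_expression_matrix(matrix: ExpressionMatrix, path, gene_map=None, col_groups=None) -> None:
    buf = io.StringIO()
    matrix.values.to_csv(buf, sep="\t", index_label="id", float_format="%.8g")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
    if gene_map is not None:
        if matrix.row_to_gene is None:
            raise ValueError("matrix has no row_to_gene annotation to write")
        write_mapping(matrix.row_to_gene, gene_map)
    if col_groups is not None:
        if matrix.col_groups is None:
            raise ValueError("matrix has no col_groups annotation to write")
        write_mapping(matrix.col_groups, col_groups)


def read_mapping(path) -> dict[str, str]:
    """Read a two-column ``key<TAB>value`` TSV into a dict."""
    out: dict[str, str] = {}
    for lineno, line in _iter_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"expected 2 columns, found {len(fields)}", path, lineno)
        key, value = fields[0].strip(), fields[1].strip()
        if key in out:
            raise FormatError(f"duplicate key {key!r}", path, lineno)
        out[key] = value
    if not out:
        raise FormatError("empty mapping file", path)
    return out


def write_mapping(mapping: Mapping[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key in mapping:
            fh.write(f"{key}\t{mapping[key]}\n")
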