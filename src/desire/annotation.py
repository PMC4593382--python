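"""Gene annotation I/O.

Reads GTF or SAF-style gene/exon tables into an exon-union gene model.
Coordinates are kept 1-based inclusive (the GTF convention) throughout;
conversion to 0-based half-open happens only at SAM arithmetic boundaries
in :mod:`desire.counting`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals, so overlaps are not double-counted."""
    ivs = sorted(intervals)
    if not ivs:
        return []
    merged = [list(ivs[0])]
    for start, end in ivs[1:]:
        if start <= merged[-1][1] + 1:  # adjacent intervals coalesce
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


@dataclass(frozen=True)
class GeneModel:
    """A gene as a union of exon intervals on one chromosome.

    Exons are stored merged (pairwise disjoint, sorted), 1-based inclusive.
    ``merged_length_kb`` is the exon-union length L_i in kilobases, the
    denominator of RPKM.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-", "."}:
            raise AnnotationError(
                f"gene {self.gene_id}: invalid strand {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id}: no exons")
        for start, end in self.exons:
            if start < 1 or end < start:
                raise AnnotationError(
                    f"gene {self.gene_id}: bad exon interval ({start}, {end})"
                )

    @property
    def merged_length_bp(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def merged_length_kb(self) -> float:
        return self.merged_length_bp / 1000.0

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class GeneAnnotation:
    """Ordered collection of genes with a gene_id index.

    Ordering follows the annotation file (deterministic re-reads), and the
    gene count G is the size of the expression vectors downstream.
    """

    genes: list[GeneModel]
    gene_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.gene_index = {g.gene_id: i for i, g in enumerate(self.genes)}
        if len(self.gene_index) != len(self.genes):
            seen: set[str] = set()
            for g in self.genes:
                if g.gene_id in seen:
                    raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
                seen.add(g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[self.gene_index[gene_id]]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def lengths_kb(self):
        import numpy as np

        return np.array([g.merged_length_kb for g in self.genes])

    def chrom_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g.chrom, None)
        return list(seen)


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _build_annotation(
    records: Sequence[tuple[str, str, int, int, str]],
) -> GeneAnnotation:
    """Assemble GeneModels from (gene_id, chrom, start, end, strand) records."""
    order: list[str] = []
    by_gene: dict[str, list[tuple[str, int, int, str]]] = {}
    for gene_id, chrom, start, end, strand in records:
        if gene_id not in by_gene:
            order.append(gene_id)
            by_gene[gene_id] = []
        by_gene[gene_id].append((chrom, start, end, strand))

    genes: list[GeneModel] = []
    for gene_id in order:
        recs = by_gene[gene_id]
        chroms = {r[0] for r in recs}
        if len(chroms) > 1:
            raise AnnotationError(
                f"gene {gene_id!r} has exons on multiple chromosomes: "
                f"{sorted(chroms)}"
            )
        strands = {r[3] for r in recs}
        strand = strands.pop() if len(strands) == 1 else "."
        exons = merge_intervals((s, e) for _, s, e, _ in recs)
        genes.append(
            GeneModel(
                gene_id=gene_id, chrom=recs[0][0], strand=strand, exons=tuple(exons)
            )
        )
    if not genes:
        raise AnnotationError("annotation contains zero genes")
    return GeneAnnotation(genes)


def _read_gtf(path: Path) -> GeneAnnotation:
    records: list[tuple[str, str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = (
                fields
            )
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            attr_map = dict(_GTF_ATTR_RE.findall(attrs))
            gene_id = attr_map.get("gene_id")
            if gene_id is None:
                raise AnnotationError(f"{path}:{lineno}: missing gene_id attribute")
            records.append((gene_id, chrom, start, end, strand))
    return _build_annotation(records)


def _read_saf(path: Path) -> GeneAnnotation:
    records: list[tuple[str, str, int, int, str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["GeneID", "Chr", "Start", "End", "Strand"]
        if [h.strip() for h in header[:5]] != expected:
            raise AnnotationError(
                f"{path}:1: SAF header must start with {expected}, got {header[:5]}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise AnnotationError(
                    f"{path}:{lineno}: expected ≥5 tab-separated fields"
                )
            gene_id, chrom, start_s, end_s, strand = fields[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            records.append((gene_id, chrom, start, end, strand))
    return _build_annotation(records)


def read_annotation(path: str | Path, format: str | None = None) -> GeneAnnotation:
    """Read a gene annotation from GTF or SAF-style TSV.

    Parameters
    ----------
    path
        Annotation file. GTF exon records are grouped by their ``gene_id``
        attribute; SAF rows are grouped by the ``GeneID`` column. Exons of
        one gene are merged by interval union so overlapping exons are not
        double-counted in gene length.
    format
        ``"gtf"`` or ``"saf"``. Inferred from the file suffix when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "saf" if path.suffix.lower() in {".saf", ".tsv", ".txt"} else "gtf"
    if format == "gtf":
        return _read_gtf(path)
    if format == "saf":
        return _read_saf(path)
    raise ValueError(f"unknown annotation format {format!r}")


def write_gtf(annotation: GeneAnnotation, path: str | Path) -> None:
    """Write the annotation back out as exon-level GTF."""
    with open(path, "w") as fh:
        for gene in annotation:
            for start, end in gene.exons:
                attrs = f'gene_id "{gene.gene_id}";'
                fh.write(
                    f"{gene.chrom}\tdesire\texon\t{start}\t{end}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )
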