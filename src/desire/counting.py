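"""Gene-level summarization of mapped fragments.

A minimal featureCounts-style counter: each mapped fragment is assigned to
at most one gene by overlap of its aligned blocks with the gene's exon
union. Fragments overlapping two or more genes are handled by an
ambiguity policy (discarded by default), fragments overlapping none are
unassigned. Only primary alignments contribute; counting is unstranded by
default.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from intervaltree import IntervalTree

from desire.annotation import GeneAnnotation
from desire.subsample import _open_alignment

logger = logging.getLogger(__name__)


@dataclass
class CountVector:
    """Integer reads-per-gene vector for one sample, aligned to annotation order.

    ``library_size`` is the sum of gene-assigned counts N_lib = Σ_i N_i.
    """

    sample_id: str
    counts: np.ndarray
    annotation: GeneAnnotation

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.annotation):
            raise ValueError(
                f"count vector length {len(self.counts)} != gene count "
                f"{len(self.annotation)}"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def library_size(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class CountMatrix:
    """G × S integer count matrix c_ij with per-sample condition labels."""

    annotation: GeneAnnotation
    samples: list[str]
    values: np.ndarray
    condition_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.annotation), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} != "
                f"({len(self.annotation)}, {len(self.samples)})"
            )
        if (self.values < 0).any():
            raise ValueError("negative counts")

    @classmethod
    def from_vectors(
        cls,
        vectors: Iterable[CountVector],
        condition_labels: dict[str, str] | None = None,
    ) -> "CountMatrix":
        vectors = list(vectors)
        annotation = vectors[0].annotation
        values = np.column_stack([v.counts for v in vectors])
        return cls(
            annotation=annotation,
            samples=[v.sample_id for v in vectors],
            values=values,
            condition_labels=condition_labels or {},
        )

    def column(self, sample_id: str) -> CountVector:
        j = self.samples.index(sample_id)
        return CountVector(
            sample_id=sample_id,
            counts=self.values[:, j],
            annotation=self.annotation,
        )

    @property
    def library_sizes(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["gene_id"] + self.samples)
            for i, gene_id in enumerate(self.annotation.gene_ids):
                w.writerow([gene_id] + [int(v) for v in self.values[i]])

    @classmethod
    def read_tsv(
        cls, path: str | Path, annotation: GeneAnnotation
    ) -> "CountMatrix":
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            samples = header[1:]
            rows: dict[str, list[int]] = {}
            for row in reader:
                rows[row[0]] = [int(v) for v in row[1:]]
        values = np.array(
            [rows[g] for g in annotation.gene_ids], dtype=np.int64
        ).reshape(len(annotation), len(samples))
        return cls(annotation=annotation, samples=samples, values=values)


@dataclass
class CountingSummary:
    """Fragment bookkeeping: assigned + ambiguous + unassigned = mapped."""

    assigned: int = 0
    ambiguous: int = 0
    unassigned: int = 0

    @property
    def total_mapped(self) -> int:
        return self.assigned + self.ambiguous + self.unassigned


def _exon_trees(annotation: GeneAnnotation) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees of exon-union pieces → gene index.

    Exon intervals convert from 1-based inclusive to 0-based half-open here,
    at the SAM arithmetic boundary.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, gene in enumerate(annotation):
        tree = trees.setdefault(gene.chrom, IntervalTree())
        for start, end in gene.exons:
            tree.addi(start - 1, end, idx)
    return trees


def _fragment_gene_overlaps(
    blocks: list[tuple[str, int, int]], trees: dict[str, IntervalTree]
) -> dict[int, int]:
    """Bases of overlap between a fragment's aligned blocks and each gene."""
    overlaps: dict[int, int] = {}
    for chrom, bstart, bend in blocks:
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.overlap(bstart, bend):
            bases = min(bend, iv.end) - max(bstart, iv.begin)
            if bases > 0:
                overlaps[iv.data] = overlaps.get(iv.data, 0) + bases
    return overlaps


def count_fragments(
    alignments: str | Path,
    annotation: GeneAnnotation,
    min_overlap: int = 1,
    ambiguous_policy: str = "discard",
    sample_id: str | None = None,
    return_summary: bool = False,
) -> CountVector | tuple[CountVector, CountingSummary]:
    """Summarize a SAM/BAM into gene-level counts.

    A fragment whose aligned blocks overlap the exon union of exactly one
    gene by at least ``min_overlap`` bases increments that gene. Gapped
    alignments contribute their aligned blocks (CIGAR M/=/X segments), not
    the full reference span, so spliced reads are not counted against
    intronic genes. Fragments hitting ≥2 genes follow ``ambiguous_policy``:
    ``"discard"`` (default) counts neither, ``"count_all"`` counts every
    gene hit. Records on chromosomes absent from the annotation are
    unassigned, not errors.
    """
    if ambiguous_policy not in {"discard", "count_all"}:
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    alignments = Path(alignments)
    if sample_id is None:
        sample_id = alignments.stem
    trees = _exon_trees(annotation)

    # Group aligned blocks by fragment (read name); mates pool their blocks.
    fragment_blocks: dict[str, list[tuple[str, int, int]]] = {}
    with _open_alignment(alignments) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            blocks = fragment_blocks.setdefault(rec.query_name, [])
            chrom = rec.reference_name
            for bstart, bend in rec.get_blocks():
                blocks.append((chrom, bstart, bend))

    counts = np.zeros(len(annotation), dtype=np.int64)
    summary = CountingSummary()
    for blocks in fragment_blocks.values():
        overlaps = _fragment_gene_overlaps(blocks, trees)
        hits = [g for g, bases in overlaps.items() if bases >= min_overlap]
        if len(hits) == 1:
            counts[hits[0]] += 1
            summary.assigned += 1
        elif len(hits) > 1:
            summary.ambiguous += 1
            if ambiguous_policy == "count_all":
                for g in hits:
                    counts[g] += 1
        else:
            summary.unassigned += 1
    if summary.unassigned:
        logger.info(
            "%s: %d mapped fragments unassigned to any gene",
            sample_id,
            summary.unassigned,
        )
    vector = CountVector(sample_id=sample_id, counts=counts, annotation=annotation)
    if return_summary:
        return vector, summary
    return vector
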