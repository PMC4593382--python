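"""Shared fixtures: hand-built annotations and SAM files, small simulations."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from desire.annotation import GeneAnnotation, GeneModel, read_annotation
from desire.simulate import SimulationConfig, simulate_annotation, simulate_reads


def write_sam(
    path: Path,
    chrom_lengths: dict[str, int],
    reads: list[tuple],
) -> Path:
    """Write a minimal single-end SAM.

    ``reads`` entries are (name, chrom, pos1, cigar) for mapped records or
    (name, None) for unmapped ones.
    """
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom, length in chrom_lengths.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")
    for read in reads:
        if read[1] is None:
            name = read[0]
            lines.append(f"{name}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*")
        else:
            name, chrom, pos1, cigar = read
            lines.append(
                f"{name}\t0\t{chrom}\t{pos1}\t60\t{cigar}\t*\t0\t0\t*\t*"
            )
    path.write_text("\n".join(lines) + "\n")
    return path


THREE_GENE_GTF = """\
chr1\ttest\texon\t101\t300\t.\t+\t.\tgene_id "geneA";
chr1\ttest\texon\t251\t400\t.\t+\t.\tgene_id "geneA";
chr1\ttest\texon\t1001\t1500\t.\t-\t.\tgene_id "geneB";
chr2\ttest\texon\t501\t900\t.\t+\t.\tgene_id "geneC";
chr2\ttest\texon\t1101\t1300\t.\t+\t.\tgene_id "geneC";
"""


@pytest.fixture
def three_gene_annotation(tmp_path: Path) -> GeneAnnotation:
    gtf = tmp_path / "three.gtf"
    gtf.write_text(THREE_GENE_GTF)
    return read_annotation(gtf)


@pytest.fixture
def flat_annotation() -> GeneAnnotation:
    """Single-exon genes of identical 1 kb length, convenient for arithmetic."""
    genes = [
        GeneModel(f"g{i}", "chr1", "+", ((i * 3000 + 1, i * 3000 + 1000),))
        for i in range(5)
    ]
    return GeneAnnotation(genes)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory) -> dict:
    """A clean (noise-free) simulated sample reused across tests."""
    d = tmp_path_factory.mktemp("smallsim")
    config = SimulationConfig(
        n_genes=40, library_size=3000, n_chroms=2, noise_fraction=0.0, seed=11
    )
    annotation = simulate_annotation(config, d / "ann.gtf")
    truth = simulate_reads(annotation, config, d / "sample.sam", "sample")
    return {
        "dir": d,
        "config": config,
        "annotation": annotation,
        "gtf": d / "ann.gtf",
        "sam": d / "sample.sam",
        "truth": truth,
    }


def brute_force_counts(
    annotation: GeneAnnotation,
    fragments: dict[str, list[tuple[str, int, int]]],
    min_overlap: int = 1,
    ambiguous_policy: str = "discard",
) -> np.ndarray:
    """Per-fragment interval-overlap counting oracle by explicit base sets.

    ``fragments`` maps fragment name to aligned blocks as (chrom, start1,
    end1) 1-based inclusive intervals.
    """
    gene_bases = []
    for gene in annotation:
        bases = set()
        for s, e in gene.exons:
            bases.update((gene.chrom, p) for p in range(s, e + 1))
        gene_bases.append(bases)
    counts = np.zeros(len(annotation), dtype=int)
    for blocks in fragments.values():
        frag_bases = set()
        for chrom, s, e in blocks:
            frag_bases.update((chrom, p) for p in range(s, e + 1))
        hits = [
            gi
            for gi, gb in enumerate(gene_bases)
            if len(frag_bases & gb) >= min_overlap
        ]
        if len(hits) == 1:
            counts[hits[0]] += 1
        elif len(hits) > 1 and ambiguous_policy == "count_all":
            for gi in hits:
                counts[gi] += 1
    return counts
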