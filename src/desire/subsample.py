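"""DESIRE subsampling of aligned reads.

Draws a fraction f of the fragments of an aligned sample, without
replacement, R times per depth — an m-out-of-n bootstrap on the alignment
file. Each draw produces a new SAM/BAM that simulates a sequencing
experiment at reduced depth; f refers to all reads of the library, not to
the reads of a single gene, which is what makes the surrogate datasets
behave like real lower-depth runs.

The sampling unit is the fragment (read name): all alignment records of a
selected fragment, both mates of a pair included, travel together into the
output. The number drawn is round(f·N) with round-half-even, and the
selection depends only on the fragment set, the fraction and the seed —
never on record order in the file.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

DEFAULT_DEPTH_GRID: tuple[float, ...] = (
    0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
)


def _open_alignment(path: str | Path, mode: str = "r") -> pysam.AlignmentFile:
    path = Path(path)
    read_mode = "rb" if path.suffix == ".bam" else "r"
    return pysam.AlignmentFile(str(path), read_mode, check_sq=False)


@dataclass
class AlignmentSet:
    """The fragment population of one aligned sample.

    ``fragment_ids`` lists distinct read names in file order; ``n_mapped``
    counts fragments with at least one mapped alignment record.
    """

    source: Path
    fragment_ids: list[str]
    n_mapped: int

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_ids)


def load_alignment_set(path: str | Path) -> AlignmentSet:
    """Scan a SAM/BAM and enumerate its fragments."""
    path = Path(path)
    seen: dict[str, bool] = {}
    with _open_alignment(path) as fh:
        for rec in fh:
            mapped = not rec.is_unmapped
            if rec.query_name in seen:
                seen[rec.query_name] = seen[rec.query_name] or mapped
            else:
                seen[rec.query_name] = mapped
    return AlignmentSet(
        source=path,
        fragment_ids=list(seen),
        n_mapped=sum(seen.values()),
    )


@dataclass
class SubsampleSpec:
    """Replication plan for one sample: depth grid × R replicates."""

    depth_grid: Sequence[float] = DEFAULT_DEPTH_GRID
    replicates: int = 24
    base_seed: int = 0

    def __post_init__(self) -> None:
        for f in self.depth_grid:
            if not 0 < f <= 1:
                raise ValueError(f"depth fraction {f} outside (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def select_fragments(
    fragment_ids: Sequence[str], fraction: float, seed: int
) -> set[str]:
    """Choose round(f·N) fragments uniformly without replacement.

    Fragment ids are sorted before drawing so the selection is a function
    of the fragment *set*, not of file ordering.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    ordered = sorted(fragment_ids)
    n = len(ordered)
    k = round(fraction * n)  # round-half-even
    if fraction == 1.0:
        return set(ordered)  # degenerate draw-all
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=k, replace=False)
    return {ordered[i] for i in chosen}


def subsample_alignments(
    alignments: AlignmentSet | str | Path,
    fraction: float,
    seed: int,
    out: str | Path,
) -> AlignmentSet:
    """Write one subsampled replicate of an aligned sample.

    All records whose fragment was selected are copied to ``out`` with the
    header preserved verbatim. ``fraction=1.0`` reproduces the input
    fragment set exactly.
    """
    if not isinstance(alignments, AlignmentSet):
        alignments = load_alignment_set(alignments)
    selected = select_fragments(alignments.fragment_ids, fraction, seed)
    out = Path(out)
    write_mode = "wb" if out.suffix == ".bam" else "wh"
    with _open_alignment(alignments.source) as src:
        with pysam.AlignmentFile(str(out), write_mode, template=src) as dst:
            for rec in src:
                if rec.query_name in selected:
                    dst.write(rec)
    return load_alignment_set(out)


@dataclass
class ReplicateRecord:
    sample: str
    fraction: float
    replicate: int
    seed: int
    path: Path
    n_fragments: int


@dataclass
class Manifest:
    """Audit trail of a replicate-generation run, serializable as TSV."""

    records: list[ReplicateRecord] = field(default_factory=list)

    COLUMNS = ("sample", "fraction", "replicate", "seed", "path", "n_fragments")

    def __len__(self) -> int:
        return len(self.records)

    def paths(self) -> list[Path]:
        return [r.path for r in self.records]

    def subset(self, fraction: float | None = None) -> list[ReplicateRecord]:
        return [
            r
            for r in self.records
            if fraction is None or r.fraction == fraction
        ]

    def write(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(self.COLUMNS)
            for r in self.records:
                w.writerow(
                    [r.sample, r.fraction, r.replicate, r.seed, r.path,
                     r.n_fragments]
                )

    @classmethod
    def read(cls, path: str | Path) -> "Manifest":
        records = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                records.append(
                    ReplicateRecord(
                        sample=row["sample"],
                        fraction=float(row["fraction"]),
                        replicate=int(row["replicate"]),
                        seed=int(row["seed"]),
                        path=Path(row["path"]),
                        n_fragments=int(row["n_fragments"]),
                    )
                )
        return cls(records)


def generate_replicates(
    alignments: AlignmentSet | str | Path,
    spec: SubsampleSpec,
    out_dir: str | Path,
    sample_id: str | None = None,
    overwrite: bool = False,
) -> Manifest:
    """Run the full DESIRE plan: |depth_grid| × R subsampled files.

    Replicate r at any depth uses seed ``base_seed + r``; the manifest
    records every (fraction, replicate, seed, path, fragment count) so the
    run is reproducible and auditable. With the default 10-depth grid and
    R = 24 this produces 240 subsampled datasets per sample.
    """
    if not isinstance(alignments, AlignmentSet):
        alignments = load_alignment_set(alignments)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if sample_id is None:
        sample_id = alignments.source.stem
    manifest_path = out_dir / f"{sample_id}.manifest.tsv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"manifest {manifest_path} exists; pass overwrite=True to replace"
        )
    manifest = Manifest()
    for fraction in spec.depth_grid:
        for rep in range(spec.replicates):
            seed = spec.base_seed + rep
            out = out_dir / f"{sample_id}_f{fraction:g}_r{rep}.sam"
            sub = subsample_alignments(alignments, fraction, seed, out)
            manifest.records.append(
                ReplicateRecord(
                    sample=sample_id,
                    fraction=fraction,
                    replicate=rep,
                    seed=seed,
                    path=out,
                    n_fragments=sub.n_fragments,
                )
            )
    manifest.write(manifest_path)
    return manifest
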