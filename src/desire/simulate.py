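"""Synthetic aligned RNA-seq data with known ground truth.

Generates a small artificial genome annotation, per-gene expression
profiles with negative-binomial-style overdispersion, and single-end
aligned reads written as SAM, so the full subsampling pipeline runs
without any external data. The generator emulates the structure of real
bulk RNA-seq samples — a log-normal spread of expression across genes,
gamma–Poisson (negative binomial) count noise, a fraction of reads
falling outside annotated genes — at a genome and library scale small
enough to iterate on.

Per-gene counts are produced by modulating a log-normal expression
profile with per-gene gamma noise of variance ``nb_dispersion`` (so the
marginal count law is negative binomial) and then drawing a multinomial
conditioned on the configured library size, which fixes the total
fragment count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pysam
import yaml

from desire.annotation import GeneAnnotation, GeneModel, write_gtf
from desire.counting import CountVector


@dataclass
class SimulationConfig:
    """Ground-truth parameters of one synthetic experiment.

    ``nb_mean_distribution`` gives the (mu, sigma) of the log-normal that
    spreads expected expression across genes; ``nb_dispersion`` is the
    extra-Poisson dispersion α in Var = μ + αμ². ``group_effect``
    multiplies the across-gene variance of the expression profile in the
    second phenotype group while preserving its mean, mimicking a disease
    state that narrows (or widens) the expression distribution.
    """

    n_genes: int = 200
    gene_length_range: tuple[float, float] = (0.5, 3.0)  # kb
    n_chroms: int = 3
    library_size: int = 50_000
    nb_mean_distribution: tuple[float, float] = (1.0, 1.5)  # lognormal mu, sigma
    nb_dispersion: float = 0.2
    group_effect: float = 1.0
    noise_fraction: float = 0.05
    read_length: int = 75
    min_gene_gap: int = 300  # bp between genes; > read_length so reads never bleed over
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_chroms < 1 or self.library_size < 0:
            raise ValueError("n_genes, n_chroms positive; library_size >= 0")
        if not 0 <= self.noise_fraction < 1:
            raise ValueError("noise_fraction must be in [0, 1)")
        if self.gene_length_range[0] <= 0:
            raise ValueError("gene lengths must be positive")
        if self.min_gene_gap <= self.read_length:
            raise ValueError("min_gene_gap must exceed read_length")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["gene_length_range"] = list(d["gene_length_range"])
        d["nb_mean_distribution"] = list(d["nb_mean_distribution"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["gene_length_range"] = tuple(d["gene_length_range"])
        d["nb_mean_distribution"] = tuple(d["nb_mean_distribution"])
        return cls(**d)


def simulate_annotation(
    config: SimulationConfig, gtf_out: str | Path | None = None
) -> GeneAnnotation:
    """Place non-overlapping genes with 1–3 exons on ``n_chroms`` chromosomes.

    Genes are laid out left to right with at least ``min_gene_gap`` bases
    between them and assigned to chromosomes round-robin; the layout is a
    pure function of the seed.
    """
    rng = np.random.default_rng(config.seed)
    lo_bp = int(config.gene_length_range[0] * 1000)
    hi_bp = int(config.gene_length_range[1] * 1000)
    cursor = {f"chrS{c + 1}": 1000 for c in range(config.n_chroms)}
    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        chrom = f"chrS{(i % config.n_chroms) + 1}"
        total_len = int(rng.integers(lo_bp, hi_bp + 1))
        n_exons = int(rng.integers(1, 4))
        # split total exon length into n_exons positive pieces
        cuts = np.sort(rng.choice(np.arange(1, total_len), size=n_exons - 1, replace=False)) if n_exons > 1 else np.array([], dtype=int)
        pieces = np.diff(np.concatenate(([0], cuts, [total_len])))
        start = cursor[chrom] + int(rng.integers(0, 200))
        exons = []
        pos = start
        for j, piece in enumerate(pieces):
            exons.append((pos, pos + int(piece) - 1))
            pos += int(piece)
            if j < len(pieces) - 1:
                pos += int(rng.integers(100, 501))  # intron
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"G{i + 1:05d}",
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
            )
        )
        cursor[chrom] = exons[-1][1] + config.min_gene_gap
    annotation = GeneAnnotation(genes)
    if gtf_out is not None:
        write_gtf(annotation, gtf_out)
    return annotation


def chrom_lengths(annotation: GeneAnnotation, margin: int = 2000) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for gene in annotation:
        lengths[gene.chrom] = max(lengths.get(gene.chrom, 0), gene.end + margin)
    return lengths


def draw_gene_weights(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Log-normal expected expression per gene (arbitrary units)."""
    mu, sigma = config.nb_mean_distribution
    return rng.lognormal(mean=mu, sigma=sigma, size=config.n_genes)


def shrink_variance(weights: np.ndarray, effect: float) -> np.ndarray:
    """Scale the across-gene variance of a profile by ``effect``, mean fixed.

    w → w̄ + sqrt(effect)·(w − w̄); results are clipped at zero for
    effect > 1 where the affine map could turn small weights negative.
    """
    wbar = weights.mean()
    return np.clip(wbar + np.sqrt(effect) * (weights - wbar), 0.0, None)


def draw_true_counts(
    config: SimulationConfig,
    rng: np.random.Generator,
    gene_weights: np.ndarray,
    n_reads: int,
) -> np.ndarray:
    """Gamma–Poisson counts conditioned on the total ``n_reads``."""
    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = gene_weights * rng.gamma(shape, scale=1.0 / shape, size=len(gene_weights))
    else:
        lam = gene_weights.astype(float)
    if lam.sum() == 0:
        raise ValueError("all gene weights are zero")
    return rng.multinomial(n_reads, lam / lam.sum())


def _intergenic_intervals(
    annotation: GeneAnnotation, lengths: dict[str, int], buffer: int
) -> list[tuple[str, int, int]]:
    """1-based intervals at least ``buffer`` bases from any gene span."""
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}
    for gene in annotation:
        by_chrom[gene.chrom].append((gene.start, gene.end))
    out = []
    for chrom, spans in by_chrom.items():
        spans.sort()
        prev_end = 0
        for s, e in spans:
            lo, hi = prev_end + buffer + 1, s - buffer - 1
            if hi - lo >= buffer:
                out.append((chrom, lo, hi))
            prev_end = e
        lo, hi = prev_end + buffer + 1, lengths[chrom] - buffer
        if hi - lo >= buffer:
            out.append((chrom, lo, hi))
    return out


def _write_sam(
    path: Path,
    lengths: dict[str, int],
    reads: list[tuple[str, str, int]],
    read_length: int,
) -> None:
    """Write single-end 75M-style records; sequences are placeholder bases."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": n} for c, n in lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for name, chrom, pos0 in reads:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = name
            rec.flag = 0
            rec.reference_id = fh.header.references.index(chrom)
            rec.reference_start = pos0
            rec.mapping_quality = 60
            rec.cigartuples = [(0, read_length)]
            rec.query_sequence = "A" * read_length
            fh.write(rec)


def simulate_reads(
    annotation: GeneAnnotation,
    config: SimulationConfig,
    out_sam: str | Path,
    sample_id: str = "sample",
    rng: np.random.Generator | None = None,
    gene_weights: np.ndarray | None = None,
) -> CountVector:
    """Write an aligned synthetic sample as SAM; return the true counts.

    Exactly ``library_size`` single-end reads are emitted:
    round(noise_fraction · library_size) land in intergenic space, the rest
    inside gene exon unions (uniform over exonic positions), so the true
    per-gene count vector is returned for oracle checks and, at
    noise_fraction = 0 with unambiguous genes, equals what the counter
    recovers from the file.
    """
    if config.library_size == 0:
        raise ValueError("library_size must be positive to simulate reads")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if gene_weights is None:
        gene_weights = draw_gene_weights(config, rng)
    lengths = chrom_lengths(annotation)
    n_noise = round(config.noise_fraction * config.library_size)
    n_gene_reads = config.library_size - n_noise
    true_counts = draw_true_counts(config, rng, gene_weights, n_gene_reads)

    reads: list[tuple[str, str, int]] = []
    read_no = 0
    for gi, gene in enumerate(annotation):
        c = int(true_counts[gi])
        if c == 0:
            continue
        # cumulative exon-union coordinates → uniform position within exons
        exon_starts = np.array([s for s, _ in gene.exons])
        exon_lens = np.array([e - s + 1 for s, e in gene.exons])
        cum = np.concatenate(([0], np.cumsum(exon_lens)))
        offsets = rng.integers(0, exon_lens.sum(), size=c)
        for off in offsets:
            k = int(np.searchsorted(cum, off, side="right") - 1)
            pos1 = int(exon_starts[k] + (off - cum[k]))  # 1-based
            reads.append((f"{sample_id}:r{read_no:07d}", gene.chrom, pos1 - 1))
            read_no += 1
    if n_noise:
        intergenic = _intergenic_intervals(annotation, lengths, config.read_length)
        if not intergenic:
            raise ValueError("no intergenic space available for noise reads")
        span_lens = np.array([hi - lo + 1 for _, lo, hi in intergenic])
        picks = rng.choice(len(intergenic), size=n_noise, p=span_lens / span_lens.sum())
        for k in picks:
            chrom, lo, hi = intergenic[int(k)]
            pos1 = int(rng.integers(lo, hi + 1))
            reads.append((f"{sample_id}:r{read_no:07d}", chrom, pos1 - 1))
            read_no += 1

    _write_sam(Path(out_sam), lengths, reads, config.read_length)
    return CountVector(
        sample_id=sample_id, counts=true_counts, annotation=annotation
    )


@dataclass
class CohortSample:
    sample_id: str
    group: str
    path: Path
    true_counts: CountVector


@dataclass
class Cohort:
    """Two synthetic phenotype groups with recorded ground truth."""

    annotation: GeneAnnotation
    samples: list[CohortSample] = field(default_factory=list)
    group_weights: dict[str, np.ndarray] = field(default_factory=dict)

    def group_paths(self, group: str) -> list[Path]:
        return [s.path for s in self.samples if s.group == group]

    @property
    def labels(self) -> dict[str, str]:
        return {s.sample_id: s.group for s in self.samples}


def simulate_cohort(
    config: SimulationConfig,
    n_per_group: int,
    out_dir: str | Path,
    group_names: tuple[str, str] = ("groupA", "groupB"),
) -> Cohort:
    """Simulate two phenotype groups of aligned samples.

    Both groups share one log-normal expression profile; the second
    group's profile has its across-gene variance multiplied by
    ``config.group_effect`` (mean preserved), so with group_effect < 1 the
    second group's expression distribution is narrower — the higher-moment
    signal the moment comparison is meant to detect. Samples draw
    independent negative-binomial noise around their group profile.
    """
    if n_per_group < 2:
        raise ValueError("need n_per_group >= 2 for group comparisons")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    base_rng = np.random.default_rng(ss.spawn(1)[0])
    annotation = simulate_annotation(config, gtf_out=out_dir / "annotation.gtf")
    base_weights = draw_gene_weights(config, base_rng)
    group_weights = {
        group_names[0]: base_weights,
        group_names[1]: shrink_variance(base_weights, config.group_effect),
    }
    cohort = Cohort(annotation=annotation, group_weights=group_weights)
    sample_seeds = ss.spawn(2 * n_per_group + 1)[1:]
    k = 0
    for group in group_names:
        for j in range(n_per_group):
            sid = f"{group}_s{j + 1}"
            path = out_dir / f"{sid}.sam"
            truth = simulate_reads(
                annotation,
                config,
                path,
                sample_id=sid,
                rng=np.random.default_rng(sample_seeds[k]),
                gene_weights=group_weights[group],
            )
            cohort.samples.append(
                CohortSample(sample_id=sid, group=group, path=path, true_counts=truth)
            )
            k += 1
    return cohort
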