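"""Count normalization: CPM, RPKM, and the direct-scaling contrast.

CPM for gene i is c_i = N_i × 10⁶ / N_lib; RPKM additionally divides by
the exon-union gene length L_i in kilobases. Direct scaling multiplies a
count matrix elementwise by a depth fraction f — the computational
shortcut that subsampling of reads is compared against: after CPM the
scaling is invisible (cpm(f·X) = cpm(X)), which is precisely why
threshold-based expressed-gene counts distinguish the two approaches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from desire.annotation import GeneAnnotation
from desire.counting import CountMatrix, CountVector


@dataclass
class NormalizedVector:
    """Real-valued expression vector in CPM, RPKM or raw units."""

    sample_id: str
    values: np.ndarray
    method: str  # {"cpm", "rpkm", "raw"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.method not in {"cpm", "rpkm", "raw"}:
            raise ValueError(f"unknown normalization method {self.method!r}")


def cpm(counts: CountVector) -> NormalizedVector:
    """Counts per million: values_i = counts_i × 10⁶ / library_size.

    The CPM vector sums to 10⁶ exactly (up to float round-off), so its
    mean over the full annotation is 10⁶/G regardless of depth.
    """
    n_lib = counts.library_size
    if n_lib == 0:
        raise ValueError(f"sample {counts.sample_id}: empty library (N_lib = 0)")
    return NormalizedVector(
        sample_id=counts.sample_id,
        values=counts.counts * 1e6 / n_lib,
        method="cpm",
    )


def rpkm(counts: CountVector, annotation: GeneAnnotation | None = None) -> NormalizedVector:
    """Reads per kilobase per million: counts_i × 10⁶ / (N_lib × L_i)."""
    if annotation is None:
        annotation = counts.annotation
    n_lib = counts.library_size
    if n_lib == 0:
        raise ValueError(f"sample {counts.sample_id}: empty library (N_lib = 0)")
    lengths_kb = annotation.lengths_kb
    if (lengths_kb <= 0).any():
        raise ValueError("annotation contains genes of zero length")
    return NormalizedVector(
        sample_id=counts.sample_id,
        values=counts.counts * 1e6 / (n_lib * lengths_kb),
        method="rpkm",
    )


@dataclass
class ScaledMatrix:
    """Real-valued count-matrix scaled by a depth fraction f.

    Mirrors CountMatrix's shape but holds reals: Σ scaled / Σ raw = f
    exactly when rounding is "none".
    """

    annotation: GeneAnnotation
    samples: list[str]
    values: np.ndarray
    fraction: float

    def column_values(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.samples.index(sample_id)]


def scale_count_matrix(
    matrix: CountMatrix, fraction: float, rounding: str = "none"
) -> ScaledMatrix:
    """Multiply every entry of a count matrix by ``fraction``.

    ``rounding="nearest"`` rounds entries back to integers; the default
    keeps reals so the total-count ratio equals f to machine precision.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    if rounding not in {"none", "nearest"}:
        raise ValueError(f"unknown rounding {rounding!r}")
    values = matrix.values * float(fraction)
    if rounding == "nearest":
        values = np.rint(values)
    return ScaledMatrix(
        annotation=matrix.annotation,
        samples=list(matrix.samples),
        values=values,
        fraction=fraction,
    )
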