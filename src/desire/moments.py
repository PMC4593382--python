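"""Moments of the per-sample expression distribution and their comparison.

The distribution studied here is the distribution of expression values
over all genes *within* one sample (not the count distribution of a gene
across samples). Its first four moments — mean, variance, skewness,
kurtosis — summarize the distributional shape; comparing them between
phenotype groups can detect signal that a mean-based comparison misses,
because disease may change the spread and the tails of the expression
distribution while leaving the mean untouched (for CPM the mean over the
full annotation is pinned at 10⁶/G by construction).

Conventions: variance is unbiased (n−1); skewness is m₃/m₂^{3/2} and
kurtosis the plain (non-excess) m₄/m₂², both with central moments m_k
computed with 1/n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from desire.counting import CountVector
from desire.normalize import NormalizedVector
from desire.saturation import _ttest_three

logger = logging.getLogger(__name__)

MOMENT_NAMES = ("mean", "variance", "skewness", "kurtosis")


@dataclass
class MomentSummary:
    """First four moments of one sample's expression distribution.

    ``skewness`` and ``kurtosis`` are ``None`` (undefined) when all values
    are identical; variance is then exactly 0.
    """

    sample_id: str
    mean: float
    variance: float
    skewness: float | None
    kurtosis: float | None
    normalization: str = "raw"
    fraction: float | None = None
    replicate: int | None = None
    filter_theta: int | None = None

    def moment(self, name: str) -> float | None:
        return getattr(self, name)

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "fraction": self.fraction,
            "replicate": self.replicate,
            "normalization": self.normalization,
            "filter_theta": self.filter_theta,
            "mean": self.mean,
            "variance": self.variance,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
        }


def distribution_moments(
    values: NormalizedVector | CountVector | np.ndarray,
    filter_theta: int | None = None,
    raw_counts: np.ndarray | None = None,
    sample_id: str | None = None,
    fraction: float | None = None,
    replicate: int | None = None,
) -> MomentSummary:
    """Mean, variance, skewness and kurtosis over the genes of one sample.

    ``filter_theta`` keeps only genes whose *raw* count meets the
    expression threshold before the moments are taken; for normalized
    input, supply the matching raw counts via ``raw_counts``. By default
    the full annotation vector (zeros included) enters the moments.
    """
    if isinstance(values, NormalizedVector):
        x = values.values
        normalization = values.method
        sid = sample_id or values.sample_id
    elif isinstance(values, CountVector):
        x = values.counts.astype(float)
        normalization = "raw"
        sid = sample_id or values.sample_id
        if raw_counts is None:
            raw_counts = values.counts
    else:
        x = np.asarray(values, dtype=float)
        normalization = "raw"
        sid = sample_id or "sample"

    if filter_theta is not None:
        if raw_counts is None:
            raise ValueError(
                "filter_theta on normalized values requires raw_counts"
            )
        x = x[np.asarray(raw_counts) >= filter_theta]
    if len(x) < 2:
        raise ValueError("need >= 2 values to compute distribution moments")

    mean = float(np.mean(x))
    variance = float(np.var(x, ddof=1))
    if np.all(x == x[0]):
        skewness: float | None = None
        kurtosis: float | None = None
    else:
        skewness = float(stats.skew(x, bias=True))
        kurtosis = float(stats.kurtosis(x, fisher=False, bias=True))
    return MomentSummary(
        sample_id=sid,
        mean=mean,
        variance=variance,
        skewness=skewness,
        kurtosis=kurtosis,
        normalization=normalization,
        fraction=fraction,
        replicate=replicate,
        filter_theta=filter_theta,
    )


def moments_table(summaries: Iterable[MomentSummary]) -> pd.DataFrame:
    """Per-depth mean (SD) table of the four moments across replicates."""
    df = pd.DataFrame([s.as_dict() for s in summaries])
    rows = []
    for frac, grp in df.groupby("fraction", dropna=False):
        row = {"depth": frac}
        for m in MOMENT_NAMES:
            vals = grp[m].dropna().astype(float)
            row[f"{m}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{m}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def _pooled_medians(
    summaries: Sequence[MomentSummary], moment: str
) -> np.ndarray:
    """Per-depth medians across replicates — the pooled test samples."""
    rows = [
        {"fraction": s.fraction, "value": s.moment(moment)}
        for s in summaries
        if s.moment(moment) is not None
    ]
    if not rows:
        return np.array([])
    return pd.DataFrame(rows).groupby("fraction")["value"].median().to_numpy()


def compare_moments(
    group_a: Sequence[MomentSummary],
    group_b: Sequence[MomentSummary],
    pool_across_depths: bool = True,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sample t-tests per moment between two phenotype groups.

    With ``pool_across_depths`` (default) the test samples are the
    per-depth medians across replicates, pooled over the depth grid, so a
    9-depth grid gives n = 9 observations per condition and moment. With
    pooling off, every summary's value enters directly. Reports two-sided,
    left-sided (A < B) and right-sided p-values per moment. When both
    groups are degenerate with zero variance, p = 1 by convention.
    """
    rows = []
    for m in MOMENT_NAMES:
        if pool_across_depths:
            va = _pooled_medians(group_a, m)
            vb = _pooled_medians(group_b, m)
        else:
            va = np.array(
                [s.moment(m) for s in group_a if s.moment(m) is not None]
            )
            vb = np.array(
                [s.moment(m) for s in group_b if s.moment(m) is not None]
            )
        if len(va) < 2 or len(vb) < 2:
            # moments undefined on degenerate (constant) data: p = 1 by
            # convention rather than an error, so tables stay complete
            logger.warning(
                "moment %s degenerate (<2 defined observations in a group); "
                "p = 1 by convention", m,
            )
            two, left, right = 1.0, 1.0, 1.0
        else:
            two, left, right = _ttest_three(va, vb, equal_var)
        rows.append(
            {
                "moment": m,
                "p_two_sided": two,
                "p_left_sided": left,
                "p_right_sided": right,
            }
        )
    return pd.DataFrame(rows)
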