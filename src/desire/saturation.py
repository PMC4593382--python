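"""Expressed-gene saturation analysis.

The number of expressed genes — genes with raw count c_ij ≥ θ — grows
with sequencing depth. Tracking that number over the DESIRE depth grid
gives a saturation curve per sample and threshold; a Gompertz growth
function f(x) = a·exp(−b·exp(−c·x)) is fitted to the curve because the
number of genes of an organism is bounded above, and its rate parameter c
summarizes how fast the curve approaches the asymptote a. Whether any
curve has flattened at full depth drives two simple optimal-depth
estimators, and two-sample t-tests compare expressed-gene medians and
growth rates between phenotype groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from desire.annotation import GeneAnnotation
from desire.counting import CountMatrix, CountVector, count_fragments
from desire.normalize import scale_count_matrix
from desire.subsample import Manifest

DEFAULT_THETA_GRID: tuple[int, ...] = (1, 10, 50, 100)


def expressed_gene_count(counts: CountVector | np.ndarray, theta: int) -> int:
    """Number of genes with raw count ≥ θ."""
    if theta < 1:
        raise ValueError(f"theta must be >= 1, got {theta}")
    values = counts.counts if isinstance(counts, CountVector) else np.asarray(counts)
    return int((values >= theta).sum())


@dataclass
class SaturationCurve:
    """Expressed-gene counts over the depth grid for one (sample, θ).

    ``points`` holds one (fraction, replicate, expressed_gene_count) triple
    per subsampled dataset; ``method`` records whether the depths came from
    read subsampling ("desire") or direct count scaling ("scaled").
    """

    sample_id: str
    theta: int
    points: list[tuple[float, int, int]]
    method: str = "desire"

    def fractions(self) -> list[float]:
        return sorted({p[0] for p in self.points})

    def counts_at(self, fraction: float) -> np.ndarray:
        return np.array([c for f, _, c in self.points if f == fraction])

    def median_at(self, fraction: float) -> float:
        return float(np.median(self.counts_at(fraction)))

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        pts = sorted(self.points)
        return (
            np.array([p[0] for p in pts], dtype=float),
            np.array([p[2] for p in pts], dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.points, columns=["fraction", "replicate", "expressed_genes"]
        ).assign(sample_id=self.sample_id, theta=self.theta, method=self.method)


def build_saturation_curves(
    manifest: Manifest | None,
    annotation: GeneAnnotation,
    theta_grid: Sequence[int] = DEFAULT_THETA_GRID,
    method: str = "desire",
    full_counts: CountMatrix | None = None,
    depth_grid: Sequence[float] | None = None,
    **count_kwargs,
) -> list[SaturationCurve]:
    """Expressed-gene curves for every (sample, θ).

    ``method="desire"`` counts each subsampled alignment file listed in the
    manifest and thresholds the resulting raw counts. ``method="scaled"``
    instead multiplies the full-depth count matrix by each fraction of
    ``depth_grid`` and thresholds the scaled (real-valued) entries — the
    shortcut that subsampling is contrasted with. Both methods use raw,
    unnormalized values.
    """
    curves: list[SaturationCurve] = []
    if method == "desire":
        if manifest is None:
            raise ValueError("desire method requires a replicate manifest")
        by_sample: dict[str, list] = {}
        for rec in manifest.records:
            by_sample.setdefault(rec.sample, []).append(rec)
        for sample, recs in by_sample.items():
            per_theta: dict[int, list[tuple[float, int, int]]] = {
                t: [] for t in theta_grid
            }
            for rec in recs:
                if not rec.path.exists():
                    raise FileNotFoundError(
                        f"replicate file missing for sample {sample}, "
                        f"f={rec.fraction}, replicate {rec.replicate}: {rec.path}"
                    )
                cv = count_fragments(rec.path, annotation, **count_kwargs)
                for theta in theta_grid:
                    per_theta[theta].append(
                        (rec.fraction, rec.replicate, expressed_gene_count(cv, theta))
                    )
            for theta in theta_grid:
                curves.append(
                    SaturationCurve(sample, theta, per_theta[theta], "desire")
                )
    elif method == "scaled":
        if full_counts is None or depth_grid is None:
            raise ValueError("scaled method requires full_counts and depth_grid")
        for sample in full_counts.samples:
            per_theta: dict[int, list[tuple[float, int, int]]] = {
                t: [] for t in theta_grid
            }
            for fraction in depth_grid:
                scaled = scale_count_matrix(full_counts, fraction, rounding="none")
                col = scaled.column_values(sample)
                for theta in theta_grid:
                    per_theta[theta].append(
                        (fraction, 0, int((col >= theta).sum()))
                    )
            for theta in theta_grid:
                curves.append(
                    SaturationCurve(sample, theta, per_theta[theta], "scaled")
                )
    else:
        raise ValueError(f"unknown method {method!r}")
    return curves


def _gompertz(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * np.exp(-b * np.exp(-c * x))


@dataclass
class GompertzFit:
    """Result of a Gompertz least-squares fit.

    Standard errors are the asymptotic errors from the covariance of the
    nonlinear least-squares estimate. ``converged`` is False (rather than
    parameters being garbage) when no restart produced a finite optimum.
    """

    a: float
    b: float
    c: float
    se_a: float
    se_b: float
    se_c: float
    rss: float
    n_points: int
    converged: bool
    message: str = ""

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _gompertz(np.asarray(x, dtype=float), self.a, self.b, self.c)

    def relative_slope_at(self, x: float) -> float:
        """(df/dx)/a at x — the saturation detector statistic."""
        return float(
            self.b * self.c * np.exp(-self.c * x) * np.exp(-self.b * np.exp(-self.c * x))
        )

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": [self.a, self.b, self.c],
                "std_error": [self.se_a, self.se_b, self.se_c],
            },
            index=["a (asymptote)", "b (displacement)", "c (growth rate)"],
        )


class GompertzModel:
    """Gompertz growth model a·exp(−b·exp(−c·x)) for saturation curves.

    Follows the model/results convention: construct from (x, y) points or a
    :class:`SaturationCurve`, call :meth:`fit` for a :class:`GompertzFit`.
    All replicate points are fitted (not their medians), so replicate
    scatter enters the standard errors.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same shape")
        if len(np.unique(self.x)) < 3:
            raise ValueError("need >= 3 distinct x values to fit 3 parameters")

    @classmethod
    def from_curve(
        cls, curve: SaturationCurve, x_scale: str = "fraction",
        library_size: int | None = None,
    ) -> "GompertzModel":
        x, y = curve.xy()
        if x_scale == "reads":
            if library_size is None:
                raise ValueError("x_scale='reads' requires the full library size")
            x = x * library_size
        elif x_scale != "fraction":
            raise ValueError(f"unknown x_scale {x_scale!r}")
        return cls(x, y)

    def _starts(self) -> list[tuple[float, float, float]]:
        a0 = float(self.y.max()) if self.y.max() > 0 else 1.0
        y_min = float(self.y[np.argmin(self.x)])
        x_min = float(self.x.min())
        x_max = float(self.x.max())  # rate starts scale with the x units
        starts = []
        for c0 in (1.0, 0.5, 2.0, 4.0, 8.0):
            c0 = c0 / x_max
            # invert f(x_min) = a·exp(−b·exp(−c·x_min)) for b
            ratio = min(max(y_min / (a0 * 1.05), 1e-6), 1 - 1e-9)
            b0 = -np.log(ratio) / np.exp(-c0 * x_min)
            starts.append((a0 * 1.05, float(b0), c0))
        starts.append((a0 * 1.05, 2.0, 3.0 / x_max))
        return starts

    def fit(self) -> GompertzFit:
        best: GompertzFit | None = None
        last_err = ""
        for p0 in self._starts():
            try:
                popt, pcov = optimize.curve_fit(
                    _gompertz,
                    self.x,
                    self.y,
                    p0=p0,
                    bounds=([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
                    maxfev=20000,
                )
            except (RuntimeError, ValueError) as exc:
                last_err = str(exc)
                continue
            resid = self.y - _gompertz(self.x, *popt)
            rss = float(resid @ resid)
            if not np.all(np.isfinite(popt)):
                continue
            se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
            fit = GompertzFit(
                a=float(popt[0]),
                b=float(popt[1]),
                c=float(popt[2]),
                se_a=float(se[0]),
                se_b=float(se[1]),
                se_c=float(se[2]),
                rss=rss,
                n_points=len(self.x),
                converged=True,
            )
            if best is None or fit.rss < best.rss:
                best = fit
        if best is None:
            return GompertzFit(
                a=np.nan, b=np.nan, c=np.nan,
                se_a=np.nan, se_b=np.nan, se_c=np.nan,
                rss=np.nan, n_points=len(self.x),
                converged=False, message=last_err or "no start converged",
            )
        return best


def fit_gompertz(
    curve: SaturationCurve,
    x_scale: str = "fraction",
    library_size: int | None = None,
) -> GompertzFit:
    """Fit a Gompertz growth function to one saturation curve."""
    return GompertzModel.from_curve(curve, x_scale, library_size).fit()


@dataclass
class DepthEstimate:
    """Optimal-depth estimators from per-sample saturation behaviour.

    Estimator I (``mean_reads_bound``) is the mean full-depth library size
    across samples; Estimator II (``max_reads_bound``) is the largest one.
    When no fitted curve has flattened at full depth, both are reported as
    lower bounds on the depth required for saturation.
    """

    mean_reads_bound: float
    max_reads_bound: float
    saturated: dict[str, bool]
    is_lower_bound: bool

    @property
    def any_saturated(self) -> bool:
        return any(self.saturated.values())


def estimate_optimal_depth(
    fits: Mapping[str, GompertzFit],
    library_sizes: Mapping[str, int | float],
    saturation_tolerance: float = 1e-3,
) -> DepthEstimate:
    """Estimate the sequencing depth needed for saturation.

    A sample counts as saturated iff its fitted curve's relative slope at
    full depth, (df/dx)/a at x = 1, is below ``saturation_tolerance``.
    If no curve saturates the estimators are only lower bounds: more reads
    than the mean (Estimator I) respectively the maximum (Estimator II)
    library size are needed.
    """
    converged = {s: f for s, f in fits.items() if f.converged}
    if not converged:
        raise ValueError("no converged Gompertz fits; cannot assess saturation")
    saturated = {
        s: bool(f.relative_slope_at(1.0) < saturation_tolerance)
        for s, f in converged.items()
    }
    sizes = np.array([float(library_sizes[s]) for s in fits], dtype=float)
    return DepthEstimate(
        mean_reads_bound=float(sizes.mean()),
        max_reads_bound=float(sizes.max()),
        saturated=saturated,
        is_lower_bound=not all(saturated.values()),
    )


def _ttest_three(
    a: np.ndarray, b: np.ndarray, equal_var: bool = False
) -> tuple[float, float, float]:
    """Two-sample t-test p-values: two-sided, left (A < B), right (A > B)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return (1.0, 1.0, 1.0)  # degenerate identical groups, by convention
    two = stats.ttest_ind(a, b, equal_var=equal_var, alternative="two-sided").pvalue
    left = stats.ttest_ind(a, b, equal_var=equal_var, alternative="less").pvalue
    right = stats.ttest_ind(a, b, equal_var=equal_var, alternative="greater").pvalue
    return (float(two), float(left), float(right))


def compare_expressed_gene_medians(
    group_a: Iterable[SaturationCurve],
    group_b: Iterable[SaturationCurve],
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-depth t-tests on group means of per-sample replicate medians.

    For each depth fraction, the median expressed-gene count over the R
    replicates is taken per sample; the two groups of per-sample medians
    are then compared by a two-sample t-test (Welch by default), reporting
    two-sided, left-sided (A < B) and right-sided p-values — one table row
    per depth.
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group for a t-test")
    fracs = sorted(
        set.intersection(*(set(c.fractions()) for c in group_a + group_b))
    )
    rows = []
    for f in fracs:
        med_a = np.array([c.median_at(f) for c in group_a])
        med_b = np.array([c.median_at(f) for c in group_b])
        two, left, right = _ttest_three(med_a, med_b, equal_var)
        rows.append(
            {
                "depth": f,
                "p_two_sided": two,
                "p_left_sided": left,
                "p_right_sided": right,
            }
        )
    return pd.DataFrame(rows)


def compare_growth_rates(
    fits_a: Mapping[int, Sequence[GompertzFit]],
    fits_b: Mapping[int, Sequence[GompertzFit]],
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-threshold t-tests on fitted growth rates c between two groups.

    ``fits_a``/``fits_b`` map θ to one converged fit per sample. The output
    mirrors the expressed-gene test table: one row per θ with two-sided,
    left-sided and right-sided p-values.
    """
    rows = []
    for theta in sorted(fits_a):
        ca = np.array([f.c for f in fits_a[theta] if f.converged])
        cb = np.array([f.c for f in fits_b[theta] if f.converged])
        if len(ca) < 2 or len(cb) < 2:
            raise ValueError(f"theta={theta}: need >= 2 converged fits per group")
        two, left, right = _ttest_three(ca, cb, equal_var)
        rows.append(
            {
                "theta": theta,
                "p_two_sided": two,
                "p_left_sided": left,
                "p_right_sided": right,
            }
        )
    return pd.DataFrame(rows)
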