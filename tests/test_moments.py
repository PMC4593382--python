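"""Expression-distribution moments and the group-level moment tests."""

import numpy as np
import pytest
from scipy import stats

from desire.annotation import GeneAnnotation, GeneModel
from desire.counting import CountVector, count_fragments
from desire.moments import (
    MomentSummary,
    compare_moments,
    distribution_moments,
    moments_table,
)
from desire.normalize import cpm
from desire.subsample import subsample_alignments


def test_symmetric_values_have_zero_skewness():
    m = distribution_moments(np.array([1.0, 2.0, 3.0]))
    assert m.skewness == pytest.approx(0.0, abs=1e-12)
    assert m.variance == pytest.approx(1.0)  # unbiased, n−1


def test_normal_sample_kurtosis_near_three():
    rng = np.random.default_rng(4)
    m = distribution_moments(rng.standard_normal(100_000))
    assert m.kurtosis == pytest.approx(3.0, abs=0.1)
    assert m.skewness == pytest.approx(0.0, abs=0.05)


def test_constant_vector_reports_undefined_shape_moments():
    m = distribution_moments(np.full(10, 7.0))
    assert m.variance == 0.0
    assert m.skewness is None and m.kurtosis is None


def test_moment_conventions_match_manual_formulas():
    rng = np.random.default_rng(9)
    x = rng.lognormal(1, 1, size=200)
    m = distribution_moments(x)
    n = len(x)
    mu = x.mean()
    m2 = ((x - mu) ** 2).mean()
    m3 = ((x - mu) ** 3).mean()
    m4 = ((x - mu) ** 4).mean()
    assert m.mean == pytest.approx(mu)
    assert m.variance == pytest.approx(((x - mu) ** 2).sum() / (n - 1))
    assert m.skewness == pytest.approx(m3 / m2 ** 1.5)
    assert m.kurtosis == pytest.approx(m4 / m2 ** 2)  # plain, not excess


def big_annotation(g):
    return GeneAnnotation(
        [
            GeneModel(f"g{i}", "chrS1", "+", ((i * 2000 + 1, i * 2000 + 1000),))
            for i in range(g)
        ]
    )


def test_cpm_mean_is_pinned_at_million_over_gene_count():
    """Over the full annotation the CPM mean is 10⁶/G at any depth."""
    G = 23_648
    ann = big_annotation(G)
    rng = np.random.default_rng(12)
    counts = rng.negative_binomial(1, 0.01, size=G)
    v = CountVector("s", counts, ann)
    means = []
    for fraction in (1.0, 0.5, 0.1):
        scaled = np.floor(counts * fraction).astype(int)
        if scaled.sum() == 0:
            continue
        sv = CountVector("s", scaled, ann)
        means.append(distribution_moments(cpm(sv)).mean)
    for mu in means:
        assert mu == pytest.approx(1e6 / G, rel=1e-12)
    assert 1e6 / G == pytest.approx(42.29, abs=0.005)


def test_moments_invariant_to_gene_order():
    rng = np.random.default_rng(5)
    x = rng.lognormal(2, 1, size=500)
    m1 = distribution_moments(x)
    m2 = distribution_moments(rng.permutation(x))
    assert (m1.mean, m1.variance, m1.skewness, m1.kurtosis) == pytest.approx(
        (m2.mean, m2.variance, m2.skewness, m2.kurtosis)
    )


def test_theta_filter_applies_to_raw_counts_before_normalization():
    counts = np.array([0, 1, 5, 20])
    ann = big_annotation(4)
    v = CountVector("s", counts, ann)
    normalized = cpm(v)
    m = distribution_moments(normalized, filter_theta=5, raw_counts=counts)
    kept = normalized.values[counts >= 5]
    assert m.mean == pytest.approx(kept.mean())
    with pytest.raises(ValueError, match="raw_counts"):
        distribution_moments(
            np.asarray(normalized.values), filter_theta=5
        )


def test_cpm_moments_depth_stable_but_raw_moments_drift(small_sim, tmp_path):
    """Across depths, the CPM mean has CV < 10⁻⁶ while the raw mean moves
    with depth (CV > 0.1) — the reason normalization is indispensable."""
    ann = small_sim["annotation"]
    cpm_means, raw_means = [], []
    for i, f in enumerate((0.1, 0.3, 0.5, 0.7, 0.9)):
        out = tmp_path / f"sub{i}.sam"
        subsample_alignments(small_sim["sam"], f, seed=i, out=out)
        cv_counts = count_fragments(out, ann)
        raw_means.append(distribution_moments(cv_counts).mean)
        cpm_means.append(distribution_moments(cpm(cv_counts)).mean)
    cpm_cv = np.std(cpm_means) / np.mean(cpm_means)
    raw_cv = np.std(raw_means) / np.mean(raw_means)
    assert cpm_cv < 1e-6
    assert raw_cv > 0.1


def test_equal_groups_give_p_one_for_degenerate_and_table_layout():
    ms = [
        MomentSummary(f"s{i}", mean=5.0, variance=0.0, skewness=None,
                      kurtosis=None, fraction=f)
        for i in range(4)
        for f in (0.1, 0.2, 0.3)
    ]
    table = compare_moments(ms, list(ms))
    assert list(table.moment) == ["mean", "variance", "skewness", "kurtosis"]
    mean_row = table.set_index("moment").loc["mean"]
    assert mean_row.p_two_sided == 1.0


def test_null_permutation_p_values_are_uniform():
    """Permuting group labels yields uniform two-sided p-values."""
    rng = np.random.default_rng(77)
    depths = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))
    pvals = []
    for _ in range(400):
        # exchangeable per-depth medians under the null
        va = rng.normal(size=len(depths))
        vb = rng.normal(size=len(depths))
        ms_a = [
            MomentSummary("a", mean=v, variance=1.0, skewness=0.0,
                          kurtosis=3.0, fraction=f)
            for f, v in zip(depths, va)
        ]
        ms_b = [
            MomentSummary("b", mean=v, variance=1.0, skewness=0.0,
                          kurtosis=3.0, fraction=f)
            for f, v in zip(depths, vb)
        ]
        table = compare_moments(ms_a, ms_b).set_index("moment")
        pvals.append(table.loc["mean", "p_two_sided"])
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_variance_difference_detected_directionally():
    """Variance ratio 2 at n = 9 per group: the directional test fires in
    most simulations while the mean stays quiet."""
    rng = np.random.default_rng(13)
    depths = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))
    hits = 0
    n_sim = 60
    for _ in range(n_sim):
        ms_a, ms_b = [], []
        for f in depths:
            xa = rng.lognormal(0, 1.0, size=800)
            xb = rng.lognormal(0, 0.75, size=800)  # smaller spread
            ms_a.append(distribution_moments(xa, sample_id="a", fraction=f))
            ms_b.append(distribution_moments(xb, sample_id="b", fraction=f))
        table = compare_moments(ms_a, ms_b).set_index("moment")
        # group A has the larger variance: right-sided (A > B) should fire
        if table.loc["variance", "p_right_sided"] < 0.05:
            hits += 1
    assert hits / n_sim >= 0.8


def test_moments_table_mirrors_depth_rows(small_sim):
    ann = small_sim["annotation"]
    cv = count_fragments(small_sim["sam"], ann)
    ms = [
        distribution_moments(cpm(cv), fraction=f, replicate=r)
        for f in (0.5, 1.0)
        for r in range(3)
    ]
    table = moments_table(ms)
    assert list(table.depth) == [0.5, 1.0]
    assert {"mean_mean", "mean_sd", "kurtosis_mean", "kurtosis_sd"} <= set(
        table.columns
    )
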