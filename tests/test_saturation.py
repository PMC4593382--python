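"""Saturation curves, Gompertz fits, depth estimators and group tests."""

import numpy as np
import pytest

from desire.annotation import GeneAnnotation, GeneModel
from desire.counting import CountMatrix, CountVector, count_fragments
from desire.saturation import (
    GompertzModel,
    SaturationCurve,
    build_saturation_curves,
    compare_expressed_gene_medians,
    compare_growth_rates,
    estimate_optimal_depth,
    expressed_gene_count,
    fit_gompertz,
)
from desire.simulate import SimulationConfig, simulate_annotation, simulate_reads
from desire.subsample import SubsampleSpec, generate_replicates

# Full-depth library sizes of the eight bulk samples the depth estimators
# are calibrated on (four tumors, four controls).
LIBRARY_SIZES = {
    "t1": 34_974_017, "t2": 46_677_107, "t3": 17_574_408, "t4": 24_440_340,
    "c1": 25_900_791, "c2": 43_454_785, "c3": 31_426_867, "c4": 33_517_581,
}


def gompertz(x, a, b, c):
    return a * np.exp(-b * np.exp(-c * x))


def test_expressed_gene_count_thresholding():
    counts = np.array([0, 1, 10, 100])
    assert expressed_gene_count(counts, 10) == 2
    assert expressed_gene_count(counts, 1) == 3
    assert expressed_gene_count(np.zeros(5, dtype=int), 1) == 0


def test_expressed_gene_count_matches_comprehension_and_monotone_in_theta():
    rng = np.random.default_rng(3)
    counts = rng.negative_binomial(2, 0.05, size=500)
    prev = None
    for theta in (1, 10, 50, 100):
        got = expressed_gene_count(counts, theta)
        assert got == sum(1 for c in counts if c >= theta)
        if prev is not None:
            assert got <= prev
        prev = got


@pytest.fixture(scope="module")
def near_threshold(tmp_path_factory):
    """Sample whose genes sit near the low-depth detection limit.

    Counts cluster around 20 reads per gene: at f = 0.1 direct scaling
    keeps every such gene expressed at θ = 1 (20·0.1 ≥ 1) while real
    subsampling misses all 20 reads with probability ≈ 0.9²⁰ ≈ 0.12 per
    gene — the regime where the two depth simulations visibly diverge.
    """
    d = tmp_path_factory.mktemp("satur")
    config = SimulationConfig(
        n_genes=120,
        library_size=2400,  # ≈ 20 reads per gene
        n_chroms=2,
        noise_fraction=0.0,
        nb_mean_distribution=(0.0, 0.3),
        nb_dispersion=0.05,
        seed=21,
    )
    annotation = simulate_annotation(config, d / "ann.gtf")
    simulate_reads(annotation, config, d / "s.sam", "s")
    spec = SubsampleSpec(depth_grid=(0.1, 0.4, 0.7, 1.0), replicates=6, base_seed=3)
    manifest = generate_replicates(d / "s.sam", spec, d / "reps")
    full = count_fragments(d / "s.sam", annotation, sample_id="s")
    return {
        "annotation": annotation,
        "manifest": manifest,
        "full": full,
        "grid": spec.depth_grid,
    }


def test_desire_curves_sit_below_scaled_at_low_depth(near_threshold):
    """At θ = 1 and small f, real subsampling loses near-threshold genes
    that deterministic scaling retains, so its curve sits strictly below;
    the gap closes as f → 1."""
    ann = near_threshold["annotation"]
    desire = build_saturation_curves(
        near_threshold["manifest"], ann, theta_grid=(1,), method="desire"
    )[0]
    scaled = build_saturation_curves(
        None,
        ann,
        theta_grid=(1,),
        method="scaled",
        full_counts=CountMatrix.from_vectors([near_threshold["full"]]),
        depth_grid=near_threshold["grid"],
    )[0]
    assert desire.counts_at(0.1).max() < scaled.counts_at(0.1)[0]
    gaps = [
        scaled.counts_at(f)[0] - desire.median_at(f)
        for f in near_threshold["grid"]
    ]
    assert gaps == sorted(gaps, reverse=True)  # divergence grows as f -> 0
    # at full depth the two methods agree exactly
    assert set(desire.counts_at(1.0)) == set(scaled.counts_at(1.0))


def test_subsample_curve_never_exceeds_full_depth_per_replicate(near_threshold):
    ann = near_threshold["annotation"]
    for theta in (1, 10):
        curve = build_saturation_curves(
            near_threshold["manifest"], ann, theta_grid=(theta,), method="desire"
        )[0]
        full = curve.counts_at(1.0).max()
        for f, _, count in curve.points:
            assert count <= full


def test_median_expressed_count_increases_with_depth(near_threshold):
    ann = near_threshold["annotation"]
    curve = build_saturation_curves(
        near_threshold["manifest"], ann, theta_grid=(1,), method="desire"
    )[0]
    medians = [curve.median_at(f) for f in curve.fractions()]
    assert medians == sorted(medians)


def test_gompertz_recovers_noise_free_parameters():
    a, b, c = 20_000.0, 2.0, 3.0
    x = np.arange(0.1, 1.01, 0.1)
    fit = GompertzModel(x, gompertz(x, a, b, c)).fit()
    assert fit.converged
    for est, true in zip(fit.params, (a, b, c)):
        assert abs(est - true) / true < 1e-4
    # fitted curve is nondecreasing on x >= 0
    xs = np.linspace(0, 2, 50)
    assert np.all(np.diff(fit.predict(xs)) >= 0)


def test_gompertz_needs_three_distinct_depths():
    with pytest.raises(ValueError, match="3 distinct"):
        GompertzModel(np.array([0.1, 0.1, 0.5]), np.array([1.0, 1.1, 2.0]))


def test_gompertz_degenerate_constant_curve_does_not_crash():
    pts = [(f, 0, 100) for f in (0.1, 0.3, 0.5, 0.7, 1.0)]
    fit = fit_gompertz(SaturationCurve("s", 1, pts))
    # either flagged unconverged, or collapsed to the constant asymptote
    assert (not fit.converged) or abs(fit.a - 100) / 100 < 0.05


def test_gompertz_x_scale_in_reads():
    a, b, c = 15_000.0, 1.5, 2.0
    x = np.arange(0.1, 1.01, 0.1)
    curve = SaturationCurve(
        "s", 1, [(float(f), 0, float(gompertz(f, a, b, c))) for f in x]
    )
    fit = fit_gompertz(curve, x_scale="reads", library_size=1_000_000)
    assert fit.converged
    # rate per read is the per-fraction rate divided by the library size
    assert fit.c == pytest.approx(c / 1_000_000, rel=1e-3)


def unsaturated_fits():
    x = np.arange(0.1, 1.01, 0.1)
    fits = {}
    for i, sample in enumerate(LIBRARY_SIZES):
        a, b, c = 20_000 + 100 * i, 2.0, 2.5  # still steep at f = 1
        fits[sample] = GompertzModel(x, gompertz(x, a, b, c)).fit()
    return fits


def test_depth_estimators_on_the_eight_bulk_samples():
    """With no curve saturated, Estimator I is the mean library size and
    Estimator II the largest one — both lower bounds."""
    est = estimate_optimal_depth(unsaturated_fits(), LIBRARY_SIZES)
    assert est.mean_reads_bound == pytest.approx(32_245_737, abs=0.5)
    assert est.max_reads_bound == 46_677_107
    assert est.is_lower_bound
    assert not est.any_saturated
    sd = np.std(list(LIBRARY_SIZES.values()), ddof=1)
    assert sd == pytest.approx(9_710_593, abs=1)


def test_saturated_sample_is_an_estimate_not_a_bound():
    x = np.arange(0.1, 1.01, 0.1)
    flat = {"s1": GompertzModel(x, gompertz(x, 10_000, 3.0, 12.0)).fit()}
    est = estimate_optimal_depth(flat, {"s1": 5_000_000})
    assert est.saturated["s1"]
    assert not est.is_lower_bound


def test_infinite_tolerance_saturates_everything():
    est = estimate_optimal_depth(
        unsaturated_fits(), LIBRARY_SIZES, saturation_tolerance=np.inf
    )
    assert all(est.saturated.values())
    assert not est.is_lower_bound


def test_all_unconverged_fits_error():
    bad = fit_gompertz(
        SaturationCurve("s", 1, [(0.1, 0, 1), (0.5, 0, 1), (1.0, 0, 1)])
    )
    object.__setattr__(bad, "converged", False)
    with pytest.raises(ValueError, match="no converged"):
        estimate_optimal_depth({"s": bad}, {"s": 1000})


def curve_from_medians(sample, values, rng, spread=5.0):
    points = []
    for f, v in zip(np.arange(0.1, 1.01, 0.1), values):
        for r in range(5):
            points.append((float(f), r, float(v + rng.normal(0, spread))))
    return SaturationCurve(sample, 1, points)


def test_expressed_gene_median_comparison_detects_direction():
    """Group A consistently below group B → left-sided p ≪ right-sided p."""
    rng = np.random.default_rng(8)
    base = 10_000 + 3_000 * np.arange(0.1, 1.01, 0.1)
    group_a = [curve_from_medians(f"a{i}", base - 300, rng) for i in range(4)]
    group_b = [curve_from_medians(f"b{i}", base + 300, rng) for i in range(4)]
    table = compare_expressed_gene_medians(group_a, group_b)
    assert set(table.columns) == {
        "depth", "p_two_sided", "p_left_sided", "p_right_sided"
    }
    assert (table.p_left_sided < 0.05).all()
    assert (table.p_left_sided < table.p_right_sided / 100).all()


def test_comparison_requires_two_samples_per_group():
    rng = np.random.default_rng(0)
    a = [curve_from_medians("a", np.ones(10), rng)]
    b = [curve_from_medians(f"b{i}", np.ones(10), rng) for i in range(2)]
    with pytest.raises(ValueError, match=">= 2 samples"):
        compare_expressed_gene_medians(a, b)


def make_fit(c_value, rng):
    x = np.repeat(np.arange(0.1, 1.01, 0.1), 3)
    y = gompertz(x, 20_000, 2.0, c_value) + rng.normal(0, 50, size=len(x))
    return GompertzModel(x, y).fit()


def test_growth_rate_comparison_identical_groups_p_one():
    rng = np.random.default_rng(1)
    fits = [make_fit(3.0, rng) for _ in range(3)]
    table = compare_growth_rates({1: fits}, {1: list(fits)})
    assert table.p_two_sided.iloc[0] == pytest.approx(1.0)


def test_growth_rate_comparison_separated_groups():
    rng = np.random.default_rng(2)
    fits_a = {1: [make_fit(2.0, rng) for _ in range(4)]}
    fits_b = {1: [make_fit(4.0, rng) for _ in range(4)]}
    table = compare_growth_rates(fits_a, fits_b)
    assert table.p_two_sided.iloc[0] < 0.01
    assert list(table.columns) == [
        "theta", "p_two_sided", "p_left_sided", "p_right_sided"
    ]
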