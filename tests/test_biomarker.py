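"""Ratio, threshold discovery, gated tests, ROC — against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smpull.biomarker import (
    CumulativeDiff,
    alpha_syn_proportion,
    combined_score,
    compare_groups,
    discover_thresholds,
    distinct_fraction,
    group_cumulative_hist,
    max_cumulative_difference,
    roc_auc,
    run_cohort_analysis,
)
from smpull.errors import UndefinedFractionError, ValidationError
from smpull.synth import CohortSpec, simulate_cohort


def pair_count_auc(scores, labels):
    """Brute-force AUC oracle: concordant pairs + half the ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


# ------------------------------------------------------------------- ratio

def test_ratio_with_printed_group_means():
    assert alpha_syn_proportion(200, 140) == pytest.approx(200 / 340)


def test_ratio_boundaries_and_symmetry():
    assert alpha_syn_proportion(0, 5) == 0.0
    assert alpha_syn_proportion(5, 0) == 1.0
    assert alpha_syn_proportion(3, 3) == 0.5
    with pytest.raises(UndefinedFractionError):
        alpha_syn_proportion(0, 0)


# ------------------------------------------------------- cumulative histograms

def test_single_sample_ecdf_on_grid():
    cd = group_cumulative_hist(
        {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([1.0, 2.0, 3.0])},
        {"a": "PD", "b": "control"},
        np.array([1.5, 2.5, 3.5]),
    )
    np.testing.assert_allclose(cd.cdf_pd, [1 / 3, 2 / 3, 1.0])
    np.testing.assert_allclose(cd.cdf_control, [1 / 3, 2 / 3, 1.0])


def test_identical_samples_average_to_member_cdf(rng):
    v = rng.exponential(1.0, 50)
    grid = np.linspace(0, 5, 40)
    cd = group_cumulative_hist(
        {"a": v, "b": v, "c": v}, {"a": "PD", "b": "PD", "c": "control"}, grid
    )
    single = np.searchsorted(np.sort(v), grid, side="right") / v.size
    np.testing.assert_allclose(cd.cdf_pd, single)


def test_group_cdf_approaches_uniform_identity(rng):
    """Glivenko–Cantelli: averaged ECDFs of Uniform(0,1) samples approach t."""
    samples = {f"s{i}": rng.uniform(0, 1, 2000) for i in range(10)}
    groups = {f"s{i}": "PD" if i < 5 else "control" for i in range(10)}
    grid = np.linspace(0.01, 0.99, 99)
    cd = group_cumulative_hist(samples, groups, grid)
    assert np.abs(cd.cdf_pd - grid).max() < 0.02
    assert np.abs(cd.cdf_control - grid).max() < 0.02


def test_cdfs_are_monotone_in_01(rng):
    samples = {"a": rng.normal(0, 1, 30), "b": rng.normal(0, 1, 30)}
    cd = group_cumulative_hist(samples, {"a": "PD", "b": "control"}, np.linspace(-4, 4, 100))
    for cdf in (cd.cdf_pd, cd.cdf_control):
        assert (np.diff(cdf) >= 0).all()
        assert cdf[0] >= 0 and cdf[-1] == 1.0


def test_bad_grid_rejected(rng):
    with pytest.raises(ValidationError):
        group_cumulative_hist({"a": np.ones(3)}, {"a": "PD"}, np.array([2.0, 1.0]))


# -------------------------------------------------------- threshold discovery

def test_analytic_gaussian_cdf_argmax():
    """For N(0,1) controls vs N(1,1) cases the maximum gap is at 0.5."""
    grid = np.linspace(-4, 5, 1801)
    cd = CumulativeDiff(grid, stats.norm.cdf(grid, 0, 1), stats.norm.cdf(grid, 1, 1))
    pick = max_cumulative_difference(cd)
    step = grid[1] - grid[0]
    assert abs(pick.threshold - 0.5) <= step
    assert pick.max_diff == pytest.approx(2 * stats.norm.cdf(0.5) - 1, abs=1e-4)
    assert not pick.degenerate


def test_identical_cdfs_flagged_degenerate():
    grid = np.linspace(0, 1, 11)
    cd = CumulativeDiff(grid, grid.copy(), grid.copy())
    pick = max_cumulative_difference(cd)
    assert pick.degenerate
    assert pick.threshold == grid[0]
    assert pick.max_diff == 0.0


def test_step_cdfs():
    grid = np.linspace(0, 3, 301)
    cd = CumulativeDiff(grid, (grid >= 1).astype(float), (grid >= 2).astype(float))
    pick = max_cumulative_difference(cd)
    assert pick.max_diff == 1.0
    assert pick.threshold == pytest.approx(1.0, abs=0.011)


def test_threshold_recovery_converges_with_cohort_size():
    """Recovered (P*, C*) approach the analytic argmax of the generative model."""
    from smpull.synth.cohort import DEFAULT_MORPHOLOGY_PARAMS

    mp_pd = DEFAULT_MORPHOLOGY_PARAMS[("PD", "alpha_syn")]
    mp_c = DEFAULT_MORPHOLOGY_PARAMS[("control", "alpha_syn")]
    p_true = np.exp(0.5 * (mp_pd.log_perimeter_mu + mp_c.log_perimeter_mu))
    c_true = 1.0 / (1.0 + np.exp(-0.5 * (mp_pd.circ_logit_mu + mp_c.circ_logit_mu)))

    errs = {}
    for n, agg_per_fov in ((4, 100), (24, 2000)):
        e_p, e_c = [], []
        for seed in (1, 2, 3):
            spec = CohortSpec(n_per_group=n, fovs_per_sample_dlim=1, fovs_per_sample_storm=1, seed=seed)
            bundle = simulate_cohort(spec, aggregates_per_storm_fov=agg_per_fov)
            th = discover_thresholds(bundle.morphology, "alpha_syn")
            e_p.append(abs(th["perimeter_um"] - p_true))
            e_c.append(abs(th["circularity"] - c_true))
        errs[n] = (np.mean(e_p), np.mean(e_c))
    assert errs[24][0] < errs[4][0]
    assert errs[24][0] < 0.04            # within ~2 grid steps of 0.24 µm
    assert errs[24][1] < 0.05


# --------------------------------------------------------- distinct fraction

def test_distinct_fraction_with_printed_thresholds():
    f = distinct_fraction([0.1, 0.3, 0.3], [0.9, 0.5, 0.9], 0.24, 0.64)
    assert f == pytest.approx(1 / 3)


def test_distinct_fraction_boundaries():
    assert distinct_fraction([1, 2], [1, 1], 0.1, 0.1) == 1.0
    assert distinct_fraction([1, 2], [1, 1], 10, 10) == 0.0
    with pytest.raises(UndefinedFractionError):
        distinct_fraction([], [], 0.24, 0.64)


def test_combined_score():
    assert combined_score(0.6, 0.5) == pytest.approx(0.3)
    assert combined_score(0.8, 0.0) == 0.0
    assert combined_score(1.0, 1.0) == 1.0
    with pytest.raises(ValidationError):
        combined_score(1.2, 0.5)


# -------------------------------------------------------------- group tests

def test_separated_groups_use_welch_and_reject(rng):
    a = rng.normal(5.0, 1.0, 20)
    b = rng.normal(0.0, 1.0, 20)
    res = compare_groups(a, b)
    assert res.test == "welch_t"
    assert res.p_value < 1e-3


def test_heavy_tails_route_to_nonparametric(rng):
    picks = []
    for _ in range(20):
        a = rng.lognormal(0, 1.2, 50)
        b = rng.lognormal(0, 1.2, 50)
        picks.append(compare_groups(a, b).test)
    assert picks.count("mann_whitney") > 10


def test_constant_samples_forced_nonparametric():
    res = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert res.degenerate
    assert res.test == "mann_whitney"
    assert res.p_value == 1.0


def test_too_small_groups_rejected():
    with pytest.raises(ValidationError):
        compare_groups([1, 2], [1, 2, 3])


# --------------------------------------------------------------------- ROC

def test_perfect_ranking_gives_auc_one():
    r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
    assert r.auc == 1.0
    assert r.sensitivity == 1.0 and r.specificity == 1.0


def test_shuffled_labels_give_null_auc(rng):
    scores = rng.normal(size=2000)
    labels = rng.integers(0, 2, 2000)
    r = roc_auc(scores, labels)
    assert r.auc == pytest.approx(0.5, abs=0.04)


def test_small_example_pair_counting():
    # PD {3, 1} vs control {2, 0}: 3 concordant pairs of 4 -> 0.75
    r = roc_auc([3, 1, 2, 0], [1, 1, 0, 0])
    assert r.auc == pytest.approx(0.75)


def test_auc_equals_pair_oracle_and_trapezoid(rng):
    """Rank estimator == brute-force pairs == curve area, ties included."""
    for trial in range(60):
        n = int(rng.integers(4, 13))
        scores = rng.integers(0, 5, n).astype(float)  # heavy ties
        labels = np.zeros(n, int)
        labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if labels.sum() in (0, n):
            continue
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)
        assert r.auc == pytest.approx(np.trapezoid(r.tpr, r.fpr), abs=1e-12)


def test_curve_is_monotone_and_anchored(rng):
    scores = rng.normal(size=50)
    labels = (rng.random(50) < 0.4).astype(int)
    r = roc_auc(scores, labels)
    assert r.fpr[0] == 0 and r.tpr[0] == 0
    assert r.fpr[-1] == 1 and r.tpr[-1] == 1
    assert (np.diff(r.fpr) >= 0).all() and (np.diff(r.tpr) >= 0).all()


def test_auc_converges_to_gaussian_form(rng):
    """AUC for N(δ,1) vs N(0,1) scores approaches Φ(δ/√2)."""
    n = 4000
    for delta in (0.0, 0.5, 1.0, 2.0):
        scores = np.concatenate([rng.normal(delta, 1, n), rng.normal(0, 1, n)])
        labels = np.concatenate([np.ones(n, int), np.zeros(n, int)])
        expected = stats.norm.cdf(delta / np.sqrt(2))
        assert roc_auc(scores, labels).auc == pytest.approx(expected, abs=0.02)


def test_single_class_rejected():
    with pytest.raises(ValidationError):
        roc_auc([1, 2, 3], [1, 1, 1])


def test_wilson_intervals_bracket_the_point_estimate():
    r = roc_auc([3, 1, 2, 0, 5, 4], [1, 1, 0, 0, 1, 0])
    lo, hi = r.sensitivity_ci
    assert lo <= r.sensitivity <= hi
    lo, hi = r.specificity_ci
    assert lo <= r.specificity <= hi


# ------------------------------------------------------------ cohort driver

def _null_spec(seed):
    params = {(g, c): (150.0, 80.0) for g in ("PD", "control") for c in ("alpha_syn", "abeta")}
    from smpull.synth.cohort import DEFAULT_MORPHOLOGY_PARAMS, MorphologyParams

    mp = MorphologyParams(log_perimeter_mu=np.log(0.24), circ_logit_mu=0.5)
    morph = {k: mp for k in DEFAULT_MORPHOLOGY_PARAMS}
    return CohortSpec(
        n_per_group=20, count_params=params, morphology_params=morph,
        fovs_per_sample_dlim=6, fovs_per_sample_storm=2, seed=seed,
    )


def test_null_cohort_has_no_signal():
    bundle = simulate_cohort(_null_spec(314))
    res = run_cohort_analysis(bundle.fov_counts, bundle.morphology)
    for metric, r in res.roc.items():
        assert 0.3 <= r.auc <= 0.7, metric


def test_effect_cohort_orders_discriminators():
    bundle = simulate_cohort(CohortSpec(seed=2718))
    res = run_cohort_analysis(bundle.fov_counts, bundle.morphology)
    assert res.roc["combined_score"].auc >= 0.7
    assert res.roc["combined_score"].auc >= res.roc["count_abeta"].auc


def test_single_sample_per_group_rejected():
    bundle = simulate_cohort(CohortSpec(n_per_group=2, fovs_per_sample_dlim=2, fovs_per_sample_storm=1, seed=9))
    metrics = bundle.fov_counts[bundle.fov_counts["sample_id"].isin(["PD_000", "control_000"])]
    with pytest.raises(ValidationError):
        run_cohort_analysis(metrics)


def test_counts_only_mode_runs_without_morphology():
    bundle = simulate_cohort(CohortSpec(n_per_group=5, fovs_per_sample_dlim=4, fovs_per_sample_storm=1, seed=10))
    res = run_cohort_analysis(bundle.fov_counts, None)
    assert res.counts_only
    assert "ratio" in res.roc
    assert "combined_score" in res.roc  # intensity fraction stands in
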