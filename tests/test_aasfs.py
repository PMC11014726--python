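"""Age-adjusted SFS: binning, matching, Delta resampling and tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from teselect.aasfs import (AgeAdjustedSFS, assign_equal_count_age_bins,
                            delta_frequency, frequency_match_resample,
                            match_downsample_neutral, resample_delta)
from teselect.aasfs import test_delta_below_zero as delta_below_zero
from teselect.aasfs import test_oldest_vs_others as oldest_vs_others

from conftest import site_frame


# ---------------------------------------------------------------------------
# equal-count binning

@pytest.mark.parametrize("n,B,expect", [
    (10, 5, [2, 2, 2, 2, 2]),
    (11, 5, [3, 2, 2, 2, 2]),
    (7, 3, [3, 2, 2]),
])
def test_bin_counts(n, B, expect):
    binning = assign_equal_count_age_bins(np.arange(n, dtype=float), B)
    assert list(binning.per_bin_count) == expect


def test_binning_rejects_too_few_sites():
    with pytest.raises(ValueError):
        assign_equal_count_age_bins([1.0, 2.0], 3)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 20), min_size=6, max_size=60),
       st.integers(2, 6))
def test_binning_matches_stable_partition(ages, B):
    """Ties across bin boundaries follow the stable (age, id) sort order."""
    if len(ages) < B:
        return
    ages = np.asarray(ages, dtype=float)
    ids = np.array([f"v{i:03d}" for i in range(len(ages))])
    binning = assign_equal_count_age_bins(ages, B, variant_ids=ids)
    order = np.lexsort((ids, ages))
    base, rem = divmod(len(ages), B)
    counts = [base + 1] * rem + [base] * (B - rem)
    expect = np.empty(len(ages), dtype=int)
    expect[order] = np.repeat(np.arange(B), counts)
    assert np.array_equal(binning.assignment, expect)
    assert int(binning.per_bin_count.max() - binning.per_bin_count.min()) <= 1


# ---------------------------------------------------------------------------
# age-matched down-sampling

def test_matching_exact_copy_recovers_focal_age_multiset(rng):
    focal_ages = rng.gamma(2, 100, size=60)
    binning = assign_equal_count_age_bins(focal_ages, 5)
    idx, per_bin = match_downsample_neutral(binning, focal_ages.copy(), rng=1)
    assert sorted(focal_ages[idx]) == pytest.approx(sorted(focal_ages))


def test_matching_counts_always_equal_focal_counts(rng):
    focal_ages = rng.gamma(2, 100, size=57)
    pool = rng.gamma(2, 120, size=400)
    binning = assign_equal_count_age_bins(focal_ages, 5)
    _, per_bin = match_downsample_neutral(binning, pool, rng=2)
    assert [len(p) for p in per_bin] == list(binning.per_bin_count)


def test_matching_quality_ks(rng):
    """Matched neutral ages track the focal age distribution closely."""
    n_ok = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        focal = r.gamma(2, 300, size=500)
        pool = r.gamma(2, 300, size=5000)  # same age process, larger pool
        binning = assign_equal_count_age_bins(focal, 5)
        idx, _ = match_downsample_neutral(binning, pool, rng=seed)
        ks = stats.ks_2samp(focal, pool[idx]).statistic
        n_ok += ks < 0.05
    assert n_ok >= 19


def test_matching_rejects_insufficient_pool(rng):
    focal = rng.gamma(2, 100, size=50)
    binning = assign_equal_count_age_bins(focal, 5)
    with pytest.raises(ValueError):
        match_downsample_neutral(binning, rng.gamma(2, 100, size=30), rng=0)


# ---------------------------------------------------------------------------
# frequency matching (bias-control mode)

def test_frequency_match_histogram_within_one_per_stratum(rng):
    target = rng.beta(0.5, 3, size=800)
    pool = rng.uniform(0, 1, size=4000)
    idx = frequency_match_resample(pool, target, rng=3)
    edges = np.quantile(target, np.linspace(0, 1, 11))
    t_hist = np.histogram(target, bins=edges)[0] / len(target)
    p_hist = np.histogram(pool[idx], bins=edges)[0] / len(idx)
    assert np.all(np.abs(t_hist - p_hist) * len(idx) <= len(edges))
    assert len(np.unique(idx)) == len(idx)  # without replacement


def test_frequency_match_mode_off_leaves_pipeline_unchanged(neutral_site_tables):
    focal, neutral = neutral_site_tables
    res_direct = AgeAdjustedSFS(focal, neutral).fit(seed=5)
    res_off = AgeAdjustedSFS(focal, neutral, frequency_match=False).fit(seed=5)
    assert np.array_equal(res_direct.deltas, res_off.deltas)


# ---------------------------------------------------------------------------
# Delta arithmetic

def test_delta_examples_and_brute_force(rng):
    assert delta_frequency([0.1, 0.1], [0.3, 0.3]) == pytest.approx(-0.2)
    x = rng.uniform(0, 1, 37)
    assert delta_frequency(x, x) == 0.0
    a, b = rng.uniform(0, 1, 20), rng.uniform(0, 1, 31)
    assert delta_frequency(a, b) == pytest.approx(sum(a) / 20 - sum(b) / 31)
    with pytest.raises(ValueError):
        delta_frequency([], [0.1])


# ---------------------------------------------------------------------------
# resampling

def test_resample_deterministic_and_default_R(neutral_site_tables):
    focal, neutral = neutral_site_tables
    r1 = resample_delta(focal, neutral, seed=123)
    r2 = resample_delta(focal, neutral, seed=123)
    assert r1.deltas.shape == (100, 5)
    assert np.array_equal(r1.deltas, r2.deltas)
    assert np.all((r1.deltas >= -1) & (r1.deltas <= 1))


def test_resample_exact_copy_pool_gives_all_zero_deltas(rng):
    ages = rng.gamma(2, 100, size=50)
    freqs = np.full(50, 0.2)
    focal = site_frame(ages, freqs)
    res = resample_delta(focal, focal.copy(), n_bins=5, seed=1)
    assert np.all(res.deltas == 0.0)


# ---------------------------------------------------------------------------
# tests on Delta estimates

def test_below_zero_strong_signal_all_methods():
    deltas = np.tile(np.array([[-0.1, -0.12, -0.09, -0.11, -0.1]]), (100, 1))
    deltas += np.random.default_rng(0).normal(0, 1e-3, deltas.shape)
    for method in ("normal", "wilcoxon"):
        out = delta_below_zero(deltas, method=method)
        assert out["significant"].all(), method
    # quantile granularity floor: p_raw = 1/(R+1)
    out = delta_below_zero(deltas, method="quantile")
    assert np.allclose(out["p_raw"], 1 / 101)


def test_below_zero_all_zero_estimates_not_significant():
    out = delta_below_zero(np.zeros((100, 3)), method="wilcoxon")
    assert np.all(out["p_raw"] == 1.0)
    out = delta_below_zero(np.zeros((100, 3)), method="normal")
    assert not out["significant"].any()


def test_below_zero_type_I_on_symmetric_estimates():
    """Centred estimate distributions stay non-significant (default method)."""
    rng = np.random.default_rng(17)
    n_any = 0
    for _ in range(100):
        deltas = rng.normal(0, 0.02, size=(100, 5))
        out = delta_below_zero(deltas, alpha=0.01)
        n_any += out["significant"].any()
    assert n_any == 0  # doubled-variance null absorbs the centre's noise


def test_bonferroni_factor_applied():
    deltas = np.random.default_rng(2).normal(-0.05, 0.01, size=(100, 4))
    out = delta_below_zero(deltas)
    assert np.allclose(out["p_bonferroni"],
                       np.minimum(out["p_raw"] * 4, 1.0))


def test_oldest_vs_others_detects_shifted_oldest():
    rng = np.random.default_rng(3)
    deltas = rng.normal(-0.05, 0.01, size=(100, 5))
    deltas[:, -1] -= 0.25
    out = oldest_vs_others(deltas)
    assert out["significant"].all()
    assert len(out) == 4


def test_oldest_vs_others_single_comparison_for_two_bins():
    rng = np.random.default_rng(4)
    deltas = rng.normal(0, 0.01, size=(50, 2))
    deltas[:, 1] -= 0.3
    out = oldest_vs_others(deltas)
    assert len(out) == 1
    assert np.allclose(out["p_bonferroni"], out["p_raw"])


def test_oldest_vs_others_null_exchangeable_rarely_flags():
    rng = np.random.default_rng(11)
    n_flag = 0
    for _ in range(200):
        deltas = rng.normal(0, 0.02, size=(20, 5))  # replicate-mean unit
        n_flag += bool(oldest_vs_others(deltas)["significant"].all())
    assert n_flag <= 10


# ---------------------------------------------------------------------------
# model-level behaviour

def test_exchangeability_null_symmetric_deltas(neutral_site_tables):
    """Swapping focal/neutral labels mirrors the Delta distribution."""
    focal, neutral = neutral_site_tables
    res_fwd = AgeAdjustedSFS(focal, neutral.iloc[:len(focal)]).fit(seed=21)
    res_rev = AgeAdjustedSFS(neutral.iloc[:len(focal)], focal).fit(seed=21)
    m = res_fwd.deltas.mean() + res_rev.deltas.mean()
    spread = res_fwd.deltas.std() / np.sqrt(res_fwd.deltas.size)
    assert abs(m) < 6 * spread


def test_result_frame_and_summary(neutral_site_tables):
    focal, neutral = neutral_site_tables
    res = AgeAdjustedSFS(focal, neutral, n_bins=4).fit(seed=2)
    frame = res.to_frame()
    assert list(frame["n_focal"]) == list(res.binning.per_bin_count)
    assert (frame["age_min"] <= frame["age_max"]).all()
    assert "Age-adjusted SFS" in res.summary()
    assert res.deltas.shape == (100, 4)


def test_frequency_match_mode_on_runs_and_is_finite(neutral_site_tables):
    focal, neutral = neutral_site_tables
    res = AgeAdjustedSFS(focal, neutral, frequency_match=True).fit(seed=9)
    assert np.isfinite(res.deltas).all()
    assert res.deltas.shape == (100, 5)


def test_result_plot_smoke(neutral_site_tables):
    import matplotlib
    matplotlib.use("Agg")
    focal, neutral = neutral_site_tables
    ax = AgeAdjustedSFS(focal, neutral).fit(seed=3).plot()
    assert len(ax.get_xticklabels()) == 5
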