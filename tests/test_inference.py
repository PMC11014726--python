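"""Selection inference: pattern screen, r*, age quantiles, S*."""
import numpy as np
import pandas as pd
import pytest

from teselect.inference import (SelectionScan, estimate_selection_strength,
                                infer_max_neutral_ratio,
                                oldest_bin_age_quantiles,
                                pattern_reproduction_screen,
                                relative_age_difference)
from teselect.wf import SimulationConfig, simulate_grid


# ---------------------------------------------------------------------------
# r* aggregation arithmetic

def flags_frame(rows):
    return pd.DataFrame(rows, columns=["r", "S", "reproduced"])


def test_rstar_spec_aggregation_example():
    """Pattern true only at r in {0, 0.05} for 6 of 7 S values -> r* = 0.10."""
    S_grid = [-5, -8, -10, -12, -15, -20, -50]
    rows = []
    for r in (0.0, 0.05, 0.10, 0.25):
        for i, S in enumerate(S_grid):
            if i == 6:  # one S where the pattern persists everywhere
                rows.append((r, S, True))
            else:
                rows.append((r, S, r <= 0.05))
    r_star, per_r = infer_max_neutral_ratio(flags_frame(rows), exclude_S=())
    assert r_star == 0.10
    assert not per_r.loc[per_r["r"] == 0.05, "majority_failed"].item()


def test_rstar_all_flags_false_gives_smallest_r():
    rows = [(r, S, False) for r in (0.0, 0.1) for S in (-5, -10)]
    r_star, _ = infer_max_neutral_ratio(flags_frame(rows), exclude_S=())
    assert r_star == 0.0


def test_rstar_all_true_is_none_and_single_S_degenerates():
    rows = [(r, -5, True) for r in (0.0, 0.1)]
    r_star, _ = infer_max_neutral_ratio(flags_frame(rows), exclude_S=())
    assert r_star is None
    rows = [(0.0, -5, True), (0.1, -5, False)]
    r_star, _ = infer_max_neutral_ratio(flags_frame(rows), exclude_S=())
    assert r_star == 0.1


def test_rstar_excludes_effectively_neutral_S():
    rows = [(0.1, -1.0, True), (0.1, -5.0, False), (0.1, -10.0, False)]
    r_star, per_r = infer_max_neutral_ratio(flags_frame(rows))
    assert r_star == 0.1 and per_r["n_S"].item() == 2


def test_rstar_ignores_unevaluated_cells():
    rows = [(0.1, -5.0, pd.NA), (0.1, -10.0, False), (0.1, -20.0, False)]
    r_star, per_r = infer_max_neutral_ratio(flags_frame(rows))
    assert r_star == 0.1 and per_r["n_S"].item() == 2


# ---------------------------------------------------------------------------
# age quantiles and relative age difference

def test_oldest_bin_quantiles_brute_force():
    ages = np.arange(1.0, 26.0)  # 25 sites, oldest bin of 5: {21..25}
    q = oldest_bin_age_quantiles(ages, n_bins=5, q=(25, 50, 75))
    assert q[50] == np.median([21, 22, 23, 24, 25]) == 23
    assert q[25] == np.percentile([21, 22, 23, 24, 25], 25)
    assert oldest_bin_age_quantiles([10.0, 20.0, 30.0, 40.0], n_bins=2,
                                    q=(50,))[50] == pytest.approx(35.0)
    same = oldest_bin_age_quantiles([7.0] * 10, n_bins=5)
    assert set(same.values()) == {7.0}


def test_relative_age_difference_normalisation():
    rad = relative_age_difference({-1: 100.0, -10: 60.0, -50: 40.0}, obs_age=50.0)
    assert rad[-1] == pytest.approx(1.0)      # the maximum |difference|
    assert rad[-10] == pytest.approx(0.2)
    assert rad[-50] == pytest.approx(-0.2)
    assert max(abs(v) for v in rad.values()) == 1.0
    # sim == obs everywhere -> all zero
    assert set(relative_age_difference({-1: 5.0, -2: 5.0}, 5.0).values()) == {0.0}


def test_relative_age_difference_invariant_to_common_rescaling():
    sim = {-1: 120.0, -5: 80.0, -20: 30.0}
    obs = 60.0
    a = relative_age_difference(sim, obs)
    b = relative_age_difference({k: 7.5 * v for k, v in sim.items()}, 7.5 * obs)
    for k in sim:
        assert a[k] == pytest.approx(b[k])


def test_estimate_selection_strength_self_consistency(rng):
    """Matching a cell's own ages recovers that cell's S exactly."""
    grid_ages = {S: rng.gamma(2.0, 50.0 / (1 + abs(S) / 5), size=400)
                 for S in (-1.0, -5.0, -10.0, -20.0)}
    s_star, table = estimate_selection_strength(grid_ages[-5.0], grid_ages)
    assert s_star == (-5.0,)
    assert table.loc[table["is_best"], "relative_age_difference"].abs().max() == 0.0


# ---------------------------------------------------------------------------
# screen on constructed and simulated data

def _toy_cell(rng, n_reps, shift_oldest=0.0, n_sites=120):
    """Synthetic replicate site tables with a controllable oldest-bin deficit."""
    reps = []
    for _ in range(n_reps):
        ages = rng.gamma(2.0, 200.0, size=n_sites)
        freq = rng.uniform(0.02, 0.6, size=n_sites)
        order = np.argsort(ages)
        f = freq.copy()
        f[order[-n_sites // 5:]] += shift_oldest
        focal = pd.DataFrame({"age": ages, "sample_frequency": np.clip(f, 0.01, 0.99),
                              "mut_class": "focal_selected"})
        neutral = pd.DataFrame({
            "age": rng.gamma(2.0, 200.0, size=5 * n_sites),
            "sample_frequency": rng.uniform(0.02, 0.6, size=5 * n_sites),
            "mut_class": "neutral_marker"})
        reps.append(pd.concat([focal, neutral], ignore_index=True))
    return reps


def test_screen_flags_shifted_oldest_bin(rng):
    grid = {(0.0, -10.0): _toy_cell(rng, 10, shift_oldest=-0.35),
            (0.5, -10.0): _toy_cell(rng, 10, shift_oldest=0.0)}
    flags = pattern_reproduction_screen(grid, seed=1)
    by_cell = flags.set_index(["r", "S"])["reproduced"]
    assert bool(by_cell.loc[(0.0, -10.0)]) is True
    assert bool(by_cell.loc[(0.5, -10.0)]) is False


def test_screen_marks_underpowered_cells_not_evaluated(rng):
    grid = {(0.0, -5.0): _toy_cell(rng, 1)}
    flags = pattern_reproduction_screen(grid, seed=2)
    assert flags["reproduced"].isna().all()
    assert flags["n_replicates_used"].item() == 1


def test_scan_end_to_end_on_small_simulated_grid():
    """Strong selection with r=0 reproduces the pattern; r=1 does not."""
    cfg = SimulationConfig(N=300, L=20_000, mu_neutral=5e-6, mu_focal=2.5e-6,
                           n_generations=3000, n_replicates=8, sample_size=40,
                           seed=11)
    grid = simulate_grid([0.0, 1.0], [-10.0, -20.0], cfg)
    observed = pd.concat([
        s.sites[s.sites["mut_class"] != "neutral_marker"]
        for s in grid[(0.0, -20.0)]])
    scan = SelectionScan(grid, observed=observed, n_resamples=50)
    res = scan.fit(seed=5)
    by_cell = res.flags.set_index(["r", "S"])["reproduced"]
    assert bool(by_cell.loc[(0.0, -10.0)]) and bool(by_cell.loc[(0.0, -20.0)])
    assert res.r_star == 1.0
    # observed data came from the S=-20 cell of the same grid
    assert -20.0 in res.s_star
    assert "r*" in res.summary()


def test_screen_pooled_estimates_unit(rng):
    grid = {(0.0, -10.0): _toy_cell(rng, 6, shift_oldest=-0.35)}
    flags = pattern_reproduction_screen(grid, seed=3, unit="pooled_estimates")
    assert bool(flags["reproduced"].item()) is True
    with pytest.raises(ValueError):
        pattern_reproduction_screen(grid, unit="bogus")


def test_scan_replicatewise_age_quantiles(rng):
    import matplotlib
    matplotlib.use("Agg")
    grid = {(0.0, -5.0): _toy_cell(rng, 6, shift_oldest=-0.1),
            (0.0, -20.0): _toy_cell(rng, 6, shift_oldest=-0.3, n_sites=60)}
    obs = grid[(0.0, -5.0)][0]
    obs = obs[obs["mut_class"] != "neutral_marker"]
    res = SelectionScan(grid, observed=obs, n_resamples=20,
                        pooled_ages=False).fit(seed=8)
    assert res.s_star is not None and len(res.rad_table) == 6
    axes = res.plot()
    assert len(np.atleast_1d(axes)) == 3
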