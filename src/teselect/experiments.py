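"""Composed experiments at the desk-scale study conditions.

These functions wire the forward simulator to the selection-inference
machinery at the default desk-scale conditions (N = 1,000 diploids on a
100 kb fragment, selfing rate 0.7, codominance, 20 replicates per grid
cell, 5 equal-count age bins, 100 matched resamples) and are what the
reproduction script and the acceptance tests run.
"""
from __future__ import annotations

import numpy as np

from .inference import SelectionScan, SelectionScanResult
from .wf import SimulationConfig, run_wf_simulation, simulate_grid

__all__ = [
    "DEFAULT_R_GRID",
    "DEFAULT_S_GRID",
    "desk_scale_config",
    "neutral_ratio_screen",
    "selection_strength_recovery",
]

#: simulated neutral-mutation ratios (fractions)
DEFAULT_R_GRID = (0.0, 0.05, 0.10, 0.25, 0.50)
#: scaled selection coefficients; the effectively neutral S = -1 is run
#: separately where needed and excluded from the r* majority vote
DEFAULT_S_GRID = (-5.0, -8.0, -10.0, -12.0, -15.0, -20.0, -50.0)


def desk_scale_config(seed=0, **overrides) -> SimulationConfig:
    """The default desk-scale simulation configuration."""
    return SimulationConfig(seed=seed, **overrides)


def neutral_ratio_screen(seed=0, r_grid=DEFAULT_R_GRID, S_grid=DEFAULT_S_GRID,
                         config=None, n_bins=5, n_resamples=100, alpha=0.01,
                         ) -> SelectionScanResult:
    """Simulate the full (r, S) grid and infer the maximum neutral ratio r*.

    Every cell runs 20 forward replicates; each replicate's age-adjusted
    SFS is computed and the oldest-bin pattern tested per cell; r* is the
    smallest grid r at which the pattern fails for a majority of S values.
    """
    cfg = (config or desk_scale_config()).replace(seed=int(seed))
    grid = simulate_grid(r_grid, S_grid, cfg)
    scan = SelectionScan(grid, n_bins=n_bins, n_resamples=n_resamples,
                         alpha=alpha)
    return scan.fit(seed=int(seed) + 1)


def selection_strength_recovery(seed=0, S_true=-8.0, S_grid=DEFAULT_S_GRID,
                                n_trials=10, config=None, n_bins=5,
                                trial_replicates=2):
    """Parameter-recovery experiment for the S* estimator.

    A reference grid is simulated at r = 0; ``n_trials`` independent
    held-out datasets simulated at ``S_true`` are then matched against it.
    Returns the list of per-trial S* tuples and the reference scan result.
    """
    cfg = (config or desk_scale_config()).replace(seed=int(seed))
    grid = simulate_grid([0.0], S_grid, cfg)
    rng = np.random.default_rng(seed)
    estimates = []
    scan = SelectionScan(grid, observed=None, n_bins=n_bins)
    grid_ages = scan._grid_ages()
    from .inference import estimate_selection_strength

    for _ in range(n_trials):
        trial_cfg = cfg.replace(seed=int(rng.integers(2**31 - 1)),
                                neutral_ratio_r=0.0, scaled_S=float(S_true),
                                n_replicates=trial_replicates)
        obs = run_wf_simulation(trial_cfg)
        ages = np.concatenate([
            s.sites.loc[s.sites["mut_class"] != "neutral_marker", "age"]
            .to_numpy(dtype=float) for s in obs])
        if len(ages) < n_bins:
            continue
        s_star, _ = estimate_selection_strength(ages, grid_ages, n_bins=n_bins)
        estimates.append(s_star)
    return estimates, grid
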