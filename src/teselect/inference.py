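"""Inference of the neutral ratio r* and selection strength S* from grids.

Two procedures are built on top of forward-simulation grids over the
neutral ratio r (fraction of focal mutations evolving neutrally) and the
scaled selection coefficient S = Ne*s:

1. *Pattern-reproduction screen*: for every (r, S) cell, does the
   simulated age-adjusted SFS reproduce the empirical pattern of the
   oldest age bin's Delta frequency lying significantly below all other
   bins?  The screen aggregates over the S grid to find r*, the smallest
   simulated neutral ratio at which the pattern is no longer reproduced
   for a majority of selection strengths: the data are then compatible
   only with neutral ratios below r*.

2. *Selection-strength estimation*: the oldest surviving mutations are
   younger under stronger purifying selection, so the age quantiles (25,
   50, 75%) of the oldest age bin discriminate S.  For each quantile the
   relative age difference (simulated minus observed, normalised by the
   maximum absolute difference across the S grid) is computed and S* is
   the grid value minimising its magnitude, with a consensus over
   quantiles (ties reported as a set).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aasfs import (AgeAdjustedSFS, assign_equal_count_age_bins,
                    test_oldest_vs_others)
from .wf import SimulatedSample

logger = logging.getLogger(__name__)

__all__ = [
    "pattern_reproduction_screen",
    "infer_max_neutral_ratio",
    "oldest_bin_age_quantiles",
    "relative_age_difference",
    "estimate_selection_strength",
    "SelectionScan",
    "SelectionScanResult",
]

FOCAL_CLASSES = ("focal_neutral", "focal_selected")


def _replicate_frames(cell) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Split one grid cell into per-replicate (focal, neutral) site tables."""
    if isinstance(cell, pd.DataFrame):
        reps = [g for _, g in cell.groupby("replicate", sort=True)]
        frames = reps
    else:
        frames = [s.sites if isinstance(s, SimulatedSample) else s for s in cell]
    out = []
    for df in frames:
        if "sample_frequency" not in df.columns and "derived_freq" in df.columns:
            df = df.rename(columns={"derived_freq": "sample_frequency"})
        is_focal = df["mut_class"].isin(FOCAL_CLASSES).to_numpy()
        out.append((df.loc[is_focal], df.loc[~is_focal]))
    return out


def pattern_reproduction_screen(grid_samples: Mapping, n_bins=5, n_resamples=100,
                                alpha=0.01, seed=None, unit="replicate",
                                freq_col="sample_frequency", age_col="age",
                                ) -> pd.DataFrame:
    """Evaluate the oldest-bin pattern for every (r, S) grid cell.

    Each replicate's age-adjusted SFS is computed separately; with
    ``unit="replicate"`` (default) every replicate contributes its mean
    Delta per bin and the rank-sum test runs on the per-replicate means,
    so the test's unit of variation is the simulation ensemble.  With
    ``unit="pooled_estimates"`` all resampling estimates of all replicates
    are pooled before testing (higher power, anti-conservative).  Cells
    with fewer than two usable replicates are flagged not-evaluated
    (``reproduced`` = NA).
    """
    if unit not in ("replicate", "pooled_estimates"):
        raise ValueError(f"unknown unit: {unit!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for (r, S), cell in sorted(grid_samples.items()):
        mats = []
        n_focal = 0
        for focal, neutral in _replicate_frames(cell):
            if len(focal) < n_bins or len(neutral) < len(focal):
                continue
            res = AgeAdjustedSFS(
                focal, neutral, n_bins=n_bins, n_resamples=n_resamples,
                freq_col=freq_col, age_col=age_col, min_focal_per_bin=0,
            ).fit(seed=int(rng.integers(2**31 - 1)))
            n_focal += len(focal)
            mats.append(res.delta_mean if unit == "replicate" else res.deltas)
        if len(mats) < 2:
            rows.append({"r": r, "S": S, "reproduced": pd.NA,
                         "n_replicates_used": len(mats), "n_focal": n_focal})
            logger.warning("cell (r=%s, S=%s): %d usable replicates; not evaluated",
                           r, S, len(mats))
            continue
        deltas = np.vstack(mats)
        flag = bool(test_oldest_vs_others(deltas, alpha=alpha)["significant"].all())
        rows.append({"r": r, "S": S, "reproduced": flag,
                     "n_replicates_used": len(mats), "n_focal": n_focal})
    return pd.DataFrame(rows)


def infer_max_neutral_ratio(flags: pd.DataFrame, exclude_S=(-1.0,)) -> tuple:
    """Aggregate per-cell flags into r*, the inferred maximum neutral ratio.

    For each selection strength S the largest r still reproducing the
    pattern is reported; r* is the smallest grid r at which the pattern
    fails for a strict majority of the S values (the effectively neutral
    S values in ``exclude_S`` are left out of the vote).  Returns
    ``(r_star, per_r_table)``; r_star is None (with a warning) when the
    pattern is reproduced everywhere.
    """
    use = flags[~flags["S"].isin(exclude_S) & flags["reproduced"].notna()]
    if use.empty:
        raise ValueError("no evaluated cells after exclusions")
    per_r = []
    for r, grp in use.groupby("r", sort=True):
        n_false = int((~grp["reproduced"].astype(bool)).sum())
        per_r.append({"r": r, "n_S": len(grp), "n_not_reproduced": n_false,
                      "majority_failed": n_false > len(grp) / 2})
    per_r = pd.DataFrame(per_r)
    failed = per_r.loc[per_r["majority_failed"], "r"]
    if failed.empty:
        logger.warning("pattern reproduced at every neutral ratio; r* undefined")
        return None, per_r
    return float(failed.min()), per_r


def oldest_bin_age_quantiles(ages, n_bins=5, q=(25, 50, 75)) -> dict[int, float]:
    """Empirical age quantiles (linear interpolation) of the oldest age bin."""
    ages = np.asarray(ages, dtype=float)
    binning = assign_equal_count_age_bins(ages, n_bins)
    oldest = ages[binning.assignment == n_bins - 1]
    if len(oldest) == 0:
        raise ValueError("oldest age bin is empty")
    return {int(qq): float(np.percentile(oldest, qq)) for qq in q}


def relative_age_difference(sim_ages: Mapping[float, float], obs_age: float,
                            max_abs_difference: float | None = None,
                            ) -> dict[float, float]:
    """(simulated - observed) age, normalised by the maximum |difference|.

    ``sim_ages`` maps each grid S to its simulated age quantile.  The
    normalisation constant defaults to max_S |sim_S - obs| over the grid,
    so exactly one S attains |value| = 1 (barring ties) and the result
    lies in [-1, 1].  If every simulated age equals the observed age the
    differences are all 0.
    """
    diffs = {S: sim - obs_age for S, sim in sim_ages.items()}
    max_abs = (max(abs(d) for d in diffs.values())
               if max_abs_difference is None else float(max_abs_difference))
    if max_abs == 0.0:
        return {S: 0.0 for S in diffs}
    if max_abs < 0:
        raise ValueError("max_abs_difference must be > 0")
    return {S: d / max_abs for S, d in diffs.items()}


def estimate_selection_strength(observed_ages, grid_ages: Mapping[float, np.ndarray],
                                q_set=(25, 50, 75), n_bins=5,
                                ) -> tuple[tuple, pd.DataFrame]:
    """Match oldest-bin age quantiles of observed data against an S grid.

    ``grid_ages`` maps each S to the (pooled) focal ages simulated under
    that S.  Returns ``(S_star, table)`` where the table holds the
    relative age difference per (S, quantile) and S_star is the consensus
    (modal) minimiser across quantiles, ties reported as a tuple.
    """
    if len(grid_ages) < 2:
        raise ValueError("grid must cover at least two S values")
    obs_q = oldest_bin_age_quantiles(observed_ages, n_bins=n_bins, q=q_set)
    sim_q = {S: oldest_bin_age_quantiles(a, n_bins=n_bins, q=q_set)
             for S, a in grid_ages.items()}
    rows = []
    best_per_q = {}
    for qq in q_set:
        rad = relative_age_difference({S: sim_q[S][qq] for S in sim_q}, obs_q[qq])
        best = min(rad, key=lambda S: (abs(rad[S]), S))
        best_per_q[qq] = best
        for S, v in sorted(rad.items()):
            rows.append({"quantile": qq, "S": S, "relative_age_difference": v,
                         "sim_age": sim_q[S][qq], "obs_age": obs_q[qq],
                         "is_best": S == best})
    votes = pd.Series(list(best_per_q.values())).value_counts()
    top = votes[votes == votes.max()]
    s_star = tuple(sorted(top.index))
    return s_star, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results

class SelectionScan:
    """Grid-based selection inference (statsmodels-style model object).

    Parameters
    ----------
    grid_samples : mapping
        ``{(r, S): [SimulatedSample or DataFrame, ...]}`` simulation grid.
    observed : DataFrame, optional
        Observed focal site table with an ``age`` column (true ages for
        synthetic data, estimated ages for real data).  When given, S* is
        estimated from the oldest-bin age quantiles.
    exclude_S : sequence
        S values treated as effectively neutral and excluded from the
        majority vote for r* (default: -1).
    r_for_ages : float, optional
        Which r row of the grid provides the age-quantile reference for
        S* (default: the smallest r in the grid).
    pooled_ages : bool
        Pool replicate ages per S (default) or average per-replicate
        quantiles.
    """

    def __init__(self, grid_samples: Mapping, observed: pd.DataFrame | None = None,
                 n_bins=5, n_resamples=100, alpha=0.01, quantiles=(25, 50, 75),
                 exclude_S=(-1.0,), screen_unit="replicate", r_for_ages=None,
                 pooled_ages=True, observed_age_col="age"):
        if not grid_samples:
            raise ValueError("grid_samples is empty")
        self.grid_samples = dict(grid_samples)
        self.observed = observed
        self.n_bins = int(n_bins)
        self.n_resamples = int(n_resamples)
        self.alpha = float(alpha)
        self.quantiles = tuple(quantiles)
        self.exclude_S = tuple(exclude_S)
        self.screen_unit = screen_unit
        self.r_grid = sorted({k[0] for k in self.grid_samples})
        self.S_grid = sorted({k[1] for k in self.grid_samples})
        self.r_for_ages = self.r_grid[0] if r_for_ages is None else float(r_for_ages)
        self.pooled_ages = bool(pooled_ages)
        self.observed_age_col = observed_age_col

    def _grid_ages(self) -> dict[float, np.ndarray]:
        out = {}
        for S in self.S_grid:
            cell = self.grid_samples.get((self.r_for_ages, S))
            if cell is None:
                continue
            if self.pooled_ages:
                ages = np.concatenate([
                    f["age"].to_numpy(dtype=float)
                    for f, _ in _replicate_frames(cell) if len(f)])
                out[S] = ages
            else:
                # represent each S by per-replicate quantile means: encode by
                # concatenating replicate oldest-bin ages weighted equally
                per_rep = [f["age"].to_numpy(dtype=float)
                           for f, _ in _replicate_frames(cell)
                           if len(f) >= self.n_bins]
                out[S] = per_rep
        return out

    def fit(self, seed=None) -> "SelectionScanResult":
        flags = pattern_reproduction_screen(
            self.grid_samples, n_bins=self.n_bins, n_resamples=self.n_resamples,
            alpha=self.alpha, seed=seed, unit=self.screen_unit)
        r_star, per_r = infer_max_neutral_ratio(flags, exclude_S=self.exclude_S)
        s_star = None
        rad_table = None
        obs_q = None
        if self.observed is not None:
            obs_ages = np.asarray(
                self.observed[self.observed_age_col], dtype=float)
            grid_ages = self._grid_ages()
            if not self.pooled_ages:
                # per-replicate quantiles averaged, then matched
                sim_q = {
                    S: {qq: float(np.mean([
                        oldest_bin_age_quantiles(a, self.n_bins, (qq,))[qq]
                        for a in reps]))
                        for qq in self.quantiles}
                    for S, reps in grid_ages.items() if len(reps) > 0}
                obs_q = oldest_bin_age_quantiles(obs_ages, self.n_bins,
                                                 self.quantiles)
                rows = []
                best_per_q = {}
                for qq in self.quantiles:
                    rad = relative_age_difference(
                        {S: sim_q[S][qq] for S in sim_q}, obs_q[qq])
                    best = min(rad, key=lambda S: (abs(rad[S]), S))
                    best_per_q[qq] = best
                    rows += [{"quantile": qq, "S": S,
                              "relative_age_difference": v,
                              "sim_age": sim_q[S][qq], "obs_age": obs_q[qq],
                              "is_best": S == best}
                             for S, v in sorted(rad.items())]
                votes = pd.Series(list(best_per_q.values())).value_counts()
                s_star = tuple(sorted(votes[votes == votes.max()].index))
                rad_table = pd.DataFrame(rows)
            else:
                s_star, rad_table = estimate_selection_strength(
                    obs_ages, grid_ages, q_set=self.quantiles,
                    n_bins=self.n_bins)
            obs_q = oldest_bin_age_quantiles(obs_ages, self.n_bins,
                                             self.quantiles)
        return SelectionScanResult(
            model=self, flags=flags, r_star=r_star, per_r=per_r,
            s_star=s_star, rad_table=rad_table, observed_quantiles=obs_q)


@dataclass
class SelectionScanResult:
    """Results of a :class:`SelectionScan` fit."""

    model: SelectionScan
    #: per-(r, S) pattern-reproduction flags
    flags: pd.DataFrame
    #: inferred maximum neutral ratio (None if never failed)
    r_star: float | None
    per_r: pd.DataFrame
    #: consensus grid S minimising |relative age difference| (tuple; None
    #: when no observed data were supplied)
    s_star: tuple | None = None
    rad_table: pd.DataFrame | None = None
    observed_quantiles: dict | None = None

    def flag_matrix(self) -> pd.DataFrame:
        return self.flags.pivot(index="S", columns="r", values="reproduced")

    def summary(self) -> str:
        lines = ["Selection scan", "==============",
                 "pattern reproduced per (S, r):",
                 self.flag_matrix().to_string()]
        if self.r_star is None:
            lines.append("r*: not reached (pattern reproduced at every r)")
        else:
            lines.append(f"r* (maximum neutral ratio): {self.r_star:g} "
                         f"({100 * self.r_star:g}%)")
        if self.s_star is not None:
            lines.append(
                "S* per oldest-bin age quantile "
                f"(consensus): {', '.join(f'{s:g}' for s in self.s_star)}")
            best = self.rad_table[self.rad_table["is_best"]]
            lines.append(best.to_string(index=False,
                                        float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar chart of relative age differences per S, one panel per quantile."""
        import matplotlib.pyplot as plt

        if self.rad_table is None:
            raise ValueError("no observed data: nothing to plot")
        qs = sorted(self.rad_table["quantile"].unique())
        if ax is None:
            _, axes = plt.subplots(1, len(qs), figsize=(4 * len(qs), 3.5),
                                   sharey=True)
        else:
            axes = np.atleast_1d(ax)
        for a, qq in zip(np.atleast_1d(axes), qs):
            sub = self.rad_table[self.rad_table["quantile"] == qq]
            a.bar([f"{s:g}" for s in sub["S"]], sub["relative_age_difference"])
            a.axhline(0, color="0.3", lw=0.8)
            a.set_title(f"{qq}% quantile")
            a.set_xlabel("scaled selection coefficient S")
        np.atleast_1d(axes)[0].set_ylabel("relative age difference")
        return axes
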