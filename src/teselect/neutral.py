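"""Neutral age-frequency theory and the age-estimate sanity check.

Under the neutral infinite-sites model the expected age of a derived
allele currently segregating at population frequency x is the Kimura &
Ohta (1973, "The age of a neutral mutant persisting in a finite
population", Genetics 75) mean

    t_bar(x) = -4 * Ne * x * ln(x) / (1 - x)   generations,

which increases monotonically from 0 (as x -> 0) to 4*Ne (as x -> 1).
Older alleles therefore sit at higher frequencies on average, and a set
of putatively neutral variants with estimated ages can be checked against
this prediction: a positive age-frequency rank correlation is the
qualitative signature of sane age estimates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "expected_neutral_age",
    "effective_population_size",
    "age_frequency_sanity_check",
    "SanityCheckReport",
]


def expected_neutral_age(x, Ne):
    """Kimura-Ohta mean age (generations) of a neutral allele at frequency x.

    Parameters
    ----------
    x : float or array-like
        Current derived-allele frequency, strictly inside (0, 1).
    Ne : float
        Effective population size (use the selfing-adjusted size for a
        partially selfing population, see :func:`effective_population_size`).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0) or np.any(x >= 1.0):
        raise ValueError("frequencies must lie strictly in (0, 1)")
    if Ne < 1:
        raise ValueError("Ne must be >= 1")
    out = -4.0 * Ne * x * np.log(x) / (1.0 - x)
    return float(out) if out.ndim == 0 else out


def effective_population_size(N, selfing_rate=0.0):
    """Inbreeding-effective size of a partially selfing population.

    At equilibrium the inbreeding coefficient is F = sigma/(2-sigma) and
    Ne = N/(1+F) = N*(2-sigma)/2.
    """
    if not 0.0 <= selfing_rate <= 1.0:
        raise ValueError("selfing_rate must be in [0, 1]")
    return N * (2.0 - selfing_rate) / 2.0


@dataclass
class SanityCheckReport:
    """Outcome of the age-frequency sanity check on neutral sites."""

    table: pd.DataFrame
    spearman_rho: float
    spearman_p: float
    verdict: str  # "pass" or "warn"
    n_sites: int
    Ne: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"Age-frequency sanity check on {self.n_sites} neutral sites (Ne={self.Ne:g})",
            f"Spearman rho = {self.spearman_rho:.3f} (p = {self.spearman_p:.2e})"
            f" -> {self.verdict.upper()}",
            self.table.to_string(index=False, float_format=lambda v: f"{v:.1f}"),
        ]
        return "\n".join(lines)


def age_frequency_sanity_check(frequencies, ages, Ne, n_freq_bins=8,
                               min_sites=100, alpha=0.01) -> SanityCheckReport:
    """Compare observed ages of neutral sites with the Kimura-Ohta curve.

    Sites are binned by frequency; the report lists the mean observed age
    and the theoretical expectation per bin.  The verdict is "pass" when
    the Spearman rank correlation between age and frequency is positive
    and significant at ``alpha`` (older alleles at higher frequencies),
    and "warn" otherwise.
    """
    freqs = np.asarray(frequencies, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if freqs.shape != ages.shape:
        raise ValueError("frequencies and ages must have equal length")
    if len(freqs) < min_sites:
        raise ValueError(
            f"need at least {min_sites} age-annotated neutral sites, got {len(freqs)}")
    rho, pval = stats.spearmanr(ages, freqs)
    edges = np.linspace(0.0, 1.0, n_freq_bins + 1)
    idx = np.clip(np.digitize(freqs, edges[1:-1]), 0, n_freq_bins - 1)
    rows = []
    for b in range(n_freq_bins):
        m = idx == b
        if not m.any():
            continue
        mid = freqs[m].mean()
        rows.append({
            "freq_lo": edges[b],
            "freq_hi": edges[b + 1],
            "n": int(m.sum()),
            "mean_age_obs": ages[m].mean(),
            "mean_age_theory": expected_neutral_age(np.clip(mid, 1e-9, 1 - 1e-9), Ne),
        })
    verdict = "pass" if (rho > 0 and pval < alpha) else "warn"
    return SanityCheckReport(table=pd.DataFrame(rows), spearman_rho=float(rho),
                             spearman_p=float(pval), verdict=verdict,
                             n_sites=len(freqs), Ne=float(Ne))
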