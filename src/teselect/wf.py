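"""Forward Wright-Fisher simulation of a partially selfing diploid population.

The simulator tracks two mutation streams on a genomic fragment: *neutral
markers* (the stand-in for synonymous SNPs) and *focal* mutations (the
stand-in for TE insertions), the latter a mixture of neutrally evolving
mutations (probability ``neutral_ratio_r``) and mutations under constant
purifying selection with scaled coefficient ``scaled_S`` = Ne*s.  Every
mutation's origin generation is recorded so that its age (sampling
generation minus origin generation) is known exactly at sampling time.

Mating follows partial self-fertilisation: each offspring is produced by
selfing with probability ``selfing_rate`` (sigma) and by random outcrossing
otherwise, with parents drawn proportionally to genotype fitness
(1, 1+h*s, 1+s for the zero/one/two-copy genotypes).  Because the fragment
is simulated in the high-recombination regime the paper's method assumes
(population-scaled recombination >> 1, multiplicative fitness across loci),
loci evolve as exchangeable single-locus diploid Wright-Fisher processes:
each mutation follows the exact marginal genotype-count recursion under
partial selfing, independently of the others.  The per-bp recombination
rate is carried in the configuration (and transformed by
:func:`rescale_config`) but does not enter the per-locus dynamics.

The engine is validated against closed-form results: the equilibrium
inbreeding coefficient F = sigma/(2-sigma), the neutral fixation
probability 1/(2N), and the Kimura-Ohta mean age of a neutral allele
segregating at frequency x, -4*Ne*x*ln(x)/(1-x).
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "SimulationConfig",
    "SimulatedSample",
    "run_wf_simulation",
    "rescale_config",
    "simulate_grid",
    "MUT_CLASSES",
]

#: integer codes used by the kernel -> mutation class labels
MUT_CLASSES = ("neutral_marker", "focal_neutral", "focal_selected")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one forward-simulation scenario.

    Defaults are the desk-scale configuration: N = 1,000 diploids on a
    100 kb fragment, obtained by lambda = 10 rescaling of an N = 10,000 /
    1 Mb population (rescaling preserves the scaled selection coefficient
    S = Ne*s and the population-scaled mutation input).  The selfing rate
    0.7 and codominance h = 0.5 reflect a highly selfing annual plant.
    """

    N: int = 1000
    L: int = 100_000
    #: per-bp per-generation rate of neutral marker mutations
    mu_neutral: float = 2.0e-7
    #: per-bp per-generation rate of focal (TE-like) mutations
    mu_focal: float = 1.8e-7
    #: per-bp per-generation recombination rate (metadata; see module docs)
    rho: float = 7.0e-7
    selfing_rate: float = 0.7
    #: fraction of focal mutations that evolve neutrally
    neutral_ratio_r: float = 0.0
    #: scaled selection coefficient Ne*s of selected focal mutations (<= 0)
    scaled_S: float = 0.0
    dominance_h: float = 0.5
    #: total generations simulated; None means 10*N
    n_generations: int | None = None
    #: stop introducing new mutations after this generation (None = never)
    mutation_stop_generation: int | None = None
    n_replicates: int = 20
    #: diploid individuals drawn at the sampling generation
    sample_size: int = 50
    seed: int = 0
    #: cumulative rescaling factor lambda applied so far (bookkeeping)
    rescale_factor: float = 1.0
    #: population-size changes as (generation, new_N) pairs
    demography: tuple[tuple[int, int], ...] = ()
    #: which Ne converts scaled_S to s: "census" (N) or "selfing_adjusted"
    #: (N*(2-sigma)/2, the equilibrium inbreeding-effective size)
    ne_for_s: str = "census"

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        for name in ("mu_neutral", "mu_focal", "rho"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValueError("selfing_rate must be in [0, 1]")
        if not 0.0 <= self.neutral_ratio_r <= 1.0:
            raise ValueError("neutral_ratio_r must be in [0, 1]")
        if self.scaled_S > 0:
            raise ValueError("scaled_S must be <= 0 (purifying selection)")
        if self.sample_size > self.N:
            raise ValueError("sample_size cannot exceed N")
        if self.ne_for_s not in ("census", "selfing_adjusted"):
            raise ValueError("ne_for_s must be 'census' or 'selfing_adjusted'")
        for gen, new_n in self.demography:
            if new_n <= 0:
                raise ValueError(f"demography: non-positive N={new_n} at generation {gen}")

    @property
    def total_generations(self) -> int:
        return int(self.n_generations) if self.n_generations is not None else 10 * self.N

    @property
    def U_neutral(self) -> float:
        """Neutral-marker mutations per gamete per generation."""
        return self.mu_neutral * self.L

    @property
    def U_focal(self) -> float:
        """Focal mutations per gamete per generation."""
        return self.mu_focal * self.L

    @property
    def selection_ne(self) -> float:
        if self.ne_for_s == "selfing_adjusted":
            return self.N * (2.0 - self.selfing_rate) / 2.0
        return float(self.N)

    @property
    def s(self) -> float:
        """Per-generation selection coefficient of selected focal mutations."""
        return self.scaled_S / self.selection_ne

    def size_history(self) -> np.ndarray:
        """Population size per generation, index 0 .. total_generations."""
        T = self.total_generations
        sizes = np.full(T + 1, self.N, dtype=np.int32)
        for gen, new_n in sorted(self.demography):
            if gen <= T:
                sizes[gen:] = new_n
        return sizes

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["demography"] = [list(x) for x in self.demography]
        return d


@dataclass
class SimulatedSample:
    """Segregating mutations observed in one sampled replicate.

    ``sites`` has one row per mutation segregating in the sample with
    columns ``position``, ``origin_generation``, ``age``, ``mut_class``,
    ``s``, ``sample_frequency``, ``pop_frequency``, ``pop_n_hom``,
    ``pop_n_het``.
    """

    sites: pd.DataFrame
    replicate: int
    seed: int
    config: SimulationConfig
    #: mutations introduced, per class
    n_introduced: Mapping[str, int] = field(default_factory=dict)
    #: mutations fixed by the sampling generation, per class
    n_fixed: Mapping[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sites)


@njit(inline="always")
def _binom(n, p):
    """Exact binomial for small/moderate means; normal tail for large ones.

    Inversion is exact and O(n*p); numpy's generator is exact elsewhere.
    When n*p*(1-p) > 36 a continuity-corrected normal draw (matched mean
    and variance, clamped to [0, n]) stands in; at that scale the CDF error
    is far below the drift noise it feeds.
    """
    if p <= 0.0 or n <= 0:
        return 0
    if p >= 1.0:
        return n
    mean = n * p
    if mean < 12.0:
        q = 1.0 - p
        ratio = p / q
        r = math.exp(n * math.log(q))
        u = np.random.random()
        x = 0
        a = (n + 1) * ratio
        while u > r:
            u -= r
            x += 1
            if x > n:
                x = n
                break
            r *= (a / x - ratio)
        return x
    var = mean * (1.0 - p)
    if var > 36.0:
        x = int(np.random.normal(mean, math.sqrt(var)) + 0.5)
        if x < 0:
            x = 0
        elif x > n:
            x = n
        return x
    return np.random.binomial(n, p)


@njit(cache=True)
def _simulate_replicate(seed, size_history, T, T_mut, U_total, p_focal, r, s_sel,
                        h, sigma, max_out):
    """Simulate every mutation of one replicate from origin to sampling.

    Returns population genotype counts (homozygous carriers, heterozygous
    carriers) at generation T for each still-segregating mutation, its age
    and class code, plus per-class introduced/fixed counters.
    """
    np.random.seed(seed)
    out_hom = np.empty(max_out, np.int32)
    out_het = np.empty(max_out, np.int32)
    out_age = np.empty(max_out, np.int32)
    out_cls = np.empty(max_out, np.int8)
    n_out = 0
    n_intro = np.zeros(3, np.int64)
    n_fixed = np.zeros(3, np.int64)
    om_sigma = 1.0 - sigma
    for g0 in range(T_mut):
        lam = 2.0 * size_history[g0] * U_total
        n_new = np.random.poisson(lam)
        for _ in range(n_new):
            if np.random.random() < p_focal:
                if np.random.random() < r:
                    cls = 1
                    s = 0.0
                else:
                    cls = 2
                    s = s_sel
            else:
                cls = 0
                s = 0.0
            n_intro[cls] += 1
            w_hom = 1.0 + s
            w_het = 1.0 + h * s
            n_hom = 0
            n_het = 1
            alive = True
            fixed = False
            for g in range(g0, T):
                Nc = size_history[g]
                Nn = size_history[g + 1]
                a_hom = n_hom * w_hom
                a_het = n_het * w_het
                W = a_hom + a_het + (Nc - n_hom - n_het)
                f_hom = a_hom / W
                f_het = a_het / W
                # allele frequency in the fitness-weighted gamete pool
                p_gam = (a_hom + 0.5 * a_het) / W
                pi_hom = sigma * (f_hom + 0.25 * f_het) + om_sigma * p_gam * p_gam
                pi_het = (sigma * 0.5 * f_het
                          + om_sigma * 2.0 * p_gam * (1.0 - p_gam))
                if pi_hom >= 1.0:
                    n_hom = Nn
                else:
                    n_hom = _binom(Nn, pi_hom)
                rem = 1.0 - pi_hom
                nrem = Nn - n_hom
                if nrem > 0 and rem > 1e-300:
                    p1 = pi_het / rem
                    n_het = nrem if p1 >= 1.0 else _binom(nrem, p1)
                else:
                    n_het = 0
                if n_hom + n_het == 0:
                    alive = False
                    break
                if n_hom == Nn:
                    fixed = True
                    n_fixed[cls] += 1
                    break
            if alive and not fixed and n_out < max_out:
                out_hom[n_out] = n_hom
                out_het[n_out] = n_het
                out_age[n_out] = T - g0
                out_cls[n_out] = cls
                n_out += 1
    return (out_hom[:n_out], out_het[:n_out], out_age[:n_out], out_cls[:n_out],
            n_intro, n_fixed)


def _replicate_seed(master_seed: int, *key) -> int:
    """Deterministic 31-bit seed derived from a master seed and a key."""
    ss = np.random.SeedSequence([int(master_seed) % 2**32]
                                + [int(k) % 2**32 for k in key])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1)) + 1


def run_wf_simulation(config: SimulationConfig) -> list[SimulatedSample]:
    """Run all replicates of one scenario and sample each at the end.

    At the sampling generation ``sample_size`` diploids are drawn without
    replacement (hypergeometric over genotype counts); mutations
    segregating in the sample (0 < frequency < 1) are reported with their
    true age.  Deterministic given ``config.seed``.
    """
    T = config.total_generations
    T_mut = (config.mutation_stop_generation
             if config.mutation_stop_generation is not None else T)
    size_history = config.size_history()
    U_total = config.U_neutral + config.U_focal
    p_focal = config.U_focal / U_total if U_total > 0 else 0.0
    samples: list[SimulatedSample] = []
    # generous bound on surviving mutations
    max_out = int(4 * config.N * U_total * 10 * math.log(2 * config.N) + 10_000)
    for rep in range(config.n_replicates):
        kseed = _replicate_seed(config.seed, rep)
        n_hom, n_het, age, cls, n_intro, n_fixed = _simulate_replicate(
            kseed, size_history, T, T_mut, U_total, p_focal,
            config.neutral_ratio_r, config.s, config.dominance_h,
            config.selfing_rate, max_out)
        rng = np.random.default_rng(_replicate_seed(config.seed, rep, 1))
        N_final = int(size_history[T])
        ns = min(config.sample_size, N_final)
        k_hom = rng.hypergeometric(n_hom, N_final - n_hom, ns)
        k_het = rng.hypergeometric(n_het, N_final - n_hom - n_het, ns - k_hom)
        freq = (2.0 * k_hom + k_het) / (2.0 * ns)
        seg = (freq > 0.0) & (freq < 1.0)
        n_seg = int(seg.sum())
        # positions are assigned at reporting time (uniform, unique);
        # under the free-recombination engine they carry no dynamics
        positions = rng.choice(config.L, size=n_seg, replace=False) + 1 \
            if n_seg <= config.L else rng.integers(1, config.L + 1, size=n_seg)
        s_arr = np.where(cls[seg] == 2, config.s, 0.0)
        sites = pd.DataFrame({
            "position": np.sort(positions),
            "origin_generation": (T - age[seg]).astype(np.int64),
            "age": age[seg].astype(np.int64),
            "mut_class": pd.Categorical.from_codes(cls[seg], MUT_CLASSES),
            "s": s_arr,
            "sample_frequency": freq[seg],
            "pop_frequency": (2.0 * n_hom[seg] + n_het[seg]) / (2.0 * N_final),
            "pop_n_hom": n_hom[seg],
            "pop_n_het": n_het[seg],
        })
        samples.append(SimulatedSample(
            sites=sites, replicate=rep, seed=kseed, config=config,
            n_introduced={c: int(n_intro[i]) for i, c in enumerate(MUT_CLASSES)},
            n_fixed={c: int(n_fixed[i]) for i, c in enumerate(MUT_CLASSES)},
        ))
    return samples


def rescale_config(config: SimulationConfig, lam: float) -> SimulationConfig:
    """Rescale a configuration by lambda >= 1 at fixed S, theta and rho*N.

    N' = N/lambda, mu' = mu*lambda, rho' = rho*lambda, generations' =
    generations/lambda; the scaled selection coefficient S = Ne*s is
    preserved (s is stored scaled, so s' = s*lambda follows automatically).
    """
    if lam < 1:
        raise ValueError("rescale factor must be >= 1")
    new_N = int(round(config.N / lam))
    if new_N < 50:
        raise ValueError(f"N/lambda = {new_N} < 50: drift regime breaks")
    gens = config.n_generations
    return config.replace(
        N=new_N,
        mu_neutral=config.mu_neutral * lam,
        mu_focal=config.mu_focal * lam,
        rho=config.rho * lam,
        n_generations=None if gens is None else int(round(gens / lam)),
        demography=tuple((int(round(g / lam)), int(round(n / lam)))
                         for g, n in config.demography),
        sample_size=min(config.sample_size, new_N),
        rescale_factor=config.rescale_factor * lam,
    )


def simulate_grid(r_grid: Sequence[float], S_grid: Sequence[float],
                  config: SimulationConfig,
                  ) -> dict[tuple[float, float], list[SimulatedSample]]:
    """Run every (neutral ratio, scaled S) combination of the grids.

    Each cell runs ``config.n_replicates`` replicates; cell seeds are
    derived deterministically from (config.seed, r-index, S-index) so any
    sub-grid of a given grid reproduces the same per-cell data.
    """
    if len(r_grid) == 0 or len(S_grid) == 0:
        raise ValueError("grids must be non-empty")
    out: dict[tuple[float, float], list[SimulatedSample]] = {}
    for r in r_grid:
        for S in S_grid:
            cell_seed = _replicate_seed(config.seed, 7919,
                                        int(round(r * 10_000)),
                                        int(round(S * 1_000)))
            cell_cfg = config.replace(neutral_ratio_r=float(r),
                                      scaled_S=float(S), seed=cell_seed)
            out[(float(r), float(S))] = run_wf_simulation(cell_cfg)
    return out
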