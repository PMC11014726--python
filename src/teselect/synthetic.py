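"""Synthetic polymorphism datasets with known ground truth.

The generator emulates the per-variant records the real-data pipeline
produces - class label, derived allele frequency, age in generations,
optional noisy age estimate, genomic position - either parametrically or
from an attached forward-simulation run, so that every downstream stage
(age-adjusted SFS, selection inference, sanity checks) can be exercised
with a known answer.

Parametric mode draws sample allele-frequency counts from the expected
frequency spectrum (neutral: proportional to 1/k; selected: Wright's
semidominant polymorphism density with scaled coefficient 2S) and ages
conditional on frequency from a Gamma distribution around the Kimura-Ohta
mean for every class; selection acts through the spectrum tilt, which
lowers selected sites' frequencies at a given age and compresses their
age marginal (the forward simulator remains the ground truth for selected
age-frequency structure).  Transposition-rate bursts reweight the
focal origin-time density; demographic change is emulated as a monotone
age warp applied identically to all classes.  All randomness derives from
the configuration seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .neutral import expected_neutral_age

__all__ = [
    "SyntheticConfig",
    "generate_dataset",
    "apply_burst_schedule",
    "add_age_noise",
    "apply_demographic_warp",
    "dataset_from_simulation",
    "write_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic dataset."""

    n_sites_focal: int = 1000
    n_sites_neutral: int = 5000
    #: fraction of focal sites that are truly neutral
    neutral_ratio_r: float = 1.0
    #: scaled selection coefficient of the selected focal sites (<= 0)
    scaled_S: float = 0.0
    Ne: int = 10_000
    #: haploid sample size (number of sequenced accessions; the species is
    #: highly selfing, so accessions are treated as haploid lines)
    sample_size: int = 50
    #: (start_age, end_age, rate_multiplier) transposition bursts, in
    #: generations before sampling
    burst_schedule: tuple[tuple[float, float, float], ...] = ()
    #: log-scale sd of multiplicative age-estimate noise
    age_noise_sd: float = 0.0
    #: (start_age, end_age, stretch) epochs emulating population-size
    #: change as a common time warp of all ages
    demography_warp: tuple[tuple[float, float, float], ...] = ()
    #: additional SNP comparison classes
    n_sites_nonsyn: int = 0
    n_sites_high_effect: int = 0
    scaled_S_nonsyn: float = -2.0
    scaled_S_high_effect: float = -8.0
    #: per-site probability of dropping a focal call (caller false
    #: negatives); 0 disables
    drop_probability: float = 0.0
    #: Gamma shape of the age-given-frequency distribution
    age_shape: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.neutral_ratio_r <= 1.0:
            raise ValueError("neutral_ratio_r must be in [0, 1]")
        if self.Ne < 2:
            raise ValueError("Ne must be >= 2")
        if self.sample_size > 2 * self.Ne:
            raise ValueError("sample_size cannot exceed 2*Ne")
        if self.sample_size < 3:
            raise ValueError("sample_size must be >= 3")
        if self.age_noise_sd < 0:
            raise ValueError("age_noise_sd must be >= 0")
        if any(s <= 0 for *_, s in self.burst_schedule):
            raise ValueError("burst rate multipliers must be > 0")
        for s in (self.scaled_S, self.scaled_S_nonsyn, self.scaled_S_high_effect):
            if s > 0:
                raise ValueError("scaled selection coefficients must be <= 0")

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


def _sfs_weights(n_hap: int, scaled_S: float) -> np.ndarray:
    """Expected sample frequency-spectrum weights at counts 1..n-1.

    Neutral: 1/k.  Under semidominant selection with Gamma = 2*S the
    standard polymorphism density tau(q) = (1 - exp(-Gamma*(1-q))) /
    (q*(1-q)*(1 - exp(-Gamma))) is evaluated at q = k/n.
    """
    k = np.arange(1, n_hap)
    q = k / n_hap
    if scaled_S == 0.0:
        w = 1.0 / k
    else:
        gamma = 2.0 * scaled_S  # negative for purifying selection
        w = -np.expm1(-gamma * (1.0 - q)) / (q * (1.0 - q) * -np.expm1(-gamma))
    return w / w.sum()


def _draw_class(rng, n, n_hap, Ne, scaled_S, shape):
    """Draw (frequency, age) pairs for one site class.

    Frequencies follow the class's expected spectrum; ages given
    frequency keep the neutral Kimura-Ohta conditional for every class.
    Selection enters through the spectrum tilt alone, which is what the
    age-adjusted SFS keys on: concentrating selected sites at low
    frequencies both lowers their mean frequency at a given age
    (negative Delta) and compresses their age marginal (younger oldest
    sites as |S| grows).
    """
    if n == 0:
        return np.empty(0), np.empty(0)
    k = rng.choice(np.arange(1, n_hap), size=n, p=_sfs_weights(n_hap, scaled_S))
    freq = k / n_hap
    ages = rng.gamma(shape, expected_neutral_age(freq, Ne) / shape)
    return freq, np.maximum(ages, 1e-9)


def apply_burst_schedule(origin_times, burst_schedule, rng=None) -> np.ndarray:
    """Thin origin times so their density is multiplied inside burst windows.

    ``burst_schedule`` is a list of non-overlapping (start, end,
    rate_multiplier) windows on the origin-time axis.  Acceptance
    probability is multiplier/max-multiplier, which multiplies the density
    by the multiplier up to a common renormalisation; a multiplier of 1
    everywhere returns the input unchanged.  Returns the retained subset.
    """
    times = np.asarray(origin_times, dtype=float)
    sched = sorted(burst_schedule)
    for (s1, e1, _), (s2, _e2, _) in zip(sched, sched[1:]):
        if s2 < e1:
            raise ValueError("burst intervals overlap")
    if any(m <= 0 for *_, m in sched):
        raise ValueError("burst rate multipliers must be > 0")
    w = np.ones(len(times))
    for start, end, mult in sched:
        w[(times >= start) & (times < end)] *= mult
    wmax = w.max() if len(w) else 1.0
    if wmax <= 1.0 and np.all(w == w.max()):
        return times
    rng = np.random.default_rng(rng)
    keep = rng.random(len(times)) < w / wmax
    return times[keep]


def add_age_noise(ages, age_noise_sd, rng=None) -> np.ndarray:
    """Multiplicative log-normal age-estimate noise (median-unbiased)."""
    if age_noise_sd < 0:
        raise ValueError("age_noise_sd must be >= 0")
    ages = np.asarray(ages, dtype=float)
    if np.any(ages <= 0):
        raise ValueError("ages must be > 0")
    if age_noise_sd == 0:
        return ages.copy()
    rng = np.random.default_rng(rng)
    return ages * np.exp(age_noise_sd * rng.standard_normal(len(ages)))


def apply_demographic_warp(ages, epochs) -> np.ndarray:
    """Monotone piecewise-linear time warp emulating population-size change.

    ``epochs`` is a list of (start, end, stretch) windows on the age axis:
    time inside a window runs ``stretch`` times slower (stretch > 1
    spreads ages out, < 1 compresses them).  Applied identically to every
    site class, so age-conditional structure is preserved.
    """
    ages = np.asarray(ages, dtype=float)
    out = ages.copy()
    for start, end, stretch in sorted(epochs):
        if end <= start or stretch <= 0:
            raise ValueError("invalid demographic epoch")
        inside = np.clip(ages, start, end) - start
        out += inside * (stretch - 1.0)
    return out


def _draw_focal(rng, cfg: SyntheticConfig, n_needed: int):
    """Draw focal sites honouring the burst schedule by thinning."""
    freqs = np.empty(0)
    ages = np.empty(0)
    labels = np.empty(0, dtype=object)
    while len(freqs) < n_needed:
        m = max(2 * (n_needed - len(freqs)), 100)
        n_neu = rng.binomial(m, cfg.neutral_ratio_r)
        f_n, a_n = _draw_class(rng, n_neu, cfg.sample_size, cfg.Ne, 0.0,
                               cfg.age_shape)
        f_s, a_s = _draw_class(rng, m - n_neu, cfg.sample_size, cfg.Ne,
                               cfg.scaled_S, cfg.age_shape)
        f = np.concatenate([f_n, f_s])
        a = np.concatenate([a_n, a_s])
        lab = np.array(["focal_neutral"] * len(f_n) + ["focal_selected"] * len(f_s),
                       dtype=object)
        if cfg.burst_schedule:
            w = np.ones(len(a))
            for start, end, mult in cfg.burst_schedule:
                w[(a >= start) & (a < end)] *= mult
            keep = rng.random(len(a)) < w / w.max()
            f, a, lab = f[keep], a[keep], lab[keep]
        perm = rng.permutation(len(f))
        freqs = np.concatenate([freqs, f[perm]])
        ages = np.concatenate([ages, a[perm]])
        labels = np.concatenate([labels, lab[perm]])
    return freqs[:n_needed], ages[:n_needed], labels[:n_needed]


def generate_dataset(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a synthetic age-annotated site table with ground truth.

    Returns one row per site with columns ``variant_id``, ``clade``,
    ``var_class``, ``te_class``, ``effect``, ``mut_class`` (ground
    truth), ``derived_freq``, ``minor_freq``, ``true_age``, ``age``
    (noisy when ``age_noise_sd`` > 0), ``position`` and
    ``gene_distance_category``.  Deterministic given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    f_freq, f_age, f_lab = _draw_focal(rng, cfg, cfg.n_sites_focal)
    n_freq, n_age = _draw_class(rng, cfg.n_sites_neutral, cfg.sample_size,
                                cfg.Ne, 0.0, cfg.age_shape)
    parts = [
        pd.DataFrame({"mut_class": f_lab, "var_class": "TE",
                      "te_class": "retrotransposon", "effect": pd.NA,
                      "derived_freq": f_freq, "true_age": f_age}),
        pd.DataFrame({"mut_class": "neutral_marker", "var_class": "SNP",
                      "te_class": pd.NA, "effect": "synonymous",
                      "derived_freq": n_freq, "true_age": n_age}),
    ]
    for n, S, eff in ((cfg.n_sites_nonsyn, cfg.scaled_S_nonsyn, "non_synonymous"),
                      (cfg.n_sites_high_effect, cfg.scaled_S_high_effect,
                       "high_effect")):
        if n:
            f, a = _draw_class(rng, n, cfg.sample_size, cfg.Ne, S, cfg.age_shape)
            parts.append(pd.DataFrame({
                "mut_class": "snp_selected", "var_class": "SNP",
                "te_class": pd.NA, "effect": eff,
                "derived_freq": f, "true_age": a}))
    df = pd.concat(parts, ignore_index=True)
    if cfg.demography_warp:
        df["true_age"] = apply_demographic_warp(df["true_age"], cfg.demography_warp)
    df["age"] = add_age_noise(df["true_age"].to_numpy(), cfg.age_noise_sd, rng)
    if cfg.drop_probability > 0:
        drop = (df["var_class"].eq("TE").to_numpy()
                & (rng.random(len(df)) < cfg.drop_probability))
        df = df.loc[~drop].reset_index(drop=True)
    df["minor_freq"] = np.minimum(df["derived_freq"], 1.0 - df["derived_freq"])
    df["position"] = np.sort(rng.choice(10**8, size=len(df), replace=False))
    df["chrom"] = "chr1"
    df["variant_id"] = [f"syn_{i:06d}" for i in range(len(df))]
    df["clade"] = "synthetic"
    df["gene_distance_category"] = pd.NA
    return df


def dataset_from_simulation(samples, age_noise_sd=0.0, seed=None) -> pd.DataFrame:
    """Convert forward-simulation samples into the shared site-table format."""
    rows = []
    for s in samples:
        d = s.sites.copy()
        d["replicate"] = s.replicate
        rows.append(d)
    df = pd.concat(rows, ignore_index=True)
    df = df.rename(columns={"sample_frequency": "derived_freq"})
    df["true_age"] = df["age"].astype(float)
    df["age"] = add_age_noise(df["true_age"].to_numpy(), age_noise_sd, seed)
    df["minor_freq"] = np.minimum(df["derived_freq"], 1 - df["derived_freq"])
    df["var_class"] = np.where(df["mut_class"] == "neutral_marker", "SNP", "TE")
    df["effect"] = np.where(df["var_class"] == "SNP", "synonymous", None)
    df["te_class"] = np.where(df["var_class"] == "TE", "retrotransposon", None)
    df["variant_id"] = [f"sim_{i:06d}" for i in range(len(df))]
    df["clade"] = "simulated"
    df["chrom"] = "chr1"
    return df


# ---------------------------------------------------------------------------
# writers: same on-disk formats the real-data reader consumes

def write_dataset(df: pd.DataFrame, vcf_path, age_path, clade_path,
                  outgroup_samples=4) -> None:
    """Write a generated site table as VCF + age table + clade table.

    Per-sample calls are reconstructed from the derived allele frequency
    (carriers rounded to frequency * sample count, homozygous calls, ALT =
    derived); ``outgroup_samples`` extra samples from the ancestral C
    clade carry the ancestral allele, so the polarisation step of the
    real-data reader recovers the generated derived allele frequencies.
    """
    df = df.reset_index(drop=True)
    n_hap = int(round(1.0 / np.min(np.diff(np.unique(
        np.concatenate([[0.0, 1.0], df["derived_freq"].to_numpy()]))))))
    n_hap = max(n_hap, 2)
    focal_samples = [f"acc{i:03d}" for i in range(n_hap)]
    out_samples = [f"out{i:03d}" for i in range(outgroup_samples)]
    rng = np.random.default_rng(0xC0FFEE)
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=TECLASS,Number=1,Type=String,Description="TE class">\n')
        fh.write('##INFO=<ID=SUPERFAM,Number=1,Type=String,Description="TE superfamily">\n')
        fh.write('##INFO=<ID=FAMILY,Number=1,Type=String,Description="TE family">\n')
        fh.write('##INFO=<ID=EFFECT,Number=1,Type=String,Description="SnpEff-style effect">\n')
        for f in ("QD", "FS", "SOR", "MQ", "MQRankSum", "ReadPosRankSum"):
            fh.write(f'##INFO=<ID={f},Number=1,Type=Float,Description="{f}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=chr1,length=200000000>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(focal_samples + out_samples) + "\n")
        for _, row in df.iterrows():
            k = int(round(row["derived_freq"] * n_hap))
            carriers = set(rng.choice(n_hap, size=k, replace=False))
            calls = ["1/1" if i in carriers else "0/0" for i in range(n_hap)]
            calls += ["0/0"] * outgroup_samples
            if row["var_class"] == "TE":
                ref, alt = "N", "<INS>"
                info = (f"TECLASS={row['te_class']};SUPERFAM=Copia;"
                        f"FAMILY=fam{int(row['position']) % 7}")
            else:
                ref, alt = "A", "T"
                info = f"EFFECT={row['effect']}"
            info += ";QD=25.0;FS=1.0;SOR=1.0;MQ=60.0;MQRankSum=0.0;ReadPosRankSum=0.0"
            fh.write(f"{row['chrom']}\t{int(row['position'])}\t{row['variant_id']}"
                     f"\t{ref}\t{alt}\t100\tPASS\t{info}\tGT\t" + "\t".join(calls)
                     + "\n")
    df[["variant_id", "clade", "age"]].rename(
        columns={"age": "age_generations"}).to_csv(age_path, sep="\t", index=False)
    clade_rows = [{"sample": s, "clade": str(df["clade"].iloc[0]), "coverage": 30.0}
                  for s in focal_samples]
    clade_rows += [{"sample": s, "clade": "C", "coverage": 30.0}
                   for s in out_samples]
    pd.DataFrame(clade_rows).to_csv(clade_path, sep="\t", index=False)
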