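"""Reading, cleaning and summarising TE/SNP polymorphism tables.

The on-disk inputs are a VCF combining TE presence/absence polymorphisms
(symbolic ALT alleles, TE class/superfamily/family in INFO) and SNPs
(effect labels in INFO), a tab-separated allele-age table keyed on
(variant_id, clade), a tab-separated sample-to-clade assignment table and
a GFF3 gene annotation.  Cleaning follows the hard-filter, heterozygote
and multiallelic rules of the upstream variant-calling protocol; derived
allele states are assigned by polarising against a fixed outgroup clade.

Call codes used throughout: 0 = reference/TE absent, 1 = alternate/TE
present, 2 = heterozygous, -1 = missing.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PolymorphismRecord",
    "PolymorphismDataset",
    "HARD_FILTERS",
    "read_polymorphism_table",
    "apply_snp_hard_filters",
    "remove_het_and_multiallelic",
    "merge_tips",
    "polarize",
    "age_annotated_sites",
    "folded_sfs",
    "classify_gene_distance",
    "GENE_DISTANCE_CATEGORIES",
]

MISSING, REF, ALT, HET = -1, 0, 1, 2

GENE_DISTANCE_CATEGORIES = ("genic_to_1kb", "1kb_to_5kb", "over_5kb")

#: removal conditions on the GATK site annotations: a SNP is removed when
#: ANY condition holds (all inequalities strict).  The rank-sum
#: annotations are filtered as symmetric bands: values outside
#: (-2.5, 2.5) for MQRankSum and outside (-2.0, 2.0) for ReadPosRankSum.
HARD_FILTERS: tuple[tuple[str, str, float], ...] = (
    ("QD", "<", 5.0),
    ("FS", ">", 20.0),
    ("SOR", ">", 3.0),
    ("MQ", "<", 50.0),
    ("MQRankSum", ">", 2.5),
    ("MQRankSum", "<", -2.5),
    ("ReadPosRankSum", ">", 2.0),
    ("ReadPosRankSum", "<", -2.0),
)


@dataclass
class PolymorphismRecord:
    """One TE or SNP polymorphism with per-sample calls."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    var_class: str  # "SNP" or "TE"
    te_class: str | None = None  # retrotransposon / DNA_transposon / unclassified
    superfamily: str | None = None
    family: str | None = None
    effect: str | None = None  # synonymous / non_synonymous / high_effect
    calls: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    site_stats: dict = field(default_factory=dict)
    n_alt_alleles: int = 1

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1")
        if self.var_class == "TE" and self.te_class is None:
            self.te_class = "unclassified"
        if self.var_class == "SNP":
            self.te_class = None


@dataclass
class PolymorphismDataset:
    """Records plus the sample panel and auxiliary tables."""

    records: list[PolymorphismRecord]
    samples: tuple[str, ...]
    age_table: pd.DataFrame | None = None
    clades: pd.DataFrame | None = None

    def sample_clades(self) -> dict[str, str]:
        if self.clades is None:
            raise ValueError("no clade table attached")
        return dict(zip(self.clades["sample"], self.clades["clade"]))

    def high_coverage_mask(self, min_coverage=20.0) -> np.ndarray:
        """Boolean mask over samples with mean mapping coverage >= cutoff."""
        if self.clades is None or "coverage" not in self.clades.columns:
            raise ValueError("no coverage column available")
        cov = dict(zip(self.clades["sample"], self.clades["coverage"]))
        return np.array([cov.get(s, np.nan) >= min_coverage for s in self.samples])


def read_polymorphism_table(variant_file, age_file=None, clade_table=None,
                            ) -> PolymorphismDataset:
    """Read the combined TE/SNP VCF and join the age and clade tables.

    Raises on unparseable files and on duplicate variant ids.  Sites
    missing from the age table remain in ``records`` (they are excluded
    later from age-based analyses); join statistics are logged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(variant_file))
    samples = tuple(vcf.samples)
    records: list[PolymorphismRecord] = []
    seen: set[str] = set()
    for v in vcf:
        vid = v.ID or f"{v.CHROM}:{v.POS}"
        if vid in seen:
            raise ValueError(f"duplicate variant id: {vid}")
        seen.add(vid)
        te_class = v.INFO.get("TECLASS")
        is_te = te_class is not None or any(a.startswith("<") for a in v.ALT)
        # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(v.gt_types)
        calls = np.full(len(gt), MISSING, dtype=np.int8)
        calls[gt == 0] = REF
        calls[gt == 3] = ALT
        calls[gt == 1] = HET
        stats = {k: v.INFO.get(k) for k, *_ in HARD_FILTERS if v.INFO.get(k) is not None}
        records.append(PolymorphismRecord(
            variant_id=vid, chrom=v.CHROM, pos=v.POS,
            var_class="TE" if is_te else "SNP",
            te_class=te_class if is_te else None,
            superfamily=v.INFO.get("SUPERFAM"), family=v.INFO.get("FAMILY"),
            effect=v.INFO.get("EFFECT"), calls=calls, site_stats=stats,
            n_alt_alleles=len(v.ALT)))
    age_df = None
    if age_file is not None:
        age_df = pd.read_csv(age_file, sep="\t")
        required = {"variant_id", "clade", "age_generations"}
        if not required.issubset(age_df.columns):
            raise ValueError(f"age table must have columns {sorted(required)}")
        dup = age_df.duplicated(["variant_id", "clade"])
        if dup.any():
            raise ValueError("age table has duplicate (variant_id, clade) rows")
        n_aged = age_df["variant_id"].isin(seen).sum()
        logger.info("age table: %d rows, %d join to the %d variants read",
                    len(age_df), n_aged, len(records))
        missing = len(records) - age_df["variant_id"].nunique()
        if missing > 0:
            logger.warning("%d variants have no age estimate; they are kept in "
                           "records but excluded from age-based analyses", missing)
    clade_df = None
    if clade_table is not None:
        clade_df = pd.read_csv(clade_table, sep="\t")
        if not {"sample", "clade"}.issubset(clade_df.columns):
            raise ValueError("clade table must have columns sample, clade")
    return PolymorphismDataset(records=records, samples=samples,
                               age_table=age_df, clades=clade_df)


def apply_snp_hard_filters(records, filters=HARD_FILTERS) -> list[PolymorphismRecord]:
    """Drop SNPs failing any hard-filter condition; TEs pass untouched.

    A missing annotation never triggers its condition (the site is
    retained for that condition); occurrences are logged.
    """
    out = []
    n_missing = 0
    for rec in records:
        if rec.var_class != "SNP":
            out.append(rec)
            continue
        removed = False
        for key, op, cutoff in filters:
            val = rec.site_stats.get(key)
            if val is None:
                n_missing += 1
                continue
            if (op == "<" and val < cutoff) or (op == ">" and val > cutoff):
                removed = True
                break
        if not removed:
            out.append(rec)
    if n_missing:
        logger.info("%d missing filter annotations treated as passing", n_missing)
    return out


def remove_het_and_multiallelic(records) -> list[PolymorphismRecord]:
    """Clean genotype calls: drop multiallelic sites, neutralise heterozygotes.

    Multiallelic TE or SNP sites (> 2 alleles) are removed entirely.
    Heterozygous SNP calls are set to missing; heterozygous TE calls are
    recoded as homozygous present (TE calls are treated as homozygous in
    a highly selfing species).
    """
    out = []
    for rec in records:
        if rec.n_alt_alleles > 1:
            continue
        calls = rec.calls.copy()
        if rec.var_class == "SNP":
            calls[calls == HET] = MISSING
        else:
            calls[calls == HET] = ALT
        out.append(replace(rec, calls=calls))
    return out


def merge_tips(records, max_gap=100) -> list[PolymorphismRecord]:
    """Merge same-family TE insertions called < ``max_gap`` bp apart.

    Single-linkage: consecutive same-family TIPs on a chromosome whose
    positions differ by strictly less than ``max_gap`` collapse into one
    record chaining transitively.  The merged record keeps the leftmost
    position and id and the per-sample union of presence calls.  Non-TE
    records pass through unchanged; output order is (chrom, pos).
    """
    tes = [r for r in records if r.var_class == "TE"]
    others = [r for r in records if r.var_class != "TE"]
    merged: list[PolymorphismRecord] = []
    keyfun = (lambda r: (r.chrom, r.family if r.family is not None else ""))
    tes_sorted = sorted(tes, key=lambda r: (keyfun(r), r.pos))
    cluster: list[PolymorphismRecord] = []

    def flush():
        if not cluster:
            return
        base = cluster[0]
        if len(cluster) == 1:
            merged.append(base)
        else:
            calls = base.calls.copy()
            for other in cluster[1:]:
                calls = np.maximum(calls, other.calls)
            merged.append(replace(base, calls=calls))
        cluster.clear()

    prev_key = None
    for rec in tes_sorted:
        key = keyfun(rec)
        if cluster and (key != prev_key or rec.pos - cluster[-1].pos >= max_gap):
            flush()
        cluster.append(rec)
        prev_key = key
    flush()
    return sorted(merged + others, key=lambda r: (r.chrom, r.pos))


def polarize(records, sample_clades, outgroup_clade="C", samples=None,
             sample_mask=None) -> tuple[pd.DataFrame, dict]:
    """Assign derived alleles using a fixed outgroup clade.

    The derived allele at a site is the allele absent from the outgroup
    when the outgroup is fixed; sites whose outgroup calls are polymorphic
    or entirely missing are excluded (counted in the exclusion log).
    Returns a (variant x focal clade) table of derived allele frequencies
    over non-missing calls, plus the exclusion counts.
    """
    if samples is None:
        raise ValueError("polarize requires the sample name list")
    samples = list(samples)
    clade_arr = np.array([sample_clades.get(s) for s in samples], dtype=object)
    keep = np.ones(len(samples), dtype=bool) if sample_mask is None \
        else np.asarray(sample_mask, dtype=bool)
    out_idx = (clade_arr == outgroup_clade) & keep
    if not out_idx.any():
        raise ValueError(f"no samples in outgroup clade {outgroup_clade!r}")
    focal_clades = sorted({c for c in clade_arr[keep]
                           if c is not None and c != outgroup_clade})
    exclusions = {"polymorphic_outgroup": 0, "missing_outgroup": 0}
    rows = []
    for rec in records:
        og = rec.calls[out_idx]
        og = og[og != MISSING]
        if len(og) == 0:
            exclusions["missing_outgroup"] += 1
            continue
        alleles = np.unique(og)
        if len(alleles) > 1:
            exclusions["polymorphic_outgroup"] += 1
            continue
        derived = ALT if alleles[0] == REF else REF
        row = {"variant_id": rec.variant_id, "chrom": rec.chrom, "pos": rec.pos,
               "var_class": rec.var_class, "te_class": rec.te_class,
               "superfamily": rec.superfamily, "family": rec.family,
               "effect": rec.effect, "derived_allele": derived}
        for clade in focal_clades:
            cc = rec.calls[(clade_arr == clade) & keep]
            cc = cc[cc != MISSING]
            row[f"derived_freq_{clade}"] = (
                np.mean(cc == derived) if len(cc) else np.nan)
        rows.append(row)
    logger.info("polarised %d sites; excluded %s", len(rows), exclusions)
    return pd.DataFrame(rows), exclusions


def age_annotated_sites(polarized: pd.DataFrame, age_table: pd.DataFrame,
                        ) -> pd.DataFrame:
    """Long (variant, clade) table of derived frequencies joined with ages.

    One row per variant x clade where both a derived frequency and an age
    estimate exist; ``minor_freq`` = min(p, 1-p).  Fixed or absent sites
    (frequency 0 or 1 in a clade) are dropped - ages are defined for
    segregating variants.
    """
    freq_cols = [c for c in polarized.columns if c.startswith("derived_freq_")]
    long = polarized.melt(
        id_vars=[c for c in polarized.columns if c not in freq_cols],
        value_vars=freq_cols, var_name="clade", value_name="derived_freq")
    long["clade"] = long["clade"].str.removeprefix("derived_freq_")
    long = long.dropna(subset=["derived_freq"])
    long = long[(long["derived_freq"] > 0) & (long["derived_freq"] < 1)]
    merged = long.merge(
        age_table.rename(columns={"age_generations": "age"}),
        on=["variant_id", "clade"], how="inner")
    merged = merged[merged["age"] > 0]
    merged["minor_freq"] = np.minimum(merged["derived_freq"],
                                      1.0 - merged["derived_freq"])
    logger.info("age-annotated sites: %d of %d segregating (variant, clade) pairs",
                len(merged), len(long))
    return merged.reset_index(drop=True)


def folded_sfs(minor_freqs, bins=10):
    """Histogram of minor allele frequencies on [0, 0.5].

    ``bins`` may be a count or explicit edges.  Total mass equals the
    number of input sites; a frequency above 0.5 is an invariant breach
    and raises.
    """
    maf = np.asarray(minor_freqs, dtype=float)
    if np.any((maf < 0) | (maf > 0.5)):
        raise ValueError("minor allele frequencies must lie in [0, 0.5]")
    if np.isscalar(bins):
        bins = np.linspace(0.0, 0.5, int(bins) + 1)
    counts, edges = np.histogram(maf, bins=bins)
    return counts, edges


def _gene_intervals(gff3_path) -> dict[str, np.ndarray]:
    """Merged gene-body intervals per chromosome from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(str(gff3_path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    per_chrom: dict[str, list] = {}
    for gene in db.features_of_type("gene"):
        per_chrom.setdefault(gene.seqid, []).append((gene.start, gene.end))
    out = {}
    for chrom, iv in per_chrom.items():
        iv.sort()
        merged = [list(iv[0])]
        for s, e in iv[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.asarray(merged)
    return out


def classify_gene_distance(sites: pd.DataFrame, gff3_path,
                           near=1000, far=5000) -> pd.Series:
    """Distance-to-nearest-gene category per site.

    Distance is measured in bp from the site position to the nearest
    gene-body edge (0 inside a gene; interval ends inclusive).  Categories:
    <= ``near`` bp (including genic) -> "genic_to_1kb"; (near, far] ->
    "1kb_to_5kb"; > far -> "over_5kb".  Sites on chromosomes absent from
    the annotation get NA with a warning.
    """
    intervals = _gene_intervals(gff3_path)
    cats = []
    warned = set()
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        iv = intervals.get(chrom)
        if iv is None:
            if chrom not in warned:
                logger.warning("chromosome %s absent from annotation", chrom)
                warned.add(chrom)
            cats.append(pd.NA)
            continue
        starts, ends = iv[:, 0], iv[:, 1]
        i = np.searchsorted(starts, pos, side="right") - 1
        d_inside = 0 if (i >= 0 and pos <= ends[i]) else None
        if d_inside is not None:
            d = 0
        else:
            d_left = pos - ends[i] if i >= 0 else np.inf
            d_right = starts[i + 1] - pos if i + 1 < len(starts) else np.inf
            d = min(d_left, d_right)
        if d <= near:
            cats.append(GENE_DISTANCE_CATEGORIES[0])
        elif d <= far:
            cats.append(GENE_DISTANCE_CATEGORIES[1])
        else:
            cats.append(GENE_DISTANCE_CATEGORIES[2])
    return pd.Series(cats, index=sites.index, name="gene_distance_category")
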