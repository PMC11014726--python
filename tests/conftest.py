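import numpy as np
import pandas as pd
import pytest

from teselect.io import PolymorphismRecord


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240412)


def make_snp(vid, pos=100, chrom="chr1", calls=(0, 0, 1, 1), stats=None,
             n_alt=1, effect="synonymous"):
    return PolymorphismRecord(
        variant_id=vid, chrom=chrom, pos=pos, var_class="SNP", effect=effect,
        calls=np.asarray(calls, dtype=np.int8),
        site_stats=stats if stats is not None else
        dict(QD=25.0, FS=1.0, SOR=1.0, MQ=60.0, MQRankSum=0.0,
             ReadPosRankSum=0.0),
        n_alt_alleles=n_alt)


def make_te(vid, pos, family="famA", chrom="chr1", calls=(0, 1, 0, 1),
            te_class="retrotransposon"):
    return PolymorphismRecord(
        variant_id=vid, chrom=chrom, pos=pos, var_class="TE",
        te_class=te_class, family=family, superfamily="Copia",
        calls=np.asarray(calls, dtype=np.int8))


@pytest.fixture
def toy_gff(tmp_path):
    """Three genes on chr1, one on chr2."""
    text = "\n".join([
        "##gff-version 3",
        "chr1\tsrc\tgene\t10000\t12000\t.\t+\t.\tID=gene1",
        "chr1\tsrc\tgene\t30000\t31000\t.\t-\t.\tID=gene2",
        "chr1\tsrc\tgene\t31500\t33000\t.\t+\t.\tID=gene3",
        "chr2\tsrc\tgene\t5000\t6000\t.\t+\t.\tID=gene4",
        "",
    ])
    path = tmp_path / "genes.gff3"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def neutral_site_tables():
    """A fully neutral focal set and a neutral pool with matching structure."""
    from teselect.synthetic import SyntheticConfig, generate_dataset

    df = generate_dataset(SyntheticConfig(n_sites_focal=800, n_sites_neutral=4000,
                                          neutral_ratio_r=1.0, seed=7))
    focal = df[df["var_class"] == "TE"].reset_index(drop=True)
    neutral = df[df["var_class"] == "SNP"].reset_index(drop=True)
    return focal, neutral


def site_frame(ages, freqs):
    return pd.DataFrame({"age": np.asarray(ages, float),
                         "derived_freq": np.asarray(freqs, float)})
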