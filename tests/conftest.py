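import numpy as np
import pytest

from scsnv.synthdata import SyntheticSpec, ToyGenomeSpec, gen_feature_table, gen_toy_genome


@pytest.fixture(scope="session")
def small_table():
    """Labeled 7-feature table, small enough for fast CV in unit tests."""
    return gen_feature_table(SyntheticSpec(seed=7, n_pos=150, n_neg=200))


@pytest.fixture(scope="session")
def small_table_11():
    return gen_feature_table(SyntheticSpec(seed=7, n_pos=150, n_neg=200, n_features=11))


@pytest.fixture(scope="session")
def toy_genome_files(tmp_path_factory):
    """Toy FASTA + GTF on disk, with the raw text for direct inspection."""
    fasta, gtf = gen_toy_genome(ToyGenomeSpec(seed=3, n_genes=3, exons_per_gene=3))
    d = tmp_path_factory.mktemp("toygenome")
    fa_path, gtf_path = d / "toy.fa", d / "toy.gtf"
    fa_path.write_text(fasta)
    gtf_path.write_text(gtf)
    chrom_seq = "".join(fasta.splitlines()[1:])
    return {"fasta": fa_path, "gtf": gtf_path, "seq": {"chrT": chrom_seq}}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
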