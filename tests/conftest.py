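import numpy as np
import pytest

from btob import AssocRecord
from btob.datasets import example_gene_windows, example_study_pair
from btob.sumstats import write_sumstats


@pytest.fixture(scope="session")
def example_pair():
    """The bundled eight-locus example: (marginal study, adjusted study)."""
    return example_study_pair()


@pytest.fixture(scope="session")
def example_windows():
    return example_gene_windows()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_record(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G",
                beta=0.1, se=0.01, pvalue=0.5, n=50000) -> AssocRecord:
    return AssocRecord(snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea,
                       other_allele=oa, beta=beta, se=se, pvalue=pvalue, n=n)


@pytest.fixture
def sumstats_file(tmp_path):
    """Write records to a GIANT-style file and return the path."""

    def _write(records, name="study.txt"):
        path = tmp_path / name
        write_sumstats(records, path)
        return path

    return _write
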