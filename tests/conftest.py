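import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from svcompare.synthetic import implant_svs, make_fig4a_locus, make_reference
from svcompare.variants import Genotype, make_record

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def simple_record(contig="ctg1", pos=100, svtype="DEL", size=100, *,
                  ref_seq=None, ins_seq=None, genotypes=None, qual=None,
                  source="base", record_id=None):
    """Hand-build a sequence-resolved record without a reference in scope."""
    if svtype == "DEL":
        deleted = ref_seq if ref_seq is not None else "A" * size
        ref_allele = "G" + deleted
        alt_allele = "G"
    else:
        ins = ins_seq if ins_seq is not None else "A" * size
        ref_allele = "G"
        alt_allele = "G" + ins
    return make_record(contig, pos, ref_allele, alt_allele, qual=qual,
                       genotypes=genotypes or {}, source=source,
                       record_id=record_id)


def gt(alleles, phased=False):
    return Genotype(tuple(alleles), phased)


@pytest.fixture(scope="session")
def small_reference():
    reference, _ = make_reference(1, 100_000, seed=42)
    return reference


@pytest.fixture(scope="session")
def truth_callset(small_reference):
    return implant_svs(small_reference, n_del=8, n_ins=12, n_samples=2, seed=42)


@pytest.fixture(scope="session")
def fig_locus():
    return make_fig4a_locus(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
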