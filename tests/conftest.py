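import pytest

from glioseg.datasets import load_affected_pedigree, load_candidate_cohort
from glioseg.model import (
    AnnotatedVariant,
    Cohort,
    Family,
    FunctionalClass,
    GenotypeCall,
    Individual,
    PopulationFrequencies,
)
from glioseg.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def candidate_fixture():
    """The packaged 21-candidate cohort with config and Sanger reads."""
    return load_candidate_cohort()


@pytest.fixture(scope="session")
def affected_pedigree():
    """The packaged 20-family affected-members pedigree."""
    return load_affected_pedigree()


@pytest.fixture(scope="session")
def sim_result():
    """One default synthetic cohort (seed 0)."""
    return simulate(SimConfig(seed=0))


def make_trio_cohort(variants=(), genotypes=None):
    """A single sequenced trio (child affected) for small filter tests."""
    fam = Family(
        "T1",
        [
            Individual("dad", "T1", sex="male", sequenced=True),
            Individual("mom", "T1", sex="female", sequenced=True),
            Individual(
                "kid", "T1", father_id="dad", mother_id="mom",
                sex="female", affected=True, sequenced=True,
            ),
        ],
    )
    return Cohort(families=[fam], variants=list(variants), genotypes=genotypes or {})


def make_variant(pos=40_000_000, gene="GENEX", func=FunctionalClass.MISSENSE,
                 esp=None, kg=None, kg_ceu=None, dbsnp=None, cscore=None,
                 ref="A", alt="G", chrom="17"):
    return AnnotatedVariant(
        chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
        gene_symbol=gene, functional_class=func,
        dbsnp_id=dbsnp,
        freqs=PopulationFrequencies(
            esp_percent=esp, kg_percent=kg, kg_ceu_percent=kg_ceu
        ),
        scaled_c_score=cscore,
    )


HET = GenotypeCall.CARRIER_HET
HOM = GenotypeCall.CARRIER_HOM
REF = GenotypeCall.NON_CARRIER
MISS = GenotypeCall.MISSING
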