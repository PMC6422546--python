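import pytest

from rflpkit import (
    GelModel,
    build_allele_pair,
    build_locus,
    default_assay,
    default_enzymes,
    default_layouts,
    default_pairs,
    default_primers,
)

SNPS = ("CYP3A4*4", "CYP3A4*18B", "CYP3A4*22")


@pytest.fixture(scope="session")
def enzymes():
    return default_enzymes()


@pytest.fixture(scope="session")
def primers():
    return default_primers()


@pytest.fixture(scope="session")
def layouts():
    return default_layouts()


@pytest.fixture(scope="session")
def pairs():
    return default_pairs()


@pytest.fixture(scope="session")
def amplicon_seqs(layouts):
    """All six synthetic amplicons (3 SNPs x wild/variant), default seed."""
    return {name: build_allele_pair(layout) for name, layout in layouts.items()}


@pytest.fixture(scope="session")
def wild_loci(layouts):
    """Wild-allele loci with 200 bp flanks, default seed."""
    return {snp: build_locus(layouts[snp], "wild", 200) for snp in SNPS}


@pytest.fixture(scope="session")
def assay():
    return default_assay()


@pytest.fixture(scope="session")
def gel():
    return GelModel()
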