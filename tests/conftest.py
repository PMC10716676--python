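import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cismr import (
    HarmonisedInstrumentSet,
    LDMatrix,
    SummaryDataset,
    VariantAssociation,
    table1_fixture,
)


def make_variant(rsid="rs1", chrom="4", pos=120_500_000, ea="A", oa="G",
                 eaf=0.3, beta=0.1, se=0.02, pval=1e-9, n=100_000):
    return VariantAssociation(
        rsid=rsid, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se, pval=pval, n=n,
    )


def make_hset(gamma, gamma_se, Gamma, Gamma_se, r=None, pvals=None):
    gamma = np.asarray(gamma, float)
    k = len(gamma)
    rsids = [f"rs{i+1}" for i in range(k)]
    ld = LDMatrix(rsids=rsids, ref_alleles=["A"] * k,
                  r=np.eye(k) if r is None else np.asarray(r, float))
    return HarmonisedInstrumentSet(
        rsids=rsids, gamma=gamma, gamma_se=np.asarray(gamma_se, float),
        Gamma=np.asarray(Gamma, float), Gamma_se=np.asarray(Gamma_se, float),
        ld=ld, exposure_pvals=None if pvals is None else np.asarray(pvals, float),
    )


@pytest.fixture
def table1():
    return table1_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
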