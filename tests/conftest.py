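import numpy as np
import pytest
from hypothesis import settings

from centscan import (CohortSpec, ReferencePanel, ReferenceSNP,
                      simulate_cohorts)

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


def make_snp(snp_id="rs1", chrom="1", pos=1000, effect="A", other="G",
             maf=0.3, beta_clin=0.2, beta_meta=0.15, is_apoe=False):
    return ReferenceSNP(snp_id=snp_id, chrom=chrom, pos=pos,
                        effect_allele=effect, other_allele=other,
                        maf_ref=maf, beta_clin=beta_clin,
                        beta_meta=beta_meta, is_apoe=is_apoe)


@pytest.fixture(scope="session")
def small_panel():
    """Five-SNP panel with the two APOE SNPs flagged."""
    return ReferencePanel([
        make_snp("rs429358", "19", 44908684, "C", "T", 0.089, 1.1944, 1.05,
                 is_apoe=True),
        make_snp("rs7412", "19", 44908822, "T", "C", 0.0461, -1.1463, -0.80,
                 is_apoe=True),
        make_snp("rs100", "1", 5000, "A", "G", 0.30, 0.18, 0.14),
        make_snp("rs200", "2", 6000, "C", "T", 0.15, -0.25, -0.18),
        make_snp("rs300", "3", 7000, "G", "A", 0.45, 0.10, 0.08),
    ], name="small")


@pytest.fixture(scope="session")
def small_sim(small_panel):
    """Modest-size simulated dataset for I/O, association and PRS tests."""
    spec = CohortSpec(n_cases=500, n_controls=500, n_centenarians=200, seed=42)
    return simulate_cohorts(small_panel, spec)
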