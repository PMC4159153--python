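import numpy as np
import pytest

from episcan import synthdata as sd


@pytest.fixture(scope="session")
def small_cohort():
    """500 samples x 80 SNPs, no planted effects, a little missingness."""
    return sd.simulate_cohort(500, 80, seed=42, missing_rate=0.02)


@pytest.fixture(scope="session")
def planted_cohort():
    """1500 samples x 60 SNPs with one additive SNP and one XOR-like pair."""
    markers = sd.uniform_marker_map(60, spacing_bp=20_000)
    panel = sd.simulate_haplotypes(2000, markers, seed=1)
    g, kin = sd.simulate_genotypes(panel, 1500, seed=2)
    freq = g.allele_freq()
    mat = sd.center_epistasis(sd.xor_matrix(0.4), freq[10], freq[30])
    spec = sd.EffectSpec(
        marginal={markers.snp_id[5]: (0.3, 0.0)},
        epistatic={(markers.snp_id[10], markers.snp_id[30]): mat},
    )
    pheno = sd.simulate_phenotype(g, spec, seed=3)
    return g, pheno["trait"].to_numpy(), spec, kin
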