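import numpy as np
import pytest

from dipscaffold import simdip


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_bundle():
    """One 120 kb chromosome, heterozygosity 0.5%, ~10 contigs per haplotype."""
    bundle = simdip.simulate_diploid(
        n_chrom=1, chrom_len=120_000, snp_rate=0.005, seed=101
    )
    simdip.fragment_contigs(bundle, n50_target=12_000, seed=102)
    simdip.simulate_map(bundle, density_per_mb=1600, seed=103)
    return bundle


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
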