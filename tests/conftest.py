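import numpy as np
import pytest

from hapreml.geno_io import PhasedGenotypes


def make_panel(
    hap_calls,
    chromosomes=None,
    positions=None,
    ids=None,
):
    """Build a small phased panel from an (n, m, 2) alt-indicator array."""
    hap = np.asarray(hap_calls, dtype=np.int8)
    n, m, _ = hap.shape
    if chromosomes is None:
        chromosomes = ["chr1"] * m
    if positions is None:
        positions = [1000 * (k + 1) for k in range(m)]
    if ids is None:
        ids = [f"s{i}" for i in range(n)]
    return PhasedGenotypes(
        individual_ids=np.array(ids, dtype=object),
        chromosomes=np.array(chromosomes, dtype=object),
        positions_bp=np.array(positions, dtype=np.int64),
        ref_alleles=np.array(["A"] * m, dtype=object),
        alt_alleles=np.array(["C"] * m, dtype=object),
        haplotype_calls=hap,
    )


def random_hwe_panel(rng, n, m, p_alt=None, chromosomes=None, positions=None):
    """Unlinked SNPs: every haplotype allele drawn independently (HWE, LE)."""
    if p_alt is None:
        p_alt = rng.uniform(0.1, 0.9, size=m)
    hap = (rng.random((n, m, 2)) < p_alt[None, :, None]).astype(np.int8)
    return make_panel(hap, chromosomes=chromosomes, positions=positions)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
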