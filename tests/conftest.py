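import numpy as np
import pytest

from ficipop.genotypes import GenotypeMatrix


def make_gm(dosage, pos=None, chrom=None, ploidy=2, pops=None, depth=None):
    """Build a small GenotypeMatrix from a (samples x sites) array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_sites = dosage.shape
    sample_ids = [f"s{i}" for i in range(n_samples)]
    if pops is None:
        pops = {s: "pop" for s in sample_ids}
    else:
        pops = {s: p for s, p in zip(sample_ids, pops)}
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 1000
    if chrom is None:
        chrom = ["chr1"] * n_sites
    return GenotypeMatrix(
        sample_ids=sample_ids,
        pop_labels=pops,
        chrom=np.array(chrom, dtype=object),
        pos=np.asarray(pos),
        dosage=dosage,
        ploidy=ploidy,
        depth=None if depth is None else np.asarray(depth, dtype=float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20231127)
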