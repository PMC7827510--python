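import numpy as np
import pandas as pd
import pytest

from sweepscan.model import GenotypeMatrix, HaplotypeMatrix


def make_gm(dosages, groups=None, positions=None, chrom="chr1", refs=None, alts=None,
            effect=None, chrom_lengths=None):
    """Build a small GenotypeMatrix from a samples x sites dosage array.

    ``groups`` maps sample index ranges by default: first half A, second
    half B. Use -1 for missing.
    """
    G = np.asarray(dosages, dtype=np.int8)
    n, m = G.shape
    samples = [f"s{i}" for i in range(n)]
    if groups is None:
        groups = {s: ("A" if i < n // 2 else "B") for i, s in enumerate(samples)}
    else:
        groups = {samples[i]: g for i, g in enumerate(groups)}
    if positions is None:
        positions = [100 * (j + 1) for j in range(m)]
    sites = pd.DataFrame(
        {
            "chrom": chrom if isinstance(chrom, str) else list(chrom),
            "pos": positions,
            "ref": refs if refs is not None else ["A"] * m,
            "alt": alts if alts is not None else ["G"] * m,
            "effect_class": effect if effect is not None else [None] * m,
        }
    )
    return GenotypeMatrix(samples=samples, sites=sites, genotypes=G,
                          groups=groups, chrom_lengths=chrom_lengths)


def make_hm(haplotypes, positions=None, chrom="chr1", chrom_length=None):
    H = np.asarray(haplotypes, dtype=np.uint8)
    n_hap, m = H.shape
    assert n_hap % 2 == 0
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    samples = [f"s{i}" for i in range(n_hap // 2)]
    return HaplotypeMatrix(
        chrom=chrom,
        positions=np.asarray(positions),
        haplotypes=H,
        sample_of=[s for s in samples for _ in range(2)],
        chrom_length=chrom_length,
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated dataset (2 x 2 Mb, 5v5, sweep in B on chr1)."""
    from sweepscan.simulate import default_config, simulate

    return simulate(default_config(seed=7))
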