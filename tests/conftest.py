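import numpy as np
import pandas as pd
import pytest

from admixcape.genio import GenotypeMatrix


def make_gm(calls, populations, chrom="1", pos=None, ref="A", alt="G", cm=None):
    """Build a GenotypeMatrix from a call array and per-sample population labels."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * m if np.isscalar(chrom) else chrom,
            "pos": pos,
            "id": [f"snp{j}" for j in range(m)],
            "ref": [ref] * m if isinstance(ref, str) else ref,
            "alt": [alt] * m if isinstance(alt, str) else alt,
        }
    )
    if cm is not None:
        variants["cm"] = cm
    samples = pd.DataFrame(
        {"population": populations},
        index=pd.Index([f"s{i}" for i in range(n)], name="sample"),
    )
    return GenotypeMatrix(calls, samples, variants)


def gm_from_freqs(rng, freqs_by_pop, n_per_pop, cm=None):
    """Hardy-Weinberg genotypes from per-population allele-frequency arrays."""
    blocks, pops = [], []
    for pop, p in freqs_by_pop.items():
        p = np.asarray(p, float)
        g = rng.binomial(1, p, (2 * n_per_pop, len(p)))
        blocks.append(g[0::2] + g[1::2])
        pops += [pop] * n_per_pop
    return make_gm(np.concatenate(blocks, axis=0), pops, cm=cm)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
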