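"""Rarefaction-standardized counts of private alleles shared by a
population pair.

For a standardized subsample of g allele copies drawn without replacement
from each population, the probability that allele i (k copies among the
n sampled copies of population j) appears in population j's subsample is

    P_present(j) = 1 - C(n_j - k_ij, g) / C(n_j, g).

An allele's contribution to the shared-private count of the pair (A, B)
is P_present(A) * P_present(B) * prod_{j in others} (1 - P_present(j)):
present in both focal subsamples and absent from every other population's
subsample.  Contributions are summed over alleles and averaged over loci.

Loci where any population has fewer than g non-missing copies are excluded
(ADZE-style) and counted in the result.  Note the curve is guaranteed
non-decreasing in g only when there are no third populations; with others
present, larger subsamples also detect the allele in the other populations
more often and the expected count can decrease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genio import GenotypeMatrix, GenotypeError


@dataclass
class RarefactionCurve:
    pop_a: str
    pop_b: str
    levels: np.ndarray            # g = levels[i]
    mean_shared_private: np.ndarray
    n_loci: np.ndarray            # loci contributing at each g
    n_excluded: np.ndarray        # loci excluded for insufficient copies

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "g": self.levels,
                "mean_shared_private": self.mean_shared_private,
                "n_loci": self.n_loci,
                "n_excluded": self.n_excluded,
            }
        )


def _log_comb(n: np.ndarray, k: int) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def presence_probability(n: np.ndarray, k: np.ndarray, g: int) -> np.ndarray:
    """P(allele with k of n copies appears in a g-copy subsample), exact."""
    n = np.asarray(n, float)
    k = np.asarray(k, float)
    absent = np.zeros_like(n)
    ok = n - k >= g
    with np.errstate(invalid="ignore"):
        absent[ok] = np.exp(_log_comb(n[ok] - k[ok], g) - _log_comb(n[ok], g))
    return 1.0 - absent


def shared_private_alleles(
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    other_pops: list[str],
    g_max: int,
    g_min: int = 1,
) -> RarefactionCurve:
    """Rarefaction curve of private alleles shared exclusively by A and B.

    Both SNP alleles contribute.  When ``pop_a == pop_b`` the curve
    degenerates to the single-population private-allele rarefaction of A
    (presence in A's subsample, absence everywhere else).
    """
    pops = [pop_a] + ([pop_b] if pop_b != pop_a else []) + list(other_pops)
    counts = {p: gm.allele_counts(p) for p in pops}
    for p, (_, tot) in counts.items():
        if int(tot.max(initial=0)) < g_max:
            raise GenotypeError(
                f"population {p!r} never has {g_max} non-missing allele copies"
            )
    levels = np.arange(g_min, g_max + 1)
    means = np.zeros(len(levels))
    n_loci = np.zeros(len(levels), dtype=int)
    n_excl = np.zeros(len(levels), dtype=int)
    for gi, g in enumerate(levels):
        usable = np.ones(gm.n_snps, dtype=bool)
        for p in pops:
            usable &= counts[p][1] >= g
        n_excl[gi] = int((~usable).sum())
        n_loci[gi] = int(usable.sum())
        if n_loci[gi] == 0:
            means[gi] = np.nan
            continue
        total = np.zeros(int(usable.sum()))
        for allele in ("alt", "ref"):
            def k_of(p):
                alt, tot = counts[p]
                k = alt if allele == "alt" else tot - alt
                return tot[usable], k[usable]
            na, ka = k_of(pop_a)
            pa = presence_probability(na, ka, int(g))
            if pop_b == pop_a:
                contrib = pa
            else:
                nb, kb = k_of(pop_b)
                contrib = pa * presence_probability(nb, kb, int(g))
            for p in other_pops:
                if p in (pop_a, pop_b):
                    continue
                no, ko = k_of(p)
                contrib = contrib * (1.0 - presence_probability(no, ko, int(g)))
            total += contrib
        means[gi] = float(total.mean())
    return RarefactionCurve(pop_a, pop_b, levels, means, n_loci, n_excl)
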