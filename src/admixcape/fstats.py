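"""Allele-frequency differentiation and admixture statistics.

Implements the Weir & Cockerham (1984) variance-components FST estimator,
f3 and f4 admixture tests with weighted block-jackknife standard errors,
an exhaustive f3 source screen, and Fisher-exact carrier-frequency
comparison between two populations.

f3(T; A, B) is the average over SNPs of (t-a)(t-b); significantly negative
values (low Z) indicate that T is admixed between populations related to A
and B.  The heterozygosity-corrected version subtracts the sampling-noise
term h_t / n_t (h_t the unbiased target heterozygosity, n_t the sampled
allele count), which removes the upward bias of the plug-in estimator.
f4(A, B; C, D) averages (a-b)(c-d) and tests correlated frequency
differences (treeness).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix, GenotypeError

MIN_DIPLOIDS = 2  # per population per SNP for a frequency to be defined


@dataclass(frozen=True)
class JackknifeConfig:
    """Delete-one-block jackknife layout for f-statistics.

    Blocks are contiguous along the genome: *block_size_cm* on the genetic
    map when the variant table has a ``cm`` column, otherwise
    *block_size_mb* physical.  Blocks with fewer than *min_snps_per_block*
    SNPs are merged into the preceding block.
    """

    block_size_cm: float = 5.0
    block_size_mb: float = 5.0
    min_snps_per_block: int = 1

    def __post_init__(self) -> None:
        if self.block_size_cm <= 0 or self.block_size_mb <= 0:
            raise GenotypeError("block size must be positive")


@dataclass
class FStatResult:
    value: float
    se: float
    z: float
    n_blocks: int
    n_snps_used: int
    pops: tuple[str, ...]
    value_uncorrected: float | None = None

    def to_row(self) -> dict:
        d = {f"pop{i+1}": p for i, p in enumerate(self.pops)}
        d.update(
            value=self.value, se=self.se, z=self.z,
            n_snps=self.n_snps_used, n_blocks=self.n_blocks,
        )
        return d


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def _wc_components(gm: GenotypeMatrix, pops: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP WC (1984) variance components a and (a+b+c)."""
    r = len(pops)
    n = np.empty((r, gm.n_snps))       # diploids called
    p = np.empty((r, gm.n_snps))       # alt frequency
    h = np.empty((r, gm.n_snps))       # observed het fraction
    for i, pop in enumerate(pops):
        sub = gm.calls[gm.sample_mask(pop)]
        called = sub != -1
        n[i] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[i] = np.where(called, sub, 0).sum(axis=0) / (2 * n[i])
            h[i] = ((sub == 1) & called).sum(axis=0) / n[i]
    ok = (n >= MIN_DIPLOIDS).all(axis=0)
    nbar = n.mean(axis=0)
    nsum = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n * p).sum(axis=0) / nsum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    mono = (pbar <= 0) | (pbar >= 1)
    ok &= ~mono & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    a = np.where(ok, a, np.nan)
    denom = np.where(ok, a + b + c, np.nan)
    return a, denom


def wc_fst(
    gm: GenotypeMatrix, pops: list[str] | tuple[str, ...], per_snp: bool = False
):
    """Weir-Cockerham FST among two or more populations.

    Returns the genome-wide ratio-of-sums estimate ``sum(a)/sum(a+b+c)``;
    with ``per_snp=True`` also the per-SNP values (NaN where a SNP is
    skipped: monomorphic across all populations or under-called).  Per-SNP
    values may legitimately be negative.
    """
    pops = list(pops)
    if len(pops) < 2:
        raise GenotypeError("need at least two populations")
    a, denom = _wc_components(gm, pops)
    ok = np.isfinite(a)
    if not ok.any():
        raise GenotypeError("no usable SNPs for FST")
    global_fst = float(np.nansum(a) / np.nansum(denom))
    if not per_snp:
        return global_fst
    with np.errstate(invalid="ignore", divide="ignore"):
        snp_fst = a / denom
    return global_fst, snp_fst


# ---------------------------------------------------------------------------
# Block jackknife
# ---------------------------------------------------------------------------

def assign_blocks(variants: pd.DataFrame, cfg: JackknifeConfig) -> np.ndarray:
    """Contiguous genomic block index per SNP."""
    if "cm" in variants.columns and variants["cm"].notna().all():
        coord = variants["cm"].to_numpy(float)
        size = cfg.block_size_cm
    else:
        coord = variants["pos"].to_numpy(float) / 1e6
        size = cfg.block_size_mb
    chroms = variants["chrom"].astype(str).to_numpy()
    block = np.zeros(len(variants), dtype=np.int64)
    nxt = 0
    for ch in pd.unique(chroms):
        m = chroms == ch
        local = np.floor((coord[m] - coord[m].min()) / size).astype(np.int64)
        _, local = np.unique(local, return_inverse=True)
        block[m] = local + nxt
        nxt = block[m].max() + 1
    return block


def _weighted_jackknife(per_snp: np.ndarray, blocks: np.ndarray) -> tuple[float, float, int, int]:
    """Busing-style weighted delete-one-block jackknife of a SNP-mean statistic.

    Returns (estimate, SE, n_blocks, n_snps_used)."""
    ok = np.isfinite(per_snp)
    x = per_snp[ok]
    blk = blocks[ok]
    n = len(x)
    if n == 0:
        raise GenotypeError("no usable SNPs")
    uniq, inv = np.unique(blk, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise GenotypeError("fewer than 2 jackknife blocks: SE undefined")
    m = np.bincount(inv).astype(float)          # SNPs per block
    s = np.bincount(inv, weights=x)             # sum per block
    total = x.sum()
    theta = total / n
    theta_del = (total - s) / (n - m)           # delete-one-block estimates
    h = n / m
    theta_j = g * theta - ((1 - 1 / h) * theta_del).sum()
    var = np.sum((h * theta - (h - 1) * theta_del - theta_j) ** 2 / (h - 1)) / g
    return float(theta), float(np.sqrt(var)), g, n


def _pop_freqs(gm: GenotypeMatrix, pops: list[str]) -> tuple[np.ndarray, np.ndarray]:
    freqs = np.stack([gm.allele_freq(p, MIN_DIPLOIDS) for p in pops])
    counts = np.stack([gm.allele_counts(p)[1] for p in pops]).astype(float)
    return freqs, counts


def _fstat(gm, pops, per_snp_fn, cfg) -> tuple[float, float, int, int, np.ndarray]:
    freqs, counts = _pop_freqs(gm, pops)
    per_snp = per_snp_fn(freqs, counts)
    per_snp[~np.isfinite(freqs).all(axis=0)] = np.nan
    blocks = assign_blocks(gm.variants, cfg or JackknifeConfig())
    return *_weighted_jackknife(per_snp, blocks), per_snp


def f3_test(
    gm: GenotypeMatrix,
    target: str,
    source_a: str,
    source_b: str,
    cfg: JackknifeConfig | None = None,
    freq_corrected: bool = True,
) -> FStatResult:
    """f3(target; source_a, source_b) with block-jackknife SE.

    With ``freq_corrected`` (default) the target sampling-noise term
    h_t/n_t is subtracted per SNP; the uncorrected mean is reported in
    ``value_uncorrected``.  Z is defined as 0 when both the value and SE
    are exactly 0 (degenerate identical-population input).
    """
    if len({target, source_a, source_b}) != 3:
        raise GenotypeError("f3 requires three distinct population labels")
    pops = [target, source_a, source_b]

    def per_snp(freqs, counts):
        t, a, b = freqs
        nt = counts[0]
        raw = (t - a) * (t - b)
        if freq_corrected:
            with np.errstate(invalid="ignore", divide="ignore"):
                het = t * (1 - t) * nt / (nt - 1)
                raw = raw - het / nt
        return raw

    value, se, n_blocks, n_used, _ = _fstat(gm, pops, per_snp, cfg)
    if freq_corrected:
        freqs, counts = _pop_freqs(gm, pops)
        raw = (freqs[0] - freqs[1]) * (freqs[0] - freqs[2])
        raw[~np.isfinite(freqs).all(axis=0)] = np.nan
        unc = float(np.nanmean(raw))
    else:
        unc = value
    z = 0.0 if (se == 0 and value == 0) else value / se if se > 0 else np.inf * np.sign(value)
    return FStatResult(value, se, float(z), n_blocks, n_used, tuple(pops), unc)


def f4_test(
    gm: GenotypeMatrix, a: str, b: str, c: str, d: str, cfg: JackknifeConfig | None = None
) -> FStatResult:
    """f4(a, b; c, d): positive values indicate allele-frequency differences
    a-b correlate with c-d (a/c and b/d affinity)."""
    if len({a, b, c, d}) != 4:
        raise GenotypeError("f4 requires four distinct population labels")
    pops = [a, b, c, d]

    def per_snp(freqs, counts):
        return (freqs[0] - freqs[1]) * (freqs[2] - freqs[3])

    value, se, n_blocks, n_used, _ = _fstat(gm, pops, per_snp, cfg)
    z = 0.0 if (se == 0 and value == 0) else value / se if se > 0 else np.inf * np.sign(value)
    return FStatResult(value, se, float(z), n_blocks, n_used, tuple(pops))


def f3_screen(
    gm: GenotypeMatrix,
    target: str,
    candidate_pops: list[str],
    cfg: JackknifeConfig | None = None,
    fixed_source: str | None = None,
    freq_corrected: bool = True,
) -> pd.DataFrame:
    """All unordered source pairs tested as f3(target; A, B), sorted ascending
    by Z (most negative = strongest admixture signal first).  With
    *fixed_source* only pairs containing it are run."""
    cands = [p for p in candidate_pops if p != target]
    if len(cands) < 2:
        raise GenotypeError("need at least two candidate sources")
    if fixed_source is not None:
        if fixed_source not in cands:
            raise GenotypeError(f"fixed source {fixed_source!r} not among candidates")
        pairs = [(fixed_source, c) for c in cands if c != fixed_source]
    else:
        pairs = list(itertools.combinations(cands, 2))
    rows = []
    for sa, sb in pairs:
        res = f3_test(gm, target, sa, sb, cfg, freq_corrected)
        row = {"target": target, "source_a": sa, "source_b": sb}
        row.update(
            value=res.value, se=res.se, z=res.z,
            n_snps=res.n_snps_used, n_blocks=res.n_blocks,
        )
        rows.append(row)
    return pd.DataFrame(rows).sort_values("z", ignore_index=True)


# ---------------------------------------------------------------------------
# Carrier-frequency comparison
# ---------------------------------------------------------------------------

def carrier_frequency_test(
    counts_a: tuple[int, int, int],
    counts_b: tuple[int, int, int],
    model: str = "allelic",
) -> dict:
    """Compare allele or carrier frequency between two populations.

    *counts* are genotype counts ``(hom_alt, het, hom_ref)``.  The allelic
    model compares alternate-allele counts over 2N chromosomes; the
    ``dominant_carrier`` model compares carriers (hom_alt + het) against
    hom_ref individuals.  Two-sided Fisher exact p on the 2x2 table.
    """
    for counts in (counts_a, counts_b):
        if any(c < 0 for c in counts):
            raise GenotypeError("genotype counts must be non-negative")
        if sum(counts) == 0:
            raise GenotypeError("at least one observation per population required")
    def table_row(counts):
        hom_alt, het, hom_ref = counts
        n = hom_alt + het + hom_ref
        if model == "allelic":
            alt = 2 * hom_alt + het
            return alt, 2 * n - alt
        if model == "dominant_carrier":
            return hom_alt + het, hom_ref
        raise GenotypeError(f"unknown model {model!r}")

    row_a, row_b = table_row(counts_a), table_row(counts_b)
    _, p = stats.fisher_exact([row_a, row_b], alternative="two-sided")
    return {
        "freq_a": row_a[0] / sum(row_a),
        "freq_b": row_b[0] / sum(row_b),
        "p_value": float(p),
        "table": (row_a, row_b),
        "model": model,
    }
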