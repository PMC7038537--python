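"""Extended haplotype homozygosity statistics: EHH, iHS and XP-EHH.

EHH at a flanking SNP x, for the haplotypes carrying a core allele at the
focal SNP, is the probability that two distinct carrier haplotypes are
identical over the whole interval from the focal SNP to x:

    EHH(x) = sum_h C(n_h, 2) / C(n_core, 2)

over the distinct extended haplotypes h.  EHH starts at 1 at the focal SNP
and is non-increasing with distance.  The computation is truncated when
EHH drops below a floor (0.05 by default) or when the gap between
consecutive SNPs exceeds 200 kb, matching the maximum inter-SNP distance
rule used for array data.

iHS integrates EHH over genetic distance separately for the ancestral and
derived core alleles (iHH_A, iHH_D); the unstandardized score
ln(iHH_A/iHH_D) is standardized within derived-allele-frequency bins so
that scores are comparable across frequencies.  XP-EHH contrasts the same
integral between two populations at every SNP, using all haplotypes of
each population (no polarization needed), standardized genome-wide.

Note the combinatorial EHH estimator is unbiased but not exactly invariant
under duplicating every haplotype (sample-frequency squared would be); the
difference is O(1/n) and vanishes with haplotype count.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .genio import GenotypeError

EHH_FLOOR = 0.05
GAP_MAX_BP = 200_000


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes on a shared SNP grid.

    ``hap`` is (n_haplotypes, n_snps) with values in {0,1}; haplotypes
    2i and 2i+1 belong to diploid sample i.  ``pos_cm`` defaults to
    ``pos_bp`` scaled at 1 cM/Mb when no genetic map is given.
    """

    hap: np.ndarray
    pos_bp: np.ndarray
    pos_cm: np.ndarray | None = None
    chrom: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hap = np.asarray(self.hap, dtype=np.uint8)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        if self.hap.ndim != 2 or self.hap.shape[1] != len(self.pos_bp):
            raise GenotypeError("hap must be (n_haplotypes, n_snps) matching positions")
        if not np.isin(self.hap, (0, 1)).all():
            raise GenotypeError("haplotype values must be 0/1")
        if np.any(np.diff(self.pos_bp) <= 0):
            raise GenotypeError("positions must be strictly increasing")
        if self.hap.shape[0] % 2:
            raise GenotypeError("haplotype count must be even (diploid samples)")
        if self.pos_cm is None:
            self.pos_cm = self.pos_bp / 1e6  # 1 cM/Mb
        self.pos_cm = np.asarray(self.pos_cm, dtype=float)
        if self.chrom is None:
            self.chrom = np.repeat("1", len(self.pos_bp))

    @property
    def n_haplotypes(self) -> int:
        return self.hap.shape[0]

    @property
    def n_snps(self) -> int:
        return self.hap.shape[1]


def assign_ancestral(
    variants: pd.DataFrame, outgroup_alleles: np.ndarray
) -> pd.DataFrame:
    """Ancestral-allele assignment by outgroup unanimity.

    *outgroup_alleles* is (n_snps, n_outgroups) of allele letters with
    missing entries as ``""`` or ``None``.  The ancestral allele is the
    unanimous non-missing outgroup state when it matches one of the SNP's
    two alleles; otherwise unknown.  Unknowns are data (excluded from iHS),
    not errors.
    """
    og = np.asarray(outgroup_alleles, dtype=object)
    if og.ndim != 2 or og.shape[0] != len(variants):
        raise GenotypeError("outgroup_alleles must be (n_snps, n_outgroups)")
    ref = variants["ref"].to_numpy()
    alt = variants["alt"].to_numpy()
    anc = np.full(len(variants), None, dtype=object)
    n_agree = np.zeros(len(variants), dtype=int)
    for j in range(len(variants)):
        states = {a for a in og[j] if a not in (None, "", ".")}
        if len(states) == 1:
            state = states.pop()
            n_agree[j] = sum(1 for a in og[j] if a == state)
            if state in (ref[j], alt[j]):
                anc[j] = state
    return pd.DataFrame(
        {"ancestral": anc, "n_outgroups_agreeing": n_agree}, index=variants.index
    )


def _pair_hom(counts: np.ndarray, n: int) -> float:
    """sum C(c,2) / C(n,2) over group sizes c."""
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _ehh_side(
    hap: np.ndarray,
    carriers: np.ndarray,
    focal: int,
    step: int,
    pos_bp: np.ndarray,
    gap_max_bp: int,
    floor: float,
) -> tuple[list[int], list[float]]:
    """EHH along one direction; returns flanking SNP indices and EHH values,
    stopping before the first sub-floor value or a >gap_max_bp gap."""
    n = int(carriers.sum())
    group = np.zeros(n, dtype=np.int64)
    sub = hap[carriers]
    idxs: list[int] = []
    vals: list[float] = []
    j = focal
    while True:
        j_next = j + step
        if j_next < 0 or j_next >= hap.shape[1]:
            break
        if abs(int(pos_bp[j_next]) - int(pos_bp[j])) > gap_max_bp:
            break
        key = group * 2 + sub[:, j_next]
        _, group = np.unique(key, return_inverse=True)
        ehh = _pair_hom(np.bincount(group), n)
        if ehh < floor:
            break
        idxs.append(j_next)
        vals.append(ehh)
        j = j_next
        if ehh == 0.0:
            break
    return idxs, vals


def ehh_curve(
    haps: HaplotypeSet,
    focal_snp: int,
    core_allele: int,
    gap_max_bp: int = GAP_MAX_BP,
    floor: float = EHH_FLOOR,
) -> pd.DataFrame:
    """EHH decay curve around a focal SNP for one core allele.

    Returns a frame of (snp_index, pos_bp, pos_cm, side, ehh) including the
    focal SNP (ehh = 1) on both sides, truncated at the EHH floor and at
    gaps > *gap_max_bp*.
    """
    carriers = haps.hap[:, focal_snp] == core_allele
    if carriers.sum() < 2:
        raise GenotypeError("EHH undefined: fewer than 2 core-allele carriers")
    rows = []
    for side, step in (("left", -1), ("right", +1)):
        rows.append((focal_snp, side, 1.0))
        idxs, vals = _ehh_side(
            haps.hap, carriers, focal_snp, step, haps.pos_bp, gap_max_bp, floor
        )
        rows += [(i, side, v) for i, v in zip(idxs, vals)]
    out = pd.DataFrame(rows, columns=["snp_index", "side", "ehh"])
    out["pos_bp"] = haps.pos_bp[out["snp_index"]]
    out["pos_cm"] = haps.pos_cm[out["snp_index"]]
    return out[["snp_index", "pos_bp", "pos_cm", "side", "ehh"]]


def _ihh(
    hap: np.ndarray,
    carriers: np.ndarray,
    focal: int,
    pos_bp: np.ndarray,
    pos_cm: np.ndarray,
    gap_max_bp: int,
    floor: float,
) -> float:
    """Integrated EHH (trapezoid over cM) for one core, both directions."""
    total = 0.0
    for step in (-1, +1):
        idxs, vals = _ehh_side(hap, carriers, focal, step, pos_bp, gap_max_bp, floor)
        prev_cm, prev_ehh = pos_cm[focal], 1.0
        for i, v in zip(idxs, vals):
            total += abs(pos_cm[i] - prev_cm) * (v + prev_ehh) / 2.0
            prev_cm, prev_ehh = pos_cm[i], v
    return total


def ihs_scan(
    haps: HaplotypeSet,
    ancestral: pd.DataFrame,
    variants: pd.DataFrame | None = None,
    maf_min: float = 0.05,
    gap_max_bp: int = GAP_MAX_BP,
    floor: float = EHH_FLOOR,
    bin_width: float = 0.05,
    min_bin_snps: int = 20,
) -> pd.DataFrame:
    """Integrated haplotype score scan within one population.

    *ancestral* is the frame from :func:`assign_ancestral` (its ``ancestral``
    column, aligned to the SNP grid; when *variants* is given the letters are
    translated against ref/alt, otherwise a non-null entry means "0 is
    ancestral" unless it equals the string "alt").  Scores are standardized
    within derived-allele-frequency bins of *bin_width*; bins with fewer
    than *min_bin_snps* SNPs are merged with their neighbours.

    Returns per-SNP (pos_bp, freq_derived, ihs_raw, ihs_std, flag).
    """
    n_snps = haps.n_snps
    anc_col = ancestral["ancestral"].to_numpy(object)
    if variants is not None:
        ref = variants["ref"].to_numpy()
        anc_is_zero = np.array(
            [a is not None and a == ref[j] for j, a in enumerate(anc_col)]
        )
        polarized = np.array([a is not None for a in anc_col])
    else:
        polarized = np.array([a is not None for a in anc_col])
        anc_is_zero = np.array([a != "alt" for a in anc_col])

    freq1 = haps.hap.mean(axis=0)
    raw = np.full(n_snps, np.nan)
    daf = np.full(n_snps, np.nan)
    flag = np.full(n_snps, "ok", dtype=object)
    for j in range(n_snps):
        if not polarized[j]:
            flag[j] = "unpolarized"
            continue
        # derived allele is the non-ancestral one
        f_derived = freq1[j] if anc_is_zero[j] else 1 - freq1[j]
        daf[j] = f_derived
        if min(freq1[j], 1 - freq1[j]) < maf_min:
            flag[j] = "maf"
            continue
        anc_allele = 0 if anc_is_zero[j] else 1
        carriers_a = haps.hap[:, j] == anc_allele
        carriers_d = ~carriers_a
        if carriers_a.sum() < 2 or carriers_d.sum() < 2:
            flag[j] = "singleton_core"
            continue
        ihh_a = _ihh(haps.hap, carriers_a, j, haps.pos_bp, haps.pos_cm, gap_max_bp, floor)
        ihh_d = _ihh(haps.hap, carriers_d, j, haps.pos_bp, haps.pos_cm, gap_max_bp, floor)
        if ihh_a <= 0 or ihh_d <= 0:
            flag[j] = "ehh_floor"
            continue
        raw[j] = np.log(ihh_a / ihh_d)

    std = _standardize_binned(raw, daf, bin_width, min_bin_snps)
    return pd.DataFrame(
        {
            "pos_bp": haps.pos_bp,
            "freq_derived": daf,
            "ihs_raw": raw,
            "ihs_std": std,
            "flag": flag,
        }
    )


def _standardize_binned(
    raw: np.ndarray, freq: np.ndarray, bin_width: float, min_bin_snps: int
) -> np.ndarray:
    """Z-standardize scores within frequency bins, merging sparse bins."""
    std = np.full_like(raw, np.nan)
    ok = np.isfinite(raw) & np.isfinite(freq)
    if not ok.any():
        return std
    nbins = int(np.ceil(1.0 / bin_width))
    code = np.minimum((freq[ok] / bin_width).astype(int), nbins - 1)
    # merge sparse bins left-to-right into groups of >= min_bin_snps
    group_of_bin = np.zeros(nbins, dtype=int)
    counts = np.bincount(code, minlength=nbins)
    gid, acc = 0, 0
    for b in range(nbins):
        group_of_bin[b] = gid
        acc += counts[b]
        if acc >= min_bin_snps:
            gid, acc = gid + 1, 0
    if acc > 0 and gid > 0:  # trailing underfull group merges into previous
        group_of_bin[group_of_bin == gid] = gid - 1
    groups = group_of_bin[code]
    x = raw[ok]
    out = np.full(len(x), np.nan)
    for g in np.unique(groups):
        m = groups == g
        if m.sum() < 2:
            warnings.warn(f"standardization bin {g} has <2 SNPs; dropped")
            continue
        mu, sd = x[m].mean(), x[m].std(ddof=0)
        if sd == 0:
            warnings.warn(f"standardization bin {g} has zero variance; dropped")
            continue
        out[m] = (x[m] - mu) / sd
    std[ok] = out
    return std


def xpehh_scan(
    haps_a: HaplotypeSet,
    haps_b: HaplotypeSet,
    gap_max_bp: int = GAP_MAX_BP,
    floor: float = EHH_FLOOR,
    standardize: bool = True,
) -> pd.DataFrame:
    """Cross-population EHH scan: ln(iHH_A / iHH_B) per SNP.

    Both populations must share the SNP grid.  At each focal SNP the decay
    extent is determined on the pooled haplotypes (truncating when the
    pooled EHH drops below the floor or at a >gap_max_bp gap) and both
    populations are integrated over that same extent, so identical
    populations score exactly 0 and swapping populations negates every
    score.  Standardization is genome-wide (single bin).
    """
    if haps_a.n_snps != haps_b.n_snps or not np.array_equal(haps_a.pos_bp, haps_b.pos_bp):
        raise GenotypeError("populations must share the same SNP grid")
    if haps_a.n_haplotypes < 2 or haps_b.n_haplotypes < 2:
        raise GenotypeError("need at least 2 haplotypes per population")
    nA, nB = haps_a.n_haplotypes, haps_b.n_haplotypes
    hap = np.concatenate([haps_a.hap, haps_b.hap], axis=0)
    pos_bp, pos_cm = haps_a.pos_bp, haps_a.pos_cm
    n_snps = haps_a.n_snps
    n = nA + nB

    raw = np.full(n_snps, np.nan)
    flag = np.full(n_snps, "ok", dtype=object)
    for j in range(n_snps):
        ihh_a = ihh_b = 0.0
        for step in (-1, +1):
            group = np.zeros(n, dtype=np.int64)
            prev_cm = pos_cm[j]
            ehh_a_prev = ehh_b_prev = 1.0
            k = j
            while True:
                k_next = k + step
                if k_next < 0 or k_next >= n_snps:
                    break
                if abs(int(pos_bp[k_next]) - int(pos_bp[k])) > gap_max_bp:
                    break
                key = group * 2 + hap[:, k_next]
                _, group = np.unique(key, return_inverse=True)
                counts_a = np.bincount(group[:nA])
                counts_b = np.bincount(group[nA:])
                pooled = _pair_hom(np.bincount(group), n)
                if pooled < floor:
                    break
                ehh_a = _pair_hom(counts_a, nA)
                ehh_b = _pair_hom(counts_b, nB)
                d = abs(pos_cm[k_next] - prev_cm)
                ihh_a += d * (ehh_a + ehh_a_prev) / 2.0
                ihh_b += d * (ehh_b + ehh_b_prev) / 2.0
                prev_cm, ehh_a_prev, ehh_b_prev = pos_cm[k_next], ehh_a, ehh_b
                k = k_next
        if ihh_a <= 0 or ihh_b <= 0:
            flag[j] = "zero_ihh"
            continue
        raw[j] = np.log(ihh_a / ihh_b)

    out = pd.DataFrame({"pos_bp": pos_bp, "xpehh_raw": raw, "flag": flag})
    if standardize:
        ok = np.isfinite(raw)
        std = np.full(n_snps, np.nan)
        if ok.sum() >= 2 and raw[ok].std(ddof=0) > 0:
            std[ok] = (raw[ok] - raw[ok].mean()) / raw[ok].std(ddof=0)
        elif ok.any():
            std[ok] = 0.0  # degenerate: all scores identical (e.g. pop vs itself)
        out["xpehh_std"] = std
    return out
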