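"""Genotype containers, PED/MAP and VCF I/O, quality control, merging,
relatedness pruning and local-ancestry masking.

The central container is :class:`GenotypeMatrix`: diploid biallelic calls
stored as alternate-allele counts (``0/1/2``, ``-1`` for missing) in a
``samples x variants`` integer array, with a variant table (chrom, pos, id,
ref, alt, optional cM position) and a population label per sample.

Coordinate conventions: positions are 1-based on disk (VCF/MAP) and kept
1-based in the variant table; ancestry-tract intervals are 0-based
half-open in base pairs, as in BED.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

MISSING = -1

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


class GenotypeError(ValueError):
    """Raised for malformed genotype data or invalid parameters."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for a set of labelled samples.

    Parameters
    ----------
    calls
        ``(n_samples, n_snps)`` int array of alternate-allele counts in
        ``{0, 1, 2}`` with ``-1`` marking a missing call.
    samples
        DataFrame indexed by unique sample id with a ``population`` column.
    variants
        DataFrame with columns ``chrom, pos, id, ref, alt`` and optionally
        ``cm`` (genetic position in centimorgans).
    """

    calls: np.ndarray
    samples: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise GenotypeError("calls must be 2-D (samples x variants)")
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise GenotypeError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if not self.samples.index.is_unique:
            raise GenotypeError("sample labels must be unique")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeError("calls must be in {0,1,2} or -1 (missing)")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))

    def sample_mask(self, population: str) -> np.ndarray:
        mask = (self.samples["population"] == population).to_numpy()
        if not mask.any():
            raise GenotypeError(f"population {population!r} not present")
        return mask

    def take_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls[mask], self.samples.loc[mask].copy(), self.variants.copy())

    def take_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls[:, mask], self.samples.copy(), self.variants.loc[mask].copy()
        )

    def allele_counts(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP (alt allele count, total called allele count) in a population."""
        sub = self.calls[self.sample_mask(population)]
        called = sub != MISSING
        alt = np.where(called, sub, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)

    def allele_freq(self, population: str, min_diploids: int = 1) -> np.ndarray:
        """Per-SNP alternate-allele frequency; NaN where fewer than
        *min_diploids* non-missing diploid calls."""
        alt, total = self.allele_counts(population)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = alt / total
        freq[total < 2 * min_diploids] = np.nan
        return freq

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.calls, other.calls)
            and self.samples.equals(other.samples)
            and self.variants[VARIANT_COLUMNS].equals(other.variants[VARIANT_COLUMNS])
        )


@dataclass
class QcReport:
    n_removed_missingness: int = 0
    n_removed_hwe: int = 0
    n_removed_atcg: int = 0
    n_removed_structural: int = 0
    samples_removed: list[str] = field(default_factory=list)
    pairs_flagged_ibs: list[tuple[str, str]] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["structural", "individual_missingness", "snp_missingness", "hwe", "atcg"],
                "n_removed": [
                    self.n_removed_structural,
                    len(self.samples_removed),
                    self.n_removed_missingness,
                    self.n_removed_hwe,
                    self.n_removed_atcg,
                ],
            }
        )


@dataclass
class MergeReport:
    n_overlap: int
    n_flipped: int
    n_dropped_mismatch: int
    n_allele_swapped: int


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def save_genotypes(gm: GenotypeMatrix, prefix_or_path, fmt: str = "ped_map") -> None:
    """Write *gm* as PED/MAP (``fmt='ped_map'``, path is a prefix) or as an
    uncompressed VCF v4.2 with unphased GT (``fmt='vcf'``)."""
    if fmt == "ped_map":
        _write_ped_map(gm, str(prefix_or_path))
    elif fmt == "vcf":
        _write_vcf(gm, str(prefix_or_path))
    else:
        raise GenotypeError(f"unknown format {fmt!r}")


def load_genotypes(path, fmt: str = "ped_map", alleles: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Load genotypes from PED/MAP (*path* is the shared prefix) or VCF.

    For PED, *alleles* may provide the ref/alt designation per SNP (a frame
    with ``ref``/``alt`` columns aligned to the MAP order); otherwise the
    major observed allele is taken as ref (ties broken alphabetically).
    """
    if fmt == "ped_map":
        return _read_ped_map(str(path), alleles)
    if fmt == "vcf":
        return _read_vcf(str(path))
    raise GenotypeError(f"unknown format {fmt!r}")


def _write_ped_map(gm: GenotypeMatrix, prefix: str) -> None:
    v = gm.variants
    with open(prefix + ".map", "w") as fh:
        cm = v["cm"] if "cm" in v.columns else pd.Series(0.0, index=v.index)
        for chrom, vid, c, pos in zip(v["chrom"], v["id"], cm, v["pos"]):
            fh.write(f"{chrom}\t{vid}\t{c:.6f}\t{pos}\n")
    ref = v["ref"].to_numpy(dtype="U1")
    alt = v["alt"].to_numpy(dtype="U1")
    # genotype code -> two allele letters per SNP
    lookup = np.stack(
        [
            np.char.add(np.char.add(ref, " "), ref),      # 0
            np.char.add(np.char.add(ref, " "), alt),      # 1
            np.char.add(np.char.add(alt, " "), alt),      # 2
        ]
    )
    with open(prefix + ".ped", "w") as fh:
        for i, (sid, row) in enumerate(gm.samples.iterrows()):
            g = gm.calls[i]
            fields = np.where(g == MISSING, "0 0", lookup[np.clip(g, 0, 2), np.arange(gm.n_snps)])
            fh.write(f"{row['population']} {sid} 0 0 0 -9 " + " ".join(fields) + "\n")


def _read_ped_map(prefix: str, alleles: pd.DataFrame | None) -> GenotypeMatrix:
    vmap = pd.read_csv(
        prefix + ".map", sep=r"\s+", header=None, names=["chrom", "id", "cm", "pos"],
        dtype={"chrom": str},
    )
    n_snps = len(vmap)
    sample_ids, pops, rows = [], [], []
    with open(prefix + ".ped") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise GenotypeError(
                    f"{prefix}.ped line {lineno}: expected {6 + 2 * n_snps} fields, got {len(parts)}"
                )
            pops.append(parts[0])
            sample_ids.append(parts[1])
            rows.append(np.array(parts[6:], dtype="U1").reshape(n_snps, 2))
    if not rows:
        raise GenotypeError(f"{prefix}.ped: no samples")
    allele_pairs = np.stack(rows)  # (n_samples, n_snps, 2)
    if alleles is not None:
        ref = alleles["ref"].to_numpy(dtype="U1")
        alt = alleles["alt"].to_numpy(dtype="U1")
    else:
        ref, alt = _infer_alleles(allele_pairs)
    calls = np.full((len(rows), n_snps), MISSING, dtype=np.int8)
    observed = allele_pairs != "0"
    is_alt = allele_pairs == alt[None, :, None]
    is_ref = allele_pairs == ref[None, :, None]
    valid = (observed & (is_alt | is_ref)).all(axis=2)
    calls[valid] = is_alt.sum(axis=2)[valid]
    variants = vmap[["chrom", "pos", "id"]].copy()
    variants["ref"] = ref
    variants["alt"] = alt
    variants["cm"] = vmap["cm"]
    samples = pd.DataFrame({"population": pops}, index=pd.Index(sample_ids, name="sample"))
    return GenotypeMatrix(calls, samples, variants)


def _infer_alleles(pairs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n_snps = pairs.shape[1]
    ref = np.empty(n_snps, dtype="U1")
    alt = np.empty(n_snps, dtype="U1")
    for j in range(n_snps):
        col = pairs[:, j, :].ravel()
        letters, counts = np.unique(col[col != "0"], return_counts=True)
        if len(letters) > 2:
            raise GenotypeError(f"SNP column {j}: more than two alleles {letters.tolist()}")
        if len(letters) == 0:
            ref[j], alt[j] = "A", "C"  # fully missing column, arbitrary
        elif len(letters) == 1:
            ref[j], alt[j] = letters[0], "0"
        else:
            order = np.lexsort((letters, -counts))  # major first, alphabetical tie-break
            ref[j], alt[j] = letters[order[0]], letters[order[1]]
    return ref, alt


def _write_vcf(gm: GenotypeMatrix, path: str, haplotypes: np.ndarray | None = None) -> None:
    codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(gm.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, gm.samples.index)) + "\n")
        v = gm.variants
        for j in range(gm.n_snps):
            if haplotypes is None:
                gts = "\t".join(codes[int(g)] for g in gm.calls[:, j])
            else:
                gts = "\t".join(
                    f"{haplotypes[2 * i, j]}|{haplotypes[2 * i + 1, j]}"
                    for i in range(gm.n_samples)
                )
            fh.write(
                f"{v['chrom'][j]}\t{v['pos'][j]}\t{v['id'][j]}\t{v['ref'][j]}\t{v['alt'][j]}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def load_phased_vcf(path: str) -> tuple[GenotypeMatrix, np.ndarray]:
    """Read a fully phased VCF; returns the genotype matrix plus the
    (2*n_samples, n_snps) haplotype array (sample i -> rows 2i, 2i+1)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    chroms, poss, ids, refs, alts, cols = [], [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise GenotypeError(f"{path} pos {rec.POS}: not biallelic")
        gts = np.asarray(rec.genotypes, dtype=object)
        if not all(gts[:, 2]):
            raise GenotypeError(f"{path} pos {rec.POS}: unphased genotype")
        hap = gts[:, :2].astype(int)
        if (hap < 0).any():
            raise GenotypeError(f"{path} pos {rec.POS}: missing call in phased input")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        cols.append(hap.reshape(-1))
    vcf.close()
    if not cols:
        raise GenotypeError(f"{path}: no variant records")
    haps = np.stack(cols, axis=1).astype(np.uint8)
    calls = (haps[0::2] + haps[1::2]).astype(np.int8)
    variants = pd.DataFrame({"chrom": chroms, "pos": poss, "id": ids, "ref": refs, "alt": alts})
    samples = pd.DataFrame(
        {"population": ["unknown"] * len(sample_ids)},
        index=pd.Index(sample_ids, name="sample"),
    )
    return GenotypeMatrix(calls, samples, variants), haps


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    chroms, poss, ids, refs, alts, rows = [], [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise GenotypeError(f"{path} pos {rec.POS}: not biallelic")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        gt = np.asarray(rec.genotypes, dtype=object)[:, :2].astype(int)
        col = np.where((gt < 0).any(axis=1), MISSING, gt.clip(min=0).sum(axis=1))
        rows.append(col)
    vcf.close()
    if not rows:
        raise GenotypeError(f"{path}: no variant records")
    calls = np.stack(rows, axis=1).astype(np.int8)
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "id": ids, "ref": refs, "alt": alts}
    )
    samples = pd.DataFrame(
        {"population": ["unknown"] * len(sample_ids)},
        index=pd.Index(sample_ids, name="sample"),
    )
    return GenotypeMatrix(calls, samples, variants)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value (plain exact, no mid-p correction).

    Sums the probabilities of all heterozygote counts, conditional on the
    observed allele counts, that are no more likely than the observed one.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(het = h | allele counts) up to a shared constant
    logp = (
        hets * np.log(2.0)
        + special.gammaln(n + 1)
        - special.gammaln((n_rare - hets) / 2 + 1)
        - special.gammaln(hets + 1)
        - special.gammaln(n - (n_rare + hets) / 2 + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_het)]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


_SEX_MITO = {"x", "y", "xy", "mt", "m", "23", "24", "25", "26"}


def qc_filter(
    gm: GenotypeMatrix,
    snp_missing_max: float = 0.10,
    ind_missing_max: float = 0.15,
    hwe_alpha: float = 0.001,
    drop_atcg: bool = True,
    hwe_per_population: bool = False,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply standard array QC.

    Order: structural removals (chrom 0, sex/mito chromosomes, indels,
    duplicate positions) -> individual missingness (> *ind_missing_max*
    removed) -> SNP missingness recomputed on the surviving samples
    (> *snp_missing_max* removed) -> exact HWE at p < *hwe_alpha* -> A/T and
    C/G (strand-ambiguous) SNPs.  Thresholds are exclusive: a SNP exactly at
    the missingness bound is retained.

    With ``hwe_per_population`` the exact HWE test runs within each
    population and a SNP is removed if it fails in any of them; the pooled
    test is otherwise confounded by allele-frequency structure (Wahlund
    excess homozygosity) and preferentially removes differentiated SNPs.
    """
    if gm.n_snps == 0 or gm.n_samples == 0:
        raise GenotypeError("empty genotype matrix")
    rep = QcReport()
    v = gm.variants
    chrom = v["chrom"].astype(str).str.lower()
    acgt = set("ACGT")
    is_indel = ~(v["ref"].isin(acgt) & v["alt"].isin(acgt))
    is_dup = v.duplicated(subset=["chrom", "pos"], keep=False)
    structural = (chrom == "0") | chrom.isin(_SEX_MITO) | is_indel | is_dup
    rep.n_removed_structural = int(structural.sum())
    logged = pd.Series(False, index=v.index)
    for rule, mask in (
        ("chrom0", chrom == "0"),
        ("sex_mito", chrom.isin(_SEX_MITO)),
        ("indel", is_indel),
        ("duplicate", is_dup),
    ):
        fresh = mask & ~logged  # one attributable rule per removed SNP
        logged |= mask
        for vid in v.loc[fresh, "id"]:
            rep.log.append(f"snp\t{vid}\tremoved\t{rule}")
    gm = gm.take_variants(~structural.to_numpy())
    if gm.n_snps == 0:
        rep.log.append("warning\tall SNPs removed by QC")
        return gm, rep

    miss_ind = (gm.calls == MISSING).mean(axis=1)
    keep_ind = miss_ind <= ind_missing_max
    rep.samples_removed = list(gm.samples.index[~keep_ind])
    for sid in rep.samples_removed:
        rep.log.append(f"sample\t{sid}\tremoved\tind_missingness")
    gm = gm.take_samples(keep_ind)
    if gm.n_samples == 0:
        raise GenotypeError("all samples removed by missingness filter")

    miss_snp = (gm.calls == MISSING).mean(axis=0)
    keep = miss_snp <= snp_missing_max
    rep.n_removed_missingness = int((~keep).sum())
    for vid in gm.variants.loc[~keep, "id"]:
        rep.log.append(f"snp\t{vid}\tremoved\tsnp_missingness")
    gm = gm.take_variants(keep)

    groups = (
        [gm.sample_mask(p) for p in gm.populations()]
        if hwe_per_population
        else [np.ones(gm.n_samples, dtype=bool)]
    )
    keep = np.ones(gm.n_snps, dtype=bool)
    for mask in groups:
        sub = gm.calls[mask]
        n_het = (sub == 1).sum(axis=0)
        n_hom_ref = (sub == 0).sum(axis=0)
        n_hom_alt = (sub == 2).sum(axis=0)
        pvals = np.array(
            [hwe_exact_p(int(h), int(a), int(b)) for h, a, b in zip(n_het, n_hom_ref, n_hom_alt)]
        )
        keep &= pvals >= hwe_alpha
    rep.n_removed_hwe = int((~keep).sum())
    for vid in gm.variants.loc[~keep, "id"]:
        rep.log.append(f"snp\t{vid}\tremoved\thwe")
    gm = gm.take_variants(keep)

    if drop_atcg:
        pair = gm.variants["ref"] + gm.variants["alt"]
        ambiguous = pair.isin(["AT", "TA", "CG", "GC"]).to_numpy()
        rep.n_removed_atcg = int(ambiguous.sum())
        for vid in gm.variants.loc[ambiguous, "id"]:
            rep.log.append(f"snp\t{vid}\tremoved\tatcg")
        gm = gm.take_variants(~ambiguous)
    if gm.n_snps == 0:
        rep.log.append("warning\tall SNPs removed by QC")
    return gm, rep


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def merge_datasets(a: GenotypeMatrix, b: GenotypeMatrix) -> tuple[GenotypeMatrix, MergeReport]:
    """Merge two QC'd datasets on overlapping (chrom, pos).

    Allele-set mismatches are resolved by complementing b's alleles once
    (a strand flip); SNPs still mismatching are dropped.  When b's alleles
    match a's but with ref/alt swapped, b's calls are recoded (2 - g).
    Requires A/T and C/G SNPs to have been removed (flips are otherwise
    ambiguous).
    """
    ka = pd.MultiIndex.from_frame(a.variants[["chrom", "pos"]])
    kb = pd.MultiIndex.from_frame(b.variants[["chrom", "pos"]])
    common = ka.intersection(kb)
    if len(common) == 0:
        raise GenotypeError("no overlapping positions between datasets")
    ia = ka.get_indexer(common)
    ib = kb.get_indexer(common)
    ref_a = a.variants["ref"].to_numpy()[ia]
    alt_a = a.variants["alt"].to_numpy()[ia]
    ref_b = b.variants["ref"].to_numpy()[ib]
    alt_b = b.variants["alt"].to_numpy()[ib]

    comp = np.vectorize(_COMPLEMENT.get)
    same = (ref_a == ref_b) & (alt_a == alt_b)
    swapped = (ref_a == alt_b) & (alt_a == ref_b)
    cref_b, calt_b = comp(ref_b), comp(alt_b)
    flip_same = ~same & ~swapped & (ref_a == cref_b) & (alt_a == calt_b)
    flip_swap = ~same & ~swapped & (ref_a == calt_b) & (alt_a == cref_b)
    keep = same | swapped | flip_same | flip_swap

    calls_b = b.calls[:, ib].copy()
    recode = swapped | flip_swap
    cols = calls_b[:, recode]
    calls_b[:, recode] = np.where(cols == MISSING, MISSING, 2 - cols)

    merged_calls = np.concatenate([a.calls[:, ia][:, keep], calls_b[:, keep]], axis=0)
    variants = a.variants.iloc[ia[keep]].reset_index(drop=True)
    samples = pd.concat([a.samples, b.samples])
    if not samples.index.is_unique:
        raise GenotypeError("sample ids collide between datasets")
    rep = MergeReport(
        n_overlap=len(common),
        n_flipped=int((flip_same | flip_swap).sum()),
        n_dropped_mismatch=int((~keep).sum()),
        n_allele_swapped=int(recode.sum()),
    )
    return GenotypeMatrix(merged_calls, samples, variants), rep


# ---------------------------------------------------------------------------
# Relatedness
# ---------------------------------------------------------------------------

def relatedness_prune(
    gm: GenotypeMatrix, threshold: float = 0.25
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Flag and prune related sample pairs by a PI-HAT-style estimate.

    A method-of-moments decomposition of genome-wide identity-by-state into
    IBD-sharing probabilities (P0, P1, P2) given sample allele frequencies;
    relatedness = P1/2 + P2.  Pairs at or above *threshold* are flagged and
    the member with higher missingness is removed.  Raw mean IBS is reported
    alongside.
    """
    if gm.n_samples < 2:
        raise GenotypeError("need at least two samples")
    freq = _overall_freq(gm)
    poly = (freq > 0) & (freq < 1)
    if not poly.any():
        raise GenotypeError("no polymorphic SNPs: allele frequencies undefined")
    p = freq[poly]
    q = 1 - p
    # expected IBS category probabilities given IBD state, summed over SNPs
    e0_ibd0 = float(np.sum(2 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e2_ibd0 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e1_ibd1 = float(np.sum(2 * p * q))
    e2_ibd1 = float(np.sum(p**2 + q**2))

    calls = gm.calls[:, poly]
    records = []
    for i, j in itertools.combinations(range(gm.n_samples), 2):
        gi, gj = calls[i], calls[j]
        ok = (gi != MISSING) & (gj != MISSING)
        n_ok = int(ok.sum())
        if n_ok == 0:
            continue
        diff = np.abs(gi[ok] - gj[ok])
        ibs0 = int((diff == 2).sum())
        ibs1 = int((diff == 1).sum())
        ibs2 = n_ok - ibs0 - ibs1
        scale = n_ok / len(p)  # missingness-adjusted expectations
        p0 = ibs0 / (e0_ibd0 * scale) if e0_ibd0 > 0 else 0.0
        p1 = (ibs1 - p0 * e1_ibd0 * scale) / (e1_ibd1 * scale) if e1_ibd1 > 0 else 0.0
        p0, p1 = max(p0, 0.0), max(p1, 0.0)
        p2 = (ibs2 - p0 * e2_ibd0 * scale - p1 * e2_ibd1 * scale) / n_ok
        p2 = min(max(p2, 0.0), 1.0)
        tot = p0 + p1 + p2
        if tot > 1:
            p0, p1, p2 = p0 / tot, p1 / tot, p2 / tot
        pi_hat = p1 / 2 + p2
        records.append(
            {
                "sample_a": gm.samples.index[i],
                "sample_b": gm.samples.index[j],
                "pi_hat": pi_hat,
                "mean_ibs": (2 * ibs2 + ibs1) / (2 * n_ok),
                "flagged": pi_hat >= threshold,
            }
        )
    pairs = pd.DataFrame.from_records(
        records, columns=["sample_a", "sample_b", "pi_hat", "mean_ibs", "flagged"]
    )
    missing_rate = pd.Series((gm.calls == MISSING).mean(axis=1), index=gm.samples.index)
    to_drop: set[str] = set()
    for _, row in pairs[pairs["flagged"]].iterrows():
        sa, sb = row["sample_a"], row["sample_b"]
        if sa in to_drop or sb in to_drop:
            continue
        to_drop.add(sa if missing_rate[sa] >= missing_rate[sb] else sb)
    keep = ~gm.samples.index.isin(to_drop)
    return gm.take_samples(np.asarray(keep)), pairs


def _overall_freq(gm: GenotypeMatrix) -> np.ndarray:
    called = gm.calls != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called, gm.calls, 0).sum(axis=0) / (2 * called.sum(axis=0))


# ---------------------------------------------------------------------------
# Local-ancestry masking
# ---------------------------------------------------------------------------

def mask_by_local_ancestry(
    gm: GenotypeMatrix, tracts: pd.DataFrame, keep_label: str
) -> GenotypeMatrix:
    """Set calls to missing wherever either haplotype carries non-*keep_label*
    ancestry.

    *tracts* is BED-like: columns ``chrom, start_bp, end_bp, haplotype_id,
    ancestry`` with 0-based half-open intervals and haplotype ids of the form
    ``<sample>_h0`` / ``<sample>_h1``.  Samples without tracts are left
    untouched only if they appear nowhere in *tracts*; a sample with tracts
    on one haplotype but not the other raises.
    """
    tr = tracts.copy()
    tr["sample"] = tr["haplotype_id"].str.rsplit("_h", n=1).str[0]
    tract_samples = set(tr["sample"])
    calls = gm.calls.copy()
    pos0 = gm.variants["pos"].to_numpy() - 1  # 0-based for half-open interval tests
    chrom = gm.variants["chrom"].astype(str).to_numpy()
    for i, sid in enumerate(gm.samples.index):
        if sid not in tract_samples:
            continue
        sub = tr[tr["sample"] == sid]
        haps = set(sub["haplotype_id"].str.rsplit("_h", n=1).str[1].astype(int))
        if haps != {0, 1}:
            raise GenotypeError(f"sample {sid}: tracts missing for one haplotype")
        bad = np.zeros(gm.n_snps, dtype=bool)
        for _, t in sub[sub["ancestry"] != keep_label].iterrows():
            bad |= (chrom == str(t["chrom"])) & (pos0 >= t["start_bp"]) & (pos0 < t["end_bp"])
        calls[i, bad] = MISSING
    return GenotypeMatrix(calls, gm.samples.copy(), gm.variants.copy())
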