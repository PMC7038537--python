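"""Synthetic source panels and an admixed cohort with known truth.

The simulator emulates the statistical structure of a recently founded,
predominantly European colonial population with minor ancestry
contributions from several other continental groups: K source populations
diverged from a shared ancestral allele-frequency spectrum under the
Balding-Nichols model, plus an admixed target formed by a single admixture
pulse g generations ago with stated ancestry proportions.

Under the single-pulse model each admixed haplotype is a Markov mosaic of
source ancestries along the genetic map: switch points form a Poisson
process with rate g per Morgan and each tract's ancestry is drawn
independently from the proportion vector alpha.  This is the simplest
process whose ancestry autocorrelation (and hence admixture-induced
weighted LD) decays exactly as exp(-g d) at genetic distance d, which is
the quantity the dating module fits.

Emitted truth: phased haplotypes, genotypes, per-haplotype ancestry tracts
(tiling each chromosome exactly), a genetic map, and realized per-individual
ancestry fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, GenotypeError, save_genotypes, _write_vcf

FREQ_CLAMP = 1e-6
CM_PER_MB = 1.0  # constant genetic<->physical scaling unless a map is given

_ALLELES = ("A", "G")  # synthetic SNPs are A/G: strand-unambiguous, QC-neutral


@dataclass(frozen=True)
class SourcePopSpec:
    """One source panel: divergence F from the ancestral population and size."""

    name: str
    fst_to_ancestor: float
    n_samples: int

    def __post_init__(self) -> None:
        if not 0 < self.fst_to_ancestor < 1:
            raise GenotypeError(f"{self.name}: F must be in (0,1)")
        if self.n_samples < 1:
            raise GenotypeError(f"{self.name}: n_samples must be >= 1")


@dataclass(frozen=True)
class AdmixtureScenario:
    """Single-pulse admixture scenario.

    ``proportions`` must sum to 1; ``generations_ago`` is the pulse time g
    (the quantity weighted-LD dating must recover); the chromosome is
    ``chromosome_length_morgans`` long with ``n_snps`` evenly spaced SNPs.
    """

    sources: tuple[SourcePopSpec, ...]
    proportions: tuple[float, ...]
    generations_ago: float
    n_admixed: int
    n_snps: int = 4000
    chromosome_length_morgans: float = 2.0
    n_chromosomes: int = 1
    admixed_name: str = "ADMIX"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(self.sources))
        object.__setattr__(self, "proportions", tuple(float(a) for a in self.proportions))
        if len(self.sources) != len(self.proportions):
            raise GenotypeError("one proportion per source required")
        if any(a < 0 for a in self.proportions):
            raise GenotypeError("proportions must be non-negative")
        if abs(sum(self.proportions) - 1.0) > 1e-12:
            raise GenotypeError("proportions must sum to 1 within 1e-12")
        if self.generations_ago <= 0:
            raise GenotypeError("generations_ago must be positive")
        if self.n_snps < 1 or self.n_admixed < 1 or self.n_chromosomes < 1:
            raise GenotypeError("n_snps, n_admixed and n_chromosomes must be >= 1")


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix          # sources + admixed
    haplotypes: np.ndarray             # (2*n_samples, n_snps) phased 0/1
    tracts: pd.DataFrame               # chrom, start_bp, end_bp, haplotype_id, ancestry
    truth_q: pd.DataFrame              # admixed individuals x source names
    source_freqs: pd.DataFrame         # SNPs x sources, true alt frequencies
    scenario: AdmixtureScenario = field(repr=False, default=None)

    @property
    def map_cm(self) -> np.ndarray:
        return self.genotypes.variants["cm"].to_numpy()


def uniform_spectrum(low: float = 0.05, high: float = 0.95):
    """Default ancestral spectrum: Uniform(low, high), bounded away from
    fixation so downstream statistics rarely hit monomorphic SNPs."""

    def draw(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(low, high, n)

    return draw


def draw_source_frequencies(
    ancestral_spectrum,
    specs: list[SourcePopSpec] | tuple[SourcePopSpec, ...],
    n_snps: int,
    seed: int,
) -> pd.DataFrame:
    """Balding-Nichols source frequencies around a shared ancestral spectrum.

    For ancestral frequency p and divergence F the source frequency is
    Beta(p(1-F)/F, (1-p)(1-F)/F), so E[p_k] = p and Var[p_k] = F p(1-p).
    Returns a (n_snps x K) frame with one column per source; the ancestral
    draw is stored under the ``_ancestral`` column.  Deterministic for a
    fixed seed.
    """
    if n_snps < 1:
        raise GenotypeError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    p_anc = np.clip(ancestral_spectrum(rng, n_snps), FREQ_CLAMP, 1 - FREQ_CLAMP)
    out = {"_ancestral": p_anc}
    for spec in specs:
        F = spec.fst_to_ancestor
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        out[spec.name] = np.clip(rng.beta(a, b), FREQ_CLAMP, 1 - FREQ_CLAMP)
    return pd.DataFrame(out)


def _simulate_tracts(
    rng: np.random.Generator, n_haps: int, g: float, length_m: float, alpha: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per haplotype: (breakpoints in Morgans incl. 0 and L, tract ancestries)."""
    out = []
    k = len(alpha)
    for _ in range(n_haps):
        n_switch = rng.poisson(g * length_m)
        cuts = np.sort(rng.uniform(0.0, length_m, n_switch))
        bounds = np.concatenate([[0.0], cuts, [length_m]])
        anc = rng.choice(k, size=len(bounds) - 1, p=alpha)
        out.append((bounds, anc))
    return out


def simulate_admixed_haplotypes(
    freqs: pd.DataFrame, scenario: AdmixtureScenario, pos_morgans: np.ndarray | None = None,
    rng: np.random.Generator | None = None, chrom: str = "1",
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Simulate phased admixed haplotypes under the single-pulse tract model.

    Simulates one chromosome (label *chrom*).  Returns ``(haplotypes,
    tracts, truth_q)`` where haplotypes is a ``(2*n_admixed, n_snps)``
    0/1 array, tracts a BED-like frame (0-based half-open bp intervals)
    and truth_q the realized tract-length ancestry fraction per admixed
    individual.
    """
    if pos_morgans is None:
        pos_morgans = _snp_positions(scenario.n_snps, scenario.chromosome_length_morgans)
    if len(pos_morgans) == 0:
        raise GenotypeError("empty genetic map")
    missing = [s.name for s in scenario.sources if s.name not in freqs.columns]
    if missing:
        raise GenotypeError(f"freqs missing sources: {missing}")
    if rng is None:
        rng = np.random.default_rng(scenario.seed + 1)
    L = scenario.chromosome_length_morgans
    alpha = np.asarray(scenario.proportions)
    n_haps = 2 * scenario.n_admixed
    p = freqs[[s.name for s in scenario.sources]].to_numpy()  # (n_snps, K)

    haps = np.empty((n_haps, len(pos_morgans)), dtype=np.uint8)
    tract_rows = []
    q = np.zeros((scenario.n_admixed, len(alpha)))
    tracts = _simulate_tracts(rng, n_haps, scenario.generations_ago, L, alpha)
    for h, (bounds, anc) in enumerate(tracts):
        snp_anc = anc[np.clip(np.searchsorted(bounds, pos_morgans, side="right") - 1, 0, len(anc) - 1)]
        haps[h] = rng.random(len(pos_morgans)) < p[np.arange(len(pos_morgans)), snp_anc]
        lengths = np.diff(bounds)
        np.add.at(q[h // 2], anc, lengths)
        sample = f"{scenario.admixed_name}{h // 2:04d}"
        for b0, b1, a in zip(bounds[:-1], bounds[1:], anc):
            tract_rows.append(
                {
                    "chrom": chrom,
                    "start_bp": int(round(_m_to_bp(b0))),
                    "end_bp": int(round(_m_to_bp(b1))),
                    "haplotype_id": f"{sample}_h{h % 2}",
                    "ancestry": scenario.sources[a].name,
                }
            )
    q /= 2 * L
    truth_q = pd.DataFrame(
        q,
        index=pd.Index(
            [f"{scenario.admixed_name}{i:04d}" for i in range(scenario.n_admixed)], name="sample"
        ),
        columns=[s.name for s in scenario.sources],
    )
    return haps, pd.DataFrame(tract_rows), truth_q


def _snp_positions(n_snps: int, length_morgans: float) -> np.ndarray:
    """Evenly spaced SNP positions in Morgans over (0, L), endpoints excluded."""
    return (np.arange(n_snps) + 0.5) * length_morgans / n_snps


def _m_to_bp(morgans: float) -> float:
    return morgans * 100.0 / CM_PER_MB * 1e6


def simulate_cohort(scenario: AdmixtureScenario, ancestral_spectrum=None) -> SimulatedCohort:
    """Simulate source panels plus the admixed cohort.

    Source genotypes are Hardy-Weinberg pairings of independent Bernoulli
    haplotypes; admixed genotypes pair the two tract-mosaic haplotypes of
    each individual.  All randomness derives from ``scenario.seed``.
    """
    if ancestral_spectrum is None:
        ancestral_spectrum = uniform_spectrum()
    freqs = draw_source_frequencies(
        ancestral_spectrum, scenario.sources, scenario.n_snps, scenario.seed
    )
    rng = np.random.default_rng(scenario.seed + 1)
    n_chrom = scenario.n_chromosomes
    snps_per_chrom = np.full(n_chrom, scenario.n_snps // n_chrom)
    snps_per_chrom[: scenario.n_snps % n_chrom] += 1

    hap_blocks, sample_ids, pops = [], [], []
    for spec in scenario.sources:
        p = freqs[spec.name].to_numpy()
        hap_blocks.append(
            (rng.random((2 * spec.n_samples, scenario.n_snps)) < p).astype(np.uint8)
        )
        sample_ids += [f"{spec.name}{i:04d}" for i in range(spec.n_samples)]
        pops += [spec.name] * spec.n_samples

    adm_blocks, tract_frames, truth_parts = [], [], []
    offset = 0
    for c, n_c in enumerate(snps_per_chrom):
        sub_freqs = freqs.iloc[offset : offset + int(n_c)].reset_index(drop=True)
        pos_m = _snp_positions(int(n_c), scenario.chromosome_length_morgans)
        haps_c, tracts_c, q_c = simulate_admixed_haplotypes(
            sub_freqs, scenario, pos_m, rng, chrom=str(c + 1)
        )
        adm_blocks.append(haps_c)
        tract_frames.append(tracts_c)
        truth_parts.append(q_c)
        offset += int(n_c)
    adm_haps = np.concatenate(adm_blocks, axis=1)
    truth_q = sum(truth_parts) / n_chrom
    tracts = pd.concat(tract_frames, ignore_index=True)
    hap_blocks.append(adm_haps)
    sample_ids += list(truth_q.index)
    pops += [scenario.admixed_name] * scenario.n_admixed

    haplotypes = np.concatenate(hap_blocks, axis=0)
    calls = (haplotypes[0::2] + haplotypes[1::2]).astype(np.int8)
    chrom_col, pos_bp, pos_cm = [], [], []
    for c, n_c in enumerate(snps_per_chrom):
        pm = _snp_positions(int(n_c), scenario.chromosome_length_morgans)
        chrom_col += [str(c + 1)] * int(n_c)
        pos_bp.append(np.round(_m_to_bp(pm)).astype(np.int64))
        pos_cm.append(pm * 100.0)
    variants = pd.DataFrame(
        {
            "chrom": chrom_col,
            "pos": np.concatenate(pos_bp),
            "id": [f"snp{j}" for j in range(scenario.n_snps)],
            "ref": _ALLELES[0],
            "alt": _ALLELES[1],
            "cm": np.concatenate(pos_cm),
        }
    )
    samples = pd.DataFrame(
        {"population": pops}, index=pd.Index(sample_ids, name="sample")
    )
    gm = GenotypeMatrix(calls, samples, variants)
    return SimulatedCohort(gm, haplotypes, tracts, truth_q, freqs, scenario)


def write_cohort(cohort: SimulatedCohort, outdir, basename: str = "cohort") -> None:
    """Write PED/MAP, a phased VCF, truth tracts (BED-like TSV) and truth_q."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_genotypes(cohort.genotypes, outdir / basename, fmt="ped_map")
    _write_vcf(cohort.genotypes, str(outdir / f"{basename}.vcf"), haplotypes=cohort.haplotypes)
    cohort.tracts.to_csv(outdir / f"{basename}.tracts.bed", sep="\t", index=False)
    cohort.truth_q.to_csv(outdir / f"{basename}.truth_q.tsv", sep="\t")
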