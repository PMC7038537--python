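"""Runs-of-homozygosity calling with the scanning-window algorithm.

The caller mirrors the sliding-window heuristic of the standard genotype
RoH tools: 5 Mb windows anchored at every SNP slide along each chromosome;
a window is "homozygous" when it contains at most one heterozygous call
(missing calls are tolerated: they neither count as heterozygous nor break
a window).  Each SNP's hit rate is the fraction of windows containing it
that are homozygous; SNPs at or above the hit-rate threshold are
run-eligible.  Maximal eligible stretches are split at inter-SNP gaps
larger than the gap limit, then filtered by minimum length, minimum SNP
count and SNP density.  Windows shrink at chromosome edges (a SNP's
denominator counts only the windows that actually contain it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, GenotypeError, MISSING


@dataclass(frozen=True)
class RohParams:
    """Scanning-window parameters (length units: kb).

    ``window_missing_max`` caps missing calls per homozygous window (the
    reference tool's inherited default of 5): without it a fully masked
    ancestry tract, which carries no evidence at all, would read as a long
    homozygous run.
    """

    window_kb: float = 5000.0
    window_het_max: int = 1
    window_missing_max: int = 5
    window_hit_threshold: float = 0.05
    min_kb: float = 500.0
    min_snps: int = 25
    density_kb_per_snp: float = 50.0
    max_gap_kb: float = 100.0

    def __post_init__(self) -> None:
        if min(self.window_kb, self.min_kb, self.density_kb_per_snp, self.max_gap_kb) <= 0:
            raise GenotypeError("RoH length parameters must be positive")
        if not 0 < self.window_hit_threshold <= 1:
            raise GenotypeError("window_hit_threshold must be in (0,1]")
        if self.min_snps < 1 or self.window_het_max < 0:
            raise GenotypeError("invalid SNP-count parameters")


@dataclass
class RohSegment:
    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


def _eligible_snps(geno: np.ndarray, pos: np.ndarray, params: RohParams) -> np.ndarray:
    """Boolean run-eligibility per SNP on one chromosome (hit-rate rule)."""
    m = len(pos)
    het = (geno == 1).astype(np.int64)
    chet = np.concatenate([[0], np.cumsum(het)])
    miss = (geno == MISSING).astype(np.int64)
    cmiss = np.concatenate([[0], np.cumsum(miss)])
    window_bp = params.window_kb * 1000.0
    # window anchored at SNP i spans [pos_i, pos_i + window_bp]
    end = np.searchsorted(pos, pos + window_bp, side="right")  # exclusive
    n_het_window = chet[end] - chet[np.arange(m)]
    n_miss_window = cmiss[end] - cmiss[np.arange(m)]
    hom_window = (
        (n_het_window <= params.window_het_max)
        & (n_miss_window <= params.window_missing_max)
    ).astype(np.int64)
    chom = np.concatenate([[0], np.cumsum(hom_window)])
    # windows containing SNP j: anchors i with i <= j < end_i; end is
    # non-decreasing so the smallest valid anchor is searchsorted(end, j+1)
    first = np.searchsorted(end, np.arange(m) + 1, side="left")
    denom = np.arange(m) - first + 1
    hits = chom[np.arange(m) + 1] - chom[first]
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = hits / denom
    return (denom > 0) & (rate >= params.window_hit_threshold)


def call_roh(gm: GenotypeMatrix, sample: str, params: RohParams | None = None) -> list[RohSegment]:
    """Call RoH segments for one sample."""
    params = params or RohParams()
    try:
        i = gm.samples.index.get_loc(sample)
    except KeyError:
        raise GenotypeError(f"sample {sample!r} not found") from None
    segments: list[RohSegment] = []
    chroms = gm.variants["chrom"].astype(str).to_numpy()
    pos_all = gm.variants["pos"].to_numpy(np.int64)
    for ch in pd.unique(chroms):
        m = chroms == ch
        pos = pos_all[m]
        if np.any(np.diff(pos) <= 0):
            raise GenotypeError(f"variants unsorted on chromosome {ch}")
        geno = gm.calls[i, m]
        eligible = _eligible_snps(geno, pos.astype(float), params)
        segments += _segments_from_eligible(eligible, geno, pos, str(ch), sample, params)
    return segments


def _segments_from_eligible(
    eligible: np.ndarray,
    geno: np.ndarray,
    pos: np.ndarray,
    chrom: str,
    sample: str,
    params: RohParams,
) -> list[RohSegment]:
    out: list[RohSegment] = []
    idx = np.flatnonzero(eligible)
    if len(idx) == 0:
        return out
    # split maximal eligible stretches at non-eligible SNPs and at large gaps
    breaks = np.flatnonzero(
        (np.diff(idx) > 1) | (np.diff(pos[idx]) > params.max_gap_kb * 1000.0)
    )
    for chunk in np.split(idx, breaks + 1):
        start, end = pos[chunk[0]], pos[chunk[-1]]
        length_kb = (end - start) / 1000.0
        n_snps = len(chunk)
        if length_kb < params.min_kb or n_snps < params.min_snps:
            continue
        if length_kb / n_snps > params.density_kb_per_snp:
            continue
        out.append(
            RohSegment(
                sample=sample,
                chrom=chrom,
                start_bp=int(start),
                end_bp=int(end),
                n_snps=n_snps,
                n_het=int((geno[chunk] == 1).sum()),
            )
        )
    return out


def segments_to_frame(segments: list[RohSegment]) -> pd.DataFrame:
    rows = [
        {**vars(s), "length_kb": s.length_kb} for s in segments
    ]
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start_bp", "end_bp", "n_snps", "n_het", "length_kb"]
    )


DEFAULT_LENGTH_CLASSES = ((500.0, 1000.0), (1000.0, 2000.0), (2000.0, 4000.0), (4000.0, np.inf))


def summarize_roh(
    segments: list[RohSegment],
    samples: pd.DataFrame,
    length_classes: tuple[tuple[float, float], ...] = DEFAULT_LENGTH_CLASSES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual totals and per-population means of RoH burden.

    *length_classes* are [lo, hi) intervals in kb.  Returns
    ``(per_individual, per_population)``; the population table carries mean
    and SD of total length, count, and per-class counts.
    """
    seg = segments_to_frame(segments)
    per_ind = pd.DataFrame(index=samples.index)
    per_ind["population"] = samples["population"]
    grouped = seg.groupby("sample") if len(seg) else None
    per_ind["total_kb"] = (grouped["length_kb"].sum() if grouped is not None else 0.0)
    per_ind["n_segments"] = (grouped.size() if grouped is not None else 0)
    for lo, hi in length_classes:
        name = f"n_{lo:g}_{hi:g}kb" if np.isfinite(hi) else f"n_gt{lo:g}kb"
        if grouped is not None:
            counts = seg[(seg["length_kb"] >= lo) & (seg["length_kb"] < hi)].groupby("sample").size()
        else:
            counts = pd.Series(dtype=int)
        per_ind[name] = counts
    per_ind = per_ind.fillna(0.0)
    num_cols = [c for c in per_ind.columns if c != "population"]
    per_pop = per_ind.groupby("population")[num_cols].agg(["mean", "std"])
    per_pop.columns = ["_".join(c) for c in per_pop.columns]
    return per_ind, per_pop.fillna(0.0)
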