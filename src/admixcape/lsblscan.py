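"""Locus-specific branch length (LSBL) scan with peak calling.

For a target population T and two references R1, R2, the three pairwise
per-SNP FST values decompose additively onto the branches of the
three-population star tree; the length of the target branch at a SNP is

    LSBL(T) = (FST(T,R1) + FST(T,R2) - FST(R1,R2)) / 2.

Per-SNP FST components are the Weir-Cockerham estimates and may be
negative; they are used as-is (no clamping), which preserves the exact
branch additivity LSBL(T) + LSBL(R1) + LSBL(R2) = (sum of pairwise FST)/2
at every SNP.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, GenotypeError
from .fstats import wc_fst


@dataclass
class Peak:
    chrom: str
    start_bp: int
    end_bp: int
    apex_pos: int
    apex_id: str
    apex_value: float
    n_snps: int


def lsbl_scan(gm: GenotypeMatrix, target: str, ref1: str, ref2: str) -> pd.DataFrame:
    """Per-SNP LSBL track for the target branch.

    Returns a frame with chrom, pos, id, the three pairwise FST tracks and
    ``lsbl``; SNPs where any pairwise FST is undefined (monomorphic in both
    populations of a pair, or under-called) carry NaN.
    """
    for pop in (target, ref1, ref2):
        gm.sample_mask(pop)  # raises if absent
    _, f_t1 = wc_fst(gm, [target, ref1], per_snp=True)
    _, f_t2 = wc_fst(gm, [target, ref2], per_snp=True)
    _, f_12 = wc_fst(gm, [ref1, ref2], per_snp=True)
    track = gm.variants[["chrom", "pos", "id"]].copy()
    track["fst_target_ref1"] = f_t1
    track["fst_target_ref2"] = f_t2
    track["fst_ref1_ref2"] = f_12
    track["lsbl"] = (f_t1 + f_t2 - f_12) / 2.0
    return track


def call_peaks(
    track: pd.DataFrame,
    top_n: int = 5,
    merge_window_bp: int = 500_000,
    value_col: str = "lsbl",
) -> list[Peak]:
    """Greedy apex-merge peak calling.

    SNPs are ranked descending by the statistic; the highest remaining SNP
    becomes a peak apex and absorbs every unassigned SNP within
    *merge_window_bp* of it on the same chromosome; repeat until *top_n*
    peaks (fewer, with a warning, if the track is exhausted).
    """
    t = track.dropna(subset=[value_col])
    if len(t) == 0:
        raise GenotypeError("empty track")
    chrom = t["chrom"].astype(str).to_numpy()
    pos = t["pos"].to_numpy()
    ids = t["id"].to_numpy()
    vals = t[value_col].to_numpy(float)
    order = np.argsort(-vals, kind="stable")
    assigned = np.zeros(len(t), dtype=bool)
    peaks: list[Peak] = []
    for idx in order:
        if assigned[idx] or len(peaks) >= top_n:
            continue
        members = (
            ~assigned
            & (chrom == chrom[idx])
            & (np.abs(pos - pos[idx]) <= merge_window_bp)
        )
        assigned |= members
        peaks.append(
            Peak(
                chrom=str(chrom[idx]),
                start_bp=int(pos[members].min()),
                end_bp=int(pos[members].max()),
                apex_pos=int(pos[idx]),
                apex_id=str(ids[idx]),
                apex_value=float(vals[idx]),
                n_snps=int(members.sum()),
            )
        )
    if len(peaks) < top_n:
        warnings.warn(f"only {len(peaks)} peaks available (requested {top_n})")
    return peaks


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in peaks])
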