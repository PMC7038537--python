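"""Weighted-LD admixture dating and date arithmetic.

A single admixture pulse n generations ago leaves linkage disequilibrium
between ancestry-informative markers that decays exponentially with
genetic distance d (in Morgans) at rate n.  The weighted-LD curve is, per
distance bin, the average over SNP pairs of the admixed-sample genotype
covariance weighted by the product of reference allele-frequency
differences delta(l) = freq_ref1(l) - freq_ref2(l):

    a(d) = mean over pairs at distance d of cov(g_l1, g_l2) * delta(l1) * delta(l2)

and the date is the rate of the least-squares fit A*exp(-n*d) + c.

Conversions: generations * generation_time = years ago; calendar year =
reference (mean participant birth) year - years ago.  Ancestor equivalents
express an ancestry fraction f as f * 2^g of the 2^g ancestor slots g
generations ago, truncated (not rounded) to one decimal; the same ancestor
may fill many slots (pedigree collapse), so the count is an equivalent,
not a census.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .genio import GenotypeMatrix, GenotypeError, MISSING


@dataclass
class WeightedLdCurve:
    bin_right_morgans: np.ndarray     # right edge of each (left-open] bin
    mean_weighted_ld: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d_morgans": self.bin_right_morgans,
                "weighted_ld": self.mean_weighted_ld,
                "n_pairs": self.n_pairs,
            }
        )


@dataclass
class DecayFit:
    amplitude: float | None
    generations: float | None
    offset: float | None
    rmse: float
    window: tuple[float, float]
    status: str = "ok"              # "ok" | "failed"


def weighted_ld_curve(
    gm: GenotypeMatrix,
    admixed_pop: str,
    ref1: str,
    ref2: str,
    bin_cm: float = 0.1,
    d_min_cm: float = 0.5,
    d_max_cm: float = 30.0,
) -> WeightedLdCurve:
    """Binned weighted-LD curve for one reference pair.

    Requires a genetic map (``cm`` column) and at least 10 admixed
    diploids.  The curve is symmetric in ref1/ref2 (weights enter as a
    product of two deltas).  Missing admixed calls are mean-imputed for
    the covariance (missingness is rare in simulated panels; documented).
    """
    if "cm" not in gm.variants.columns or gm.variants["cm"].isna().any():
        raise GenotypeError("genetic map (cm positions) required for weighted LD")
    if ref1 == ref2:
        raise GenotypeError("reference populations must differ (weights would be zero)")
    mask = gm.sample_mask(admixed_pop)
    if mask.sum() < 10:
        raise GenotypeError("need at least 10 admixed diploids")
    delta = gm.allele_freq(ref1) - gm.allele_freq(ref2)
    ok = np.isfinite(delta)
    g = gm.calls[mask][:, ok].astype(float)
    g[g == MISSING] = np.nan
    col_mean = np.nanmean(g, axis=0)
    inds = np.where(np.isnan(g))
    g[inds] = col_mean[inds[1]]
    z = g - g.mean(axis=0)
    n_ind = z.shape[0]
    delta = delta[ok]
    cm = gm.variants["cm"].to_numpy(float)[ok]
    chrom = gm.variants["chrom"].astype(str).to_numpy()[ok]

    d_min, d_max, width = d_min_cm / 100.0, d_max_cm / 100.0, bin_cm / 100.0
    n_bins = int(np.ceil((d_max - d_min) / width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    pos_m = cm / 100.0
    for ch in pd.unique(chrom):
        sel = chrom == ch
        zc = z[:, sel]
        dc = delta[sel]
        pc = pos_m[sel]
        L = len(pc)
        lo = np.searchsorted(pc, pc + d_min, side="left")
        hi = np.searchsorted(pc, pc + d_max, side="right")
        for i in range(L):
            a, b = lo[i], hi[i]
            if a >= b:
                continue
            cov = (zc[:, i] @ zc[:, a:b]) / (n_ind - 1)
            w = dc[i] * dc[a:b]
            bins = np.minimum(((pc[a:b] - pc[i] - d_min) / width).astype(np.int64), n_bins - 1)
            np.add.at(sums, bins, cov * w)
            counts += np.bincount(bins, minlength=n_bins)
    kept = counts > 0
    with np.errstate(invalid="ignore"):
        means = sums / counts
    edges = d_min + width * (np.arange(n_bins) + 1)
    return WeightedLdCurve(edges[kept], means[kept], counts[kept])


def _profile_fit(d: np.ndarray, y: np.ndarray, w: np.ndarray, n: float):
    """Weighted LSQ of A e^{-n d} + c with A, c solved analytically."""
    x = np.exp(-n * d)
    X = np.column_stack([x, np.ones_like(x)])
    W = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * W[:, None], y * W, rcond=None)
    resid = y - X @ coef
    rss = float(np.sum(w * resid**2))
    return coef[0], coef[1], rss


def fit_decay(
    curve: WeightedLdCurve,
    starts: tuple[float, ...] = (1.0, 5.0, 10.0, 50.0, 200.0),
    n_bounds: tuple[float, float] = (1e-3, 1e4),
) -> DecayFit:
    """Fit A*exp(-n d) + c to the binned curve, weighted by pair counts.

    Multi-start local optimization over n with A and c profiled out
    analytically at each n.  A non-decaying curve (A <= 0, or n pinned at
    a bound) yields ``status='failed'`` with no rate reported.
    """
    d = np.asarray(curve.bin_right_morgans, float)
    y = np.asarray(curve.mean_weighted_ld, float)
    w = np.asarray(curve.n_pairs, float)
    keep = np.isfinite(y) & (w > 0)
    d, y, w = d[keep], y[keep], w[keep]
    if len(d) < 5:
        raise GenotypeError("need at least 5 bins to fit a decay")
    window = (float(d.min()), float(d.max()))
    if np.allclose(y, y[0]):
        return DecayFit(None, None, None, 0.0, window, status="failed")

    def objective(n: float) -> float:
        return _profile_fit(d, y, w, n)[2]

    best_n, best_rss = None, np.inf
    for n0 in starts:
        lo = max(n_bounds[0], n0 / 20.0)
        hi = min(n_bounds[1], n0 * 20.0)
        res = optimize.minimize_scalar(
            objective, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
        )
        if res.fun < best_rss:
            best_rss, best_n = float(res.fun), float(res.x)
    polish = optimize.minimize_scalar(
        objective,
        bounds=(max(n_bounds[0], best_n * 0.5), min(n_bounds[1], best_n * 2.0)),
        method="bounded",
        options={"xatol": 1e-12},
    )
    n_hat = float(polish.x) if polish.fun <= best_rss else best_n
    A, c, rss = _profile_fit(d, y, w, n_hat)
    rmse = math.sqrt(rss / w.sum())
    if A <= 0 or not (n_bounds[0] * 1.01 < n_hat < n_bounds[1] * 0.99):
        return DecayFit(None, None, None, rmse, window, status="failed")
    return DecayFit(float(A), float(n_hat), float(c), rmse, window)


def jackknife_generations(
    gm: GenotypeMatrix, admixed_pop: str, ref1: str, ref2: str, **curve_kwargs
) -> tuple[float | None, float | None]:
    """Delete-one-chromosome jackknife of the fitted rate.

    Returns (n_hat on all data, jackknife SD); SD is None with fewer than
    two chromosomes or when any delete-one fit fails.
    """
    full = fit_decay(weighted_ld_curve(gm, admixed_pop, ref1, ref2, **curve_kwargs))
    if full.status != "ok":
        return None, None
    chroms = pd.unique(gm.variants["chrom"].astype(str))
    if len(chroms) < 2:
        return full.generations, None
    ests = []
    for ch in chroms:
        sub = gm.take_variants((gm.variants["chrom"].astype(str) != ch).to_numpy())
        fit = fit_decay(weighted_ld_curve(sub, admixed_pop, ref1, ref2, **curve_kwargs))
        if fit.status != "ok":
            return full.generations, None
        ests.append(fit.generations)
    m = len(ests)
    mean = float(np.mean(ests))
    sd = math.sqrt((m - 1) / m * float(np.sum((np.asarray(ests) - mean) ** 2)))
    return full.generations, sd


def admixture_calendar(
    generations: float, generation_time: float = 30.0, reference_year: float | None = None
) -> tuple[float, float | None]:
    """Convert a generation count to years ago and (optionally) a calendar
    year given the mean participant birth year."""
    if generations <= 0:
        raise GenotypeError("generations must be positive")
    years_ago = generations * generation_time
    calendar = reference_year - years_ago if reference_year is not None else None
    return years_ago, calendar


def ancestor_equivalents(fraction: float, generations: int) -> tuple[int, float]:
    """Ancestry fraction as ancestor-slot equivalents g generations ago.

    Returns (2^g total slots, fraction * 2^g truncated to one decimal).
    Truncation, not rounding: 0.008 * 2048 = 16.384 -> 16.3.
    """
    if not 0 <= fraction <= 1:
        raise GenotypeError("fraction must be in [0,1]")
    if generations < 1 or int(generations) != generations:
        raise GenotypeError("generations must be a positive integer")
    total = 2 ** int(generations)
    equiv = math.floor(round(fraction * total * 10, 9)) / 10.0
    return total, equiv
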