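"""Supervised ancestry-proportion estimation, replicate mode matching and
ancestry-composition summaries.

Given fixed source panels with allele frequencies p_kl, each target
individual's ancestry vector q on the K-simplex maximizes the binomial
log-likelihood

    L(q) = sum_l [ g_l ln(pi_l) + (2 - g_l) ln(1 - pi_l) ],   pi_l = sum_k q_k p_kl,

fit by EM (each allele copy's source is the latent variable).  The
likelihood is concave in q per individual, the EM update keeps q on the
simplex and never decreases L.  Source frequencies are maximum-likelihood
counts with a pseudocount of 0.5 per allele, clamped to [1e-6, 1-1e-6].

Replicate Q matrices (e.g. from repeated clustering runs) are grouped into
modes via the symmetric similarity G'(Q, Q') = 1 - ||Q - Q'P||_F / sqrt(2C)
maximized over column permutations P (C = individuals); replicates with
G' >= 0.9 join a common mode.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.stats import spearmanr

from .genio import GenotypeMatrix, GenotypeError, MISSING

FREQ_CLAMP = 1e-6


@dataclass
class QMatrix:
    q: pd.DataFrame               # individuals x K source fractions
    log_likelihood: float
    n_iterations: int
    converged: bool = True
    flat_likelihood: bool = False

    def __post_init__(self) -> None:
        arr = self.q.to_numpy(float)
        if (arr < -1e-12).any() or (arr > 1 + 1e-12).any():
            raise GenotypeError("Q entries must lie in [0,1]")
        if np.abs(arr.sum(axis=1) - 1).max() > 1e-8:
            raise GenotypeError("Q rows must sum to 1 within 1e-8")

    @property
    def source_labels(self) -> list[str]:
        return list(self.q.columns)


def source_frequencies(gm: GenotypeMatrix, source_pops: list[str]) -> pd.DataFrame:
    """Pseudocounted ML allele frequencies per source panel."""
    out = {}
    for pop in source_pops:
        mask = gm.sample_mask(pop)
        if mask.sum() < 2:
            raise GenotypeError(f"source {pop!r} has fewer than 2 samples")
        alt, total = gm.allele_counts(pop)
        out[pop] = np.clip((alt + 0.5) / (total + 1.0), FREQ_CLAMP, 1 - FREQ_CLAMP)
    return pd.DataFrame(out)


class _SupervisedEM:
    """EM machinery for supervised ancestry estimation.

    With ``update_freqs`` the source frequencies are re-estimated jointly
    from the panel genotypes (binomial counts) plus the expected allele-copy
    assignments of the target individuals, under a Beta(1.5, 1.5) prior
    (pseudocount 0.5 per allele).  This models the panel-sampling noise that
    otherwise leaks ancestry mass between weakly diverged sources; with
    fixed frequencies that noise appears on both sides of the likelihood
    and biases small components upward.
    """

    def __init__(self, w_alt, w_ref, panel_alt, panel_tot, p0, update_freqs):
        self.w_alt, self.w_ref = w_alt, w_ref
        self.panel_alt, self.panel_tot = panel_alt, panel_tot
        self.p0 = p0
        self.update_freqs = update_freqs
        self.n, self.L = w_alt.shape
        self.n_copies = w_alt.sum(axis=1) + w_ref.sum(axis=1)

    def objective(self, q, p):
        pi = np.clip(q @ p, FREQ_CLAMP, 1 - FREQ_CLAMP)
        ll = float(np.sum(self.w_alt * np.log(pi) + self.w_ref * np.log(1 - pi)))
        if self.update_freqs:
            ll += float(
                np.sum(self.panel_alt * np.log(p) + (self.panel_tot - self.panel_alt) * np.log(1 - p))
            )
            ll += 0.5 * float(np.sum(np.log(p) + np.log(1 - p)))  # Beta(1.5,1.5) prior
        return ll

    def step(self, q, p):
        pi = np.clip(q @ p, FREQ_CLAMP, 1 - FREQ_CLAMP)
        alt_resp = self.w_alt / pi                 # (n, L)
        ref_resp = self.w_ref / (1 - pi)
        qn = q * (alt_resp @ p.T + ref_resp @ (1 - p).T)
        qn /= self.n_copies[:, None]
        qn = np.clip(qn, 1e-300, None)
        qn /= qn.sum(axis=1, keepdims=True)
        if self.update_freqs:
            alt_kl = (q.T @ alt_resp) * p          # expected target alt copies from k
            ref_kl = (q.T @ ref_resp) * (1 - p)
            pn = (self.panel_alt + alt_kl + 0.5) / (self.panel_tot + alt_kl + ref_kl + 1.0)
            pn = np.clip(pn, FREQ_CLAMP, 1 - FREQ_CLAMP)
        else:
            pn = p
        return qn, pn

    def project(self, q, p):
        q = np.clip(q, 1e-12, None)
        q /= q.sum(axis=1, keepdims=True)
        return q, np.clip(p, FREQ_CLAMP, 1 - FREQ_CLAMP)


def supervised_admixture(
    gm: GenotypeMatrix,
    target_pop: str,
    source_pops: list[str],
    tol: float = 1e-6,
    max_iter: int = 2000,
    freqs: pd.DataFrame | None = None,
    update_freqs: bool = True,
) -> QMatrix:
    """Per-individual ancestry fractions against source panels by EM.

    By default source frequencies are re-estimated jointly with q from the
    panel genotype counts (see :class:`_SupervisedEM`); passing explicit
    *freqs* treats them as known and disables the update.  Missing
    genotypes are dropped per individual.  The EM map is accelerated with
    SQUAREM extrapolation, falling back to the plain double step whenever
    extrapolation would decrease the objective, so the recorded objective
    history is non-decreasing.  Convergence when the objective improves by
    less than *tol* per cycle; non-convergence at *max_iter* map
    applications is flagged, not raised.  When the initial source
    frequencies are identical across sources the target likelihood is flat
    in q: the uniform vector is returned with ``flat_likelihood=True``.
    """
    if len(source_pops) < 2:
        raise GenotypeError("need K >= 2 sources")
    if freqs is not None:
        update_freqs = False
    else:
        freqs = source_frequencies(gm, source_pops)
    p = freqs[source_pops].to_numpy(float).T      # (K, L)
    K, L = p.shape
    tmask = gm.sample_mask(target_pop)
    targets = gm.calls[tmask]
    ids = gm.samples.index[tmask]
    n = targets.shape[0]
    flat = bool(np.max(np.abs(p - p[0])) < 1e-12)

    g = targets.astype(float)
    obs = targets != MISSING
    w_alt = np.where(obs, g, 0.0)                 # alt-allele copies
    w_ref = np.where(obs, 2.0 - g, 0.0)           # ref-allele copies
    if ((w_alt + w_ref).sum(axis=1) == 0).any():
        raise GenotypeError("an individual has no non-missing genotypes")
    panel_alt = np.zeros((K, L))
    panel_tot = np.zeros((K, L))
    for k, pop in enumerate(source_pops):
        panel_alt[k], panel_tot[k] = gm.allele_counts(pop)
    em = _SupervisedEM(w_alt, w_ref, panel_alt, panel_tot, p, update_freqs)

    q = np.full((n, K), 1.0 / K)
    ll_hist = [em.objective(q, p)]
    n_steps = 0
    converged = False
    while n_steps < max_iter:
        q1, p1 = em.step(q, p)
        q2, p2 = em.step(q1, p1)
        n_steps += 2
        rq, rp = q1 - q, p1 - p
        vq, vp = q2 - q1 - rq, p2 - p1 - rp
        vnorm = np.sqrt(np.sum(vq**2) + np.sum(vp**2))
        accepted = False
        if vnorm > 0:
            alpha = -np.sqrt(np.sum(rq**2) + np.sum(rp**2)) / vnorm
            alpha = min(alpha, -1.0)
            qs = q - 2 * alpha * rq + alpha**2 * vq
            ps = p - 2 * alpha * rp + alpha**2 * vp
            qs, ps = em.project(qs, ps)
            qs, ps = em.step(qs, ps)               # stabilizing step
            n_steps += 1
            if em.objective(qs, ps) >= em.objective(q2, p2):
                q, p = qs, ps
                accepted = True
        if not accepted:
            q, p = q2, p2
        ll = em.objective(q, p)
        ll_hist.append(ll)
        if ll - ll_hist[-2] < tol:
            converged = True
            break
    qm = QMatrix(
        pd.DataFrame(q, index=ids, columns=source_pops),
        log_likelihood=ll_hist[-1],
        n_iterations=n_steps,
        converged=converged,
        flat_likelihood=flat,
    )
    qm.ll_history = ll_hist  # kept for monotonicity checks
    return qm


# ---------------------------------------------------------------------------
# Mode matching
# ---------------------------------------------------------------------------

def g_prime(q1: np.ndarray, q2: np.ndarray, allow_hungarian: bool = False) -> tuple[float, tuple[int, ...]]:
    """Symmetric similarity between two Q matrices, maximized over column
    permutations.  Returns (G', best permutation of q2's columns)."""
    q1 = np.asarray(q1, float)
    q2 = np.asarray(q2, float)
    if q1.shape != q2.shape:
        raise GenotypeError("Q matrices must have equal shape")
    C, K = q1.shape
    if K > 8 and not allow_hungarian:
        raise GenotypeError(
            "K > 8: exhaustive permutation search is infeasible; "
            "pass allow_hungarian=True for the assignment approximation"
        )
    norm = np.sqrt(2.0 * C)
    if K > 8:
        from scipy.optimize import linear_sum_assignment

        cost = -(q1.T @ q2)  # maximize column overlap
        _, perm = linear_sum_assignment(cost)
        perm = tuple(int(x) for x in perm)
        return 1.0 - float(np.linalg.norm(q1 - q2[:, perm])) / norm, perm
    best, best_perm = -np.inf, tuple(range(K))
    for perm in itertools.permutations(range(K)):
        g = 1.0 - float(np.linalg.norm(q1 - q2[:, perm])) / norm
        if g > best:
            best, best_perm = g, perm
    return best, best_perm


@dataclass
class ModeGrouping:
    similarity: np.ndarray
    mode_of_replicate: np.ndarray
    representative: pd.DataFrame
    mode_sizes: list[int] = field(default_factory=list)


def match_modes(replicates: list[pd.DataFrame], threshold: float = 0.9) -> ModeGrouping:
    """Group replicate Q matrices into common modes.

    Replicates are linked when G' >= *threshold*; modes are the connected
    components of that graph.  The representative is the permutation-aligned
    average of the largest mode (aligned to its lowest-index member).
    """
    if len(replicates) < 2:
        raise GenotypeError("need at least 2 replicates")
    mats = [r.to_numpy(float) for r in replicates]
    R = len(mats)
    sim = np.eye(R)
    perms: dict[tuple[int, int], tuple[int, ...]] = {}
    for i, j in itertools.combinations(range(R), 2):
        g, perm = g_prime(mats[i], mats[j])
        sim[i, j] = sim[j, i] = g
        perms[(i, j)] = perm
    _, labels = connected_components(sim >= threshold, directed=False)
    sizes = np.bincount(labels)
    main = int(np.argmax(sizes))
    members = np.flatnonzero(labels == main)
    anchor = int(members[0])
    aligned = [mats[anchor]]
    for j in members[1:]:
        _, perm = g_prime(mats[anchor], mats[int(j)])
        aligned.append(mats[int(j)][:, perm])
    rep = pd.DataFrame(
        np.mean(aligned, axis=0),
        index=replicates[anchor].index,
        columns=replicates[anchor].columns,
    )
    return ModeGrouping(sim, labels, rep, mode_sizes=sizes.tolist())


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

SHARE_BINS = ((0.0, 0.01), (0.01, 0.05), (0.05, 0.10), (0.10, 1.0 + 1e-12))
SHARE_BIN_LABELS = ("<1%", "1-5%", "5-10%", ">10%")


def group_totals(component_means: pd.Series, group: list[str]) -> float:
    """Sum of named ancestry-component means (plain arithmetic helper)."""
    missing = [g for g in group if g not in component_means.index]
    if missing:
        raise GenotypeError(f"unknown component labels: {missing}")
    return float(component_means[group].sum())


def summarize_ancestry(
    q: QMatrix | pd.DataFrame,
    component_groups: dict[str, list[str]],
    bin_group: str | None = None,
) -> dict:
    """Ancestry-composition summary tables.

    Returns a dict with: per-component ``means`` and ``sds`` (fractions),
    per-individual grouped totals (``grouped``), per-group mean/SD
    (``group_stats``), the binned share of individuals for *bin_group*
    over [0,1%), [1,5%), [5,10%), [10%,100%] (``bins``), and pairwise
    Spearman rank correlations among the components of *bin_group*
    (``component_correlations``).
    """
    qdf = q.q if isinstance(q, QMatrix) else q
    for name, labels in component_groups.items():
        unknown = [l for l in labels if l not in qdf.columns]
        if unknown:
            raise GenotypeError(f"group {name!r}: unknown labels {unknown}")
    means = qdf.mean(axis=0)
    sds = qdf.std(axis=0, ddof=1)
    grouped = pd.DataFrame(
        {name: qdf[labels].sum(axis=1) for name, labels in component_groups.items()},
        index=qdf.index,
    )
    group_stats = pd.DataFrame({"mean": grouped.mean(), "sd": grouped.std(ddof=1)})
    out = {
        "means": means,
        "sds": sds,
        "grouped": grouped,
        "group_stats": group_stats,
    }
    if bin_group is not None:
        if bin_group not in grouped.columns:
            raise GenotypeError(f"unknown group {bin_group!r}")
        totals = grouped[bin_group]
        shares = {}
        for (lo, hi), lab in zip(SHARE_BINS, SHARE_BIN_LABELS):
            shares[lab] = float(((totals >= lo) & (totals < hi)).mean())
        out["bins"] = pd.Series(shares)
        labels = component_groups[bin_group]
        corr = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
        for a, b in itertools.combinations(labels, 2):
            rho = spearmanr(qdf[a], qdf[b]).statistic
            corr.loc[a, b] = corr.loc[b, a] = rho
        out["component_correlations"] = corr
    return out
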