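"""Genotype I/O, QC, merging, relatedness and masking."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from admixcape import genio
from admixcape.genio import MISSING, GenotypeError

from conftest import make_gm


# ---------------------------------------------------------------------------
# HWE exact test: independent enumeration oracle in exact rational arithmetic
# ---------------------------------------------------------------------------

def hwe_oracle(n_het, n_hom1, n_hom2):
    from math import factorial

    n = n_het + n_hom1 + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    n_common = 2 * n - n_rare

    def prob(h):
        rare_hom = (n_rare - h) // 2
        common_hom = (n_common - h) // 2
        return Fraction(
            2**h * factorial(n),
            factorial(rare_hom) * factorial(h) * factorial(common_hom),
        )

    hets = range(n_rare % 2, n_rare + 1, 2)
    probs = {h: prob(h) for h in hets}
    total = sum(probs.values())
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs) / total)


@pytest.mark.parametrize(
    "het,hom1,hom2",
    [(100, 0, 0), (50, 25, 25), (10, 40, 50), (1, 0, 99), (0, 50, 50), (3, 3, 3)],
)
def test_hwe_exact_matches_enumeration(het, hom1, hom2):
    assert genio.hwe_exact_p(het, hom1, hom2) == pytest.approx(
        hwe_oracle(het, hom1, hom2), rel=1e-9
    )


# ---------------------------------------------------------------------------
# File round trips
# ---------------------------------------------------------------------------

def test_ped_map_round_trip(tmp_path):
    calls = np.array(
        [[0, 1, 2, MISSING, 1], [2, 2, 0, 1, 0], [1, 0, 1, 2, MISSING]]
    )
    gm = make_gm(calls, ["P1", "P1", "P2"], ref=["A", "C", "G", "T", "A"], alt=["G", "T", "C", "C", "C"])
    genio.save_genotypes(gm, tmp_path / "toy")
    back = genio.load_genotypes(tmp_path / "toy", alleles=gm.variants)
    assert np.array_equal(back.calls, gm.calls)
    assert list(back.samples["population"]) == ["P1", "P1", "P2"]
    assert back.variants["pos"].tolist() == gm.variants["pos"].tolist()


def test_ped_dialect_allele_pairs(tmp_path):
    # hand-written two-sample file; with (ref,alt)=(A,G): "A G" -> 1, "G G" -> 2
    (tmp_path / "h.map").write_text("1\trs1\t0\t100\n")
    (tmp_path / "h.ped").write_text("FAM a 0 0 0 -9 A G\nFAM b 0 0 0 -9 G G\n")
    alleles = pd.DataFrame({"ref": ["A"], "alt": ["G"]})
    gm = genio.load_genotypes(tmp_path / "h", alleles=alleles)
    assert gm.calls[:, 0].tolist() == [1, 2]


def test_ped_malformed_line_reports_lineno(tmp_path):
    (tmp_path / "bad.map").write_text("1\trs1\t0\t100\n")
    (tmp_path / "bad.ped").write_text("FAM a 0 0 0 -9 A G\nFAM b 0 0 0 -9 A\n")
    with pytest.raises(GenotypeError, match="line 2"):
        genio.load_genotypes(tmp_path / "bad")


def test_vcf_genotype_encoding(tmp_path):
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\n"
        "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0|1\t./.\t1/1\n"
    )
    gm = genio.load_genotypes(vcf, fmt="vcf")
    assert gm.calls[:, 0].tolist() == [1, MISSING, 2]


def test_vcf_round_trip(tmp_path, rng):
    calls = rng.integers(0, 3, (4, 6))
    gm = make_gm(calls, ["P"] * 4)
    genio.save_genotypes(gm, tmp_path / "rt.vcf", fmt="vcf")
    back = genio.load_genotypes(tmp_path / "rt.vcf", fmt="vcf")
    assert np.array_equal(back.calls, gm.calls)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_qc_missingness_threshold_boundary():
    calls = np.zeros((10, 20), dtype=np.int8)  # enough SNPs that no individual fails
    calls[:2, 0] = MISSING          # 20% missing -> removed
    calls[0, 1] = MISSING           # 10% missing -> retained (<= threshold)
    calls[:, 2] = [0, 1, 2, 0, 1, 2, 0, 1, 2, 0]
    gm = make_gm(calls, ["P"] * 10)
    out, rep = genio.qc_filter(gm, hwe_alpha=0.0)
    assert rep.n_removed_missingness == 1
    assert "snp0" not in set(out.variants["id"])
    assert "snp1" in set(out.variants["id"])


def test_qc_atcg_removed_regardless_of_frequency():
    calls = np.tile([0, 1, 2, 1], (4, 1)).T  # 4 samples x 4 SNPs
    gm = make_gm(calls, ["P"] * 4, ref=["A", "C", "A", "G"], alt=["T", "G", "G", "C"])
    out, rep = genio.qc_filter(gm, hwe_alpha=0.0)
    assert rep.n_removed_atcg == 3
    assert out.variants["id"].tolist() == ["snp2"]


def test_qc_hwe_removes_all_heterozygous_snp():
    calls = np.ones((100, 2), dtype=np.int8)       # SNP0: 100/100 hets
    calls[:, 1] = [0] * 25 + [1] * 50 + [2] * 25   # SNP1: perfect HWE
    gm = make_gm(calls, ["P"] * 100)
    assert genio.hwe_exact_p(100, 0, 0) < 0.001
    out, rep = genio.qc_filter(gm)
    assert rep.n_removed_hwe == 1
    assert out.variants["id"].tolist() == ["snp1"]


def test_qc_structural_removals():
    calls = np.tile([0, 1], (5, 1)).T.repeat(3, axis=1)[:, :5].copy()
    calls = np.zeros((4, 5), dtype=np.int8)
    gm = make_gm(
        calls,
        ["P"] * 4,
        chrom=["0", "X", "1", "1", "MT"],
        pos=[100, 200, 300, 300, 500],
    )
    out, rep = genio.qc_filter(gm, hwe_alpha=0.0)
    # chrom 0, X, MT and the duplicated pair at 1:300 all go
    assert rep.n_removed_structural == 5
    assert out.n_snps == 0


def test_qc_idempotent(rng):
    calls = rng.integers(0, 3, (40, 60)).astype(np.int8)
    calls[rng.random((40, 60)) < 0.05] = MISSING
    gm = make_gm(calls, ["P"] * 40)
    once, _ = genio.qc_filter(gm)
    twice, rep2 = genio.qc_filter(once)
    assert once.equals(twice)
    assert not rep2.samples_removed


# ---------------------------------------------------------------------------
# Merge
# ---------------------------------------------------------------------------

def _pair(calls_a, alle_a, calls_b, alle_b, pos=(100,)):
    a = make_gm(calls_a, ["A"] * len(calls_a), pos=list(pos), ref=[alle_a[0]], alt=[alle_a[1]])
    b = make_gm(calls_b, ["B"] * len(calls_b), pos=list(pos), ref=[alle_b[0]], alt=[alle_b[1]])
    b.samples.index = pd.Index([f"t{i}" for i in range(len(calls_b))], name="sample")
    return a, b


def test_merge_strand_flip_once():
    a, b = _pair([[1]], "AG", [[1]], "TC")
    merged, rep = genio.merge_datasets(a, b)
    assert rep.n_flipped == 1 and rep.n_dropped_mismatch == 0
    assert merged.n_snps == 1 and merged.n_samples == 2


def test_merge_flip_with_swap_recodes_calls():
    # b is on the other strand AND has ref/alt swapped: flip + recode 2-g
    a, b = _pair([[0]], "AG", [[0]], "CT")
    merged, rep = genio.merge_datasets(a, b)
    assert rep.n_flipped == 1
    assert merged.calls[1, 0] == 2


def test_merge_irreconcilable_dropped():
    a, b = _pair([[1]], "AC", [[1]], "AG")
    merged, rep = genio.merge_datasets(a, b)
    assert rep.n_dropped_mismatch == 1 and merged.n_snps == 0
    # with a second, clean SNP the bad one is dropped and reported
    a2 = make_gm([[1, 1]], ["A"], pos=[100, 200], ref=["A", "A"], alt=["C", "G"])
    b2 = make_gm([[1, 1]], ["B"], pos=[100, 200], ref=["A", "A"], alt=["G", "G"])
    b2.samples.index = pd.Index(["t0"], name="sample")
    merged, rep = genio.merge_datasets(a2, b2)
    assert rep.n_dropped_mismatch == 1 and merged.n_snps == 1


def test_merge_disjoint_positions_error():
    a, _ = _pair([[1]], "AG", [[1]], "AG")
    b = make_gm([[1]], ["B"], pos=[999], ref=["A"], alt=["G"])
    b.samples.index = pd.Index(["t0"], name="sample")
    with pytest.raises(GenotypeError, match="overlap"):
        genio.merge_datasets(a, b)


def test_merge_symmetric_variant_sets(rng):
    pos_a = sorted(rng.choice(200, 50, replace=False) * 37 + 1)   # dense grids:
    pos_b = sorted(rng.choice(200, 50, replace=False) * 37 + 1)   # overlap certain
    a = make_gm(rng.integers(0, 3, (3, 50)), ["A"] * 3, pos=pos_a)
    b = make_gm(rng.integers(0, 3, (3, 50)), ["B"] * 3, pos=pos_b)
    b.samples.index = pd.Index([f"t{i}" for i in range(3)], name="sample")
    m_ab, _ = genio.merge_datasets(a, b)
    m_ba, _ = genio.merge_datasets(b, a)
    key = ["chrom", "pos", "ref", "alt"]
    assert m_ab.variants[key].equals(m_ba.variants[key])


# ---------------------------------------------------------------------------
# Relatedness
# ---------------------------------------------------------------------------

def test_relatedness_duplicate_flagged_and_removed(rng):
    p = rng.uniform(0.1, 0.9, 2000)
    base = rng.binomial(2, p, (5, 2000)).astype(np.int8)
    calls = np.vstack([base, base[0]])  # sample 5 duplicates sample 0
    gm = make_gm(calls, ["P"] * 6)
    pruned, pairs = genio.relatedness_prune(gm)
    dup = pairs[(pairs["sample_a"] == "s0") & (pairs["sample_b"] == "s5")]
    assert dup["pi_hat"].iloc[0] > 0.9 and bool(dup["flagged"].iloc[0])
    assert pruned.n_samples == 5


def test_relatedness_independent_samples_below_null(rng):
    p = rng.uniform(0.1, 0.9, 5000)
    calls = rng.binomial(2, p, (2, 5000)).astype(np.int8)
    gm = make_gm(calls, ["P"] * 2)
    _, pairs = genio.relatedness_prune(gm)
    assert pairs["pi_hat"].iloc[0] < 0.1


def test_relatedness_vacuous_threshold(rng):
    calls = rng.binomial(2, 0.5, (4, 500)).astype(np.int8)
    gm = make_gm(calls, ["P"] * 4)
    pruned, pairs = genio.relatedness_prune(gm, threshold=1.1)
    assert pruned.n_samples == 4 and not pairs["flagged"].any()


def test_relatedness_monomorphic_error():
    gm = make_gm(np.zeros((3, 10), dtype=np.int8), ["P"] * 3)
    with pytest.raises(GenotypeError):
        genio.relatedness_prune(gm)


# ---------------------------------------------------------------------------
# Local-ancestry masking
# ---------------------------------------------------------------------------

def _tracts(rows):
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "haplotype_id", "ancestry"])


def test_mask_identity_when_all_keep(rng):
    calls = rng.integers(0, 3, (2, 10))
    gm = make_gm(calls, ["T", "T"])
    tr = _tracts(
        [("1", 0, 20_000, f"s{i}_h{h}", "EUR") for i in range(2) for h in (0, 1)]
    )
    out = genio.mask_by_local_ancestry(gm, tr, "EUR")
    assert np.array_equal(out.calls, gm.calls)


def test_mask_counts_snps_in_non_keep_tract():
    pos = np.arange(1, 21) * 100_000  # 100 kb spacing
    gm = make_gm(np.ones((2, 20), dtype=np.int8), ["T", "X"], pos=pos)
    tr = _tracts(
        [
            ("1", 0, 1_000_000, "s0_h0", "OTHER"),   # 10 SNPs on one haplotype
            ("1", 1_000_000, 3_000_000, "s0_h0", "EUR"),
            ("1", 0, 3_000_000, "s0_h1", "EUR"),
        ]
    )
    out = genio.mask_by_local_ancestry(gm, tr, "EUR")
    assert (out.calls[0] == MISSING).sum() == 10
    assert np.array_equal(out.calls[1], gm.calls[1])  # untracted sample untouched


def test_mask_missing_haplotype_errors():
    gm = make_gm(np.ones((1, 5), dtype=np.int8), ["T"])
    tr = _tracts([("1", 0, 10_000, "s0_h0", "EUR")])
    with pytest.raises(GenotypeError, match="s0"):
        genio.mask_by_local_ancestry(gm, tr, "EUR")
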