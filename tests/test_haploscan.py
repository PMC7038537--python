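"""EHH, iHS and XP-EHH haplotype statistics."""

import numpy as np
import pandas as pd
import pytest

from admixcape import haploscan as hs, simcohort as sc
from admixcape.genio import GenotypeError


def hapset(hap, spacing_bp=10_000):
    hap = np.asarray(hap, dtype=np.uint8)
    pos = (np.arange(hap.shape[1]) + 1) * spacing_bp
    return hs.HaplotypeSet(hap, pos)


@pytest.fixture(scope="module")
def neutral_panel():
    """Unlinked haplotypes from one source panel (null for selection scans)."""
    specs = (sc.SourcePopSpec("P", 0.2, 100),)
    scen = sc.AdmixtureScenario(specs, (1.0,), 10.0, 1, n_snps=5000, seed=11)
    coh = sc.simulate_cohort(scen)
    v = coh.genotypes.variants
    return (
        hs.HaplotypeSet(coh.haplotypes[:200], v["pos"].to_numpy(), v["cm"].to_numpy()),
        v,
    )


class TestAssignAncestral:
    def test_unanimity_disagreement_missing(self):
        variants = pd.DataFrame(
            {"ref": ["A", "A", "C", "T"], "alt": ["G", "G", "T", "C"]}
        )
        outgroups = np.array(
            [
                ["A", "A", "A"],      # unanimous, matches ref
                ["A", "G", "A"],      # disagreement -> unknown
                ["C", "", "C"],       # missing tolerated
                ["G", "G", "G"],      # unanimous but not a SNP allele -> unknown
            ],
            dtype=object,
        )
        out = hs.assign_ancestral(variants, outgroups)
        assert out["ancestral"].tolist() == ["A", None, "C", None]
        assert out["n_outgroups_agreeing"].tolist()[0] == 3


class TestEhh:
    def test_identical_carriers_stay_one(self):
        hap = np.vstack([np.ones((4, 10)), np.zeros((2, 10))])
        curve = hs.ehh_curve(hapset(hap), focal_snp=5, core_allele=1)
        assert (curve["ehh"] == 1.0).all()

    def test_two_two_split_gives_one_third(self):
        hap = [[1, 1, 0], [1, 1, 0], [1, 0, 1], [1, 0, 1]]
        curve = hs.ehh_curve(hapset(hap), focal_snp=0, core_allele=1)
        right = curve[curve["side"] == "right"]
        assert right["ehh"].tolist() == [1.0, pytest.approx(1 / 3), pytest.approx(1 / 3)]

    def test_monotone_non_increasing(self, neutral_panel):
        haps, _ = neutral_panel
        for focal in (100, 2500, 4000):
            curve = hs.ehh_curve(haps, focal, core_allele=1, floor=0.0)
            for _, side_curve in curve.groupby("side"):
                d = np.abs(side_curve["pos_bp"] - haps.pos_bp[focal])
                ehh = side_curve["ehh"].to_numpy()[np.argsort(d.to_numpy(), kind="stable")]
                assert (np.diff(ehh) <= 1e-12).all()

    def test_singleton_core_errors(self):
        hap = [[1, 0], [0, 0], [0, 1]]
        with pytest.raises(GenotypeError):
            hs.ehh_curve(hapset(hap), focal_snp=0, core_allele=1)

    def test_gap_truncation_equals_manual_cut(self):
        rng = np.random.default_rng(3)
        hap = rng.integers(0, 2, (40, 30)).astype(np.uint8)
        hap[:, 10] = 1  # common focal allele
        pos = np.arange(30) * 50_000
        pos[20:] += 400_000  # gap of 450 kb between SNP 19 and 20
        full = hs.HaplotypeSet(hap, pos + 1)
        cut = hs.HaplotypeSet(hap[:, :20], pos[:20] + 1)
        carriers = hap[:, 10] == 1
        ihh_full = hs._ihh(full.hap, carriers, 10, full.pos_bp, full.pos_cm, 200_000, 0.0)
        ihh_cut = hs._ihh(cut.hap, carriers, 10, cut.pos_bp, cut.pos_cm, 200_000, 0.0)
        assert ihh_full == pytest.approx(ihh_cut)


class TestIhs:
    def test_symmetric_cores_score_zero(self):
        # ancestral and derived carriers have mirror-image haplotype structure
        hap = np.array(
            [
                [1, 1, 0, 1, 1],
                [1, 1, 0, 1, 0],
                [0, 0, 1, 0, 0],
                [0, 0, 1, 0, 1],
            ],
            dtype=np.uint8,
        )
        anc = pd.DataFrame({"ancestral": ["ref"] * 5})
        scan = hs.ihs_scan(hapset(hap), anc, maf_min=0.0, bin_width=1.0, min_bin_snps=1)
        assert scan["ihs_raw"][2] == pytest.approx(0.0)

    def test_null_calibration_and_standardization(self, neutral_panel):
        haps, variants = neutral_panel
        anc = pd.DataFrame({"ancestral": variants["ref"]})
        scan = hs.ihs_scan(haps, anc, variants)
        std = scan["ihs_std"].dropna()
        assert abs((std.abs() > 2).mean() - 0.05) < 0.02
        # per-bin standardization: mean ~0, SD ~1 in populated bins
        ok = scan["ihs_std"].notna()
        code = np.minimum((scan["freq_derived"][ok] / 0.05).astype(int), 19)
        grouped = scan[ok].groupby(code)["ihs_std"]
        stats = grouped.agg(["mean", "std", "count"])
        big = stats[stats["count"] >= 100]
        assert len(big) > 5
        assert (big["mean"].abs() < 0.02).all()
        assert big["std"].between(0.95, 1.05).all()

    def test_duplicating_haplotypes_nearly_invariant_ehh(self, neutral_panel):
        # haplotype frequencies are unchanged by duplicating every haplotype;
        # the combinatorial EHH estimator C(n_h,2)/C(n,2) is O(1/n) sensitive
        # to it, so the curves agree to that order (not exactly)
        haps, _ = neutral_panel
        sub = hs.HaplotypeSet(haps.hap[:, :400], haps.pos_bp[:400], haps.pos_cm[:400])
        dup = hs.HaplotypeSet(np.repeat(sub.hap, 2, axis=0), sub.pos_bp, sub.pos_cm)
        for focal in (50, 200, 350):
            c1 = hs.ehh_curve(sub, focal, core_allele=1, floor=0.0)
            c2 = hs.ehh_curve(dup, focal, core_allele=1, floor=0.0)
            merged = c1.merge(c2, on=["snp_index", "side"], suffixes=("_1", "_2"))
            assert np.max(np.abs(merged["ehh_1"] - merged["ehh_2"])) < 0.02

    def test_unpolarized_snps_flagged(self, neutral_panel):
        haps, variants = neutral_panel
        anc = pd.DataFrame({"ancestral": [None] * haps.n_snps})
        scan = hs.ihs_scan(haps, anc)
        assert (scan["flag"] == "unpolarized").all()
        assert scan["ihs_raw"].isna().all()


class TestXpehh:
    def test_population_against_itself_is_zero(self, neutral_panel):
        haps, _ = neutral_panel
        sub = hs.HaplotypeSet(haps.hap[:, :500], haps.pos_bp[:500], haps.pos_cm[:500])
        scan = hs.xpehh_scan(sub, sub)
        ok = scan["xpehh_raw"].notna()
        assert ok.any()
        assert np.allclose(scan.loc[ok, "xpehh_raw"], 0.0)

    def test_swap_negates_scores(self, neutral_panel):
        haps, _ = neutral_panel
        a = hs.HaplotypeSet(haps.hap[:100, :500], haps.pos_bp[:500], haps.pos_cm[:500])
        b = hs.HaplotypeSet(haps.hap[100:, :500], haps.pos_bp[:500], haps.pos_cm[:500])
        ab = hs.xpehh_scan(a, b, standardize=False)
        ba = hs.xpehh_scan(b, a, standardize=False)
        ok = ab["xpehh_raw"].notna() & ba["xpehh_raw"].notna()
        assert np.allclose(ab.loc[ok, "xpehh_raw"], -ba.loc[ok, "xpehh_raw"])

    def test_planted_sweep_detected(self, neutral_panel):
        haps, _ = neutral_panel
        hapA = haps.hap[:100].copy()
        hapB = haps.hap[100:].copy()
        # plant a fully homozygous 0.4 cM block at 50% frequency in A only
        pos_cm = haps.pos_cm
        center = 2500
        block = np.abs(pos_cm - pos_cm[center]) <= 0.2
        hapA[:50, block] = haps.hap[0, block]
        A = hs.HaplotypeSet(hapA, haps.pos_bp, pos_cm)
        B = hs.HaplotypeSet(hapB, haps.pos_bp, pos_cm)
        scan = hs.xpehh_scan(A, B)
        inside = scan["xpehh_std"][block]
        outside = scan["xpehh_std"][~block].dropna()
        assert np.nanmax(np.abs(inside)) > np.quantile(np.abs(outside), 0.99)

    def test_grid_mismatch_errors(self, neutral_panel):
        haps, _ = neutral_panel
        a = hs.HaplotypeSet(haps.hap[:, :100], haps.pos_bp[:100], haps.pos_cm[:100])
        b = hs.HaplotypeSet(haps.hap[:, 1:101], haps.pos_bp[1:101], haps.pos_cm[1:101])
        with pytest.raises(GenotypeError):
            hs.xpehh_scan(a, b)
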