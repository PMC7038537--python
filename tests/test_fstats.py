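"""f-statistics: WC FST, f3/f4 with block jackknife, carrier-frequency test."""

import itertools
from math import comb

import numpy as np
import pytest

from admixcape import fstats, simcohort as sc
from admixcape.fstats import JackknifeConfig
from admixcape.genio import GenotypeError

from conftest import make_gm, gm_from_freqs


# ---------------------------------------------------------------------------
# Independent textbook Weir-Cockerham oracle (scalar transcription)
# ---------------------------------------------------------------------------

def wc_oracle(counts1, counts2):
    """theta-hat for one SNP from genotype counts (hom_ref, het, hom_alt)."""
    r = 2
    ns, ps, hs = [], [], []
    for hom_ref, het, hom_alt in (counts1, counts2):
        n = hom_ref + het + hom_alt
        ns.append(n)
        ps.append((2 * hom_alt + het) / (2 * n))
        hs.append(het / n)
    nbar = sum(ns) / r
    nc = (sum(ns) - sum(n * n for n in ns) / sum(ns)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / sum(ns)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / sum(ns)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a / (a + b + c)


def gm_from_counts(counts1, counts2):
    calls = []
    for counts in (counts1, counts2):
        col = [0] * counts[0] + [1] * counts[1] + [2] * counts[2]
        calls.append(col)
    n1, n2 = len(calls[0]), len(calls[1])
    arr = np.full((n1 + n2, 1), 0, dtype=np.int8)
    arr[:n1, 0] = calls[0]
    arr[n1:, 0] = calls[1]
    return make_gm(arr, ["P1"] * n1 + ["P2"] * n2)


class TestWcFst:
    def test_fixed_difference_is_one(self):
        gm = gm_from_counts((10, 0, 0), (0, 0, 10))
        _, per_snp = fstats.wc_fst(gm, ["P1", "P2"], per_snp=True)
        assert per_snp[0] == pytest.approx(1.0)

    def test_null_near_zero(self, rng):
        p = rng.uniform(0.1, 0.9, 10_000)
        gm = gm_from_freqs(rng, {"P1": p, "P2": p}, 30)
        assert abs(fstats.wc_fst(gm, ["P1", "P2"])) < 0.005

    def test_matches_textbook_oracle(self, rng):
        spec_case = ((4, 4, 2), (1, 4, 5))
        cases = [spec_case]
        for _ in range(50):
            c1 = tuple(rng.integers(0, 8, 3) + np.array([1, 0, 0]))
            c2 = tuple(rng.integers(0, 8, 3) + np.array([0, 0, 1]))
            cases.append((c1, c2))
        for c1, c2 in cases:
            if sum(c1) < 2 or sum(c2) < 2:
                continue
            gm = gm_from_counts(c1, c2)
            _, per_snp = fstats.wc_fst(gm, ["P1", "P2"], per_snp=True)
            assert per_snp[0] == pytest.approx(wc_oracle(c1, c2), abs=1e-12)

    def test_monotone_in_divergence(self):
        values = []
        for F in (0.01, 0.05, 0.1, 0.2):
            specs = (sc.SourcePopSpec("A", F, 40), sc.SourcePopSpec("B", F, 40))
            scen = sc.AdmixtureScenario(specs, (1.0, 0.0), 5.0, 1, n_snps=10_000, seed=21)
            gm = sc.simulate_cohort(scen).genotypes
            values.append(fstats.wc_fst(gm, ["A", "B"]))
        assert values == sorted(values)

    def test_missing_population_errors(self, rng):
        gm = gm_from_freqs(rng, {"P1": [0.5] * 5}, 5)
        with pytest.raises(GenotypeError):
            fstats.wc_fst(gm, ["P1", "NOPE"])


def _three_pop_gm(t_calls, a_calls, b_calls, n_snps=10, n_per=10, cm=True):
    arr = np.concatenate(
        [
            np.full((n_per, n_snps), t_calls, dtype=np.int8),
            np.full((n_per, n_snps), a_calls, dtype=np.int8),
            np.full((n_per, n_snps), b_calls, dtype=np.int8),
        ]
    )
    cm_vals = np.arange(n_snps) * 2.0 if cm else None  # 2 cM spacing -> >=2 blocks
    return make_gm(arr, ["T"] * n_per + ["A"] * n_per + ["B"] * n_per, cm=cm_vals)


class TestF3:
    def test_closed_form(self):
        # t = 0.5 (all hets), a = 0, b = 1 at every SNP: (t-a)(t-b) = -0.25
        gm = _three_pop_gm(1, 0, 2)
        res = fstats.f3_test(gm, "T", "A", "B", freq_corrected=False)
        assert res.value == pytest.approx(-0.25)

    def test_target_equals_source_nonnegative(self, rng):
        p = rng.uniform(0.2, 0.8, 200)
        calls_t = rng.binomial(2, p, (10, 200)).astype(np.int8)
        calls_b = rng.binomial(2, 1 - p, (10, 200)).astype(np.int8)
        arr = np.concatenate([calls_t, calls_t, calls_b])
        gm = make_gm(arr, ["T"] * 10 + ["A"] * 10 + ["B"] * 10,
                     cm=np.arange(200) * 0.5)
        res = fstats.f3_test(gm, "T", "A", "B", freq_corrected=False)
        assert res.value == 0.0 and res.z == 0.0

    def test_admixed_target_strongly_negative(self):
        specs = (sc.SourcePopSpec("S1", 0.2, 30), sc.SourcePopSpec("S2", 0.2, 30))
        scen = sc.AdmixtureScenario(specs, (0.5, 0.5), 10.0, 50, n_snps=20_000, seed=31)
        gm = sc.simulate_cohort(scen).genotypes
        res = fstats.f3_test(gm, "ADMIX", "S1", "S2")
        assert res.value < 0 and res.z < -3

    def test_source_order_symmetry(self, rng):
        p = {k: rng.uniform(0.1, 0.9, 300) for k in ("T", "A", "B")}
        gm = gm_from_freqs(rng, p, 15, cm=np.arange(300) * 0.1)
        r1 = fstats.f3_test(gm, "T", "A", "B")
        r2 = fstats.f3_test(gm, "T", "B", "A")
        assert r1.value == r2.value and r1.se == r2.se

    def test_too_few_blocks_errors(self, rng):
        p = {k: rng.uniform(0.1, 0.9, 20) for k in ("T", "A", "B")}
        gm = gm_from_freqs(rng, p, 10, cm=np.full(20, 0.1))  # all SNPs one block
        with pytest.raises(GenotypeError, match="block"):
            fstats.f3_test(gm, "T", "A", "B")


class TestF4:
    def test_null_and_sign_relations(self, rng):
        p = {k: rng.uniform(0.1, 0.9, 2000) for k in ("A", "C", "D")}
        p["B"] = p["A"]  # b drawn from a's frequencies -> E[f4] = 0
        gm = gm_from_freqs(rng, p, 20, cm=np.arange(2000) * 0.05)
        res = fstats.f4_test(gm, "A", "B", "C", "D")
        assert abs(res.z) < 2
        swapped = fstats.f4_test(gm, "A", "B", "D", "C")
        assert swapped.value == pytest.approx(-res.value)
        pair_swap = fstats.f4_test(gm, "B", "A", "C", "D")
        assert pair_swap.value == pytest.approx(-res.value)

    def test_closed_form_one(self):
        n = 10
        arr = np.concatenate(
            [
                np.full((n, 8), 2, dtype=np.int8),   # a = 1
                np.full((n, 8), 0, dtype=np.int8),   # b = 0
                np.full((n, 8), 2, dtype=np.int8),   # c = 1
                np.full((n, 8), 0, dtype=np.int8),   # d = 0
            ]
        )
        gm = make_gm(arr, ["A"] * n + ["B"] * n + ["C"] * n + ["D"] * n,
                     cm=np.arange(8) * 3.0)
        assert fstats.f4_test(gm, "A", "B", "C", "D").value == pytest.approx(1.0)


class TestF3Screen:
    def test_pair_counts_and_fixing(self, rng):
        p = {k: rng.uniform(0.1, 0.9, 300) for k in ("T", "C1", "C2", "C3", "C4")}
        gm = gm_from_freqs(rng, p, 10, cm=np.arange(300) * 0.1)
        free = fstats.f3_screen(gm, "T", ["C1", "C2", "C3"])
        assert len(free) == 3  # C(3,2)
        fixed = fstats.f3_screen(gm, "T", ["C1", "C2", "C3", "C4"], fixed_source="C1")
        assert len(fixed) == 3
        assert ((fixed["source_a"] == "C1") | (fixed["source_b"] == "C1")).all()
        assert "T" not in set(fixed["source_a"]) | set(fixed["source_b"])
        assert (free["z"].diff().dropna() >= 0).all()  # ascending by Z


class TestJackknife:
    def test_constant_blocks_zero_se(self):
        per_snp = np.full(100, 0.42)
        blocks = np.repeat(np.arange(10), 10)
        theta, se, g, n = fstats._weighted_jackknife(per_snp, blocks)
        assert theta == pytest.approx(0.42) and se == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Carrier-frequency comparison
# ---------------------------------------------------------------------------

def fisher_oracle(table):
    """Two-sided Fisher exact p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return comb(col1, x) * comb(n - col1, row1 - x) / comb(n, row1)

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )


class TestCarrierFrequency:
    def test_identical_counts_p_one(self):
        out = fstats.carrier_frequency_test((5, 10, 5), (5, 10, 5), model="allelic")
        assert out["p_value"] == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        # allele counts (10,0) vs (0,10): p = 2 / C(20,10) ~ 1.082e-5
        out = fstats.carrier_frequency_test((5, 0, 0), (0, 0, 5), model="allelic")
        assert out["p_value"] == pytest.approx(2 / comb(20, 10), rel=1e-6)
        assert out["p_value"] == pytest.approx(fisher_oracle(out["table"]), rel=1e-6)

    @pytest.mark.parametrize("model", ["allelic", "dominant_carrier"])
    def test_random_tables_match_enumeration(self, model, rng):
        for _ in range(20):
            ca = tuple(int(x) for x in rng.integers(0, 6, 3) + [1, 0, 0])
            cb = tuple(int(x) for x in rng.integers(0, 6, 3) + [0, 0, 1])
            out = fstats.carrier_frequency_test(ca, cb, model=model)
            assert out["p_value"] == pytest.approx(fisher_oracle(out["table"]), rel=1e-6)

    def test_carrier_frequency_arithmetic(self):
        out = fstats.carrier_frequency_test((2, 3, 5), (1, 1, 1), model="dominant_carrier")
        assert out["freq_a"] == pytest.approx(0.5)

    def test_empty_population_errors(self):
        with pytest.raises(GenotypeError):
            fstats.carrier_frequency_test((0, 0, 0), (1, 1, 1))
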