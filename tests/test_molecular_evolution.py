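import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wrkykit import molecular_evolution as me

CODONS = [
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if me.translate_codon("".join(c)) is not None
]


# ---------------------------------------------------------------------------
# Independent oracle: breadth-first enumeration of single-step mutation paths
# between two codons, classifying each step by comparing translations.


def oracle_pathways(codon_a, codon_b):
    """All shortest substitution paths a->b as lists of (syn?, codon) steps."""
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    paths = []

    def extend(current, remaining, steps):
        if not remaining:
            paths.append(steps)
            return
        for pos in remaining:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            is_syn = me.translate_codon(current) == me.translate_codon(nxt)
            extend(nxt, [p for p in remaining if p != pos], steps + [(is_syn, nxt)])

    extend(codon_a, diffs, [])
    return paths


def oracle_differences(codon_a, codon_b):
    paths = oracle_pathways(codon_a, codon_b)
    valid = [p for p in paths if all(me.translate_codon(c) is not None for _, c in p)]
    chosen = valid if valid else paths
    if not chosen:
        return 0.0, 0.0
    sd = np.mean([sum(1 for s, c in p if s and me.translate_codon(c) is not None) for p in chosen])
    nd = np.mean(
        [
            sum(
                1
                for s, c in p
                if not s or me.translate_codon(c) is None
            )
            for p in chosen
        ]
    )
    return float(sd), float(nd)


def oracle_site_fraction(codon):
    aa = me.translate_codon(codon)
    syn = 0
    for pos, alt in itertools.product(range(3), "ACGT"):
        if alt == codon[pos]:
            continue
        mutant = codon[:pos] + alt + codon[pos + 1 :]
        if me.translate_codon(mutant) == aa:
            syn += 1
    return syn / 3.0


class TestSites:
    @pytest.mark.parametrize("codon", ["TTT", "CTG", "ATG", "TGG", "GGG", "CGA", "AGG"])
    def test_site_fraction_matches_oracle(self, codon):
        assert me.synonymous_site_fraction(codon) == pytest.approx(oracle_site_fraction(codon))

    def test_all_codons_site_sum(self):
        for codon in CODONS:
            s = me.synonymous_site_fraction(codon)
            assert 0.0 <= s <= 3.0

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            me.synonymous_site_fraction("TAA")


class TestNeiGojobori:
    def test_identical_sequences(self):
        result = me.nei_gojobori([("ATG", "ATG"), ("TTT", "TTT")])
        assert result.Ks == 0.0 and result.Ka == 0.0
        assert result.sd == 0.0 and result.nd == 0.0

    def test_phe_phe_single_synonymous_difference(self):
        result = me.nei_gojobori([("TTT", "TTC")])
        assert result.sd == 1.0 and result.nd == 0.0

    def test_single_nonsynonymous_difference(self):
        # ATG (Met) -> ATA (Ile)
        result = me.nei_gojobori([("ATG", "ATA")])
        assert result.sd == 0.0 and result.nd == 1.0

    def test_sites_sum_to_three_per_codon(self):
        rng = np.random.default_rng(0)
        pairs = [
            (CODONS[rng.integers(len(CODONS))], CODONS[rng.integers(len(CODONS))])
            for _ in range(40)
        ]
        result = me.nei_gojobori(pairs)
        assert result.S + result.N == pytest.approx(3 * len(pairs), abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_differences_match_pathway_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pairs = [
            (CODONS[rng.integers(len(CODONS))], CODONS[rng.integers(len(CODONS))])
            for _ in range(25)
        ]
        result = me.nei_gojobori(pairs)
        sd = nd = 0.0
        for a, b in pairs:
            d_s, d_n = oracle_differences(a, b)
            sd += d_s
            nd += d_n
        assert result.sd == pytest.approx(sd, abs=1e-9)
        assert result.nd == pytest.approx(nd, abs=1e-9)

    def test_symmetry(self):
        pairs = [("ATG", "CTG"), ("AAA", "AGG"), ("TTT", "GTC")]
        fwd = me.nei_gojobori(pairs)
        rev = me.nei_gojobori([(b, a) for a, b in pairs])
        assert fwd.sd == pytest.approx(rev.sd)
        assert fwd.nd == pytest.approx(rev.nd)
        assert fwd.S == pytest.approx(rev.S)

    def test_stop_codon_in_pair_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            me.nei_gojobori([("TAA", "TAA")])

    def test_saturation_flagged(self):
        # maximally different codon pairs drive pN above 3/4
        pairs = [("AAA", "GGG")] * 10 + [("CCC", "TTT")] * 10
        result = me.nei_gojobori(pairs)
        if result.pN >= 0.75:
            assert result.Ka is None and result.saturated

    @pytest.mark.parametrize("seed", [4, 5, 6])
    def test_matches_biopython_on_full_cds(self, seed):
        analysis = pytest.importorskip("Bio.Align.analysis")
        from Bio.Align import Alignment
        from Bio.Seq import Seq

        rng = np.random.default_rng(seed)
        codons_a = [CODONS[rng.integers(len(CODONS))] for _ in range(60)]
        codons_b = [
            CODONS[rng.integers(len(CODONS))] if rng.random() < 0.2 else c
            for c in codons_a
        ]
        mine = me.nei_gojobori(list(zip(codons_a, codons_b)))
        aln = Alignment([Seq("".join(codons_a)), Seq("".join(codons_b))])
        dn, ds = analysis.calculate_dn_ds(aln, method="NG86")
        assert mine.Ks == pytest.approx(ds, abs=1e-9)
        assert mine.Ka == pytest.approx(dn, abs=1e-9)


class TestJukesCantor:
    def test_zero(self):
        assert me.jukes_cantor(0.0) == 0.0

    def test_saturation(self):
        assert me.jukes_cantor(0.75) is None
        assert me.jukes_cantor(0.9) is None

    @given(st.floats(min_value=0.0, max_value=0.74))
    def test_monotone_and_at_least_p(self, p):
        d = me.jukes_cantor(p)
        assert d >= p - 1e-12

    def test_monotone_increasing(self):
        grid = np.linspace(0, 0.7, 50)
        values = [me.jukes_cantor(p) for p in grid]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestCodonAlign:
    def test_identical_pair(self):
        pairs = me.codon_align(("MK", "MK"), "ATGAAA", "ATGAAA")
        assert pairs == [("ATG", "ATG"), ("AAA", "AAA")]

    def test_gap_column_dropped(self):
        pairs = me.codon_align(("MK-", "MKV"), "ATGAAA", "ATGAAAGTT")
        assert pairs == [("ATG", "ATG"), ("AAA", "AAA")]

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            me.codon_align(("M", "M"), "ATGA", "ATG")

    def test_translation_mismatch_names_position(self):
        with pytest.raises(ValueError, match="codon 1"):
            me.codon_align(("MK", "MK"), "ATGGGG", "ATGAAA")

    def test_codon_with_n_dropped(self):
        pairs = me.codon_align(("MK", "MK"), "ATGAAN", "ATGAAA")
        assert pairs == [("ATG", "ATG")]


class TestDivergenceTime:
    def test_zero_ks(self):
        assert me.divergence_time(0.0).T_mya == 0.0

    def test_printed_clock_rate_arithmetic(self):
        # 0.13 / (2 * 6.5e-9) = 1e7 years = 10 mya
        assert me.divergence_time(0.13, 6.5e-9).T_mya == pytest.approx(10.0)

    def test_linearity(self):
        t1 = me.divergence_time(0.1, 6.5e-9).T_mya
        t2 = me.divergence_time(0.2, 6.5e-9).T_mya
        assert t2 == pytest.approx(2 * t1)

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            me.divergence_time(-0.1)

    def test_arabidopsis_rate_differs(self):
        assert me.CLOCK_RATES["A.thaliana"] == 1.5e-8
        assert me.CLOCK_RATES["P.edulis"] == 6.5e-9
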