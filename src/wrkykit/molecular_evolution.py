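"""Nei-Gojobori Ka/Ks estimation and molecular-clock dating of duplications.

Synonymous/nonsynonymous site counting follows the classic equal-weight
pathway method: per-codon site fractions from the standard genetic code,
multi-difference codons averaged over all shortest substitution pathways
(paths through stop codons excluded), and Jukes-Cantor correction of the
proportions. Divergence times use T = Ks / (2 * lambda).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import log
from typing import Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"

#: clock-like synonymous substitution rates (substitutions/synonymous site/year)
CLOCK_RATES = {
    "P.edulis": 6.5e-9,
    "O.sativa": 6.5e-9,
    "B.distachyon": 6.5e-9,
    "A.thaliana": 1.5e-8,
}
DEFAULT_CLOCK_RATE = 6.5e-9

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)


def translate_codon(codon: str) -> Optional[str]:
    """Amino acid for a codon, ``None`` for a stop codon."""
    codon = codon.upper()
    if codon in _STOP_CODONS:
        return None
    return _CODON_TABLE[codon]


@dataclass(frozen=True)
class KaKsResult:
    S: float
    N: float
    sd: float
    nd: float
    pS: float
    pN: float
    Ks: Optional[float]
    Ka: Optional[float]
    estimator: str = "Nei-Gojobori (1986)"

    @property
    def saturated(self) -> bool:
        return self.Ks is None or self.Ka is None


@dataclass(frozen=True)
class DuplicationDate:
    Ks: float
    clock_rate: float
    T_mya: float


# ---------------------------------------------------------------------------
# Codon-level alignment


def codon_align(
    protein_alignment: tuple[str, str], cds_a: str, cds_b: str
) -> list[tuple[str, str]]:
    """Back-translate a protein alignment into paired codon columns.

    Gap columns are dropped, as are codon pairs containing N. The CDS must
    translate to its ungapped protein row (stop codon excluded).
    """
    row_a, row_b = (r.upper() for r in protein_alignment)
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    for label, cds, row in (("a", cds_a, row_a), ("b", cds_b, row_b)):
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS {label}: length {len(cds)} is not a multiple of 3")
        protein = row.replace("-", "")
        if len(cds) != 3 * len(protein):
            raise ValueError(
                f"CDS {label}: {len(cds) // 3} codons for {len(protein)} aligned residues"
            )
        for idx, residue in enumerate(protein):
            codon = cds[3 * idx : 3 * idx + 3]
            if "N" in codon:
                continue
            aa = translate_codon(codon)
            if aa is None:
                raise ValueError(f"CDS {label}: in-frame stop codon at codon {idx}")
            if aa != residue and residue != "X":
                raise ValueError(
                    f"CDS {label}: codon {idx} ({codon}) translates to {aa}, "
                    f"protein has {residue}"
                )

    pairs: list[tuple[str, str]] = []
    ia = ib = 0
    for col_a, col_b in zip(row_a, row_b):
        codon_a = cds_a[3 * ia : 3 * ia + 3] if col_a != "-" else None
        codon_b = cds_b[3 * ib : 3 * ib + 3] if col_b != "-" else None
        if col_a != "-":
            ia += 1
        if col_b != "-":
            ib += 1
        if codon_a is None or codon_b is None:
            continue
        if "N" in codon_a or "N" in codon_b:
            continue
        pairs.append((codon_a, codon_b))
    return pairs


# ---------------------------------------------------------------------------
# Nei-Gojobori


def synonymous_site_fraction(codon: str) -> float:
    """Synonymous sites of one codon (0..3).

    Each position contributes the fraction of its three single-nucleotide
    changes that preserve the amino acid; changes to stop codons count as
    nonsynonymous.
    """
    codon = codon.upper()
    aa = translate_codon(codon)
    if aa is None:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    total = 0.0
    for pos in range(3):
        syn = 0
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if translate_codon(mutant) == aa:
                syn += 1
        total += syn / 3.0
    return total


def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences over shortest pathways.

    All orderings of the differing positions are enumerated; pathways that
    pass through a stop codon are excluded (falling back to all pathways if
    every one is blocked).
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: Sequence[int]) -> Optional[tuple[int, int]]:
        current = codon_a
        syn = non = 0
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            aa_from, aa_to = translate_codon(current), translate_codon(nxt)
            if aa_to is None:
                return None
            if aa_from == aa_to:
                syn += 1
            else:
                non += 1
            current = nxt
        return syn, non

    results = [walk(order) for order in permutations(diff_positions)]
    valid = [r for r in results if r is not None]
    if not valid:
        # every pathway passes a stop; count steps through stops as nonsynonymous
        valid = []
        for order in permutations(diff_positions):
            current = codon_a
            syn = non = 0
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
                if (
                    translate_codon(nxt) is not None
                    and translate_codon(current) == translate_codon(nxt)
                ):
                    syn += 1
                else:
                    non += 1
                current = nxt
            valid.append((syn, non))
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> Optional[float]:
    """JC distance -(3/4) ln(1 - 4p/3); ``None`` when p >= 3/4 (saturated)."""
    if p < 0:
        raise ValueError("proportion of differences must be >= 0")
    if p >= 0.75:
        return None
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def nei_gojobori(codon_pairs: Sequence[tuple[str, str]]) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks over paired codon columns."""
    if not codon_pairs:
        raise ValueError("nei_gojobori needs at least one codon pair")
    s_a = s_b = 0.0
    sd = nd = 0.0
    for codon_a, codon_b in codon_pairs:
        codon_a, codon_b = codon_a.upper(), codon_b.upper()
        if translate_codon(codon_a) is None or translate_codon(codon_b) is None:
            raise ValueError(f"stop codon in pair ({codon_a}, {codon_b})")
        s_a += synonymous_site_fraction(codon_a)
        s_b += synonymous_site_fraction(codon_b)
        d_s, d_n = _pathway_differences(codon_a, codon_b)
        sd += d_s
        nd += d_n
    n_codons = len(codon_pairs)
    S = (s_a + s_b) / 2.0
    N = 3.0 * n_codons - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    return KaKsResult(
        S=S, N=N, sd=sd, nd=nd, pS=pS, pN=pN, Ks=jukes_cantor(pS), Ka=jukes_cantor(pN)
    )


def divergence_time(ks: float, clock_rate: float = DEFAULT_CLOCK_RATE) -> DuplicationDate:
    """Date a duplication from synonymous divergence: T = Ks / (2 * lambda), in mya."""
    if ks < 0:
        raise ValueError("Ks must be >= 0")
    if clock_rate <= 0:
        raise ValueError("clock rate must be > 0")
    t_years = ks / (2.0 * clock_rate)
    return DuplicationDate(Ks=ks, clock_rate=clock_rate, T_mya=t_years / 1e6)
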