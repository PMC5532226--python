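"""Detection of WRKY heptapeptides and their downstream zinc-finger motifs.

A WRKY domain is a (near-)WRKYGQK heptapeptide followed by a zinc finger of
the form C-X(m)-C-X(n)-H-X-H (C2H2) or C-X(m)-C-X(n)-H-X-C (C2HC). The
scanner reports each heptapeptide hit, the first plausible zinc finger
downstream of it, and the spacer lengths m and n.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .io_gene_models import PROTEIN_ALPHABET, SequenceRecord

CANONICAL_HEPTAPEPTIDE = "WRKYGQK"

#: default spacer search ranges (m_min, m_max, n_min, n_max)
DEFAULT_RANGES = (4, 8, 20, 40)
#: extended n_max / window catch unusually long second spacers
EXTENDED_RANGES = (4, 8, 20, 120)
DEFAULT_WINDOW = 150
EXTENDED_WINDOW = 250
DEFAULT_MAX_MISMATCH = 2


@dataclass(frozen=True)
class HeptapeptideHit:
    position: int  # 0-based start in the protein
    sequence: str
    hamming: int


@dataclass(frozen=True)
class ZincFinger:
    zf_type: str  # C2H2 | C2HC
    m: int
    n: int
    positions: tuple[int, int, int, int]  # C, C, H, H/C (0-based)


@dataclass(frozen=True)
class WRKYDomain:
    heptapeptide: HeptapeptideHit
    zinc_finger: Optional[ZincFinger]
    terminal: str = "only"  # N | C | only

    @property
    def complete(self) -> bool:
        return self.zinc_finger is not None

    @property
    def end(self) -> int:
        """One past the last residue covered by the domain."""
        if self.zinc_finger is not None:
            return self.zinc_finger.positions[-1] + 1
        return self.heptapeptide.position + 7


@dataclass(frozen=True)
class ScanConfig:
    max_mismatch: int = DEFAULT_MAX_MISMATCH
    ranges: tuple[int, int, int, int] = DEFAULT_RANGES
    window: int = DEFAULT_WINDOW

    @classmethod
    def extended(cls, max_mismatch: int = DEFAULT_MAX_MISMATCH) -> "ScanConfig":
        return cls(max_mismatch=max_mismatch, ranges=EXTENDED_RANGES, window=EXTENDED_WINDOW)


@dataclass(frozen=True)
class PhyschemResult:
    pI: float
    mw: float


def _check_protein(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"residues {sorted(bad)} outside the protein alphabet")
    return seq


def _hamming7(window: str, target: str = CANONICAL_HEPTAPEPTIDE) -> int:
    return sum(1 for a, b in zip(window, target) if a != b)


def find_heptapeptides(seq: str, max_mismatch: int = DEFAULT_MAX_MISMATCH) -> list[HeptapeptideHit]:
    """All non-overlapping 7-mers within ``max_mismatch`` of WRKYGQK.

    Overlapping candidates are resolved by keeping the lower-distance hit,
    ties going to the leftmost; the result is ordered left to right.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    seq = _check_protein(seq)
    candidates = [
        HeptapeptideHit(position=i, sequence=seq[i : i + 7], hamming=_hamming7(seq[i : i + 7]))
        for i in range(len(seq) - 6)
    ]
    candidates = [c for c in candidates if c.hamming <= max_mismatch]
    selected: list[HeptapeptideHit] = []
    for cand in sorted(candidates, key=lambda c: (c.hamming, c.position)):
        if all(abs(cand.position - kept.position) >= 7 for kept in selected):
            selected.append(cand)
    return sorted(selected, key=lambda c: c.position)


def find_zinc_finger(
    seq: str,
    start: int,
    ranges: tuple[int, int, int, int] = DEFAULT_RANGES,
    window: int = DEFAULT_WINDOW,
) -> Optional[ZincFinger]:
    """First zinc finger C-X(m)-C-X(n)-H-X-[HC] at or after ``start``.

    "First" minimizes the first-Cys position, then m, then n — a unique,
    reproducible parse. The first Cys must fall within ``window`` residues of
    ``start``. Returns ``None`` when no match exists.
    """
    seq = _check_protein(seq)
    if start < 0 or start > len(seq):
        raise ValueError(f"start {start} outside sequence of length {len(seq)}")
    m_min, m_max, n_min, n_max = ranges
    limit = min(len(seq), start + window)
    for c1 in range(start, limit):
        if seq[c1] != "C":
            continue
        for m in range(m_min, m_max + 1):
            c2 = c1 + 1 + m
            if c2 >= len(seq) or seq[c2] != "C":
                continue
            for n in range(n_min, n_max + 1):
                h1 = c2 + 1 + n
                last = h1 + 2
                if last >= len(seq):
                    break
                if seq[h1] == "H" and seq[last] in "HC":
                    zf_type = "C2H2" if seq[last] == "H" else "C2HC"
                    return ZincFinger(zf_type=zf_type, m=m, n=n, positions=(c1, c2, h1, last))
    return None


def scan_protein(record: SequenceRecord, config: ScanConfig = ScanConfig()) -> list[WRKYDomain]:
    """Scan one protein for WRKY domains.

    Heptapeptide hits are paired greedily left to right with the first zinc
    finger downstream of each; a hit falling inside an already-claimed domain
    is dropped. Terminal labels: ``only`` for a lone domain, else ``N`` for
    the first and ``C`` for the rest.
    """
    if record.moltype != "protein":
        raise ValueError(f"{record.id}: scan_protein needs a protein record")
    seq = record.seq.upper()
    hits = find_heptapeptides(seq, config.max_mismatch)
    domains: list[WRKYDomain] = []
    cursor = 0
    for hit in hits:
        if hit.position < cursor:
            continue
        zf = find_zinc_finger(seq, hit.position + 7, config.ranges, config.window)
        domain = WRKYDomain(heptapeptide=hit, zinc_finger=zf)
        domains.append(domain)
        cursor = domain.end
    if len(domains) == 1:
        domains = [replace(domains[0], terminal="only")]
    else:
        domains = [
            replace(d, terminal="N" if i == 0 else "C") for i, d in enumerate(domains)
        ]
    return domains


# ---------------------------------------------------------------------------
# Physicochemical properties

# average residue masses (Da), monomer masses minus one water
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER_MASS = 18.01524

# EMBOSS pKa values
_PKA_POSITIVE = {"nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
_PKA_NEGATIVE = {"cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


def _net_charge(composition: dict[str, int], ph: float) -> float:
    charge = 1.0 / (1.0 + 10 ** (ph - _PKA_POSITIVE["nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (_PKA_NEGATIVE["cterm"] - ph))
    for res, pka in _PKA_POSITIVE.items():
        if res != "nterm":
            charge += composition.get(res, 0) / (1.0 + 10 ** (ph - pka))
    for res, pka in _PKA_NEGATIVE.items():
        if res != "cterm":
            charge -= composition.get(res, 0) / (1.0 + 10 ** (pka - ph))
    return charge


def compute_physchem(record: SequenceRecord) -> PhyschemResult:
    """Molecular weight (average masses + one water) and isoelectric point.

    The pI is located by bisection on the Henderson–Hasselbalch net charge to
    |charge| < 1e-4. Ambiguous residues (X) are rejected.
    """
    seq = record.seq.upper()
    if "X" in seq:
        raise ValueError(f"{record.id}: ambiguous residue X not supported")
    _check_protein(seq)
    mw = sum(_RESIDUE_MASS[res] for res in seq) + _WATER_MASS
    composition = {res: seq.count(res) for res in set(seq)}
    lo, hi = 0.0, 14.0
    charge = _net_charge(composition, (lo + hi) / 2)
    for _ in range(200):
        mid = (lo + hi) / 2
        charge = _net_charge(composition, mid)
        if abs(charge) < 1e-4:
            break
        if charge > 0:
            lo = mid
        else:
            hi = mid
    return PhyschemResult(pI=(lo + hi) / 2, mw=mw)
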