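"""Seeded generators for WRKY-like proteins, diverged CDS pairs, and
expression matrices with planted structure.

Every generator is a pure function of its parameters and seed and returns a
truth object recording exactly what was planted, so downstream stages can be
tested for recovery without any external data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .domain_scanner import CANONICAL_HEPTAPEPTIDE, _hamming7
from .io_gene_models import SequenceRecord
from .molecular_evolution import (
    _CODON_TABLE,
    synonymous_site_fraction,
    translate_codon,
)

#: heptapeptide variants observed in real WRKY families
HEPTAPEPTIDE_VARIANTS = ("WRKYGKK", "WRKYGEK", "WKKYGQK", "CRKYGQA", "WRKYGQQ", "WRKFGQK")

#: flank/spacer residues exclude C and H so planted zinc fingers stay unique
_FILLER_ALPHABET = "ADEFGIKLMNPQRSTVWY"

_GROUPS = ("group1", "group2a", "group2b", "group2c", "group2d", "group2e", "group3")

_BACK_TABLE: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON_TABLE.items()):
    _BACK_TABLE.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class PlantedDomain:
    heptapeptide: str
    zf_type: Optional[str]  # None -> no zinc finger planted
    m: Optional[int]
    n: Optional[int]
    position: int  # 0-based heptapeptide start in the protein


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    group: str
    incomplete_cterm: bool
    domains: tuple[PlantedDomain, ...]


@dataclass(frozen=True)
class FamilyTruth:
    seed: int
    genes: tuple[PlantedGene, ...]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class PairTruth:
    seed: int
    target_ks: float
    synonymous_sites: float
    n_events: int
    substitutions: tuple[tuple[int, int, str, str], ...]  # (codon, pos, from, to)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class ExpressionTruth:
    seed: int
    de_genes: tuple[str, ...]
    fold_change: float
    modules: tuple[tuple[str, ...], ...]
    module_r: float
    control_samples: tuple[str, ...]
    treated_samples: tuple[str, ...]
    dispersion: float = 0.1

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# Protein family generator


def _filler(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_FILLER_ALPHABET), size=length))


def _zinc_finger_seq(rng: np.random.Generator, zf_type: str, m: int, n: int) -> str:
    last = "H" if zf_type == "C2H2" else "C"
    return "C" + _filler(rng, m) + "C" + _filler(rng, n) + "H" + _filler(rng, 1) + last


def _pick_heptapeptide(rng: np.random.Generator, variant_rate: float) -> str:
    if rng.random() < variant_rate:
        return str(rng.choice(HEPTAPEPTIDE_VARIANTS))
    return CANONICAL_HEPTAPEPTIDE


def _domain_spec(rng: np.random.Generator, group: str) -> tuple[str, int, int]:
    """(zf_type, m, n) typical of the group."""
    if group == "group3":
        return "C2HC", int(rng.integers(6, 8)), int(rng.integers(23, 31))
    m = int(rng.integers(4, 6))
    return "C2H2", m, int(rng.integers(22, 25))


def _unexpected_heptapeptide(seq: str, planted: set[int], max_mismatch: int = 2) -> bool:
    for i in range(len(seq) - 6):
        if i in planted:
            continue
        if _hamming7(seq[i : i + 7]) <= max_mismatch:
            return True
    return False


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Random back-translation under the standard genetic code."""
    codons = []
    for residue in protein:
        options = _BACK_TABLE.get(residue)
        if options is None:
            raise ValueError(f"cannot back-translate residue {residue!r}")
        codons.append(str(rng.choice(options)))
    return "".join(codons)


def make_family(
    n_genes: int,
    group_mix: dict[str, float],
    variant_rate: float = 0.0,
    seed: int = 0,
    incomplete_rate: float = 0.0,
) -> tuple[list[SequenceRecord], list[SequenceRecord], FamilyTruth]:
    """Generate a synthetic WRKY-like family with known planted structure.

    ``group_mix`` maps group labels to proportions summing to 1. Group-1
    genes get two domains (optionally an incomplete C-terminal one at
    ``incomplete_rate``), group 2 a single C2H2 domain, group 3 a single
    C2HC domain. Flanks are rejection-sampled so no unplanted 7-mer falls
    within Hamming distance 2 of WRKYGQK.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for group, fraction in group_mix.items():
        if group not in _GROUPS:
            raise ValueError(f"unknown group {group!r} in mix")
        if fraction < 0:
            raise ValueError(f"negative proportion for {group!r}")
    total = sum(group_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"group_mix proportions sum to {total}, expected 1")
    if not 0.0 <= variant_rate <= 1.0:
        raise ValueError("variant_rate must be in [0, 1]")

    rng = np.random.default_rng(seed)
    groups = sorted(group_mix)
    probs = np.array([group_mix[g] for g in groups])

    proteins: list[SequenceRecord] = []
    cds: list[SequenceRecord] = []
    planted_genes: list[PlantedGene] = []
    for idx in range(n_genes):
        gene_id = f"syn{idx + 1:04d}"
        group = str(rng.choice(groups, p=probs))
        for _ in range(100):
            parts: list[str] = [_filler(rng, int(rng.integers(20, 41)))]
            planted_positions: set[int] = set()
            domains: list[PlantedDomain] = []
            n_domains = 2 if group == "group1" else 1
            incomplete = group == "group1" and rng.random() < incomplete_rate
            for dom_idx in range(n_domains):
                hepta = _pick_heptapeptide(rng, variant_rate)
                position = sum(len(p) for p in parts)
                planted_positions.add(position)
                parts.append(hepta)
                parts.append(_filler(rng, int(rng.integers(5, 16))))
                if incomplete and dom_idx == n_domains - 1:
                    domains.append(PlantedDomain(hepta, None, None, None, position))
                else:
                    zf_type, m, n = _domain_spec(rng, group)
                    parts.append(_zinc_finger_seq(rng, zf_type, m, n))
                    domains.append(PlantedDomain(hepta, zf_type, m, n, position))
                parts.append(_filler(rng, int(rng.integers(15, 31))))
            seq = "".join(parts)
            if not _unexpected_heptapeptide(seq, planted_positions):
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError(f"could not sample clean flanks for {gene_id}")
        proteins.append(SequenceRecord(id=gene_id, seq=seq, moltype="protein"))
        cds.append(
            SequenceRecord(id=gene_id, seq=back_translate(seq, rng), moltype="dna")
        )
        planted_genes.append(
            PlantedGene(
                gene_id=gene_id,
                group=group,
                incomplete_cterm=incomplete,
                domains=tuple(domains),
            )
        )
    return proteins, cds, FamilyTruth(seed=seed, genes=tuple(planted_genes))


# ---------------------------------------------------------------------------
# Diverged CDS pairs


def evolve_pair(
    cds: str, target_ks: float, seed: int = 0
) -> tuple[str, str, PairTruth]:
    """Diverge a CDS from itself by synonymous substitutions to a target Ks.

    ``target_ks * S`` substitution events (S = Nei-Gojobori synonymous sites,
    fractional part resolved by stochastic rounding so the expectation is
    exact) are applied to one copy by rejection sampling: random single-base
    changes are drawn and kept only when they preserve the amino acid.
    """
    cds = cds.upper()
    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i, codon in enumerate(codons):
        if translate_codon(codon) is None:
            raise ValueError(f"in-frame stop codon at codon {i}")
    s_sites = sum(synonymous_site_fraction(c) for c in codons)
    if target_ks > 0 and s_sites == 0:
        raise ValueError("CDS has no synonymous sites; target Ks unreachable")

    rng = np.random.default_rng(seed)
    expected = target_ks * s_sites
    n_events = int(expected) + int(rng.random() < expected - int(expected))
    mutated = codons.copy()
    log: list[tuple[int, int, str, str]] = []
    attempts = 0
    applied = 0
    while applied < n_events:
        attempts += 1
        if attempts > 1000 * max(n_events, 1):
            raise ValueError("target Ks unreachable for this CDS")
        ci = int(rng.integers(len(mutated)))
        pos = int(rng.integers(3))
        alt = "ACGT"[int(rng.integers(4))]
        codon = mutated[ci]
        if alt == codon[pos]:
            continue
        candidate = codon[:pos] + alt + codon[pos + 1 :]
        if translate_codon(candidate) != translate_codon(codon):
            continue
        mutated[ci] = candidate
        log.append((ci, pos, codon[pos], alt))
        applied += 1
    truth = PairTruth(
        seed=seed,
        target_ks=target_ks,
        synonymous_sites=s_sites,
        n_events=n_events,
        substitutions=tuple(log),
    )
    return cds, "".join(mutated), truth


# ---------------------------------------------------------------------------
# Expression matrices


def make_expression(
    n_genes: int,
    n_samples: int,
    n_de: int = 0,
    fc: float = 1.0,
    n_modules: int = 0,
    module_size: int = 10,
    module_r: float = 1.0,
    seed: int = 0,
    dispersion: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, ExpressionTruth]:
    """Expression matrix with planted DE genes and correlated modules.

    Returns (matrix, sample metadata, truth). Baseline counts are negative
    binomial; the first ``n_de`` genes are scaled by ``fc`` in the treated
    group; the next ``n_modules * module_size`` genes share per-module latent
    factors giving within-module correlation ~= ``module_r`` (exact scaling
    at ``module_r`` = 1).
    """
    if n_genes < 1 or n_samples < 2:
        raise ValueError("need n_genes >= 1 and n_samples >= 2")
    if n_de < 0 or n_de > n_genes:
        raise ValueError("n_de must be in [0, n_genes]")
    if not 0.0 <= module_r <= 1.0:
        raise ValueError("module_r must be in [0, 1]")
    if n_de + n_modules * module_size > n_genes:
        raise ValueError("planted DE genes and modules exceed n_genes")
    if fc <= 0:
        raise ValueError("fold change must be > 0")

    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    n_control = n_samples // 2
    samples = [f"s{i + 1:03d}" for i in range(n_samples)]
    control, treated = samples[:n_control], samples[n_control:]

    base_mean = 2.0 ** rng.uniform(3, 9, size=n_genes)
    r_nb = 1.0 / dispersion

    def nb(mu: np.ndarray) -> np.ndarray:
        return rng.negative_binomial(r_nb, r_nb / (r_nb + mu)).astype(float)

    mat = np.zeros((n_genes, n_samples))
    for gi in range(n_genes):
        mu = np.full(n_samples, base_mean[gi])
        if gi < n_de and fc != 1.0:
            mu[n_control:] *= fc
        mat[gi] = nb(mu)

    module_start = n_de
    modules: list[tuple[str, ...]] = []
    for mk in range(n_modules):
        lo = module_start + mk * module_size
        members = genes[lo : lo + module_size]
        modules.append(tuple(members))
        latent = rng.normal(size=n_samples)
        for offset, gene in enumerate(members):
            gi = lo + offset
            noise = rng.normal(size=n_samples)
            z = np.sqrt(module_r) * latent + np.sqrt(1.0 - module_r) * noise
            mat[gi] = base_mean[gi] * 2.0**z

    matrix = pd.DataFrame(mat, index=genes, columns=samples)
    meta = pd.DataFrame(
        {
            "sample": samples,
            "condition": ["control"] * n_control + ["treated"] * (n_samples - n_control),
        }
    ).set_index("sample")
    truth = ExpressionTruth(
        seed=seed,
        de_genes=tuple(genes[:n_de]),
        fold_change=fc,
        modules=tuple(modules),
        module_r=module_r,
        control_samples=tuple(control),
        treated_samples=tuple(treated),
        dispersion=dispersion,
    )
    return matrix, meta, truth
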