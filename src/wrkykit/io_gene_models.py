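"""Readers/writers for the formats the pipeline touches plus gene-structure math.

Covers FASTA sequence records, GFF3 gene models with intron-phase derivation,
the bundled WRKY family annotation table, and Newick serialization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import SeqIO

from ._tree import PhyloNode

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = set("ACGTN")

GROUP_LABELS = (
    "group1",
    "group2a",
    "group2b",
    "group2c",
    "group2d",
    "group2e",
    "group3",
    "unclassified",
)

_FAMILY_TABLE_RESOURCE = "phe_wrky_family.tsv"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein or DNA sequence."""

    id: str
    seq: str
    moltype: str = "protein"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        alphabet = PROTEIN_ALPHABET if self.moltype == "protein" else DNA_ALPHABET
        bad = set(self.seq.upper()) - alphabet
        if bad:
            raise ValueError(
                f"record {self.id!r}: residues {sorted(bad)} outside the "
                f"{self.moltype} alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one gene, 1-based inclusive GFF coordinates."""

    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model needs >=1 exon")
        for start, end in self.exons:
            if start > end or start < 1:
                raise ValueError(f"{self.gene_id}: bad exon interval ({start}, {end})")
        ordered = sorted(self.exons)
        for (_, e1), (s2, _) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if sum(e - s + 1 for s, e in self.exons) < 3:
            raise ValueError(f"{self.gene_id}: total exonic length < 3")

    @property
    def exons_transcription_order(self) -> tuple[tuple[int, int], ...]:
        ordered = tuple(sorted(self.exons))
        return ordered if self.strand == "+" else tuple(reversed(ordered))

    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.exons_transcription_order)


@dataclass(frozen=True)
class FamilyTableRow:
    """One gene row of the family annotation table.

    ``heptapeptides`` holds one slot per annotated WRKY domain (``None`` for a
    printed absent value); ``zf_types``/``m``/``n`` are parallel per-domain
    slots with ``None`` where the table prints no zinc finger.
    """

    gene_id: str
    group_label: str
    heptapeptides: tuple[Optional[str], ...]
    zf_types: tuple[Optional[str], ...]
    m: tuple[Optional[int], ...]
    n: tuple[Optional[int], ...]
    incomplete_flag: bool = False
    verbatim: tuple[str, ...] = field(default=(), compare=False)

    @property
    def n_domains(self) -> int:
        return len(self.heptapeptides)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: Union[str, Path], moltype: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, order preserved.

    Record ids are the first whitespace token of each header. Duplicate ids,
    an empty file, or sequence data before the first header raise
    :class:`FormatError` naming the offending line or id.
    """
    path = Path(path)
    with open(path) as handle:
        first_content = None
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                first_content = (lineno, line)
                break
        if first_content is None:
            raise FormatError(f"{path}: empty FASTA file")
        lineno, line = first_content
        if not line.startswith(">"):
            raise FormatError(f"{path}: line {lineno}: expected FASTA header, got {line.strip()!r}")

    records = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen[rec.id] = 1
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(id=rec.id, seq=seq, moltype=moltype))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path], width: int = 60) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Family annotation table


def _parse_slots(raw: str) -> list[Optional[str]]:
    if raw == "/":
        return [None]
    return [tok if tok != "" else None for tok in raw.split("/")]


def read_family_table(path: Union[str, Path]) -> list[FamilyTableRow]:
    """Parse the family annotation TSV into :class:`FamilyTableRow` objects.

    Column layout: gene_id, group, heptapeptide, zf_type, m, n. ``/`` denotes
    an absent value; a trailing ``*`` on the gene id flags group-1 members
    whose C-terminal domain lacks the zinc finger; two-domain rows join their
    per-domain values with ``/``.
    """
    path = Path(path)
    rows: list[FamilyTableRow] = []
    seen: set[str] = set()
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        expected = ["gene_id", "group", "heptapeptide", "zf_type", "m", "n"]
        if header != expected:
            raise FormatError(f"{path}: expected columns {expected}, got {header}")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise FormatError(f"{path}: line {lineno}: expected 6 columns")
            raw_id, raw_group, raw_hepta, raw_zf, raw_m, raw_n = fields
            incomplete = raw_id.endswith("*")
            gene_id = raw_id.rstrip("*")
            if gene_id in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)

            group = "unclassified" if raw_group == "/" else raw_group
            if group not in GROUP_LABELS:
                raise FormatError(f"{path}: line {lineno}: unknown group label {raw_group!r}")

            heptas = _parse_slots(raw_hepta)
            for h in heptas:
                if h is not None and (len(h) != 7 or not re.fullmatch(r"[A-Z]{7}", h)):
                    raise FormatError(
                        f"{path}: line {lineno}: heptapeptide {h!r} is not a 7-residue string"
                    )

            n_dom = len(heptas)

            def per_domain_int(raw: str, colname: str) -> list[Optional[int]]:
                slots = _parse_slots(raw)
                out: list[Optional[int]] = []
                for tok in slots:
                    if tok is None:
                        out.append(None)
                    else:
                        try:
                            out.append(int(tok))
                        except ValueError:
                            raise FormatError(
                                f"{path}: line {lineno}: non-integer {colname} value {tok!r}"
                            ) from None
                return out

            zf_slots = _parse_slots(raw_zf)
            m_slots = per_domain_int(raw_m, "m")
            n_slots = per_domain_int(raw_n, "n")

            # the printed table repeats a single zinc-finger column for
            # two-domain rows; broadcast it across domains, except where the
            # incomplete flag says the second domain has no zinc finger.
            if n_dom > 1 and len(zf_slots) == 1 and zf_slots[0] is not None:
                if incomplete:
                    zf_slots = [zf_slots[0]] + [None] * (n_dom - 1)
                    m_slots = m_slots + [None] * (n_dom - len(m_slots))
                    n_slots = n_slots + [None] * (n_dom - len(n_slots))
                else:
                    zf_slots = [zf_slots[0]] * n_dom
            for name, slots in (("zf_type", zf_slots), ("m", m_slots), ("n", n_slots)):
                if len(slots) != n_dom:
                    raise FormatError(
                        f"{path}: line {lineno}: {name} has {len(slots)} slots "
                        f"for {n_dom} domains"
                    )
            for zf in zf_slots:
                if zf is not None and zf not in {"C2H2", "C2HC"}:
                    raise FormatError(f"{path}: line {lineno}: unknown zinc-finger type {zf!r}")
            for m_val, n_val, zf in zip(m_slots, n_slots, zf_slots):
                if zf is not None and (m_val is None or n_val is None or m_val < 0 or n_val < 0):
                    raise FormatError(
                        f"{path}: line {lineno}: zinc finger present but m/n missing or negative"
                    )

            rows.append(
                FamilyTableRow(
                    gene_id=gene_id,
                    group_label=group,
                    heptapeptides=tuple(heptas),
                    zf_types=tuple(zf_slots),
                    m=tuple(m_slots),
                    n=tuple(n_slots),
                    incomplete_flag=incomplete,
                    verbatim=tuple(fields),
                )
            )
    if not rows:
        raise FormatError(f"{path}: table contains no data rows")
    return rows


def bundled_family_table_path() -> Path:
    """Path of the family annotation table shipped with the package."""
    return Path(resources.files("wrkykit.data") / _FAMILY_TABLE_RESOURCE)


def load_family_table() -> list[FamilyTableRow]:
    return read_family_table(bundled_family_table_path())


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gff3_gene_models(path: Union[str, Path], feature: str = "CDS") -> list[GeneModel]:
    """Collect per-gene exon intervals from the given GFF3 feature type.

    Features are grouped by their ``Parent`` attribute (falling back to
    ``ID``); intervals are stored 1-based inclusive as printed.
    """
    path = Path(path)
    by_gene: dict[str, dict] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            _, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != feature:
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            gene_id = attr_map.get("Parent", attr_map.get("ID"))
            if gene_id is None:
                raise FormatError(f"{path}: line {lineno}: feature lacks Parent/ID attribute")
            entry = by_gene.setdefault(gene_id, {"strand": strand, "exons": []})
            if entry["strand"] != strand:
                raise FormatError(f"{path}: gene {gene_id!r} mixes strands")
            entry["exons"].append((int(start), int(end)))
    return [
        GeneModel(gene_id=g, strand=v["strand"], exons=tuple(sorted(v["exons"])))
        for g, v in by_gene.items()
    ]


def intron_phases(model: GeneModel) -> list[int]:
    """Intron phases in transcription order.

    Phase of intron k is the cumulative length of exons 1..k modulo 3; a gene
    whose exon lengths do not sum to a multiple of 3 is rejected.
    """
    lengths = model.exon_lengths()
    if sum(lengths) % 3 != 0:
        raise ValueError(
            f"{model.gene_id}: CDS length {sum(lengths)} is not a multiple of 3"
        )
    phases = []
    cumulative = 0
    for length in lengths[:-1]:
        cumulative += length
        phases.append(cumulative % 3)
    return phases


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: PhyloNode) -> str:
    """Serialize a tree to a Newick string with branch lengths."""

    def fmt(node: PhyloNode, seen: set[int]) -> str:
        if id(node) in seen:
            raise ValueError("cyclic tree structure")
        seen.add(id(node))
        if node.is_leaf:
            label = node.name or ""
        else:
            inner = ",".join(fmt(c, seen) for c in node.children)
            label = f"({inner})" + (node.name or "")
        if node.length is not None:
            label += f":{node.length:.10g}"
        return label

    return fmt(tree, set()) + ";"


def read_newick(text: str) -> PhyloNode:
    """Parse a Newick string (names and branch lengths, no comments)."""
    text = text.strip()
    if not text.endswith(";"):
        raise FormatError("Newick string must end with ';'")
    pos = 0
    s = text[:-1]

    def parse_node() -> PhyloNode:
        nonlocal pos
        node = PhyloNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add_child(parse_node())
                if pos >= len(s):
                    raise FormatError("unbalanced parentheses in Newick string")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise FormatError(f"unexpected character {s[pos]!r} in Newick string")
        match = re.match(r"[^,():;]*", s[pos:])
        label = match.group(0)
        pos += len(label)
        if label:
            node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            match = re.match(r"[^,():;]+", s[pos:])
            if match is None:
                raise FormatError("missing branch length after ':'")
            node.length = float(match.group(0))
            pos += len(match.group(0))
        return node

    root = parse_node()
    if pos != len(s):
        raise FormatError("trailing characters in Newick string")
    return root
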