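"""WRKY group assignment (1, 2a-2e, 3, unclassified) and family summaries.

Two classification paths are supported: the *rule* path derives the group
from domain structure (domain count + zinc-finger type), and the *label*
path tallies annotation-table group labels as printed. The two can disagree
on rows whose printed label conflicts with their zinc-finger annotation;
both are reported rather than reconciled.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .domain_scanner import CANONICAL_HEPTAPEPTIDE, WRKYDomain
from .io_gene_models import FamilyTableRow

GROUP2_SUBGROUPS = ("group2a", "group2b", "group2c", "group2d", "group2e")


@dataclass(frozen=True)
class FamilyAssignment:
    """Group call for one gene.

    ``group`` may be the generic ``group2`` when the rule path identifies a
    single-C2H2-domain gene but no subgroup evidence is available.
    """

    gene_id: str
    group: str
    incomplete_cterm: bool = False
    two_domain_c2hc_override: bool = False
    heptapeptides: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class FamilySummary:
    counts: dict[str, int]
    variant_domains: int
    incomplete_group1: int
    total: int


def _domain_descriptors(row: FamilyTableRow) -> list[tuple[Optional[str], Optional[str]]]:
    """(heptapeptide, zf_type) per annotated domain slot of a table row."""
    return list(zip(row.heptapeptides, row.zf_types))


def assign_group(
    gene_id: str,
    domains: Sequence[tuple[Optional[str], Optional[str]]],
    subgroup_hint: Optional[str] = None,
) -> FamilyAssignment:
    """Assign the main WRKY group from (heptapeptide, zf_type) descriptors.

    Priority: two or more heptapeptides with at least one complete domain ->
    group 1 (flagging a C2HC zinc finger and a zinc-finger-less second
    domain); a single complete C2HC domain -> group 3; a single complete
    C2H2 domain -> group 2 (subgroup from ``subgroup_hint`` when given);
    anything else -> unclassified.
    """
    heptas = tuple(h for h, _ in domains if h is not None)
    zfs = [z for _, z in domains if z is not None]
    complete = len(zfs)

    if len(heptas) >= 2 and complete >= 1:
        has_c2hc = any(z == "C2HC" for z in zfs)
        incomplete_cterm = complete < len(domains)
        return FamilyAssignment(
            gene_id=gene_id,
            group="group1",
            incomplete_cterm=incomplete_cterm,
            two_domain_c2hc_override=has_c2hc,
            heptapeptides=heptas,
        )
    if complete == 1 and len(heptas) >= 1:
        zf = zfs[0]
        if zf == "C2HC":
            return FamilyAssignment(gene_id=gene_id, group="group3", heptapeptides=heptas)
        group = subgroup_hint if subgroup_hint in GROUP2_SUBGROUPS else "group2"
        return FamilyAssignment(gene_id=gene_id, group=group, heptapeptides=heptas)
    return FamilyAssignment(gene_id=gene_id, group="unclassified", heptapeptides=heptas)


def assignment_from_scan(
    gene_id: str, domains: Sequence[WRKYDomain], subgroup_hint: Optional[str] = None
) -> FamilyAssignment:
    """Rule-path assignment from scanner output."""
    descriptors = [
        (
            d.heptapeptide.sequence,
            d.zinc_finger.zf_type if d.zinc_finger is not None else None,
        )
        for d in domains
    ]
    return assign_group(gene_id, descriptors, subgroup_hint=subgroup_hint)


def classify_table(rows: Sequence[FamilyTableRow], mode: str = "label") -> list[FamilyAssignment]:
    """Classify annotation-table rows via the *label* or *rule* path."""
    if mode not in {"label", "rule"}:
        raise ValueError(f"unknown classification mode {mode!r}")
    assignments = []
    for row in rows:
        heptas = tuple(h for h in row.heptapeptides if h is not None)
        if mode == "label":
            assignments.append(
                FamilyAssignment(
                    gene_id=row.gene_id,
                    group=row.group_label,
                    incomplete_cterm=row.incomplete_flag,
                    two_domain_c2hc_override=(
                        row.group_label == "group1" and "C2HC" in row.zf_types
                    ),
                    heptapeptides=heptas,
                )
            )
        else:
            hint = row.group_label if row.group_label in GROUP2_SUBGROUPS else None
            assignments.append(
                assign_group(row.gene_id, _domain_descriptors(row), subgroup_hint=hint)
            )
    return assignments


def summarize_family(assignments: Sequence[FamilyAssignment]) -> FamilySummary:
    """Exact per-group tallies plus variant-domain and incomplete counts."""
    if not assignments:
        raise ValueError("summarize_family requires at least one assignment")
    ids = [a.gene_id for a in assignments]
    dupes = [g for g, k in Counter(ids).items() if k > 1]
    if dupes:
        raise ValueError(f"duplicate gene ids: {sorted(dupes)}")
    counts = Counter(a.group for a in assignments)
    variant_domains = sum(
        1
        for a in assignments
        for h in a.heptapeptides
        if h != CANONICAL_HEPTAPEPTIDE
    )
    incomplete_group1 = sum(
        1 for a in assignments if a.group == "group1" and a.incomplete_cterm
    )
    return FamilySummary(
        counts=dict(sorted(counts.items())),
        variant_domains=variant_domains,
        incomplete_group1=incomplete_group1,
        total=len(assignments),
    )


def count_variant_heptapeptides(rows: Sequence[FamilyTableRow]) -> int:
    """Number of annotated heptapeptide slots deviating from WRKYGQK."""
    return sum(
        1
        for row in rows
        for h in row.heptapeptides
        if h is not None and h != CANONICAL_HEPTAPEPTIDE
    )


def assign_subgroup(
    domain_seq: str,
    references: Sequence[tuple[str, str]],
) -> str:
    """Label a group-2 domain with the subgroup of its best-scoring reference.

    ``references`` are (subgroup label, sequence) pairs. Ties on global
    alignment score are broken by the label of the nearest leaf in a joint
    neighbour-joining tree, then lexicographically.
    """
    from .phylogeny_orthology import align_global, distance_matrix, nj_tree, tree_distances

    if not references:
        raise ValueError("assign_subgroup needs a non-empty reference set")
    for label, _ in references:
        if label not in GROUP2_SUBGROUPS:
            raise ValueError(f"unknown subgroup label {label!r}")

    scores: list[tuple[float, str, int]] = []
    for idx, (label, ref_seq) in enumerate(references):
        _, score, _ = align_global(domain_seq, ref_seq)
        scores.append((score, label, idx))
    best = max(s for s, _, _ in scores)
    tied = sorted({label for s, label, _ in scores if s == best})
    if len(tied) == 1:
        return tied[0]

    # tie: place the query in a joint NJ tree and take the nearest leaf label
    labels = ["__query__"] + [f"ref{i}" for i in range(len(references))]
    seqs = [domain_seq] + [seq for _, seq in references]
    if len(labels) >= 3:
        dm = distance_matrix(list(zip(labels, seqs)))
        tree = nj_tree(dm)
        dists = tree_distances(tree, "__query__")
        ref_label = {f"ref{i}": references[i][0] for i in range(len(references))}
        nearest = sorted(
            (dist, ref_label[leaf])
            for leaf, dist in dists.items()
            if leaf != "__query__" and ref_label[leaf] in tied
        )
        if nearest:
            best_dist = nearest[0][0]
            return min(lbl for dist, lbl in nearest if dist == best_dist)
    return tied[0]
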