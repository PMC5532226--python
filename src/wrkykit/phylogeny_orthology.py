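"""Pairwise alignment, distance matrices, neighbour joining, and BBH homology.

Global (Needleman-Wunsch) alignments with affine gaps feed identity-based
distance matrices and the NJ tree builder; local (Smith-Waterman) scores
drive bidirectional-best-hit orthologue/paralogue detection with a strict
unique-best (1:1) rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from ._tree import PhyloNode
from .io_gene_models import SequenceRecord

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    data: np.ndarray  # square, symmetric, zero diagonal

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape does not match labels")
        if np.isnan(d).any():
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class HomologyPair:
    id_a: str
    id_b: str
    species_a: str
    species_b: str
    score: float

    @property
    def relation(self) -> str:
        return "paralog" if self.species_a == self.species_b else "ortholog"


def _make_aligner(
    mode: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # a gap of length L costs gap_open + (L - 1) * gap_extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_global(
    a: str,
    b: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[tuple[str, str], float, float]:
    """Optimal global alignment with affine gaps.

    Returns the aligned strings, the substitution-matrix score, and the
    fractional identity over columns where both sequences have a residue.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner("global", matrix, gap_open, gap_extend)
    alignment = aligner.align(a.upper(), b.upper())[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    both = [(x, y) for x, y in zip(row_a, row_b) if x != "-" and y != "-"]
    identity = sum(1 for x, y in both if x == y) / len(both) if both else 0.0
    return (row_a, row_b), float(alignment.score), identity


def align_local_score(
    a: str,
    b: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Smith-Waterman local alignment score."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner("local", matrix, gap_open, gap_extend)
    return float(aligner.score(a.upper(), b.upper()))


def distance_matrix(
    sequences: Sequence[Union[SequenceRecord, tuple[str, str]]],
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> DistanceMatrix:
    """Pairwise 1 - identity distances from global alignments."""
    pairs = [
        (s.id, s.seq) if isinstance(s, SequenceRecord) else (s[0], s[1]) for s in sequences
    ]
    labels = tuple(label for label, _ in pairs)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence ids in distance matrix input")
    n = len(pairs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, identity = align_global(pairs[i][1], pairs[j][1], matrix, gap_open, gap_extend)
            d[i, j] = d[j, i] = 1.0 - identity
    return DistanceMatrix(labels=labels, data=d)


# ---------------------------------------------------------------------------
# Neighbour joining


def nj_tree(dm: DistanceMatrix) -> PhyloNode:
    """Saitou-Nei neighbour joining.

    Ties in the Q criterion are broken by the smallest (i, j) index pair in
    the current working matrix; negative branch lengths are clamped to zero.
    The unrooted result is returned with a trifurcating root.
    """
    if len(dm) < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    nodes: list[PhyloNode] = [PhyloNode(name=label) for label in dm.labels]
    d = dm.data.astype(float).copy()

    while len(nodes) > 2:
        size = len(nodes)
        r = d.sum(axis=1)
        best: Optional[tuple[float, int, int]] = None
        for i in range(size):
            for j in range(i + 1, size):
                q = (size - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (size - 2))
        lj = d[i, j] - li
        new = PhyloNode()
        ci, cj = nodes[i], nodes[j]
        ci.length = max(li, 0.0)
        cj.length = max(lj, 0.0)
        new.add_child(ci)
        new.add_child(cj)

        merged = np.array(
            [(d[i, k] + d[j, k] - d[i, j]) / 2 for k in range(size) if k not in (i, j)]
        )
        keep = [k for k in range(size) if k not in (i, j)]
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = merged
        d[:-1, -1] = merged
        nodes = [nodes[k] for k in keep] + [new]

    a, b = nodes
    if not a.is_leaf:
        b.length = max(d[0, 1], 0.0)
        a.add_child(b)
        return a
    a.length = max(d[0, 1], 0.0)
    b.add_child(a)
    return b


def tree_distances(tree: PhyloNode, source: str) -> dict[str, float]:
    """Path-length distances from a named leaf to every leaf in the tree."""
    adjacency: dict[int, list[tuple[int, float]]] = {}
    by_id: dict[int, PhyloNode] = {}
    for node in tree.traverse():
        by_id[id(node)] = node
        for child in node.children:
            length = child.length or 0.0
            adjacency.setdefault(id(node), []).append((id(child), length))
            adjacency.setdefault(id(child), []).append((id(node), length))
    start = next((id(n) for n in tree.traverse() if n.name == source), None)
    if start is None:
        raise ValueError(f"leaf {source!r} not in tree")
    dist = {start: 0.0}
    stack = [start]
    while stack:
        current = stack.pop()
        for nbr, length in adjacency.get(current, []):
            if nbr not in dist:
                dist[nbr] = dist[current] + length
                stack.append(nbr)
    return {
        node.name: dist[nid]
        for nid, node in by_id.items()
        if node.is_leaf and node.name is not None
    }


def midpoint_root(tree: PhyloNode) -> PhyloNode:
    """Re-root a tree at the midpoint of its longest leaf-to-leaf path.

    Operates on a copy of the topology expressed as an edge list; the
    original tree is left untouched.
    """
    leaves = tree.leaf_names()
    if len(leaves) < 2:
        return tree
    far: tuple[float, str, str] = (-1.0, "", "")
    for leaf in leaves:
        for other, dist in tree_distances(tree, leaf).items():
            if other != leaf and dist > far[0]:
                far = (dist, leaf, other)
    total, src, dst = far
    target = total / 2

    # walk the src->dst path, splitting the edge where the midpoint falls
    parent_of: dict[int, Optional[PhyloNode]] = {}
    for node in tree.traverse():
        for child in node.children:
            parent_of[id(child)] = node
    nodes = {id(n): n for n in tree.traverse()}

    def neighbours(n: PhyloNode) -> list[tuple[PhyloNode, float]]:
        out = [(c, c.length or 0.0) for c in n.children]
        p = parent_of.get(id(n))
        if p is not None:
            out.append((p, n.length or 0.0))
        return out

    src_node = next(n for n in tree.traverse() if n.name == src)
    # BFS path reconstruction
    prev: dict[int, tuple[Optional[PhyloNode], float]] = {id(src_node): (None, 0.0)}
    queue = [src_node]
    while queue:
        cur = queue.pop(0)
        for nbr, length in neighbours(cur):
            if id(nbr) not in prev:
                prev[id(nbr)] = (cur, length)
                queue.append(nbr)
    dst_node = next(n for n in tree.traverse() if n.name == dst)
    path = [dst_node]
    while prev[id(path[-1])][0] is not None:
        path.append(prev[id(path[-1])][0])
    path.reverse()  # src ... dst

    walked = 0.0
    for a, b in zip(path, path[1:]):
        edge_len = prev[id(b)][1] if prev[id(b)][0] is a else prev[id(a)][1]
        if walked + edge_len >= target - 1e-12:
            offset = target - walked
            return _reroot_on_edge(tree, a, b, offset)
        walked += edge_len
    return tree


def _reroot_on_edge(
    tree: PhyloNode, a: PhyloNode, b: PhyloNode, offset_from_a: float
) -> PhyloNode:
    """Build a new rooted tree with the root ``offset_from_a`` along edge a-b."""
    edges: list[tuple[PhyloNode, PhyloNode, float]] = []
    for node in tree.traverse():
        for child in node.children:
            edges.append((node, child, child.length or 0.0))
    adjacency: dict[int, list[tuple[PhyloNode, float]]] = {}
    for u, v, length in edges:
        adjacency.setdefault(id(u), []).append((v, length))
        adjacency.setdefault(id(v), []).append((u, length))
    edge_len = next(
        (l for u, v, l in edges if {id(u), id(v)} == {id(a), id(b)}), 0.0
    )

    def build(node: PhyloNode, parent_id: Optional[int], length: float) -> PhyloNode:
        fresh = PhyloNode(name=node.name, length=length)
        for nbr, l in adjacency.get(id(node), []):
            if id(nbr) != parent_id:
                fresh.add_child(build(nbr, id(node), l))
        return fresh

    root = PhyloNode()
    left = build(a, id(b), offset_from_a)
    right = build(b, id(a), max(edge_len - offset_from_a, 0.0))
    root.add_child(left)
    root.add_child(right)
    return _suppress_unifurcations(root)


def _suppress_unifurcations(node: PhyloNode) -> PhyloNode:
    for child in list(node.children):
        _suppress_unifurcations(child)
    if len(node.children) == 1 and node.name is None:
        only = node.children[0]
        only.length = (only.length or 0.0) + (node.length or 0.0)
        only.parent = node.parent
        if node.parent is not None:
            idx = node.parent.children.index(node)
            node.parent.children[idx] = only
        return only
    return node


# ---------------------------------------------------------------------------
# Bidirectional best hits


def bbh(
    set_a: Sequence[tuple[SequenceRecord, str]],
    set_b: Sequence[tuple[SequenceRecord, str]],
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[HomologyPair]:
    """Bidirectional best hits between two sets of (record, species) pairs.

    A pair is reported iff each member is the other's *unique* best local
    alignment score in the opposite set (ties disqualify). Pass the same set
    twice to detect paralogues; self-hits are excluded.
    """
    if not set_a or not set_b:
        return []
    same_set = [r.id for r, _ in set_a] == [r.id for r, _ in set_b]

    def unique_best(
        query: SequenceRecord, targets: Sequence[tuple[SequenceRecord, str]]
    ) -> Optional[tuple[int, float]]:
        scores = []
        for idx, (rec, _) in enumerate(targets):
            if rec.id == query.id:
                continue
            scores.append((align_local_score(query.seq, rec.seq, matrix, gap_open, gap_extend), idx))
        if not scores:
            return None
        best_score = max(s for s, _ in scores)
        hits = [idx for s, idx in scores if s == best_score]
        if len(hits) != 1:
            return None
        return hits[0], best_score

    pairs: dict[tuple[str, str], HomologyPair] = {}
    for rec_a, sp_a in set_a:
        hit = unique_best(rec_a, set_b)
        if hit is None:
            continue
        idx_b, score = hit
        rec_b, sp_b = set_b[idx_b]
        back = unique_best(rec_b, set_a)
        if back is None:
            continue
        idx_back, _ = back
        if set_a[idx_back][0].id != rec_a.id:
            continue
        if same_set and sp_a != sp_b:
            continue
        key = tuple(sorted((rec_a.id, rec_b.id)))
        if key in pairs:
            continue
        if rec_a.id <= rec_b.id:
            pairs[key] = HomologyPair(rec_a.id, rec_b.id, sp_a, sp_b, score)
        else:
            pairs[key] = HomologyPair(rec_b.id, rec_a.id, sp_b, sp_a, score)
    return sorted(pairs.values(), key=lambda p: (p.id_a, p.id_b))
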