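"""Expression computations: ddCT, up-regulation calls, clustering, networks.

Implements the 2^-ddCT relative-expression statistic, the up-regulation
filter (BH false discovery rate <= 0.05 and |log2 fold change| >= 2),
Euclidean/complete-linkage hierarchical clustering of log2-transformed
profiles, and a Pearson co-expression network thresholded at r^2 >= 0.95
with degree-based hub extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

CT_COLUMNS = ["gene", "condition", "ct_target", "ct_reference"]


@dataclass(frozen=True)
class DECall:
    gene: str
    log2fc: float
    p_value: float
    fdr: float

    @property
    def up_regulated(self) -> bool:
        return self.fdr <= 0.05 and abs(self.log2fc) >= 2.0


@dataclass(frozen=True)
class CoexpressionNetwork:
    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, float, float], ...]  # (gene_a, gene_b, r, r2)
    hub_min: int
    excluded: tuple[str, ...] = field(default=())

    @property
    def degrees(self) -> dict[str, int]:
        deg = {node: 0 for node in self.nodes}
        for a, b, _, _ in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    @property
    def hubs(self) -> list[tuple[str, int]]:
        deg = self.degrees
        qualifying = [(g, d) for g, d in deg.items() if d >= self.hub_min]
        return sorted(qualifying, key=lambda x: (-x[1], x[0]))


# ---------------------------------------------------------------------------
# qRT-PCR relative expression


def relative_expression(ct: pd.DataFrame) -> pd.DataFrame:
    """Per-gene 2^-ddCT relative expression from a CT table.

    Expects columns gene, condition (treated/untreated), ct_target,
    ct_reference; extra columns (replicate ids) are ignored. dCT is computed
    per row, ddCT as mean treated dCT minus mean untreated dCT, and the
    replicate SD is the standard deviation of per-treated-replicate
    2^-(dCT_i - mean untreated dCT).
    """
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"CT table lacks columns {missing}")
    bad_cond = set(ct["condition"]) - {"treated", "untreated"}
    if bad_cond:
        raise ValueError(f"unknown conditions {sorted(bad_cond)}")
    ct = ct.copy()
    if not np.isfinite(ct[["ct_target", "ct_reference"]].to_numpy()).all():
        raise ValueError("CT values must be finite")
    ct["dct"] = ct["ct_target"] - ct["ct_reference"]

    rows = []
    for gene, sub in ct.groupby("gene", sort=True):
        treated = sub.loc[sub["condition"] == "treated", "dct"]
        untreated = sub.loc[sub["condition"] == "untreated", "dct"]
        if treated.empty or untreated.empty:
            raise ValueError(f"gene {gene!r}: both conditions must have replicates")
        ddct = treated.mean() - untreated.mean()
        per_rep = 2.0 ** -(treated - untreated.mean())
        rows.append(
            {
                "gene": gene,
                "ddct": ddct,
                "rel_expr": 2.0**-ddct,
                "rel_sd": float(per_rep.std(ddof=1)) if len(per_rep) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Differential expression


def exact_binomial_p(x: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value (minimum-likelihood method)."""
    if n == 0:
        return 1.0
    k = np.arange(n + 1)
    pmf = binom.pmf(k, n, p0)
    observed = pmf[x]
    return float(min(1.0, pmf[pmf <= observed * (1.0 + 1e-7)].sum()))


def poisson_rate_test(sum_a: float, sum_b: float, n_a: int, n_b: int) -> float:
    """Two-sided exact test of equal Poisson rates between two sample groups.

    Conditional on the total, the group-A sum is binomial with success
    probability n_a / (n_a + n_b) under the null.
    """
    x = int(round(sum_a))
    total = x + int(round(sum_b))
    return exact_binomial_p(x, total, n_a / (n_a + n_b))


def call_upregulated(
    mat: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fdr_max: float = 0.05,
    min_abs_log2fc: float = 2.0,
    pseudocount: float = 1.0,
    test: Optional[Callable[[float, float, int, int], float]] = None,
) -> list[DECall]:
    """Apply the up-regulation rule: FDR <= ``fdr_max`` and |log2FC| >= ``min_abs_log2fc``.

    ``mat`` is genes x samples. log2FC compares group A against group B with a
    pseudocount; p-values come from ``test`` (default: two-sided exact
    Poisson rate test on group-summed counts) and are BH-corrected.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both sample groups must be non-empty")
    for sample in [*group_a, *group_b]:
        if sample not in mat.columns:
            raise ValueError(f"sample {sample!r} not in matrix columns")
    if (mat[[*group_a, *group_b]].to_numpy() < 0).any():
        raise ValueError("expression values must be nonnegative")
    test = test or poisson_rate_test

    sub_a, sub_b = mat[group_a], mat[group_b]
    log2fc = np.log2((sub_a.mean(axis=1) + pseudocount) / (sub_b.mean(axis=1) + pseudocount))
    pvals = np.array(
        [
            test(sum_a, sum_b, len(group_a), len(group_b))
            for sum_a, sum_b in zip(sub_a.sum(axis=1), sub_b.sum(axis=1))
        ]
    )
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        DECall(gene=str(gene), log2fc=float(lfc), p_value=float(p), fdr=float(q))
        for gene, lfc, p, q in zip(mat.index, log2fc, pvals, fdr)
    ]


# ---------------------------------------------------------------------------
# Hierarchical clustering


def hier_cluster(
    mat: pd.DataFrame, transform: Optional[Callable[[np.ndarray], np.ndarray]] = None
) -> tuple[np.ndarray, list[str]]:
    """Complete-linkage clustering on Euclidean distances of transformed rows.

    Default transform is log2(x + 1). Returns the scipy linkage matrix and
    the dendrogram leaf order as gene ids.
    """
    if len(mat) < 2:
        raise ValueError("clustering needs at least 2 genes")
    values = mat.to_numpy(dtype=float)
    transformed = np.log2(values + 1.0) if transform is None else transform(values)
    dists = pdist(transformed, metric="euclidean")
    z = linkage(dists, method="complete")
    order = [str(mat.index[i]) for i in leaves_list(z)]
    return z, order


# ---------------------------------------------------------------------------
# Co-expression network


def coexpression_network(
    mat: pd.DataFrame, r2_min: float = 0.95, hub_min: int = 9
) -> CoexpressionNetwork:
    """Pearson co-expression network with edges at r^2 >= ``r2_min``.

    Zero-variance genes are excluded with a warning; fewer than 3 samples is
    an error. Hubs are nodes of degree >= ``hub_min`` ranked by degree then id.
    """
    if mat.shape[1] < 3:
        raise ValueError("co-expression needs at least 3 samples")
    values = mat.to_numpy(dtype=float)
    variances = values.var(axis=1)
    excluded = tuple(str(g) for g, v in zip(mat.index, variances) if v == 0.0)
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} zero-variance gene(s) from the network",
            stacklevel=2,
        )
    keep = variances > 0.0
    genes = [str(g) for g, k in zip(mat.index, keep) if k]
    corr = np.corrcoef(values[keep]) if keep.sum() > 1 else np.ones((keep.sum(), keep.sum()))
    edges = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            r = float(corr[i, j])
            if r * r >= r2_min:
                edges.append((genes[i], genes[j], r, r * r))
    return CoexpressionNetwork(
        nodes=tuple(genes), edges=tuple(edges), hub_min=hub_min, excluded=excluded
    )
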