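"""End-to-end orchestration: run every configured stage and write a report."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml
from scipy.cluster.hierarchy import to_tree

from . import classifier, expression_analysis, io_gene_models, molecular_evolution
from . import domain_scanner, phylogeny_orthology
from ._tree import PhyloNode

log = logging.getLogger("wrkykit")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    out_dir: str = "wrkykit_out"
    family_table: Optional[str] = None  # path or "bundled"
    mode: str = "label"  # label | rule
    proteins: Optional[str] = None
    cds: Optional[str] = None
    species: str = "P.edulis"
    clock_rate: float = molecular_evolution.DEFAULT_CLOCK_RATE
    expression: Optional[str] = None
    group_a: list[str] = field(default_factory=list)
    group_b: list[str] = field(default_factory=list)
    max_mismatch: int = domain_scanner.DEFAULT_MAX_MISMATCH
    extended: bool = False
    fdr_max: float = 0.05
    min_abs_log2fc: float = 2.0
    r2_min: float = 0.95
    hub_min: int = 9
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in {"label", "rule"}:
            raise ConfigError(f"mode must be 'label' or 'rule', got {self.mode!r}")
        if not 0.0 < self.fdr_max <= 1.0:
            raise ConfigError("fdr_max must be in (0, 1]")
        if not 0.0 <= self.r2_min <= 1.0:
            raise ConfigError("r2_min must be in [0, 1]")
        if self.min_abs_log2fc < 0:
            raise ConfigError("min_abs_log2fc must be >= 0")
        if self.hub_min < 0:
            raise ConfigError("hub_min must be >= 0")
        if self.max_mismatch < 0:
            raise ConfigError("max_mismatch must be >= 0")
        if self.clock_rate <= 0:
            raise ConfigError("clock_rate must be > 0")
        for path_attr in ("proteins", "cds", "expression"):
            value = getattr(self, path_attr)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"{path_attr} path does not exist: {value}")
        if (
            self.family_table is not None
            and self.family_table != "bundled"
            and not Path(self.family_table).exists()
        ):
            raise ConfigError(f"family_table path does not exist: {self.family_table}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=True)


def linkage_to_newick(z, labels: list[str]) -> str:
    """Convert a scipy linkage matrix into a Newick dendrogram string."""
    root, _ = to_tree(z, rd=True)

    def convert(node, parent_height: float) -> PhyloNode:
        length = parent_height - node.dist
        if node.is_leaf():
            return PhyloNode(name=labels[node.id], length=length)
        out = PhyloNode(length=length)
        out.add_child(convert(node.left, node.dist))
        out.add_child(convert(node.right, node.dist))
        return out

    tree = convert(root, root.dist)
    tree.length = None
    return io_gene_models.write_newick(tree)


def characterize(config: RunConfig) -> dict:
    """Run every configured stage; write TSV/Newick outputs plus a JSON summary.

    Returns the summary dict. Deterministic given the config and seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "thresholds": {
            "fdr_max": config.fdr_max,
            "min_abs_log2fc": config.min_abs_log2fc,
            "r2_min": config.r2_min,
            "hub_min": config.hub_min,
            "max_mismatch": config.max_mismatch,
            "extended": config.extended,
            "clock_rate": config.clock_rate,
        },
        "seed": config.seed,
    }

    assignments: list[classifier.FamilyAssignment] = []
    scan_config = (
        domain_scanner.ScanConfig.extended(config.max_mismatch)
        if config.extended
        else domain_scanner.ScanConfig(max_mismatch=config.max_mismatch)
    )

    if config.family_table is not None:
        rows = (
            io_gene_models.load_family_table()
            if config.family_table == "bundled"
            else io_gene_models.read_family_table(config.family_table)
        )
        log.info("family table: %d rows", len(rows))
        assignments = classifier.classify_table(rows, mode=config.mode)
        summary["variant_heptapeptide_domains"] = classifier.count_variant_heptapeptides(rows)

    scanned: dict[str, list[domain_scanner.WRKYDomain]] = {}
    if config.proteins is not None:
        records = io_gene_models.read_fasta(config.proteins, moltype="protein")
        log.info("proteins: %d records", len(records))
        scan_rows = []
        for record in records:
            domains = domain_scanner.scan_protein(record, scan_config)
            scanned[record.id] = domains
            for i, d in enumerate(domains):
                zf = d.zinc_finger
                scan_rows.append(
                    {
                        "gene_id": record.id,
                        "domain_index": i,
                        "terminal": d.terminal,
                        "heptapeptide": d.heptapeptide.sequence,
                        "hamming": d.heptapeptide.hamming,
                        "zf_type": zf.zf_type if zf else "/",
                        "m": zf.m if zf else "/",
                        "n": zf.n if zf else "/",
                        "complete": d.complete,
                    }
                )
        pd.DataFrame(scan_rows).to_csv(out / "scan.tsv", sep="\t", index=False)
        if not assignments:
            assignments = [
                classifier.assignment_from_scan(gid, doms) for gid, doms in scanned.items()
            ]

        if len(records) >= 3:
            dm = phylogeny_orthology.distance_matrix(records)
            tree = phylogeny_orthology.nj_tree(dm)
            (out / "tree.nwk").write_text(io_gene_models.write_newick(tree) + "\n")

        tagged = [(r, config.species) for r in records]
        pairs = phylogeny_orthology.bbh(tagged, tagged)
        pair_rows = [
            {
                "id_a": p.id_a,
                "id_b": p.id_b,
                "score": p.score,
                "relation": p.relation,
            }
            for p in pairs
        ]
        pd.DataFrame(pair_rows, columns=["id_a", "id_b", "score", "relation"]).to_csv(
            out / "pairs.tsv", sep="\t", index=False
        )
        summary["paralogous_pairs"] = len(pairs)

        if config.cds is not None and pairs:
            cds_records = {
                r.id: r for r in io_gene_models.read_fasta(config.cds, moltype="dna")
            }
            kaks_rows = []
            for p in pairs:
                if p.id_a not in cds_records or p.id_b not in cds_records:
                    continue
                prot_a = next(r for r in records if r.id == p.id_a)
                prot_b = next(r for r in records if r.id == p.id_b)
                aln, _, _ = phylogeny_orthology.align_global(prot_a.seq, prot_b.seq)
                codon_pairs = molecular_evolution.codon_align(
                    aln, cds_records[p.id_a].seq, cds_records[p.id_b].seq
                )
                result = molecular_evolution.nei_gojobori(codon_pairs)
                row = {
                    "id_a": p.id_a,
                    "id_b": p.id_b,
                    "S": result.S,
                    "N": result.N,
                    "pS": result.pS,
                    "pN": result.pN,
                    "Ka": result.Ka,
                    "Ks": result.Ks,
                    "T_mya": (
                        molecular_evolution.divergence_time(result.Ks, config.clock_rate).T_mya
                        if result.Ks is not None
                        else None
                    ),
                }
                kaks_rows.append(row)
            pd.DataFrame(
                kaks_rows,
                columns=["id_a", "id_b", "S", "N", "pS", "pN", "Ka", "Ks", "T_mya"],
            ).to_csv(out / "kaks.tsv", sep="\t", index=False)

    if assignments:
        fam = classifier.summarize_family(assignments)
        pd.DataFrame(
            [
                {
                    "gene_id": a.gene_id,
                    "group": a.group,
                    "incomplete_cterm": a.incomplete_cterm,
                    "two_domain_c2hc_override": a.two_domain_c2hc_override,
                }
                for a in assignments
            ]
        ).to_csv(out / "assignments.tsv", sep="\t", index=False)
        summary["group_counts"] = fam.counts
        summary["incomplete_group1"] = fam.incomplete_group1
        summary.setdefault("variant_heptapeptide_domains", fam.variant_domains)
        summary["total_genes"] = fam.total
        log.info("classified %d genes: %s", fam.total, fam.counts)

    if config.expression is not None:
        mat = pd.read_csv(config.expression, sep="\t", index_col=0)
        log.info("expression matrix: %d genes x %d samples", *mat.shape)
        if config.group_a and config.group_b:
            calls = expression_analysis.call_upregulated(
                mat,
                config.group_a,
                config.group_b,
                fdr_max=config.fdr_max,
                min_abs_log2fc=config.min_abs_log2fc,
            )
            pd.DataFrame(
                [
                    {
                        "gene": c.gene,
                        "log2fc": c.log2fc,
                        "p_value": c.p_value,
                        "fdr": c.fdr,
                        "up_regulated": c.up_regulated,
                    }
                    for c in calls
                ]
            ).to_csv(out / "de_calls.tsv", sep="\t", index=False)
            summary["up_regulated"] = sum(c.up_regulated for c in calls)
        if len(mat) >= 2:
            z, order = expression_analysis.hier_cluster(mat)
            (out / "dendrogram.nwk").write_text(
                linkage_to_newick(z, [str(g) for g in mat.index]) + "\n"
            )
            (out / "leaf_order.txt").write_text("\n".join(order) + "\n")
        network = expression_analysis.coexpression_network(
            mat, r2_min=config.r2_min, hub_min=config.hub_min
        )
        pd.DataFrame(
            list(network.edges), columns=["gene_a", "gene_b", "r", "r2"]
        ).to_csv(out / "network_edges.tsv", sep="\t", index=False)
        pd.DataFrame(network.hubs, columns=["gene", "degree"]).to_csv(
            out / "hubs.tsv", sep="\t", index=False
        )
        summary["network_edges"] = len(network.edges)
        summary["hub_genes"] = [g for g, _ in network.hubs]

    with open(out / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
    return summary
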