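# wrkykit

A toolkit for characterizing WRKY transcription-factor families from protein
and CDS sequences: motif-level WRKY domain detection, zinc-finger typing,
group/subgroup classification, neighbour-joining phylogenies,
bidirectional-best-hit orthology, Nei–Gojobori Ka/Ks duplication dating, and
expression analyses (2^-ddCT, up-regulation calling, hierarchical
clustering, co-expression networks).

A WRKY domain is a near-WRKYGQK heptapeptide followed by a zinc finger
`C-X(m)-C-X(n)-H-X-H` (C2H2) or `C-X(m)-C-X(n)-H-X-C` (C2HC). Families are
split into group 1 (two domains), group 2 (one C2H2 domain; subgroups 2a–2e)
and group 3 (one C2HC domain). The package ships a transcribed annotation
table of the 121-member *Phyllostachys edulis* (moso bamboo) WRKY family
(`src/wrkykit/data/phe_wrky_family.tsv`) used as a reference fixture, and a
`synthetic_data` module that generates fully-specified test inputs so every
stage is verifiable offline.

## Modules

| Module | Contents |
| --- | --- |
| `io_gene_models` | FASTA/GFF3/Newick IO, family-table parsing, intron phases |
| `domain_scanner` | heptapeptide + zinc-finger detection, pI/MW |
| `classifier` | group/subgroup assignment, family summaries |
| `phylogeny_orthology` | NW/SW alignment, NJ trees, midpoint rooting, BBH |
| `molecular_evolution` | codon alignment, Nei–Gojobori Ka/Ks, T = Ks/2λ |
| `expression_analysis` | ddCT, DE calls (BH FDR ≤ 0.05, \|log2FC\| ≥ 2), clustering, r² ≥ 0.95 networks |
| `synthetic_data` | seeded generators with planted ground truth |
| `pipeline` / `cli` | end-to-end `characterize` runs and the `wrkykit` CLI |

## CLI

```bash
wrkykit scan --in proteins.fasta --out domains.tsv [--extended]
wrkykit classify --mode label --out assignments.tsv --summary summary.json
wrkykit tree --in proteins.fasta --out tree.nwk [--midpoint]
wrkykit bbh --a sppA.fasta --b sppB.fasta --species-a A --species-b B --out pairs.tsv
wrkykit kaks --pairs pairs.tsv --cds cds.fasta --prot prot.fasta --out kaks.tsv
wrkykit express ddct --in ct.tsv --out rel.tsv
wrkykit express de --in matrix.tsv --group-a s1,s2 --group-b s3,s4 --out calls.tsv
wrkykit express cluster --in matrix.tsv --out dendro.nwk
wrkykit express network --in matrix.tsv --edges edges.tsv --hubs hubs.tsv
wrkykit simulate family --n-genes 30 --seed 1 --proteins p.fasta --cds c.fasta --truth-out truth.json
wrkykit characterize --config run.yaml --out out/
```

`characterize` reads a YAML config (see `wrkykit.pipeline.RunConfig` for the
keys) and writes per-stage TSV/Newick outputs plus `summary.json`; it exits
with code 2 on configuration errors.

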