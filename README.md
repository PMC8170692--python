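# consannot

Consensus-driven protein function annotation: domain-resolved selection of
homology hits per protein, followed by integration of hits from multiple
reference profile collections (Pfam, KOfam, TIGRFAM, eggNOG, NCBI protein
family models, or any custom set) into a single consensus annotation per
query sequence.

It is aimed at people annotating proteomes, genomes and metagenome-derived
protein catalogues who run profile-HMM searches (`hmmsearch --domtblout`)
against several reference collections and need one reconciled, identifier-
rich annotation per protein instead of five disagreeing tables.

## What it computes

**Per-collection hit selection.** A multi-domain protein typically has many
overlapping profile hits. For each query and collection, the engine selects
a set of mutually compatible hits — pairwise residue overlap at most 10% of
the shorter hit — by maximizing the combination score

    score = TC × HC × CE

where, for a combination of `combo_length` hits on a query of
`query_length` residues,

- **TC** (total coverage) = non-redundant residues covered / `query_length`,
- **HC** (average hit coverage) = mean of `hit_length / query_length`,
- **CE** (combination e-value) = mean of the per-hit significances, each
  obtained by log10-transforming the independent e-value and min–max
  scaling it between the query's best e-value (→ 1) and the acceptance
  threshold (→ 0).

Three algorithms are available: `dfs` (exhaustive depth-first search over
all feasible hit subsets, with a budgeted fallback), `heuristic` (greedy by
significance), and `bpo` (best prediction only: the single hit with the
lowest full-sequence e-value).

**Cross-collection consensus.** Selected hits from all collections are
pooled. Two hits from different collections with ≥ 70% residue overlap are
*consistent* when their metadata share a database identifier or, failing
that, when their free-text descriptions are sufficiently similar
(stop-word removal, light stemming, optional IDF weighting, cosine
similarity). Over the resulting consistency graph, combinations are
re-ranked by the consensus score

    consensus_score = score × (HCN + HMMW + MQ) / 3

with **HCN** the average hit consistency ((members + directly consistent
other hits) / total hits), **HMMW** the mean collection weight (defaults:
Pfam 0.9, eggNOG 0.8, KOfam/NPFM 0.7, TIGRFAM 0.5, custom 0.7), and
**MQ** the mean metadata quality (0.25 … 1 by identifier/description
presence). The winning combination is expanded along the graph (direct and
indirect connections) and the gathered identifiers and descriptions are
merged, deduplicated and cleaned of uninformative entries
("hypothetical protein", DUF domains, …).

The engine also handles chunked execution (e-values rescaled from chunk to
sample size, so output is chunk-invariant), taxon-aware annotation along an
organism's lineage (most resolved taxon-specific collection first), and
ships a benchmark module (TP/FP/FN/TN/PNA confusion classes, precision,
recall, F1, annotation coverage, and a paired randomized-subset
signed-rank comparison of algorithms).

## Worked example

```python
from consannot.synth import generate_sample
from consannot.workflow import run_sample

sample = generate_sample(n_queries=3, domains_per_query=2, n_sources=2, seed=7)
sample.write_fasta("demo/sample.faa")
hits = sample.write_hits("demo/hits")
meta = sample.write_metadata_files("demo/meta")
run_sample("demo/sample.faa", hits, meta, out_dir="demo/out")
print(open("demo/out/consensus_annotation.tsv").read())
```

prints

```
query_id	consensus_score	is_approximate	HMM_files	identifiers	descriptions
q0000	0.237076	0	kofam;pfam	kegg_ko:K10000;kegg_ko:K10001;kegg_ko:K40000;kegg_ko:K40001;pfam:PF10000;pfam:PF10001	glucose degradation | fatty acid oxidation
q0001	0.216751	0	kofam;pfam	kegg_ko:K10002;kegg_ko:K10003;kegg_ko:K40002;kegg_ko:K40003;pfam:PF10002;pfam:PF10003	dna replication | rna polymerase subunit variant type 0 | rna polymerase subunit variant type 1
q0002	0.225583	0	kofam;pfam	kegg_ko:K10004;kegg_ko:K10005;kegg_ko:K40004;kegg_ko:K40005;pfam:PF10004;pfam:PF10005	cell wall synthesis | membrane transport
```

Each row is one query protein: both collections (`HMM_files` column)
contributed, their identifiers were merged because the planted cross-
collection hits share KEGG ortholog IDs, and the consensus score is the
combination score of the winning hit set multiplied by the mean of its
consistency, collection-weight and metadata-quality terms. Two further
files, `output_annotation.tsv` (selected hits with coordinates and
e-values) and `integrated_annotation.tsv` (the same plus metadata), and a
run log are written next to it.

The same run is available from the shell:

```bash
consannot -t demo/sample.faa \
    --hits pfam=demo/hits/pfam.hits.tsv --hits kofam=demo/hits/kofam.hits.tsv \
    --metadata pfam=demo/meta/pfam.meta.tsv --metadata kofam=demo/meta/kofam.meta.tsv \
    -o demo/out --algorithm dfs --evalue 1e-3
```

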