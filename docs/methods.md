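# Methods

This note documents the model implemented by `consannot`, the parameters
that matter, the numerical conventions, and what the synthetic-data
generator does and does not emulate.

## Hit model and ingestion

A *hit* is one profile–sequence domain match with envelope coordinates
(1-based inclusive, as printed by `hmmsearch --domtblout`), an independent
(per-domain) e-value and a full-sequence e-value. The parser consumes the
standard domtblout column layout (target = protein, columns: target length
3, full-sequence E-value 7, i-Evalue 13, envelope 20–21); the layout was
checked against real `hmmsearch` output. Query lengths are taken from the
sample FASTA and cross-checked against the table's target-length column, so
a mismatched sample/hit-file pair fails immediately rather than silently
producing wrong coverages.

E-values of zero (HMMER can print `0.0`) are clamped to 1e-300 before any
logarithm. E-values computed on a sample chunk are rescaled to the full
sample by multiplying with `total_size / chunk_size` — HMMER e-values are
linear in the searched target-set size (verified empirically with
`hmmsearch -Z`). Rescaling happens before thresholding, so the accepted hit
set does not depend on the chunking.

Significance thresholds are either static (default 1e-3, the value at
which the F1 of the underlying selection approach peaks on curated
benchmark data) or length-dependent: 1e-10 below 150 residues,
`10^(-length/10)` from 150 to 250, 1e-25 above 250. Both boundary lengths
take the formula branch; the formula is continuous with the long plateau at
250 (`10^-25`) but intentionally not with the short plateau at 150
(`10^-15` vs `10^-10`), which is how the rule is stated. A hit exactly at
its threshold passes (≤ comparison).

## Combination score

For a set of mutually compatible hits of one query:

- TC = |union of covered residues| / query_length — rewards covering the
  protein;
- HC = mean(hit_length / query_length) — rewards few large hits over many
  small ones;
- CE = mean over the combination of a per-hit scaled significance
  `s = (log10 T − log10 e) / (log10 T − log10 e_best)`, clamped to [0, 1],
  where `T` is the acceptance threshold and `e_best` the lowest e-value
  among *all* candidate hits of the query (not just the combination).

Anchoring the min–max scale at the threshold rather than at the worst
observed hit keeps `s` strictly positive for every accepted hit; anchoring
at the worst hit would assign it `s = 0` and annihilate the product for any
combination containing it. When every hit sits exactly at the threshold the
frame is degenerate and all `s = 1`. The score is the product TC × HC × CE,
each factor in [0, 1].

Two hits are compatible when their shared residues are at most 10%
(configurable) of the *shorter* hit — a symmetric denominator standard in
domain-architecture resolution.

## Search algorithms

- **dfs** explores every feasible non-empty subset with an iterative
  depth-first search (explicit stack; deep architectures cannot hit the
  interpreter recursion limit). Hits are pre-sorted by the global tie-break
  order, and the best-scoring combination is kept; equal scores are broken
  by the lexicographic tuple of member sort keys, making the result
  bit-reproducible. The search budget is either wall-clock (default 60 s)
  or a node budget (deterministic; used in tests). On exhaustion the
  greedy result is returned and flagged approximate, and the run log
  records the fallback.
- **heuristic** repeatedly takes the most significant remaining hit
  compatible with everything selected. Linear-time, optimal only when the
  most significant hit does not block a better-covering pair.
- **bpo** keeps the single hit with the lowest *full-sequence* e-value
  (the DFS and heuristic use the independent e-value).

Tie-breaking everywhere: better e-value, longer hit, smaller start
coordinate, lexicographic profile id, lexicographic collection name.

Because the greedy and single-hit selections are elements of the DFS search
space, score(dfs) ≥ score(heuristic) and score(dfs) ≥ score(bpo) hold on
every input; the test suite checks this and exhibits strict separation on a
three-hit instance where the most significant hit blocks two flanking hits
that jointly cover the query (0.4 vs 0.2601).

## Metadata and text similarity

Metadata files are tagged TSVs (`profile_id`, then `tag:value` fields; the
dialect is this package's own plumbing — reference databases each ship
their own formats, which are out of scope here). Identifier types: KEGG
orthologs, EC numbers (kept verbatim, no wildcard subsumption), Pfam,
TIGRFAM, GO, InterPro, UniProt, COG/NOG, custom. Identifiers embedded in
free text are recovered with regular expressions covering those types and
are used for consistency checking. Metadata quality (MQ) is 0.25 (nothing),
0.5 (description only), 0.75 (identifiers only), 1 (both); placeholder
descriptions ("hypothetical protein", "unknown function", "uncharacterized
protein", DUF labels) do not count as descriptions.

Description similarity is deliberately small and fully deterministic:
lowercase, strip embedded identifiers and punctuation, remove stop-words
(a compact English closed-class list plus domain fillers such as
"protein", "putative", "responsible"; extensible), apply a light one-pass
suffix stemmer ("degradation" → "degrad", "glucose" → "glucos"), optional
user-supplied synonym mapping, then cosine similarity over token counts,
IDF-weighted when corpus statistics over the loaded metadata are
available. Two descriptions are *similar* at cosine ≥ 0.8 (configurable; a
pair exactly at the threshold passes). Identical token profiles score
exactly 1.0 regardless of weighting. This pipeline is the package's own
design within the stated behavioural constraints (keyword extraction,
confounder removal, synonym hook); the metric and threshold are pluggable.

## Consensus across collections

Hits selected per collection are pooled per query. The consistency graph
links two hits iff (a) they come from different collections, (b) they share
at least 70% residue overlap of the shorter hit, and (c) their identifiers
intersect or — only as a backup, since identifier cross-linking is not
universally available — their descriptions are similar. Edges record their
evidence type.

Consensus score = combination score × (HCN + HMMW + MQ) / 3, with

- HCN = (combination size + number of *distinct* other hits directly
  adjacent to a member) / total hits of the query — a neighbour consistent
  with two members counts once, which matches both hand-worked reference
  cases ((2+3)/10 = 0.5 and (2+2)/8 = 0.5);
- HMMW = mean collection weight over members;
- MQ = mean metadata quality over members.

Since each multiplier term is ≤ 1, the consensus score never exceeds the
plain combination score. The same search machinery (DFS with fallback;
greedy/BPO selectable) ranks combinations by consensus score. The winner is
expanded to the full connected components containing its members — the 70%
overlap requirement is enforced at edge creation and not re-checked against
the combination root, which is what admits chain-connected hits.
Identifiers are merged by set union of the explicit metadata identifiers of
the connected hits (text-extracted identifiers serve consistency checking
only); descriptions are deduplicated with junk removed; contributing
collections are listed in the `HMM_files` output column. When no edges
exist the consensus contains only the winning combination's own metadata;
disagreeing hits remain visible in the integrated output. A query whose
hits all fail the threshold produces no output row.

## Workflow, chunking and taxon-aware annotation

Samples of ≤ 200,000 sequences are split into chunks balanced by residue
count (longest-processing-time greedy: sort by length descending, assign to
the currently lightest chunk; the spread between chunk totals is bounded by
one sequence length). Larger samples are split round-robin in input order
as an efficiency safeguard. The default chunk count is 4 tasks per worker,
capped so no chunk falls below 50 sequences. Per-query processing tasks are
independent and merged in query order, so worker count and task order never
change the output; outputs print e-values and scores at 6 significant
digits, which also absorbs the sub-ulp float noise of the chunk rescale
round trip — a chunked run is byte-identical to the unchunked one.

Taxon-aware annotation walks the organism's lineage from the most resolved
taxon to the root: each available taxon-specific collection is searched
with the still-unannotated sequences; sequences gaining a valid hit are not
carried further; remaining sequences finally go to the general collections.
Collections that are not taxon-resolved are always searched for every
sequence. An unknown lineage falls back to the general collections with a
logged warning.

The optional search adapter shells out to `hmmsearch --domtblout` per chunk
when profile files are supplied; the engine itself never requires it and
all algorithmic tests run from generated hit tables.

## Benchmarking

Whole-sequence comparison by identifier intersection: TP when prediction
and reference share ≥ 1 identifier, FP when none is shared, FN/TN for a
missing prediction with/without a reference, PNA (potentially new
annotation) when the reference is absent or uninformative but a prediction
exists. Annotations without identifiers count as absent; uninformative
references without a prediction belong to no class but still count in the
sample size. precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic
mean, coverage = (TP+FP+PNA)/total; zero denominators yield 0 by
convention. The paired harness draws identical random subsets for all
algorithms, computes F1 per subset (per-subset confusion counts, not pooled)
and applies the Wilcoxon signed-rank test; all-zero differences are
reported as no difference (p = 1).

## Synthetic samples

The generator plants, per query, a few disjoint domains (default 70–110
residues, 10-residue gaps) reported by every collection with strong
e-values; cross-collection metadata for the same domain shares a KEGG
ortholog with probability `p_share` and an identically-worded description
with probability `p_text`. Planted e-values share a per-query base exponent
(log-uniform over [1e-30, 1e-6]) with ±0.25 decades of per-hit jitter;
together with the bounded domain-length ratio this makes the full planted
architecture strictly outscore every proper subset, so noise-free samples
have a unique optimum and recovery is exactly 1. Noise comes in two forms:
sub-interval decoys (strictly dominated in all three score terms — pure
distractors) and full-length trap decoys with weak e-values, which can
legitimately outscore a fragmented architecture and produce genuine
recovery loss. All decoy randomness is drawn whether or not a decoy is
emitted, so for a fixed seed the decoy set at a lower rate is a subset of
that at a higher rate and recovery is deterministically non-increasing in
the rate.

What the generator does **not** emulate: real sequence content (residues
are uniform random — only lengths and hit geometry matter to the
algorithms), profile-specific score distributions, correlated decoys,
partially overlapping domain families, or the messiness of real metadata
(multi-sentence descriptions, wrong cross-links). Passing tests therefore
demonstrate algorithmic correctness — selection optimality, consensus
arithmetic, chunk invariance, format round-trips — not annotation quality
on real proteomes, which depends on the reference collections used.

## Problem sizes and tolerances in the test suite

Oracle-equivalence checks use 500 random hit sets of up to 12 hits
(exhaustive enumeration stays cheap at 2^12 subsets); recovery uses 200
queries with 3 domains and 2 collections over a 5-point decoy-rate grid at
3 seeds; chunk equivalence uses a 1,000-sequence sample at 1, 4 and 16
chunks; the signed-rank harness uses 100 subsets of 100 from 1,000
sequences. Numeric assertions on worked examples are exact or at relative
1e-12 for float identities; determinism tests compare bytes.

## Known limitations

- The DFS is exponential in the number of accepted hits per query; the
  budget/fallback path, not pruning bounds, guards pathological inputs.
- EC numbers match by exact string equality; hierarchical EC subsumption
  (1.2.-.- vs 1.2.3.4) is intentionally not implemented.
- Description similarity is bag-of-words; ontology-aware semantic
  similarity is out of scope.
- The consensus HCN counts neighbours from any other collection, including
  collections already represented in the combination (restriction is by
  the hit's own collection only), matching the reference worked examples;
  an alternative stricter reading is noted as a possible sensitivity
  analysis.
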