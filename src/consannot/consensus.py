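"""Multi-source consensus: pool hits across reference collections, pick the
best inter-source combination, and merge consistent metadata.

All selected hits of one query, regardless of reference collection, are
pooled and searched with the same combination machinery as the per-source
step, but ranked by the *consensus* score

    combination_score x (HCN + HMMW + MQ) / 3

where the combination score is TC x HC x CE and

* HCN (average hit consistency): the number of hits in the combination plus
  the number of distinct other hits whose metadata is directly consistent
  with a combination member (nodes adjacent in the metadata consistency
  graph, necessarily from other collections), divided by the total number of
  hits for the query;
* HMMW (mean reference weight): mean of the per-collection reliability
  weights over the combination;
* MQ: mean metadata quality over the combination.

Metadata consistency between two hits requires (a) different reference
collections, (b) at least 70% residue overlap of the shorter hit (default),
and (c) an identifier intersection or, as a backup, sufficiently similar
free-text descriptions.  The winning combination is expanded along the
consistency graph (direct and indirect connections) and all gathered
identifiers and descriptions are merged, deduplicated, and cleaned of
uninformative entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .combine import (
    DEFAULT_MAX_OVERLAP,
    BudgetExhausted,
    HitCombination,
    SearchBudget,
    _dfs_best,
    bpo_select,
    heuristic_select,
    residue_overlap,
    score_combination,
)
from .hits import Hit
from .metadata import AnnotatedHit, Identifier, SourceWeights, is_junk_description
from .textsim import (
    DEFAULT_SIMILARITY_THRESHOLD,
    CorpusStats,
    is_similar,
    preprocess,
)

__all__ = [
    "DEFAULT_MIN_CONSISTENCY_OVERLAP",
    "ConsistencyGraph",
    "ConsensusAnnotation",
    "build_consistency_graph",
    "hcn",
    "hmmw",
    "mean_mq",
    "consensus_score",
    "select_consensus",
    "expand_and_merge",
]

DEFAULT_MIN_CONSISTENCY_OVERLAP = 0.70


@dataclass
class ConsistencyGraph:
    """Metadata consistency graph over the annotated hits of one query.

    Nodes are hit indices into ``hits``; an edge asserts that two hits from
    different collections, overlapping sufficiently, carry consistent
    metadata.  Edge attribute ``evidence`` records whether the link came from
    an identifier intersection or from description similarity.
    """

    hits: list[AnnotatedHit]
    graph: nx.Graph = field(default_factory=nx.Graph)
    min_overlap: float = DEFAULT_MIN_CONSISTENCY_OVERLAP

    def index_of(self, hit: Hit) -> int:
        for i, ah in enumerate(self.hits):
            if ah.hit is hit or ah.hit == hit:
                return i
        raise KeyError(f"hit not in graph: {hit!r}")

    def neighbors(self, idx: int) -> set[int]:
        return set(self.graph.neighbors(idx))


def _ids_intersect(a: AnnotatedHit, b: AnnotatedHit) -> bool:
    return bool(a.metadata.all_identifiers() & b.metadata.all_identifiers())


def _descriptions_similar(
    a: AnnotatedHit,
    b: AnnotatedHit,
    threshold: float,
    corpus_stats: CorpusStats | None,
) -> bool:
    for da in a.metadata.informative_descriptions():
        pa = preprocess(da)
        for db in b.metadata.informative_descriptions():
            if is_similar(pa, preprocess(db), threshold, corpus_stats):
                return True
    return False


def build_consistency_graph(
    hits: list[AnnotatedHit],
    min_overlap: float = DEFAULT_MIN_CONSISTENCY_OVERLAP,
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    corpus_stats: CorpusStats | None = None,
) -> ConsistencyGraph:
    """Connect pairs of cross-collection hits with sufficient residue overlap
    whose metadata is consistent.

    The identifier intersection is checked first; description similarity is
    only consulted as a backup (identifier cross-linking is not universally
    available in reference metadata).
    """
    g = ConsistencyGraph(hits=hits, min_overlap=min_overlap)
    g.graph.add_nodes_from(range(len(hits)))
    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            a, b = hits[i], hits[j]
            if a.hit.source == b.hit.source:
                continue
            shorter = min(a.hit.length, b.hit.length)
            if residue_overlap(a.hit, b.hit) < min_overlap * shorter:
                continue
            if _ids_intersect(a, b):
                g.graph.add_edge(i, j, evidence="id_intersection")
            elif _descriptions_similar(a, b, similarity_threshold, corpus_stats):
                g.graph.add_edge(i, j, evidence="description_similarity")
    return g


def hcn(c: HitCombination, g: ConsistencyGraph) -> float:
    """Average hit consistency of the combination under the graph.

    (combination size + number of distinct outside hits directly consistent
    with a member) / total hits of the query.  E.g. a 2-hit combination with
    3 consistent other hits among 10 total scores (2 + 3) / 10 = 0.5.
    """
    if not c.hits:
        raise ValueError("HCN of an empty combination is undefined")
    member_idx = {g.index_of(h) for h in c.hits}
    consistent: set[int] = set()
    for idx in member_idx:
        consistent |= g.neighbors(idx)
    consistent -= member_idx
    return (len(member_idx) + len(consistent)) / len(g.hits)


def hmmw(c: HitCombination, weights: SourceWeights) -> float:
    """Mean reference-collection weight over the combination's hits."""
    if not c.hits:
        raise ValueError("HMMW of an empty combination is undefined")
    return sum(weights[h.source] for h in c.hits) / len(c.hits)


def mean_mq(c: HitCombination, g: ConsistencyGraph) -> float:
    """Mean metadata quality over the combination's hits."""
    if not c.hits:
        raise ValueError("MQ of an empty combination is undefined")
    return sum(g.hits[g.index_of(h)].mq for h in c.hits) / len(c.hits)


def consensus_score(
    c: HitCombination,
    g: ConsistencyGraph,
    weights: SourceWeights,
    threshold: float = 1e-3,
) -> float:
    """Consensus combination score: Eq.-1-style combination score times the
    mean of HCN, HMMW and MQ.  Since each of the three terms is at most 1,
    the consensus score never exceeds the plain combination score."""
    base = score_combination(c, [ah.hit for ah in g.hits], threshold)
    return base * (hcn(c, g) + hmmw(c, weights) + mean_mq(c, g)) / 3.0


def select_consensus(
    g: ConsistencyGraph,
    algorithm: str = "dfs",
    max_overlap: float = DEFAULT_MAX_OVERLAP,
    budget: SearchBudget | None = None,
    weights: SourceWeights | None = None,
    threshold: float = 1e-3,
) -> HitCombination:
    """Best combination of the pooled cross-collection hits under the
    consensus score.

    Same search machinery as the per-source step (DFS with a heuristic
    fallback when the budget is exhausted; greedy and best-prediction-only
    selectable), but ranked by the consensus score.  The returned
    combination's ``score`` field holds the consensus score.
    """
    weights = weights or SourceWeights()
    budget = budget or SearchBudget()
    pooled = [ah.hit for ah in g.hits]
    if not pooled:
        return HitCombination(hits=())

    def score_fn(c: HitCombination) -> float:
        s = consensus_score(c, g, weights, threshold)
        c.score = s
        return s

    if algorithm == "dfs":
        try:
            return _dfs_best(pooled, max_overlap, score_fn, budget)
        except BudgetExhausted:
            combo = heuristic_select(pooled, max_overlap)
            if combo.hits:
                score_fn(combo)
            combo.is_approximate = True
            return combo
    if algorithm == "heuristic":
        combo = heuristic_select(pooled, max_overlap)
    elif algorithm == "bpo":
        combo = bpo_select(pooled)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if combo.hits:
        score_fn(combo)
    return combo


@dataclass
class ConsensusAnnotation:
    """Final merged annotation of one query sequence."""

    query_id: str
    selected: HitCombination
    expansion: list[AnnotatedHit]
    identifiers: set[Identifier]
    descriptions: list[str]
    sources: list[str]
    consensus_score: float
    is_approximate: bool = False


def expand_and_merge(best: HitCombination, g: ConsistencyGraph) -> ConsensusAnnotation:
    """Expand the winning combination along the consistency graph and merge
    all gathered metadata into one consensus annotation.

    Every hit directly or indirectly connected to a combination member joins
    the expansion (the 70% residue-overlap requirement is enforced when the
    edges are created).  Identifiers are unioned; descriptions are
    deduplicated and uninformative ones dropped; contributing collections are
    listed sorted.
    """
    if not best.hits:
        raise ValueError("cannot expand an empty combination")
    member_idx = {g.index_of(h) for h in best.hits}
    gathered: set[int] = set()
    for idx in member_idx:
        gathered |= nx.node_connected_component(g.graph, idx)
    expansion_idx = sorted(gathered - member_idx)

    contributing = sorted(member_idx) + expansion_idx
    identifiers: set[Identifier] = set()
    descriptions: list[str] = []
    sources: list[str] = []
    for idx in contributing:
        ah = g.hits[idx]
        identifiers |= ah.metadata.identifiers
        for d in ah.metadata.descriptions:
            if not is_junk_description(d) and d not in descriptions:
                descriptions.append(d)
        if ah.hit.source not in sources:
            sources.append(ah.hit.source)
    return ConsensusAnnotation(
        query_id=best.hits[0].query_id,
        selected=best,
        expansion=[g.hits[i] for i in expansion_idx],
        identifiers=identifiers,
        descriptions=descriptions,
        sources=sorted(sources),
        consensus_score=best.score,
        is_approximate=best.is_approximate,
    )
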