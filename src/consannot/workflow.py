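"""End-to-end orchestration: chunk planning, taxon-aware annotation, and the
three-file TSV output.

A run takes a protein FASTA, per-collection hit tables (precomputed
domtblout/TSV files, possibly one per sample chunk) and per-collection
metadata tables, and produces:

* ``output_annotation.tsv`` — the raw selected hits per query and collection;
* ``integrated_annotation.tsv`` — the same hits with their metadata attached;
* ``consensus_annotation.tsv`` — one row per query with the merged consensus
  annotation (identifiers, descriptions, contributing collections in the
  ``HMM_files`` column, consensus score, approximate flag);

plus a plain-text log recording each step and any heuristic fallbacks.

Chunking: e-values computed on a chunk of the sample are rescaled to the
full sample size before any thresholding or selection, which makes the final
output independent of how the sample was chunked.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from Bio import SeqIO

from .combine import DEFAULT_MAX_OVERLAP, HitCombination, SearchBudget, select_hits
from .consensus import (
    DEFAULT_MIN_CONSISTENCY_OVERLAP,
    ConsensusAnnotation,
    build_consistency_graph,
    expand_and_merge,
    select_consensus,
)
from .hits import (
    Hit,
    HitTableError,
    ThresholdSpec,
    evalue_threshold_for,
    filter_hits,
    parse_domtblout,
    read_hits_tsv,
    rescale_hit,
)
from .metadata import MetadataRecord, SourceWeights, annotate_hits, load_metadata
from .textsim import DEFAULT_SIMILARITY_THRESHOLD, CorpusStats

__all__ = [
    "LENGTH_BALANCED_MAX_SEQS",
    "ChunkPlan",
    "RunConfig",
    "TableHitSource",
    "TsaSetup",
    "plan_chunks",
    "default_chunk_count",
    "tsa_annotate",
    "run_sample",
    "read_fasta_lengths",
    "load_lineage_table",
]

#: Above this many sequences, chunking falls back to round-robin (an
#: efficiency safeguard); at or below it, chunks are balanced by residues.
LENGTH_BALANCED_MAX_SEQS = 200_000

_EVALUE_FMT = "{:.6g}"
_SCORE_FMT = "{:.6g}"


# --- chunk planning ----------------------------------------------------------

@dataclass
class ChunkPlan:
    """Partition of the sample's sequences into work chunks."""

    chunks: list[list[str]]
    residue_totals: list[int]
    policy: str  # "length_balanced" | "round_robin"

    @property
    def n_chunks(self) -> int:
        return len(self.chunks)


def plan_chunks(lengths: Mapping[str, int], target_chunks: int) -> ChunkPlan:
    """Distribute sequences over ``target_chunks`` chunks.

    Samples of at most 200,000 sequences are balanced by residue count
    (longest-processing-time greedy: longest sequence first, into the
    currently lightest chunk), so every chunk holds approximately the same
    number of residues.  Larger samples are split round-robin in input order,
    independently of length.
    """
    if target_chunks < 1:
        raise ValueError(f"target_chunks must be >= 1, got {target_chunks}")
    ids = list(lengths)
    chunks: list[list[str]] = [[] for _ in range(target_chunks)]
    totals = [0] * target_chunks
    if len(ids) <= LENGTH_BALANCED_MAX_SEQS:
        policy = "length_balanced"
        for seq_id in sorted(ids, key=lambda s: (-lengths[s], s)):
            lightest = min(range(target_chunks), key=lambda i: (totals[i], i))
            chunks[lightest].append(seq_id)
            totals[lightest] += lengths[seq_id]
    else:
        policy = "round_robin"
        for pos, seq_id in enumerate(ids):
            i = pos % target_chunks
            chunks[i].append(seq_id)
            totals[i] += lengths[seq_id]
    return ChunkPlan(chunks=chunks, residue_totals=totals, policy=policy)


def default_chunk_count(n_seqs: int, workers: int, min_chunk: int = 50) -> int:
    """Four tasks per worker, capped so no chunk drops below ``min_chunk``
    sequences."""
    if n_seqs <= 0:
        return 1
    return max(1, min(workers * 4, n_seqs // min_chunk or 1))


# --- configuration -----------------------------------------------------------

@dataclass
class RunConfig:
    """All tunables of a run; flag values override config-file values."""

    algorithm: str = "dfs"
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    max_overlap: float = DEFAULT_MAX_OVERLAP
    min_consistency_overlap: float = DEFAULT_MIN_CONSISTENCY_OVERLAP
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD
    weights: SourceWeights = field(default_factory=SourceWeights)
    budget: SearchBudget = field(default_factory=SearchBudget)
    workers: int = 1

    def __post_init__(self) -> None:
        if self.algorithm not in ("dfs", "heuristic", "bpo"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not (0 <= self.max_overlap < 1):
            raise ValueError("max_overlap must be in [0, 1)")
        if not (0 < self.min_consistency_overlap <= 1):
            raise ValueError("min_consistency_overlap must be in (0, 1]")
        if not (0 <= self.similarity_threshold <= 1):
            raise ValueError("similarity_threshold must be in [0, 1]")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")

    @classmethod
    def from_ini(cls, path: str | Path) -> "RunConfig":
        """Load an INI config; ``[run]`` holds scalar options and
        ``[weights]`` per-collection weights."""
        parser = configparser.ConfigParser()
        with open(path) as fh:
            parser.read_file(fh)
        kwargs: dict = {}
        if parser.has_section("run"):
            run = parser["run"]
            if "algorithm" in run:
                kwargs["algorithm"] = run["algorithm"].strip()
            if "evalue" in run:
                kwargs["threshold"] = ThresholdSpec.from_string(run["evalue"])
            if "overlap" in run:
                kwargs["max_overlap"] = run.getfloat("overlap")
            if "consistency_overlap" in run:
                kwargs["min_consistency_overlap"] = run.getfloat("consistency_overlap")
            if "similarity_threshold" in run:
                kwargs["similarity_threshold"] = run.getfloat("similarity_threshold")
            if "workers" in run:
                kwargs["workers"] = run.getint("workers")
            if "time_limit" in run:
                kwargs["budget"] = SearchBudget(time_limit=run.getfloat("time_limit"))
        if parser.has_section("weights"):
            weights = {
                name: float(value) for name, value in parser["weights"].items()
            }
            default = weights.pop("default", 0.7)
            kwargs["weights"] = SourceWeights(weights=weights, default=default)
        return cls(**kwargs)


# --- taxon-specific annotation ----------------------------------------------

@dataclass
class TableHitSource:
    """A searchable hit collection backed by an in-memory table.

    Stands for one reference collection (e.g. a taxon-specific profile set):
    ``search`` returns the precomputed hits of the requested queries.
    """

    name: str
    hits_by_query: dict[str, list[Hit]]

    def search(self, query_ids: Iterable[str]) -> list[Hit]:
        out: list[Hit] = []
        for qid in sorted(query_ids):
            out.extend(self.hits_by_query.get(qid, ()))
        return out

    @classmethod
    def from_hits(cls, name: str, hits: Iterable[Hit]) -> "TableHitSource":
        table: dict[str, list[Hit]] = {}
        for h in hits:
            table.setdefault(h.query_id, []).append(h)
        return cls(name=name, hits_by_query=table)


@dataclass
class TsaSetup:
    """Inputs for the taxon-aware annotation loop: the query organism's
    lineage (root first, leaf last) and one hit source per taxon that has a
    taxon-specific profile collection."""

    lineage: list[str]
    tshmm_sources: dict[str, TableHitSource]
    general_source_names: tuple[str, ...] = ("eggnog", "npfm")


def tsa_annotate(
    query_ids: Iterable[str],
    lineage: Sequence[str] | None,
    tshmm_sources: Mapping[str, TableHitSource],
    general_sources: Sequence[TableHitSource],
    spec: ThresholdSpec,
    log: list[str] | None = None,
) -> dict[str, list[Hit]]:
    """Walk the lineage from the most resolved taxon to the root, searching
    each available taxon-specific collection with the still-unannotated
    sequences; finish with the general collections for any remainder.

    A sequence that gains a valid (threshold-passing) hit at one level is not
    carried to the next.  With no lineage, or a lineage without any known
    taxon, only the general collections are searched (with a logged warning
    in the latter case).
    """
    log = log if log is not None else []
    remaining = set(query_ids)
    per_source: dict[str, list[Hit]] = {}
    walked_any = False
    if lineage:
        for taxon in reversed(list(lineage)):
            if not remaining:
                break
            source = tshmm_sources.get(str(taxon))
            if source is None:
                continue
            walked_any = True
            valid = filter_hits(source.search(remaining), spec)
            if valid:
                per_source.setdefault(source.name, []).extend(valid)
                remaining -= {h.query_id for h in valid}
            log.append(
                f"tsa: taxon {taxon} ({source.name}): {len(valid)} valid hits, "
                f"{len(remaining)} sequences still unannotated"
            )
        if not walked_any:
            log.append(
                "tsa: no taxon of the lineage has a taxon-specific collection; "
                "falling back to general collections"
            )
    for source in general_sources:
        if not remaining:
            break
        valid = filter_hits(source.search(remaining), spec)
        if valid:
            per_source.setdefault(source.name, []).extend(valid)
        log.append(f"tsa: general {source.name}: {len(valid)} valid hits")
    return per_source


def load_lineage_table(path: str | Path) -> dict[str, list[str]]:
    """Read a lineage table: ``taxon_id<TAB>space-separated path`` from root
    to the taxon itself."""
    lineages: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            taxon, _, path_str = line.partition("\t")
            lineages[taxon.strip()] = path_str.split()
    return lineages


# --- sample run --------------------------------------------------------------

def read_fasta_lengths(path: str | Path) -> dict[str, int]:
    """Sequence lengths from a protein FASTA."""
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


#: A hit input is either one file covering the whole sample or a list of
#: (file, chunk_size) pairs whose e-values are on chunk scale.
HitInput = "str | Path | Sequence[tuple[str | Path, int]]"


def _load_hit_file(
    path: str | Path, source: str, sample_lengths: Mapping[str, int]
) -> list[Hit]:
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if first.startswith("query_id\t"):
            return read_hits_tsv(fh, source=source, sample_lengths=sample_lengths)
        return parse_domtblout(fh, source=source, sample_lengths=sample_lengths)


def load_hit_input(
    hit_input,
    source: str,
    sample_lengths: Mapping[str, int],
    total_size: int,
) -> list[Hit]:
    """Load one collection's hits, rescaling chunk-scale e-values to the
    full sample size."""
    if isinstance(hit_input, (str, Path)):
        return _load_hit_file(hit_input, source, sample_lengths)
    hits: list[Hit] = []
    for path, chunk_size in hit_input:
        for h in _load_hit_file(path, source, sample_lengths):
            hits.append(rescale_hit(h, chunk_size, total_size))
    return hits


@dataclass
class QueryResult:
    """Everything the pipeline derived for one query sequence."""

    query_id: str
    per_source: dict[str, HitCombination]
    consensus: ConsensusAnnotation | None


@dataclass
class SampleResult:
    results: list[QueryResult]
    log: list[str]
    out_dir: Path | None = None


def _select_for_query(
    query_id: str,
    hits_by_source: Mapping[str, list[Hit]],
    metadata: Mapping[str, Mapping[str, MetadataRecord]],
    config: RunConfig,
    corpus_stats: CorpusStats | None,
    log: list[str],
) -> QueryResult:
    """Process one query: per-collection selection, then consensus.  Queries
    are mutually independent, so these tasks can run in any order or in
    parallel; the caller merges results in query order."""
    evalue_field = "full_sequence" if config.algorithm == "bpo" else "independent"
    per_source: dict[str, HitCombination] = {}
    pooled: list[Hit] = []
    for source in sorted(hits_by_source):
        hits = filter_hits(hits_by_source[source], config.threshold, evalue_field)
        if not hits:
            continue
        threshold = evalue_threshold_for(hits[0].query_length, config.threshold)
        combo = select_hits(
            hits,
            algorithm=config.algorithm,
            max_overlap=config.max_overlap,
            budget=config.budget,
            threshold=threshold,
        )
        if combo.is_approximate:
            log.append(
                f"warning: query {query_id}, source {source}: search budget "
                "exhausted, heuristic fallback used"
            )
        if combo.hits:
            per_source[source] = combo
            pooled.extend(combo.hits)
    if not pooled:
        return QueryResult(query_id=query_id, per_source=per_source, consensus=None)

    annotated = annotate_hits(pooled, metadata)
    graph = build_consistency_graph(
        annotated,
        min_overlap=config.min_consistency_overlap,
        similarity_threshold=config.similarity_threshold,
        corpus_stats=corpus_stats,
    )
    threshold = evalue_threshold_for(pooled[0].query_length, config.threshold)
    best = select_consensus(
        graph,
        algorithm=config.algorithm,
        max_overlap=config.max_overlap,
        budget=config.budget,
        weights=config.weights,
        threshold=threshold,
    )
    if best.is_approximate:
        log.append(
            f"warning: query {query_id}: consensus search budget exhausted, "
            "heuristic fallback used"
        )
    if not best.hits:
        return QueryResult(query_id=query_id, per_source=per_source, consensus=None)
    consensus = expand_and_merge(best, graph)
    if any(c.is_approximate for c in per_source.values()):
        consensus.is_approximate = True
    return QueryResult(query_id=query_id, per_source=per_source, consensus=consensus)


def _query_task(args) -> tuple[QueryResult, list[str]]:
    qid, hits_by_source, metadata, config, corpus_stats = args
    task_log: list[str] = []
    qr = _select_for_query(qid, hits_by_source, metadata, config, corpus_stats, task_log)
    return qr, task_log


def run_sample(
    fasta: str | Path,
    hit_inputs: Mapping[str, "HitInput"],
    metadata_inputs: Mapping[str, str | Path],
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    tsa: TsaSetup | None = None,
) -> SampleResult:
    """Annotate one sample end to end.

    ``hit_inputs`` maps collection name to a hit file (domtblout or internal
    TSV) or to a list of per-chunk ``(file, chunk_size)`` pairs; chunk-scale
    e-values are rescaled to the sample size before thresholding.  When a
    taxon setup is given, the collections named in its
    ``general_source_names`` are searched only for sequences the
    taxon-specific walk left unannotated; all other collections are searched
    for every sequence.  Writes the three output TSVs and the run log when
    ``out_dir`` is given.
    """
    config = config or RunConfig()
    log: list[str] = []
    fasta = Path(fasta)
    if not fasta.exists():
        raise FileNotFoundError(f"sample FASTA not found: {fasta}")
    for name, path in metadata_inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"metadata file for {name!r} not found: {path}")
    sample_lengths = read_fasta_lengths(fasta)
    total = len(sample_lengths)
    log.append(f"sample: {fasta.name}: {total} sequences")

    # load hits per collection, rescaling chunked inputs to sample scale
    hits_by_source: dict[str, list[Hit]] = {}
    for source in sorted(hit_inputs):
        loaded = load_hit_input(hit_inputs[source], source, sample_lengths, total)
        hits_by_source[source] = loaded
        log.append(f"hits: {source}: {len(loaded)} raw hits")

    # taxon-specific walk: taxon collections first, general ones only for the
    # remainder; every other collection is searched regardless of taxonomy
    if tsa is not None:
        general = [
            TableHitSource.from_hits(name, hits_by_source.pop(name))
            for name in tsa.general_source_names
            if name in hits_by_source
        ]
        tsa_hits = tsa_annotate(
            sample_lengths, tsa.lineage, tsa.tshmm_sources, general,
            config.threshold, log,
        )
        for name, hits in tsa_hits.items():
            hits_by_source.setdefault(name, []).extend(hits)

    # metadata + corpus statistics for description weighting
    metadata: dict[str, dict[str, MetadataRecord]] = {}
    all_descriptions: list[str] = []
    for source in sorted(metadata_inputs):
        with open(metadata_inputs[source]) as fh:
            records = load_metadata(fh, source)
        metadata[source] = records
        for rec in records.values():
            all_descriptions.extend(rec.descriptions)
    corpus_stats = (
        CorpusStats.from_texts(all_descriptions) if all_descriptions else None
    )

    # group hits per query, then select + merge per query
    per_query: dict[str, dict[str, list[Hit]]] = {}
    for source, hits in hits_by_source.items():
        for h in hits:
            per_query.setdefault(h.query_id, {}).setdefault(source, []).append(h)

    queue = sorted(per_query)
    if config.workers > 1 and len(queue) > 1:
        # independent per-query tasks; worker output order does not matter,
        # results are merged back in query order
        import multiprocessing as mp

        with mp.Pool(config.workers) as pool:
            task_out = pool.map(
                _query_task,
                [
                    (qid, per_query[qid], metadata, config, corpus_stats)
                    for qid in queue
                ],
            )
        results = []
        for qr, task_log in sorted(task_out, key=lambda t: t[0].query_id):
            results.append(qr)
            log.extend(task_log)
    else:
        results = [
            _select_for_query(qid, per_query[qid], metadata, config, corpus_stats, log)
            for qid in queue
        ]
    n_annotated = sum(1 for r in results if r.consensus is not None)
    log.append(f"consensus: {n_annotated}/{total} sequences annotated")

    result = SampleResult(results=results, log=log)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_outputs(result, metadata, out_dir)
        result.out_dir = out_dir
    return result


# --- output files ------------------------------------------------------------

OUTPUT_COLUMNS = (
    "query_id", "source", "profile_id", "env_start", "env_end",
    "i_evalue", "full_evalue",
)
INTEGRATED_COLUMNS = OUTPUT_COLUMNS + ("identifiers", "description")
CONSENSUS_COLUMNS = (
    "query_id", "consensus_score", "is_approximate", "HMM_files",
    "identifiers", "descriptions",
)


def _fmt_ids(identifiers) -> str:
    return ";".join(f"{t}:{v}" for t, v in sorted(identifiers))


def write_outputs(
    result: SampleResult,
    metadata: Mapping[str, Mapping[str, MetadataRecord]],
    out_dir: Path,
) -> None:
    with open(out_dir / "output_annotation.tsv", "w") as raw, open(
        out_dir / "integrated_annotation.tsv", "w"
    ) as integ, open(out_dir / "consensus_annotation.tsv", "w") as cons:
        raw.write("\t".join(OUTPUT_COLUMNS) + "\n")
        integ.write("\t".join(INTEGRATED_COLUMNS) + "\n")
        cons.write("\t".join(CONSENSUS_COLUMNS) + "\n")
        for qr in result.results:
            for source in sorted(qr.per_source):
                for h in sorted(qr.per_source[source].hits, key=Hit.sort_key):
                    base = (
                        f"{h.query_id}\t{h.source}\t{h.profile_id}\t"
                        f"{h.env_start}\t{h.env_end}\t"
                        f"{_EVALUE_FMT.format(h.i_evalue)}\t"
                        f"{_EVALUE_FMT.format(h.full_evalue)}"
                    )
                    raw.write(base + "\n")
                    rec = metadata.get(source, {}).get(h.profile_id)
                    ids = _fmt_ids(rec.identifiers) if rec else ""
                    desc = " | ".join(rec.descriptions) if rec else ""
                    integ.write(f"{base}\t{ids}\t{desc}\n")
            if qr.consensus is not None:
                c = qr.consensus
                cons.write(
                    f"{c.query_id}\t{_SCORE_FMT.format(c.consensus_score)}\t"
                    f"{int(c.is_approximate)}\t{';'.join(c.sources)}\t"
                    f"{_fmt_ids(c.identifiers)}\t"
                    f"{' | '.join(c.descriptions)}\n"
                )
    with open(out_dir / "annotation.log", "w") as fh:
        for line in result.log:
            fh.write(line + "\n")


def read_consensus_tsv(stream: IO[str] | Iterable[str]) -> list[dict]:
    """Read ``consensus_annotation.tsv`` rows back into dictionaries with
    parsed identifier sets (used by the benchmark module)."""
    lines = iter(stream)
    header = next(lines, None)
    if header is None:
        return []
    cols = header.rstrip("\n").split("\t")
    if cols != list(CONSENSUS_COLUMNS):
        raise HitTableError(f"unexpected consensus header: {cols!r}")
    rows = []
    for line in lines:
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        ids = set()
        if fields[4]:
            for chunk in fields[4].split(";"):
                id_type, _, value = chunk.partition(":")
                ids.add((id_type, value))
        rows.append(
            {
                "query_id": fields[0],
                "consensus_score": float(fields[1]),
                "is_approximate": bool(int(fields[2])),
                "sources": fields[3].split(";") if fields[3] else [],
                "identifiers": ids,
                "descriptions": fields[5].split(" | ") if fields[5] else [],
            }
        )
    return rows
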