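"""Synthetic samples with planted ground truth.

Generates proteins, domain hits, metadata and reference annotations in the
exact formats the pipeline reads, so the whole engine is testable without
any reference-database download.  Sequences are random residues: only the
lengths and the hit geometry matter to the algorithms under test.

Planted signal and noise:

* each query gets a few mutually disjoint planted domains; every reference
  collection reports each planted domain as a hit with a strong e-value
  (log-uniform in [1e-30, 1e-6] by default);
* *local decoys* are strict sub-intervals of a planted domain with a weak
  e-value (log-uniform in [1e-5, 1e-3]); they conflict with their planted
  domain and are strictly dominated by it in every term of the combination
  score, so they act as pure distractors;
* *trap decoys* span the whole query with a weak e-value; they conflict with
  every planted hit and can genuinely outscore a fragmented architecture
  (total and average coverage 1), so recovery degrades as their rate grows.

Decoy presence is decided by comparing a per-site uniform draw to the decoy
rate, and all random quantities are drawn whether or not they are used, so
for a fixed seed the decoy sets at a lower rate are subsets of those at a
higher rate (recovery is deterministically monotone in the rate).

Cross-collection metadata for the same planted domain shares a KEGG ortholog
identifier with probability ``p_share`` and an identically-worded
description with probability ``p_text``, exercising both consensus evidence
paths.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .combine import HitCombination
from .hits import Hit, write_hits_tsv
from .metadata import AnnotatedHit, Identifier, MetadataRecord, write_metadata
from .workflow import plan_chunks

__all__ = [
    "DEFAULT_SOURCES",
    "PlantedDomain",
    "SyntheticSample",
    "generate_sample",
    "planted_recovery",
    "greedy_trap_instance",
    "fig7_instance",
    "Fig7Instance",
]

DEFAULT_SOURCES = ("pfam", "kofam", "tigrfam", "eggnog", "npfm")

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

_DESC_VOCAB = (
    "glucose degradation", "fatty acid oxidation", "dna replication",
    "rna polymerase subunit", "membrane transport", "cell wall synthesis",
    "amino acid biosynthesis", "electron transfer flavoprotein",
    "signal transduction histidine kinase", "ribosomal assembly factor",
)


def _log_uniform(rng: np.random.Generator, low: float, high: float) -> float:
    return float(10.0 ** rng.uniform(np.log10(low), np.log10(high)))


@dataclass
class PlantedDomain:
    """Ground truth for one planted domain of one query."""

    query_id: str
    index: int           # global domain index (keys identifiers/descriptions)
    start: int
    end: int
    shared_id: Identifier
    description: str


@dataclass
class SyntheticSample:
    """A generated sample plus its planted truth."""

    lengths: dict[str, int]
    sequences: dict[str, str]
    planted: dict[str, list[PlantedDomain]]
    hits_by_source: dict[str, list[Hit]]
    metadata_by_source: dict[str, dict[str, MetadataRecord]]
    reference: dict[str, set[Identifier]]
    seed: int
    decoy_rate: float

    # --- writers (the formats the pipeline reads) ---------------------------

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for qid in self.lengths:
                fh.write(f">{qid}\n{self.sequences[qid]}\n")

    def write_hits(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for source, hits in self.hits_by_source.items():
            path = directory / f"{source}.hits.tsv"
            with open(path, "w") as fh:
                write_hits_tsv(hits, fh)
            paths[source] = path
        return paths

    def write_chunked_hits(
        self, directory: str | Path, n_chunks: int
    ) -> dict[str, list[tuple[Path, int]]]:
        """Write per-chunk hit files whose e-values are on chunk scale, the
        way a per-chunk homology search would report them (sample-scale
        e-value times chunk_size / total)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        plan = plan_chunks(self.lengths, n_chunks)
        total = len(self.lengths)
        out: dict[str, list[tuple[Path, int]]] = {}
        for source, hits in self.hits_by_source.items():
            by_query: dict[str, list[Hit]] = {}
            for h in hits:
                by_query.setdefault(h.query_id, []).append(h)
            chunk_paths = []
            for ci, chunk in enumerate(plan.chunks):
                chunk_size = len(chunk)
                if chunk_size == 0:
                    continue
                factor = chunk_size / total
                chunk_hits = []
                for qid in chunk:
                    for h in by_query.get(qid, ()):
                        chunk_hits.append(
                            Hit(
                                query_id=h.query_id,
                                query_length=h.query_length,
                                source=h.source,
                                profile_id=h.profile_id,
                                env_start=h.env_start,
                                env_end=h.env_end,
                                i_evalue=h.i_evalue * factor,
                                full_evalue=h.full_evalue * factor,
                                bitscore=h.bitscore,
                            )
                        )
                path = directory / f"{source}.chunk{ci}.tsv"
                with open(path, "w") as fh:
                    write_hits_tsv(chunk_hits, fh)
                chunk_paths.append((path, chunk_size))
            out[source] = chunk_paths
        return out

    def write_metadata_files(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for source, records in self.metadata_by_source.items():
            path = directory / f"{source}.meta.tsv"
            with open(path, "w") as fh:
                write_metadata(records, fh)
            paths[source] = path
        return paths

    def write_lineage_table(
        self, path: str | Path, lineages: Mapping[str, list[str]]
    ) -> None:
        with open(path, "w") as fh:
            for taxon, lineage in lineages.items():
                fh.write(f"{taxon}\t{' '.join(lineage)}\n")

    def hits_tsv_text(self, source: str) -> str:
        buf = io.StringIO()
        write_hits_tsv(self.hits_by_source[source], buf)
        return buf.getvalue()


def generate_sample(
    n_queries: int = 50,
    domains_per_query: int = 3,
    n_sources: int = 3,
    decoy_rate: float = 0.0,
    seed: int = 0,
    p_share: float = 1.0,
    p_text: float = 0.5,
    planted_evalue_range: tuple[float, float] = (1e-30, 1e-6),
    decoy_evalue_range: tuple[float, float] = (1e-5, 1e-3),
    min_domain: int = 70,
    max_domain: int = 110,
) -> SyntheticSample:
    """Generate a deterministic sample with planted domain architectures.

    See the module docstring for the signal/noise model.  ``decoy_rate`` in
    [0, 1] controls both decoy kinds; 0 yields a noise-free sample in which
    the planted architecture is the unique best-scoring combination.

    The planted e-values of one query share a query-level base exponent with
    at most half a decade of per-hit jitter, and domain lengths stay within a
    factor of ~1.6 of each other; under the combination score these two
    conditions make every planted architecture strictly preferable to any of
    its proper subsets, so a noise-free sample has a unique optimum.
    """
    if not (0 <= decoy_rate <= 1):
        raise ValueError("decoy_rate must be in [0, 1]")
    if n_sources > len(DEFAULT_SOURCES):
        raise ValueError(f"at most {len(DEFAULT_SOURCES)} sources supported")
    rng = np.random.default_rng(seed)
    sources = DEFAULT_SOURCES[:n_sources]

    lengths: dict[str, int] = {}
    sequences: dict[str, str] = {}
    planted: dict[str, list[PlantedDomain]] = {}
    hits_by_source: dict[str, list[Hit]] = {s: [] for s in sources}
    metadata_by_source: dict[str, dict[str, MetadataRecord]] = {
        s: {} for s in sources
    }
    reference: dict[str, set[Identifier]] = {}

    gap = 10
    global_domain = 0
    for q in range(n_queries):
        qid = f"q{q:04d}"
        # place domains_per_query disjoint domains with gaps, then pad
        domain_lengths = rng.integers(min_domain, max_domain + 1, domains_per_query)
        needed = int(domain_lengths.sum()) + gap * (domains_per_query + 1)
        query_length = needed + int(rng.integers(0, 80))
        if query_length < needed:
            raise ValueError("infeasible domain geometry")
        lengths[qid] = query_length
        sequences[qid] = "".join(
            rng.choice(_RESIDUES, size=query_length)
        )
        domains: list[PlantedDomain] = []
        cursor = gap + 1
        ref_ids: set[Identifier] = set()
        # query-level significance base; per-hit jitter of +/- 0.25 decades
        lo = np.log10(planted_evalue_range[0])
        hi = np.log10(planted_evalue_range[1])
        base_exp = rng.uniform(lo + 0.25, hi - 0.25)
        for d in range(domains_per_query):
            dlen = int(domain_lengths[d])
            start, end = cursor, cursor + dlen - 1
            cursor = end + 1 + gap
            shared = ("kegg_ko", f"K{10000 + global_domain:05d}")
            desc = _DESC_VOCAB[global_domain % len(_DESC_VOCAB)]
            dom = PlantedDomain(
                query_id=qid, index=global_domain,
                start=start, end=end, shared_id=shared, description=desc,
            )
            domains.append(dom)
            global_domain += 1

            share_ids = rng.random() < p_share
            share_text = rng.random() < p_text
            for s_i, source in enumerate(sources):
                profile = f"{source}_p{dom.index:05d}"
                i_ev = float(10.0 ** (base_exp + rng.uniform(-0.25, 0.25)))
                hits_by_source[source].append(
                    Hit(
                        query_id=qid, query_length=query_length, source=source,
                        profile_id=profile, env_start=start, env_end=end,
                        i_evalue=i_ev, full_evalue=i_ev / 2,
                        bitscore=round(float(rng.uniform(50, 300)), 1),
                    )
                )
                own_id = _source_identifier(source, dom.index)
                ids = {own_id}
                if share_ids:
                    ids.add(shared)
                if share_text:
                    descs = [desc]
                else:
                    descs = [f"{desc} variant type {s_i}"]
                metadata_by_source[source][profile] = MetadataRecord(
                    profile_id=profile, source=source,
                    identifiers=ids, descriptions=descs,
                )
                ref_ids |= ids

                # local decoy: strict sub-interval of the planted domain,
                # weak e-value; strictly dominated, never selected
                # all decoy quantities are drawn whether used or not, so a
                # lower rate yields a subset of a higher rate's decoys
                u_local = rng.random()
                sub_len = max(10, dlen // 2)
                sub_start = start + int(rng.integers(0, dlen - sub_len + 1))
                decoy_ev = _log_uniform(rng, *decoy_evalue_range)
                decoy_bits = round(float(rng.uniform(5, 25)), 1)
                if u_local < decoy_rate:
                    hits_by_source[source].append(
                        Hit(
                            query_id=qid, query_length=query_length,
                            source=source,
                            profile_id=f"{source}_decoy{dom.index:05d}",
                            env_start=sub_start,
                            env_end=sub_start + sub_len - 1,
                            i_evalue=decoy_ev, full_evalue=decoy_ev,
                            bitscore=decoy_bits,
                        )
                    )
        planted[qid] = domains
        reference[qid] = ref_ids

        # trap decoy per (query, source): full-length, weak e-value
        for source in sources:
            u_trap = rng.random()
            trap_ev = _log_uniform(rng, *decoy_evalue_range)
            trap_bits = round(float(rng.uniform(5, 25)), 1)
            if u_trap < decoy_rate:
                hits_by_source[source].append(
                    Hit(
                        query_id=qid, query_length=query_length, source=source,
                        profile_id=f"{source}_trap{q:05d}",
                        env_start=1, env_end=query_length,
                        i_evalue=trap_ev, full_evalue=trap_ev,
                        bitscore=trap_bits,
                    )
                )
    return SyntheticSample(
        lengths=lengths, sequences=sequences, planted=planted,
        hits_by_source=hits_by_source, metadata_by_source=metadata_by_source,
        reference=reference, seed=seed, decoy_rate=decoy_rate,
    )


def _source_identifier(source: str, index: int) -> Identifier:
    if source == "pfam":
        return ("pfam", f"PF{10000 + index:05d}")
    if source == "tigrfam":
        return ("tigrfam", f"TIGR{10000 + index:05d}")
    if source == "kofam":
        return ("kegg_ko", f"K{40000 + index:05d}")
    if source == "eggnog":
        return ("cog_nog", f"ENOG{index:05d}")
    return ("custom", f"{source.upper()}{index:05d}")


def planted_recovery(
    sample: SyntheticSample,
    algorithm: str = "dfs",
    threshold: float = 1e-3,
    max_overlap: float = 0.10,
) -> float:
    """Fraction of planted (query, source, domain) hits recovered by the
    per-collection selection step."""
    from .combine import select_hits

    recovered = 0
    total = 0
    for source, hits in sample.hits_by_source.items():
        by_query: dict[str, list[Hit]] = {}
        for h in hits:
            by_query.setdefault(h.query_id, []).append(h)
        for qid, domains in sample.planted.items():
            combo = select_hits(
                by_query.get(qid, []), algorithm=algorithm,
                max_overlap=max_overlap, threshold=threshold,
            )
            selected = {(h.env_start, h.env_end) for h in combo.hits}
            for dom in domains:
                total += 1
                if (dom.start, dom.end) in selected:
                    recovered += 1
    return recovered / total if total else 0.0


# --- hand-built instances ----------------------------------------------------

def greedy_trap_instance() -> tuple[list[Hit], float]:
    """Three hits where the greedy choice is suboptimal.

    The most significant hit A sits across the middle of a 100-residue query
    and blocks the two flanking hits B and C, which together cover the whole
    sequence; the exhaustive search picks {B, C} while the greedy picks {A}
    and best-prediction-only also keeps a single hit.  Returns the hits and
    the acceptance threshold they were built for.
    """
    mk = lambda pid, s, e, ev: Hit(
        query_id="greedy_q", query_length=100, source="pfam", profile_id=pid,
        env_start=s, env_end=e, i_evalue=ev, full_evalue=ev,
    )
    return [
        mk("A", 25, 75, 1e-8),
        mk("B", 1, 50, 1e-7),
        mk("C", 51, 100, 1e-7),
    ], 1e-3


@dataclass
class Fig7Instance:
    """A reconstructed eight-hit inter-collection scenario.

    One query with hits A1..A8 from eight different collections.  Metadata
    links: M1-M2 share an identifier; M5-M6 have matching descriptions;
    M2-M7 and M6-M8 share identifiers, extending the chains; M4 shares an
    identifier with M1 but its hit overlaps A1 too little for an edge.  The
    combination {A1, A5} therefore has two members plus two directly
    consistent neighbours among eight hits (consistency 0.5), and expands
    through the chains to gather the metadata of M2, M6, M7 and M8.
    """

    hits: list[AnnotatedHit]
    combination: HitCombination
    expected_edges: set[tuple[int, int]]
    expected_hcn: float
    expected_expansion: set[int]  # indices of hits joining via expansion
    threshold: float = 1e-3


def fig7_instance() -> Fig7Instance:
    qid, qlen = "fig_q", 500

    def ah(idx, source, s, e, ev, ids, descs):
        hit = Hit(
            query_id=qid, query_length=qlen, source=source,
            profile_id=f"prof{idx}", env_start=s, env_end=e,
            i_evalue=ev, full_evalue=ev,
        )
        rec = MetadataRecord(
            profile_id=f"prof{idx}", source=source,
            identifiers=set(ids), descriptions=list(descs),
        )
        return AnnotatedHit(hit=hit, metadata=rec)

    hits = [
        # A1 and A5: the combination under scrutiny
        ah(1, "s1", 1, 100, 1e-20, {("pfam", "PF00001")},
           ["hexose phosphorylation"]),
        ah(2, "s2", 1, 100, 1e-8,
           {("pfam", "PF00001"), ("interpro", "IPR000001")},
           ["carbohydrate kinase"]),
        ah(3, "s3", 120, 180, 9e-4, set(), ["membrane transporter"]),
        # A4 shares PF00001 with M1 but overlaps A1 by only 41 residues
        ah(4, "s4", 60, 400, 1e-6, {("pfam", "PF00001")}, ["dna polymerase"]),
        ah(5, "s5", 201, 300, 1e-20, {("kegg_ko", "K99999")},
           ["glucose degradation"]),
        ah(6, "s6", 201, 300, 1e-8, {("go", "GO:0000001")},
           ["degradation of glucose"]),
        ah(7, "s7", 5, 100, 1e-8, {("interpro", "IPR000001")},
           ["atp synthase subunit"]),
        ah(8, "s8", 205, 300, 1e-8, {("go", "GO:0000001")},
           ["ribosomal assembly"]),
    ]
    combo = HitCombination(hits=(hits[0].hit, hits[4].hit))
    return Fig7Instance(
        hits=hits,
        combination=combo,
        expected_edges={(0, 1), (4, 5), (1, 6), (5, 7)},
        expected_hcn=0.5,
        expected_expansion={1, 5, 6, 7},
    )
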