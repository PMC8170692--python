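"""Hit ingestion: domtblout parsing, e-value rescaling and significance thresholds.

A *hit* is a single match between a reference profile (an HMM from a
collection such as Pfam or KOfam) and a region of a query protein.  HMMER's
``hmmsearch --domtblout`` output carries one row per domain hit; this module
turns those rows into :class:`Hit` records, rescales chunk-level e-values back
to the original sample size, and applies static or length-dependent
significance thresholds.

Coordinate convention: envelope coordinates are 1-based inclusive, exactly as
printed by HMMER.  ``hit_length = env_end - env_start + 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import IO, Iterable, Literal, Mapping

__all__ = [
    "EVALUE_FLOOR",
    "Hit",
    "ThresholdSpec",
    "HitTableError",
    "parse_domtblout",
    "rescale_evalue",
    "evalue_threshold_for",
    "filter_hits",
    "read_hits_tsv",
    "write_hits_tsv",
]

#: Smallest representable e-value; HMMER can print ``0.0`` which must be
#: clamped before any log10.
EVALUE_FLOOR = 1e-300

EvalueField = Literal["independent", "full_sequence"]


class HitTableError(ValueError):
    """Raised for malformed hit tables or inconsistent query lengths."""


@dataclass(frozen=True, slots=True)
class Hit:
    """One profile-sequence domain match.

    Parameters
    ----------
    query_id:
        Protein sequence identifier.
    query_length:
        Length of the query protein in residues.
    source:
        Reference collection the profile belongs to (e.g. ``"pfam"``).
    profile_id:
        Identifier of the matching profile.
    env_start, env_end:
        Envelope coordinates on the query, 1-based inclusive.
    i_evalue:
        Independent (per-domain) e-value; used by the DFS and heuristic
        selection algorithms.
    full_evalue:
        Full-sequence e-value; used by best-prediction-only selection.
    bitscore:
        Optional domain bit score.
    """

    query_id: str
    query_length: int
    source: str
    profile_id: str
    env_start: int
    env_end: int
    i_evalue: float
    full_evalue: float
    bitscore: float | None = None

    def __post_init__(self) -> None:
        if self.query_length < 1:
            raise HitTableError(
                f"query {self.query_id!r}: non-positive length {self.query_length}"
            )
        if not (1 <= self.env_start <= self.env_end <= self.query_length):
            raise HitTableError(
                f"query {self.query_id!r}: envelope {self.env_start}..{self.env_end} "
                f"outside 1..{self.query_length}"
            )
        # clamp zero e-values (HMMER may print 0.0); keep log10 finite
        if self.i_evalue <= 0:
            object.__setattr__(self, "i_evalue", EVALUE_FLOOR)
        if self.full_evalue <= 0:
            object.__setattr__(self, "full_evalue", EVALUE_FLOOR)

    @property
    def length(self) -> int:
        """Number of residues covered by the hit envelope."""
        return self.env_end - self.env_start + 1

    @property
    def coverage(self) -> float:
        """Fraction of the query covered by this hit."""
        return self.length / self.query_length

    def evalue(self, field: EvalueField = "independent") -> float:
        return self.i_evalue if field == "independent" else self.full_evalue

    def sort_key(self, field: EvalueField = "independent") -> tuple:
        """Deterministic ordering: better e-value, longer hit, leftmost
        start, then lexicographic profile and source ids."""
        return (self.evalue(field), -self.length, self.env_start,
                self.profile_id, self.source)


@dataclass(frozen=True, slots=True)
class ThresholdSpec:
    """Significance threshold, either a single static e-value or a
    query-length-dependent rule.

    The dynamic rule: below ``short_boundary`` residues the threshold is
    ``short_plateau``; above ``long_boundary`` it is ``long_plateau``; in
    between it follows ``10 ** (-length / 10)``.  Both boundaries take the
    formula branch (the formula is continuous with the long plateau at 250).
    """

    mode: Literal["static", "dynamic"] = "static"
    static_value: float = 1e-3
    short_boundary: int = 150
    long_boundary: int = 250
    short_plateau: float = 1e-10
    long_plateau: float = 1e-25

    def __post_init__(self) -> None:
        if self.static_value <= 0 or self.short_plateau <= 0 or self.long_plateau <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_string(cls, text: str) -> "ThresholdSpec":
        """Parse a CLI/config value: ``"dynamic"`` or a float literal."""
        text = text.strip().lower()
        if text == "dynamic":
            return cls(mode="dynamic")
        return cls(mode="static", static_value=float(text))


def evalue_threshold_for(query_length: int, spec: ThresholdSpec) -> float:
    """Significance threshold applicable to a query of the given length."""
    if query_length < 1:
        raise ValueError(f"query_length must be >= 1, got {query_length}")
    if spec.mode == "static":
        return spec.static_value
    if query_length < spec.short_boundary:
        return spec.short_plateau
    if query_length > spec.long_boundary:
        return spec.long_plateau
    return 10.0 ** (-query_length / 10.0)


def rescale_evalue(e_chunk: float, chunk_size: int, total_size: int) -> float:
    """Rescale an e-value computed on a chunk of ``chunk_size`` sequences to
    the full sample of ``total_size`` sequences.

    HMMER e-values are linear in the size of the searched target set, so the
    rescaling is a simple multiplication by ``total_size / chunk_size``.
    """
    if chunk_size < 1:
        raise ValueError(f"chunk_size must be >= 1, got {chunk_size}")
    if total_size < chunk_size:
        raise ValueError(
            f"total_size ({total_size}) smaller than chunk_size ({chunk_size})"
        )
    if e_chunk <= 0:
        e_chunk = EVALUE_FLOOR
    return e_chunk * (total_size / chunk_size)


def rescale_hit(hit: Hit, chunk_size: int, total_size: int) -> Hit:
    """Return a copy of *hit* with both e-values rescaled to sample scale."""
    if chunk_size == total_size:
        return hit
    return replace(
        hit,
        i_evalue=rescale_evalue(hit.i_evalue, chunk_size, total_size),
        full_evalue=rescale_evalue(hit.full_evalue, chunk_size, total_size),
    )


def filter_hits(
    hits: Iterable[Hit],
    spec: ThresholdSpec,
    evalue_field: EvalueField = "independent",
) -> list[Hit]:
    """Keep hits whose selected e-value is at or below the threshold for
    their query length.  Input order is preserved; a hit exactly at the
    threshold passes."""
    kept = []
    for h in hits:
        if h.evalue(evalue_field) <= evalue_threshold_for(h.query_length, spec):
            kept.append(h)
    return kept


# --- domtblout ---------------------------------------------------------------
# hmmsearch --domtblout column layout (whitespace-delimited, 23 columns):
#   0 target name (= protein)   2 tlen          3 query name (= profile)
#   6 full-sequence E-value    12 i-Evalue     13 domain score
#  19 env from                 20 env to
_MIN_COLUMNS = 22


def parse_domtblout(
    stream: IO[str] | Iterable[str],
    source: str,
    sample_lengths: Mapping[str, int],
) -> list[Hit]:
    """Parse an ``hmmsearch --domtblout`` table into :class:`Hit` records.

    ``sample_lengths`` must cover every protein appearing in the table; the
    table's own target-length column is cross-checked against it so that a
    mismatched sample/hit-file pair fails loudly.
    """
    hits: list[Hit] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < _MIN_COLUMNS:
            raise HitTableError(
                f"line {lineno}: expected >= {_MIN_COLUMNS} columns, got {len(fields)}"
            )
        query_id = fields[0]
        try:
            tlen = int(fields[2])
            full_evalue = float(fields[6])
            i_evalue = float(fields[12])
            bitscore = float(fields[13])
            env_start = int(fields[19])
            env_end = int(fields[20])
        except ValueError as exc:
            raise HitTableError(f"line {lineno}: malformed field ({exc})") from exc
        if not (math.isfinite(full_evalue) and math.isfinite(i_evalue)):
            raise HitTableError(f"line {lineno}: non-finite e-value")
        if query_id not in sample_lengths:
            raise HitTableError(
                f"line {lineno}: query {query_id!r} absent from the sample"
            )
        expected = sample_lengths[query_id]
        if tlen != expected:
            raise HitTableError(
                f"line {lineno}: query {query_id!r} length {tlen} in hit table "
                f"but {expected} in sample FASTA"
            )
        hits.append(
            Hit(
                query_id=query_id,
                query_length=expected,
                source=source,
                profile_id=fields[3],
                env_start=env_start,
                env_end=env_end,
                i_evalue=i_evalue,
                full_evalue=full_evalue,
                bitscore=bitscore,
            )
        )
    return hits


# --- internal hits TSV -------------------------------------------------------

_TSV_COLUMNS = (
    "query_id", "query_length", "source", "profile_id",
    "env_start", "env_end", "i_evalue", "full_evalue", "bitscore",
)


def write_hits_tsv(hits: Iterable[Hit], stream: IO[str]) -> None:
    """Write hits in the internal tab-separated dialect (round-trips exactly)."""
    stream.write("\t".join(_TSV_COLUMNS) + "\n")
    for h in hits:
        bit = "" if h.bitscore is None else repr(h.bitscore)
        stream.write(
            f"{h.query_id}\t{h.query_length}\t{h.source}\t{h.profile_id}\t"
            f"{h.env_start}\t{h.env_end}\t{h.i_evalue!r}\t{h.full_evalue!r}\t{bit}\n"
        )


def read_hits_tsv(
    stream: IO[str] | Iterable[str],
    source: str | None = None,
    sample_lengths: Mapping[str, int] | None = None,
) -> list[Hit]:
    """Read the internal hits TSV.  If *source* is given it overrides the
    file's source column; *sample_lengths*, when given, is cross-checked."""
    hits: list[Hit] = []
    lines = iter(stream)
    try:
        header = next(lines)
    except StopIteration:
        return hits
    cols = header.rstrip("\n").split("\t")
    if cols[: len(_TSV_COLUMNS)] != list(_TSV_COLUMNS):
        raise HitTableError(f"unexpected hits TSV header: {cols!r}")
    for lineno, line in enumerate(lines, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < len(_TSV_COLUMNS) - 1:
            raise HitTableError(f"line {lineno}: too few columns")
        try:
            query_length = int(fields[1])
            env_start = int(fields[4])
            env_end = int(fields[5])
            i_evalue = float(fields[6])
            full_evalue = float(fields[7])
            bitscore = (
                float(fields[8]) if len(fields) > 8 and fields[8] != "" else None
            )
        except ValueError as exc:
            raise HitTableError(f"line {lineno}: malformed field ({exc})") from exc
        if sample_lengths is not None:
            if fields[0] not in sample_lengths:
                raise HitTableError(
                    f"line {lineno}: query {fields[0]!r} absent from the sample"
                )
            if sample_lengths[fields[0]] != query_length:
                raise HitTableError(
                    f"line {lineno}: query length mismatch for {fields[0]!r}"
                )
        hits.append(
            Hit(
                query_id=fields[0],
                query_length=query_length,
                source=source if source is not None else fields[2],
                profile_id=fields[3],
                env_start=env_start,
                env_end=env_end,
                i_evalue=i_evalue,
                full_evalue=full_evalue,
                bitscore=bitscore,
            )
        )
    return hits
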