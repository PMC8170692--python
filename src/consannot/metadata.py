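"""Functional metadata: typed identifiers, descriptions and metadata quality.

Each reference profile may carry database identifiers (KEGG orthologs, EC
numbers, Pfam/TIGRFAM accessions, GO and InterPro terms, ...) and free-text
functional descriptions.  The metadata file format is a tagged TSV: the first
column is the profile id, every further column is ``tag:value`` (e.g.
``kegg_ko:K00844`` or ``description:Responsible for glucose degradation``).
Unknown tags are kept as ``custom`` identifiers.

Metadata quality (MQ) summarises how informative a hit's metadata is:
0.25 with neither identifiers nor description, 0.5 with a description only,
0.75 with identifiers only, 1 with both.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .hits import Hit

__all__ = [
    "ID_TYPES",
    "MetadataRecord",
    "AnnotatedHit",
    "SourceWeights",
    "MetadataError",
    "load_metadata",
    "write_metadata",
    "extract_ids_from_text",
    "metadata_quality",
    "is_junk_description",
    "annotate_hits",
]

ID_TYPES = (
    "kegg_ko", "enzyme_ec", "pfam", "tigrfam", "go",
    "interpro", "uniprot", "cog_nog", "custom",
)

Identifier = tuple[str, str]  # (id_type, value)


class MetadataError(ValueError):
    """Raised for malformed metadata tables."""


# patterns for identifiers embedded in free text; covers every id type named
# by the default reference collections
_ID_PATTERNS: tuple[tuple[str, re.Pattern[str]], ...] = (
    ("kegg_ko", re.compile(r"\bK\d{5}\b")),
    # no trailing \b: partial EC numbers may end in '-' (a non-word char)
    ("enzyme_ec", re.compile(r"\bEC[: ]?([\d-]+\.[\d-]+\.[\d-]+\.[\d-]+)")),
    ("pfam", re.compile(r"\bPF\d{5}\b")),
    ("tigrfam", re.compile(r"\bTIGR\d{5}\b")),
    ("go", re.compile(r"\bGO:\d{7}\b")),
    ("interpro", re.compile(r"\bIPR\d{6}\b")),
)

_JUNK_PHRASES = frozenset(
    {"unknown function", "uncharacterized protein", "hypothetical protein"}
)
_DUF_RE = re.compile(r"^(duf\d+|domain[ -]?of[ -]?unknown[ -]?function.*)$")


def normalize_identifier(id_type: str, value: str) -> Identifier:
    """Canonical identifier form: surrounding punctuation stripped, prefixed
    accessions upper-cased; EC numbers kept verbatim (no wildcard matching)."""
    value = value.strip().strip(".,;()[]")
    if id_type == "enzyme_ec":
        value = value.removeprefix("EC:").removeprefix("EC ").removeprefix("ec:")
    elif id_type in ("kegg_ko", "pfam", "tigrfam", "go", "interpro", "uniprot"):
        value = value.upper()
    return (id_type, value)


@dataclass
class MetadataRecord:
    """Identifiers and descriptions attached to one reference profile."""

    profile_id: str
    source: str
    identifiers: set[Identifier] = field(default_factory=set)
    descriptions: list[str] = field(default_factory=list)

    def merged_with(self, other: "MetadataRecord") -> "MetadataRecord":
        descs = list(self.descriptions)
        for d in other.descriptions:
            if d not in descs:
                descs.append(d)
        return MetadataRecord(
            profile_id=self.profile_id,
            source=self.source,
            identifiers=self.identifiers | other.identifiers,
            descriptions=descs,
        )

    def informative_descriptions(self) -> list[str]:
        return [d for d in self.descriptions if not is_junk_description(d)]

    def all_identifiers(self) -> set[Identifier]:
        """Explicit identifiers plus those extracted from the descriptions."""
        ids = set(self.identifiers)
        for d in self.descriptions:
            ids |= extract_ids_from_text(d)
        return ids


@dataclass
class AnnotatedHit:
    """A hit paired with its profile's metadata and cached MQ score."""

    hit: Hit
    metadata: MetadataRecord
    mq: float = 0.25

    def __post_init__(self) -> None:
        self.mq = metadata_quality(self)


@dataclass
class SourceWeights:
    """Per-collection reliability weights used by the consensus score.

    Defaults reflect curation level and annotation completeness of the
    default collections; unknown collections get ``default`` (0.7).
    """

    weights: dict[str, float] = field(
        default_factory=lambda: {
            "eggnog": 0.8,
            "pfam": 0.9,
            "npfm": 0.7,
            "kofam": 0.7,
            "tigrfam": 0.5,
        }
    )
    default: float = 0.7

    def __post_init__(self) -> None:
        for name, w in self.weights.items():
            if not (0 < w <= 1):
                raise ValueError(f"weight for {name!r} must be in (0, 1]: {w}")
        if not (0 < self.default <= 1):
            raise ValueError("default weight must be in (0, 1]")

    def __getitem__(self, source: str) -> float:
        return self.weights.get(source, self.default)


def extract_ids_from_text(text: str) -> set[Identifier]:
    """Pull database identifiers out of free text with regular expressions."""
    found: set[Identifier] = set()
    for id_type, pattern in _ID_PATTERNS:
        for m in pattern.finditer(text):
            value = m.group(1) if pattern.groups else m.group(0)
            found.add(normalize_identifier(id_type, value))
    return found


def is_junk_description(text: str) -> bool:
    """True for uninformative descriptions: the standard placeholder phrases
    and Pfam domain-of-unknown-function (DUF) labels."""
    t = text.strip().strip(".").lower()
    return t in _JUNK_PHRASES or bool(_DUF_RE.match(t))


def metadata_quality(annotated: "AnnotatedHit | MetadataRecord") -> float:
    """MQ score in {0.25, 0.5, 0.75, 1} from identifier/description presence."""
    record = annotated.metadata if isinstance(annotated, AnnotatedHit) else annotated
    has_ids = bool(record.identifiers)
    has_desc = bool(record.informative_descriptions())
    if has_ids and has_desc:
        return 1.0
    if has_ids:
        return 0.75
    if has_desc:
        return 0.5
    return 0.25


def load_metadata(
    stream: IO[str] | Iterable[str], source: str
) -> dict[str, MetadataRecord]:
    """Read a tagged metadata TSV into per-profile records.

    Rows for the same profile are merged (identifier union, description
    concatenation).  A field without a ``tag:`` prefix is an error.
    """
    records: dict[str, MetadataRecord] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        profile_id = fields[0].strip()
        if not profile_id:
            raise MetadataError(f"line {lineno}: empty profile id")
        record = MetadataRecord(profile_id=profile_id, source=source)
        for raw in fields[1:]:
            raw = raw.strip()
            if not raw:
                continue
            tag, sep, value = raw.partition(":")
            if not sep or not value:
                raise MetadataError(
                    f"line {lineno}: untagged metadata field {raw!r}"
                )
            tag = tag.strip().lower()
            if tag == "description":
                record.descriptions.append(value.strip())
            elif tag in ID_TYPES:
                record.identifiers.add(normalize_identifier(tag, value))
            else:
                # unknown tags are preserved as namespaced custom ids
                record.identifiers.add(
                    normalize_identifier("custom", f"{tag}:{value.strip()}")
                )
        if profile_id in records:
            records[profile_id] = records[profile_id].merged_with(record)
        else:
            records[profile_id] = record
    return records


def write_metadata(records: Mapping[str, MetadataRecord], stream: IO[str]) -> None:
    """Write records back to the tagged-TSV dialect (sorted, reproducible)."""
    for profile_id in sorted(records):
        rec = records[profile_id]
        parts = [profile_id]
        for id_type, value in sorted(rec.identifiers):
            parts.append(f"{id_type}:{value}")
        for d in rec.descriptions:
            parts.append(f"description:{d}")
        stream.write("\t".join(parts) + "\n")


def annotate_hits(
    hits: Iterable[Hit],
    metadata: Mapping[str, Mapping[str, MetadataRecord]],
) -> list[AnnotatedHit]:
    """Attach metadata to hits; ``metadata`` maps source -> profile -> record.
    Hits whose profile has no metadata get an empty record (MQ 0.25)."""
    out: list[AnnotatedHit] = []
    for h in hits:
        record = metadata.get(h.source, {}).get(h.profile_id)
        if record is None:
            record = MetadataRecord(profile_id=h.profile_id, source=h.source)
        out.append(AnnotatedHit(hit=h, metadata=record))
    return out
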