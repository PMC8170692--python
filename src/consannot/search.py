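"""Optional homology-search adapter.

The engine normally consumes precomputed hit tables; this adapter produces
them by shelling out to ``hmmsearch`` when profile files are available.  It
writes one FASTA per sample chunk, searches each chunk, and returns per-chunk
domtblout paths together with chunk sizes so the caller can rescale e-values
to the full sample size.
"""

from __future__ import annotations

import shutil
import subprocess
from pathlib import Path
from typing import Mapping

from .workflow import ChunkPlan

__all__ = ["hmmsearch_available", "search_sample"]


def hmmsearch_available() -> bool:
    return shutil.which("hmmsearch") is not None


def search_sample(
    fasta: str | Path,
    profile_files: Mapping[str, str | Path],
    plan: ChunkPlan,
    work_dir: str | Path,
) -> dict[str, list[tuple[Path, int]]]:
    """Run ``hmmsearch --domtblout`` per collection per chunk.

    Returns ``source -> [(domtblout path, chunk size), ...]`` in the shape
    :func:`consannot.workflow.run_sample` accepts for chunked hit inputs.
    Raises ``RuntimeError`` if the search tool is missing or fails.
    """
    if not hmmsearch_available():
        raise RuntimeError("hmmsearch not found on PATH")
    from Bio import SeqIO

    work_dir = Path(work_dir)
    work_dir.mkdir(parents=True, exist_ok=True)
    records = {rec.id: rec for rec in SeqIO.parse(str(fasta), "fasta")}

    chunk_fastas: list[tuple[Path, int]] = []
    for ci, chunk in enumerate(plan.chunks):
        if not chunk:
            continue
        path = work_dir / f"chunk{ci}.faa"
        with open(path, "w") as fh:
            for qid in chunk:
                fh.write(f">{qid}\n{records[qid].seq}\n")
        chunk_fastas.append((path, len(chunk)))

    out: dict[str, list[tuple[Path, int]]] = {}
    for source, profile in profile_files.items():
        per_chunk: list[tuple[Path, int]] = []
        for chunk_fasta, chunk_size in chunk_fastas:
            dom = work_dir / f"{source}.{chunk_fasta.stem}.domtblout"
            proc = subprocess.run(
                ["hmmsearch", "--domtblout", str(dom), str(profile),
                 str(chunk_fasta)],
                capture_output=True, text=True,
            )
            if proc.returncode != 0:
                raise RuntimeError(
                    f"hmmsearch failed for {source}: {proc.stderr.strip()}"
                )
            per_chunk.append((dom, chunk_size))
        out[source] = per_chunk
    return out
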