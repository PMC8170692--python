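"""Annotation benchmarking: confusion-matrix scoring and the paired
randomized-subset algorithm comparison.

Predictions are compared to reference annotations at the whole-sequence
level through database-identifier intersection.  Per sequence:

* TP — prediction and reference share at least one identifier;
* FP — both present but no identifier shared;
* FN — reference present, no prediction;
* TN — neither present;
* PNA — reference absent or uninformative (placeholder description / DUF)
  but a prediction exists: a potentially new annotation, excluded from
  precision/recall and counted only in coverage.

An annotation without identifiers counts as absent (descriptions are not
compared).  A sequence with an uninformative reference and no prediction
belongs to no confusion class (it still counts in the sample size).

precision = TP/(TP+FP), recall = TP/(TP+FN), F1 the harmonic mean, and
annotation coverage = (TP+FP+PNA)/total sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "classify_sequence",
    "tally",
    "metrics",
    "paired_subset_comparison",
    "read_annotation_table",
    "write_metrics_tsv",
]

Ids = "frozenset | set | None"

CLASSES = ("TP", "FP", "FN", "TN", "PNA", "EXCLUDED")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    pna: int = 0
    total_seqs: int = 0

    def __post_init__(self) -> None:
        counted = self.tp + self.fp + self.fn + self.tn + self.pna
        if counted > self.total_seqs:
            raise ValueError(
                f"classified sequences ({counted}) exceed total_seqs "
                f"({self.total_seqs})"
            )


def classify_sequence(
    reference: "set | frozenset | None",
    predicted: "set | frozenset | None",
    reference_junk: bool = False,
) -> str:
    """Assign one confusion class to a (reference, prediction) pair.

    ``reference`` / ``predicted`` are identifier sets; ``None`` or an empty
    set means no (identifier-bearing) annotation.  ``reference_junk`` marks a
    reference whose only content was uninformative, which is treated as
    absent but, combined with a prediction, yields PNA; without a prediction
    the sequence is excluded from the matrix.
    """
    has_ref = bool(reference) and not reference_junk
    has_pred = bool(predicted)
    if has_ref and has_pred:
        return "TP" if set(reference) & set(predicted) else "FP"
    if has_ref:
        return "FN"
    if has_pred:
        return "PNA"
    return "EXCLUDED" if reference_junk else "TN"


def tally(
    pairs: Iterable[tuple["set | None", "set | None", bool]]
) -> ConfusionCounts:
    """Count classes over (reference, predicted, reference_junk) triples."""
    counts = ConfusionCounts()
    for reference, predicted, junk in pairs:
        counts.total_seqs += 1
        cls = classify_sequence(reference, predicted, junk)
        if cls == "TP":
            counts.tp += 1
        elif cls == "FP":
            counts.fp += 1
        elif cls == "FN":
            counts.fn += 1
        elif cls == "TN":
            counts.tn += 1
        elif cls == "PNA":
            counts.pna += 1
    return counts


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """precision, recall, F1 and annotation coverage; any zero denominator
    yields 0 by convention."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    coverage = (
        (tp + fp + counts.pna) / counts.total_seqs if counts.total_seqs else 0.0
    )
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "coverage": coverage,
    }


def paired_subset_comparison(
    per_seq_results: Mapping[str, Sequence[tuple["set | None", "set | None", bool]]],
    n_subsets: int,
    subset_size: int,
    seed: int,
) -> dict:
    """Compare algorithms on identical random subsets of the same sequences.

    ``per_seq_results`` maps algorithm name to per-sequence
    (reference, predicted, reference_junk) triples, aligned across
    algorithms.  Draws ``n_subsets`` random subsets (the same indices for
    every algorithm), computes the F1 score per subset per algorithm, and
    applies the Wilcoxon signed-rank test to each algorithm pair.

    Returns ``{"f1": {algo: array}, "p_values": {(a, b): p}}``.  When all
    paired differences are zero the test is degenerate and reported as no
    difference (p = 1).
    """
    algos = sorted(per_seq_results)
    if len(algos) < 2:
        raise ValueError("need results for at least two algorithms")
    sizes = {len(per_seq_results[a]) for a in algos}
    if len(sizes) != 1:
        raise ValueError("per-sequence results must be aligned across algorithms")
    population = sizes.pop()
    if subset_size > population:
        raise ValueError(
            f"subset_size ({subset_size}) exceeds population ({population})"
        )
    rng = np.random.default_rng(seed)
    subsets = [
        rng.choice(population, size=subset_size, replace=False)
        for _ in range(n_subsets)
    ]
    f1: dict[str, np.ndarray] = {}
    for algo in algos:
        rows = per_seq_results[algo]
        f1[algo] = np.array(
            [metrics(tally(rows[i] for i in idx))["f1"] for idx in subsets]
        )
    p_values: dict[tuple[str, str], float] = {}
    for i, a in enumerate(algos):
        for b in algos[i + 1:]:
            diff = f1[a] - f1[b]
            if np.all(diff == 0):
                p_values[(a, b)] = 1.0
            else:
                p_values[(a, b)] = float(stats.wilcoxon(f1[a], f1[b]).pvalue)
    return {"f1": f1, "p_values": p_values}


# --- annotation tables -------------------------------------------------------

def read_annotation_table(stream: IO[str] | Iterable[str]) -> dict[str, dict]:
    """Read an annotation table in the consensus schema into
    ``query_id -> {"identifiers": set, "junk_only": bool}`` (the form the
    classifier consumes).  Descriptions are only inspected to spot
    junk-only annotations."""
    from .metadata import is_junk_description
    from .workflow import read_consensus_tsv

    out: dict[str, dict] = {}
    for row in read_consensus_tsv(stream):
        descs = row["descriptions"]
        informative = [d for d in descs if not is_junk_description(d)]
        out[row["query_id"]] = {
            "identifiers": row["identifiers"],
            "junk_only": bool(descs) and not informative and not row["identifiers"],
        }
    return out


def write_metrics_tsv(results: Mapping[str, Mapping[str, float]], stream: IO[str]) -> None:
    """Write one metrics row per labelled run."""
    stream.write("run\tprecision\trecall\tf1\tcoverage\n")
    for name in sorted(results):
        m = results[name]
        stream.write(
            f"{name}\t{m['precision']:.6g}\t{m['recall']:.6g}\t"
            f"{m['f1']:.6g}\t{m['coverage']:.6g}\n"
        )
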