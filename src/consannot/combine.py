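"""Selection of the best set of non-overlapping hits per query.

Three algorithms operate over the hits of one query:

* ``dfs`` — exhaustive depth-first search over all subsets of mutually
  compatible hits (pairwise residue overlap at most 10% of the shorter hit by
  default), ranked by the combination score TC x HC x CE, with a budgeted
  fallback to the greedy heuristic;
* ``heuristic`` — greedy: repeatedly take the most significant remaining hit
  compatible with everything already selected;
* ``bpo`` — best prediction only: the single hit with the lowest
  full-sequence e-value.

The combination score is the product of three terms in [0, 1]:

* TC (total coverage): non-redundant residues covered by the combination,
  divided by the query length;
* HC (average hit coverage): mean of hit_length / query_length over the
  combination, favouring few large hits over many small ones;
* CE (combination e-value): each hit's independent e-value is log10-scaled
  and then min-max scaled between the best (lowest) e-value observed for the
  query and the acceptance threshold, and the scaled values are averaged.
"""

from __future__ import annotations

import itertools
import math
import time
from dataclasses import dataclass

from .hits import EVALUE_FLOOR, EvalueField, Hit

__all__ = [
    "HitCombination",
    "SearchBudget",
    "overlap_allowed",
    "residue_overlap",
    "enumerate_combinations",
    "score_combination",
    "find_best_combination_dfs",
    "heuristic_select",
    "bpo_select",
    "select_hits",
]

DEFAULT_MAX_OVERLAP = 0.10


@dataclass
class HitCombination:
    """A set of mutually compatible hits of one query with cached scores."""

    hits: tuple[Hit, ...]
    tc: float = 0.0
    hc: float = 0.0
    ce: float = 0.0
    score: float = 0.0
    is_approximate: bool = False

    def __len__(self) -> int:
        return len(self.hits)

    def __bool__(self) -> bool:
        return bool(self.hits)

    @property
    def query_id(self) -> str | None:
        return self.hits[0].query_id if self.hits else None

    def tie_key(self) -> tuple:
        """Deterministic ranking key among equal-score combinations."""
        return tuple(sorted(h.sort_key() for h in self.hits))


@dataclass
class SearchBudget:
    """Limits on the DFS.  ``node_budget`` (explored nodes) gives bit-exact
    reproducibility; ``time_limit`` is the wall-clock fallback trigger."""

    time_limit: float = 60.0
    node_budget: int | None = None

    def __post_init__(self) -> None:
        if self.time_limit <= 0:
            raise ValueError("time_limit must be positive")
        if self.node_budget is not None and self.node_budget <= 0:
            raise ValueError("node_budget must be positive when set")


def residue_overlap(a: Hit, b: Hit) -> int:
    """Number of residues shared by the two hit envelopes."""
    return max(0, min(a.env_end, b.env_end) - max(a.env_start, b.env_start) + 1)


def overlap_allowed(a: Hit, b: Hit, max_overlap: float = DEFAULT_MAX_OVERLAP) -> bool:
    """True when two hits may coexist in a combination: their shared residues
    are at most ``max_overlap`` of the shorter hit."""
    if a.query_id != b.query_id:
        raise ValueError(
            f"hits on different queries: {a.query_id!r} vs {b.query_id!r}"
        )
    return residue_overlap(a, b) <= max_overlap * min(a.length, b.length)


def _compatible_with_all(h: Hit, selected: list[Hit], max_overlap: float) -> bool:
    return all(overlap_allowed(h, s, max_overlap) for s in selected)


def enumerate_combinations(
    hits: list[Hit], max_overlap: float = DEFAULT_MAX_OVERLAP
) -> list[HitCombination]:
    """Every non-empty subset whose pairs all satisfy the overlap constraint.

    Brute-force powerset filter; the testing/oracle path for the DFS.  The
    count obeys 2^N - X - 1 with X the number of infeasible subsets.
    """
    out: list[HitCombination] = []
    for r in range(1, len(hits) + 1):
        for subset in itertools.combinations(hits, r):
            if all(
                overlap_allowed(a, b, max_overlap)
                for a, b in itertools.combinations(subset, 2)
            ):
                out.append(HitCombination(hits=subset))
    return out


def _scaled_significance(
    log_e: float, log_best: float, log_threshold: float
) -> float:
    # min-max between the query's best hit (-> 1) and the threshold (-> 0)
    if log_best >= log_threshold:
        return 1.0
    s = (log_threshold - log_e) / (log_threshold - log_best)
    return min(1.0, max(0.0, s))


def score_combination(
    c: HitCombination,
    context_hits: list[Hit],
    threshold: float,
    evalue_field: EvalueField = "independent",
) -> float:
    """Compute and cache TC, HC, CE and the combination score of *c*.

    ``context_hits`` are all candidate hits of the same query; they set the
    min-max frame of the CE term (the best e-value among them maps to 1, the
    acceptance threshold to 0).
    """
    if not c.hits:
        raise ValueError("cannot score an empty combination")
    query_length = c.hits[0].query_length
    covered: set[int] = set()
    for h in c.hits:
        covered.update(range(h.env_start, h.env_end + 1))
    c.tc = len(covered) / query_length
    c.hc = sum(h.length / h.query_length for h in c.hits) / len(c.hits)

    log_threshold = math.log10(max(threshold, EVALUE_FLOOR))
    log_best = min(
        math.log10(max(h.evalue(evalue_field), EVALUE_FLOOR)) for h in context_hits
    )
    c.ce = sum(
        _scaled_significance(
            math.log10(max(h.evalue(evalue_field), EVALUE_FLOOR)),
            log_best,
            log_threshold,
        )
        for h in c.hits
    ) / len(c.hits)
    c.score = c.tc * c.hc * c.ce
    return c.score


class BudgetExhausted(Exception):
    """Internal: DFS ran out of nodes/time before exhausting the space."""


def _dfs_best(
    hits: list[Hit],
    max_overlap: float,
    score_fn,
    budget: SearchBudget,
) -> HitCombination:
    """Iterative DFS over all feasible subsets, keeping the best-scoring one.

    Raises :class:`BudgetExhausted` when the node or time budget runs out.
    An explicit stack is used so deep architectures cannot hit the recursion
    limit.
    """
    order = sorted(hits, key=Hit.sort_key)
    n = len(order)
    # precompute pairwise compatibility
    compat = [[overlap_allowed(order[i], order[j], max_overlap) for j in range(n)]
              for i in range(n)]
    best: HitCombination | None = None
    nodes = 0
    deadline = time.monotonic() + budget.time_limit
    # stack holds (members, next index to try); each pushed state is one
    # explored node (a feasible non-empty combination)
    stack: list[tuple[list[int], int]] = [([i], i + 1) for i in reversed(range(n))]
    while stack:
        nodes += 1
        if budget.node_budget is not None and nodes > budget.node_budget:
            raise BudgetExhausted
        if nodes % 4096 == 0 and time.monotonic() > deadline:
            raise BudgetExhausted
        members, start = stack.pop()
        combo = HitCombination(hits=tuple(order[i] for i in members))
        score = score_fn(combo)
        if (
            best is None
            or score > best.score
            or (score == best.score and combo.tie_key() < best.tie_key())
        ):
            best = combo
        for j in reversed(range(start, n)):
            if all(compat[i][j] for i in members):
                stack.append((members + [j], j + 1))
    if best is None:
        return HitCombination(hits=())
    return best


def find_best_combination_dfs(
    hits: list[Hit],
    max_overlap: float = DEFAULT_MAX_OVERLAP,
    budget: SearchBudget | None = None,
    threshold: float = 1e-3,
) -> HitCombination:
    """Best-scoring feasible combination by exhaustive DFS.

    Falls back to the greedy heuristic (marking the result approximate) if
    the search budget is exhausted first.
    """
    if not hits:
        return HitCombination(hits=())
    budget = budget or SearchBudget()

    def score_fn(c: HitCombination) -> float:
        return score_combination(c, hits, threshold)

    try:
        return _dfs_best(hits, max_overlap, score_fn, budget)
    except BudgetExhausted:
        fallback = heuristic_select(hits, max_overlap)
        if fallback.hits:
            score_combination(fallback, hits, threshold)
        fallback.is_approximate = True
        return fallback


def heuristic_select(
    hits: list[Hit], max_overlap: float = DEFAULT_MAX_OVERLAP
) -> HitCombination:
    """Greedy selection: iteratively add the most significant remaining hit
    (lowest independent e-value) that is compatible with all selected hits."""
    selected: list[Hit] = []
    for h in sorted(hits, key=Hit.sort_key):
        if _compatible_with_all(h, selected, max_overlap):
            selected.append(h)
    return HitCombination(hits=tuple(selected))


def bpo_select(hits: list[Hit]) -> HitCombination:
    """Best prediction only: the single hit with the lowest full-sequence
    e-value (ties broken deterministically)."""
    if not hits:
        return HitCombination(hits=())
    best = min(hits, key=lambda h: h.sort_key("full_sequence"))
    return HitCombination(hits=(best,))


def select_hits(
    hits: list[Hit],
    algorithm: str = "dfs",
    max_overlap: float = DEFAULT_MAX_OVERLAP,
    budget: SearchBudget | None = None,
    threshold: float = 1e-3,
) -> HitCombination:
    """Dispatch on the algorithm name ({'dfs', 'heuristic', 'bpo'}) and
    return a scored combination."""
    if algorithm == "dfs":
        return find_best_combination_dfs(hits, max_overlap, budget, threshold)
    if algorithm == "heuristic":
        combo = heuristic_select(hits, max_overlap)
    elif algorithm == "bpo":
        combo = bpo_select(hits)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if combo.hits:
        score_combination(combo, hits, threshold)
    return combo
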