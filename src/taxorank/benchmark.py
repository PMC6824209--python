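"""Annotation-performance metrics before and after taxonomic re-ranking.

Correctness is judged at rank 1 by short-InChIKey comparison (stereochemistry
is deliberately ignored): a true positive is a query whose top-ranked
candidate is the known structure, a false negative a query whose known
structure sits at a lower rank, and queries whose known structure never
appears among the candidates are counted apart so both precision conventions
stay computable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .io import CandidateRecord, QueryRecord
from .scoring import ScoredCandidate, score_pipeline
from .taxonomy import WeightVector

__all__ = [
    "ConfusionCounts",
    "Prf",
    "OverlapSummary",
    "BenchmarkReport",
    "rank_of_correct",
    "confusion_counts",
    "precision_recall_f1",
    "overlap_summary",
    "topk_recall_curve",
    "run_benchmark",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Rank-1 confusion counts over a set of queries with candidates.

    ``tp + fp`` equals the number of queries that returned any candidate;
    ``absent`` (no correct candidate at any rank) is excluded from ``fn``.
    """

    tp: int = 0
    fp: int = 0
    fn: int = 0
    absent: int = 0

    @property
    def n_queries_with_candidates(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class Prf:
    """Precision/recall/F1 triple; ``degenerate`` flags 0/0 divisions."""

    precision: float
    recall: float
    f1: float
    degenerate: bool = False


def rank_of_correct(
    ranked_candidates: Sequence[ScoredCandidate],
    true_short_ik: str,
    use_final: bool = True,
) -> int | None:
    """1-based rank of the correct structure in one query's candidate list.

    Returns the (initial or final) rank of the first candidate whose short
    InChIKey equals the truth, or None when the correct structure is absent.
    """
    best: int | None = None
    for c in ranked_candidates:
        if c.short_ik != true_short_ik:
            continue
        rank = c.final_rank if use_final else c.initial_rank
        if rank is None:
            raise ValueError("candidates must carry ranks; run the pipeline first")
        if best is None or rank < best:
            best = rank
    return best


def confusion_counts(per_query_ranks: Sequence[int | None]) -> ConfusionCounts:
    """Aggregate per-query correct-structure ranks into confusion counts."""
    tp = sum(1 for r in per_query_ranks if r == 1)
    fn = sum(1 for r in per_query_ranks if r is not None and r > 1)
    absent = sum(1 for r in per_query_ranks if r is None)
    fp = len(per_query_ranks) - tp
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, absent=absent)


def precision_recall_f1(c: ConfusionCounts) -> Prf:
    """Precision, recall and their harmonic mean from rank-1 confusion counts.

    0/0 divisions (no queries, or no hits at all) return 0 with the
    ``degenerate`` flag set rather than raising.
    """
    degenerate = False
    if c.tp + c.fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = c.tp / (c.tp + c.fn)
    if precision + recall == 0:
        return Prf(precision, recall, 0.0, True)
    f1 = 2 * precision * recall / (precision + recall)
    return Prf(precision, recall, f1, degenerate)


def round_percentage(value: float, ndigits: int = 1) -> float:
    """Round half-up to the printed one-decimal percentage style."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OverlapSummary:
    """Venn-style overlap of rank-1-correct query sets across tools."""

    tools: tuple[str, ...]
    #: exclusive region counts keyed by the subset of tools, e.g.
    #: ("isdb",) = correct only in isdb; ("isdb", "sirius") = in exactly those two
    regions: Mapping[tuple[str, ...], int]
    union_count: int
    total_queries: int
    union_fraction: float  # percent, one decimal, half-up


def overlap_summary(
    correct_at_rank1: Mapping[str, set[str]], total_queries: int
) -> OverlapSummary:
    """Exclusive Venn region counts, union size and union percentage.

    The union fraction is 100 x union / total, rounded half-up to one
    decimal — the style the headline coverage percentages are printed in.
    """
    tools = tuple(sorted(correct_at_rank1))
    union: set[str] = set().union(*correct_at_rank1.values()) if tools else set()
    if total_queries < len(union):
        raise ValueError(
            f"total_queries ({total_queries}) smaller than the union ({len(union)})"
        )
    regions: dict[tuple[str, ...], int] = {}
    for k in range(1, len(tools) + 1):
        for combo in itertools.combinations(tools, k):
            inside = set.intersection(*(correct_at_rank1[t] for t in combo))
            outside = set().union(
                *(correct_at_rank1[t] for t in tools if t not in combo), set()
            )
            regions[combo] = len(inside - outside)
    fraction = round_percentage(100.0 * len(union) / total_queries) if total_queries else 0.0
    return OverlapSummary(
        tools=tools,
        regions=regions,
        union_count=len(union),
        total_queries=total_queries,
        union_fraction=fraction,
    )


def topk_recall_curve(
    per_query_ranks: Sequence[int | None], k_max: int
) -> list[tuple[int, int]]:
    """Cumulative count of queries whose correct structure sits at rank <= k.

    The value at k=1 is the rank-1 true-positive count; the curve is
    non-decreasing and saturates at (queries - absent).
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    return [
        (k, sum(1 for r in per_query_ranks if r is not None and r <= k))
        for k in range(1, k_max + 1)
    ]


@dataclass
class ToolResult:
    """Before/after metrics for one annotation tool."""

    before: ConfusionCounts
    after: ConfusionCounts
    prf_before: Prf
    prf_after: Prf
    curve_before: list[tuple[int, int]] = field(default_factory=list)
    curve_after: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class BenchmarkReport:
    """Full multi-tool benchmark: per-tool metrics plus cross-tool overlap."""

    schema_version: str
    weights: WeightVector
    total_queries: int
    per_tool: dict[str, ToolResult]
    overlap_before: OverlapSummary
    overlap_after: OverlapSummary

    def to_dict(self) -> dict:
        def _overlap(o: OverlapSummary) -> dict:
            return {
                "tools": list(o.tools),
                "regions": {"+".join(k): v for k, v in o.regions.items()},
                "union_count": o.union_count,
                "total_queries": o.total_queries,
                "union_fraction_percent": o.union_fraction,
            }

        def _conf(c: ConfusionCounts) -> dict:
            return {"tp": c.tp, "fp": c.fp, "fn": c.fn, "absent": c.absent,
                    "queries_with_candidates": c.n_queries_with_candidates}

        def _prf(p: Prf) -> dict:
            return {"precision": p.precision, "recall": p.recall, "f1": p.f1,
                    "degenerate": p.degenerate}

        return {
            "schema_version": self.schema_version,
            "weights": {
                "family": self.weights.w_family,
                "genus": self.weights.w_genus,
                "species": self.weights.w_species,
            },
            "total_queries": self.total_queries,
            "tools": {
                t: {
                    "before": _conf(r.before),
                    "after": _conf(r.after),
                    "prf_before": _prf(r.prf_before),
                    "prf_after": _prf(r.prf_after),
                    "topk_curve_before": r.curve_before,
                    "topk_curve_after": r.curve_after,
                }
                for t, r in self.per_tool.items()
            },
            "overlap_before": _overlap(self.overlap_before),
            "overlap_after": _overlap(self.overlap_after),
        }


SCHEMA_VERSION = "1.0"


def run_benchmark(
    candidate_sets: Mapping[str, Sequence[CandidateRecord]],
    queries: Sequence[QueryRecord],
    weights: WeightVector,
    k_max: int = 10,
) -> BenchmarkReport:
    """Score every tool's candidates and compare rank-1 performance.

    For each tool, the pipeline is run once and the correct structure's rank
    is read off both the tool-native ordering (initial ranks, "before") and
    the taxonomically informed ordering (final ranks, "after").
    """
    truth = {q.query_id: q.true_short_ik for q in queries}
    per_tool: dict[str, ToolResult] = {}
    sets_before: dict[str, set[str]] = {}
    sets_after: dict[str, set[str]] = {}
    for tool, cands in candidate_sets.items():
        scored = score_pipeline(cands, queries, weights)
        ranks_b, ranks_a = [], []
        hits_b, hits_a = set(), set()
        for qid, ranked in scored.items():
            rb = rank_of_correct(ranked, truth[qid], use_final=False)
            ra = rank_of_correct(ranked, truth[qid], use_final=True)
            ranks_b.append(rb)
            ranks_a.append(ra)
            if rb == 1:
                hits_b.add(qid)
            if ra == 1:
                hits_a.add(qid)
        cb, ca = confusion_counts(ranks_b), confusion_counts(ranks_a)
        per_tool[tool] = ToolResult(
            before=cb,
            after=ca,
            prf_before=precision_recall_f1(cb),
            prf_after=precision_recall_f1(ca),
            curve_before=topk_recall_curve(ranks_b, k_max),
            curve_after=topk_recall_curve(ranks_a, k_max),
        )
        sets_before[tool] = hits_b
        sets_after[tool] = hits_a
    total = len(queries)
    return BenchmarkReport(
        schema_version=SCHEMA_VERSION,
        weights=weights,
        total_queries=total,
        per_tool=per_tool,
        overlap_before=overlap_summary(sets_before, total),
        overlap_after=overlap_summary(sets_after, total),
    )
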