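"""Score normalisation, taxonomic-bonus combination and re-ranking.

The core procedure: per query, tool-native candidate scores are min-max
rescaled to [0, 1], the maximum taxonomic bonus of each candidate is added
to its normalized score, and candidates are re-ranked by the combined score.
Because the normalized scores are bounded by construction, the bonus weights
have a direct interpretation: a bonus of b lets a candidate overcome a
normalized-score gap of up to b.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import CandidateRecord, QueryRecord
from .taxonomy import LevelScores, TaxonLineage, WeightVector, taxonomic_bonus

__all__ = [
    "ScoredCandidate",
    "OrphanQueryError",
    "normalize_scores",
    "combine",
    "rerank",
    "min_outranking_bonus",
    "score_pipeline",
    "scored_to_frame",
]


@dataclass(frozen=True)
class ScoredCandidate:
    """A candidate annotation carried through the scoring pipeline."""

    query_id: str
    short_ik: str
    raw_score: float
    tool: str = "generic"
    sources: tuple[TaxonLineage, ...] = ()
    molecule_name: str = ""
    normalized_score: float | None = None
    level_scores: LevelScores | None = None
    combined_score: float | None = None
    initial_rank: int | None = None
    final_rank: int | None = None

    @classmethod
    def from_record(cls, rec: CandidateRecord) -> "ScoredCandidate":
        return cls(
            query_id=rec.query_id,
            short_ik=rec.short_ik,
            raw_score=rec.raw_score,
            tool=rec.tool,
            sources=rec.sources,
            molecule_name=rec.molecule_name,
        )


class OrphanQueryError(KeyError):
    """Candidate rows referencing query ids absent from the query table."""

    def __init__(self, orphans: Sequence[str]):
        super().__init__(tuple(orphans))
        self.orphans = tuple(orphans)

    def __str__(self) -> str:
        return "candidate query_ids missing from the query table: " + ", ".join(
            self.orphans
        )


def normalize_scores(
    candidates: Sequence[CandidateRecord | ScoredCandidate],
) -> list[ScoredCandidate]:
    """Min-max rescale one query's candidate scores to [0, 1].

    The worst candidate maps to 0 and the best to 1, making scores comparable
    across tools with different native scales (including tools whose scores
    are negative, as long as higher means better).  Degenerate lists — a
    single candidate, or all scores equal — map every candidate to 1: a lone
    candidate is by definition the best one.  Input order is preserved.
    """
    scored = [
        c if isinstance(c, ScoredCandidate) else ScoredCandidate.from_record(c)
        for c in candidates
    ]
    if not scored:
        return []
    lo = min(c.raw_score for c in scored)
    hi = max(c.raw_score for c in scored)
    if hi == lo:
        return [replace(c, normalized_score=1.0) for c in scored]
    span = hi - lo
    return [replace(c, normalized_score=(c.raw_score - lo) / span) for c in scored]


def combine(
    candidates: Sequence[ScoredCandidate],
    query_lineage: TaxonLineage,
    weights: WeightVector,
) -> list[ScoredCandidate]:
    """Add the maximum taxonomic bonus to each normalized score.

    ``combined_score = normalized_score + max_taxo_score`` — plain addition,
    no re-normalisation, so the spectral and taxonomic components stay
    independent.  Initial ranks are assigned by descending normalized score
    (stable on ties); a candidate that already carries an ``initial_rank``
    (e.g. from a tool's full candidate list that was truncated upstream)
    keeps it.
    """
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-(candidates[i].normalized_score or 0.0), i),
    )
    rank_by_pos = {pos: r + 1 for r, pos in enumerate(order)}
    out = []
    for i, c in enumerate(candidates):
        if c.normalized_score is None:
            raise ValueError("normalize_scores must run before combine")
        ls = taxonomic_bonus(query_lineage, c.sources, weights)
        out.append(
            replace(
                c,
                level_scores=ls,
                combined_score=c.normalized_score + ls.max_taxo_score,
                initial_rank=c.initial_rank if c.initial_rank is not None
                else rank_by_pos[i],
            )
        )
    return out


def rerank(candidates: Sequence[ScoredCandidate]) -> list[ScoredCandidate]:
    """Sort by descending combined score and assign 1-based final ranks.

    Ties break first by better (smaller) initial rank, then by lexicographic
    short InChIKey, so a re-run always reproduces the same ordering.
    """
    for c in candidates:
        if c.combined_score is None:
            raise ValueError("combine must run before rerank")
    ordered = sorted(
        candidates,
        key=lambda c: (-c.combined_score, c.initial_rank, c.short_ik),
    )
    return [replace(c, final_rank=i + 1) for i, c in enumerate(ordered)]


def min_outranking_bonus(best_combined: float, own_normalized: float) -> float:
    """Smallest additive bonus lifting a candidate to the top combined score.

    This is the construction behind the default weights: a worst candidate
    (normalized 0) needs a bonus of 1 to reach a bonus-free best candidate
    (normalized 1), hence the family weight 1; reaching a family-bonused best
    (combined 2) needs 2, hence the genus weight; and so on to the species
    weight 3.  "Reach" is treated as sufficient — an exact tie is resolved in
    the bonused candidate's favour under :func:`rerank`'s initial-rank rule
    only when it started ahead, so strict dominance may need any positive
    epsilon more; the printed derivation uses the reach convention.
    """
    return max(0.0, best_combined - own_normalized)


def score_pipeline(
    candidates: Sequence[CandidateRecord],
    queries: Sequence[QueryRecord],
    weights: WeightVector,
    top_k: int | None = None,
) -> dict[str, list[ScoredCandidate]]:
    """Run normalize -> combine -> rerank for every query.

    Returns a mapping from query id to its re-ranked candidate list
    (truncated to ``top_k`` best when given).  Candidate rows whose query id
    is not in the query table raise :class:`OrphanQueryError` listing the
    orphans.
    """
    by_query: dict[str, list[CandidateRecord]] = {}
    for c in candidates:
        by_query.setdefault(c.query_id, []).append(c)
    lineages = {q.query_id: q.lineage for q in queries}
    orphans = sorted(set(by_query) - set(lineages))
    if orphans:
        raise OrphanQueryError(orphans)
    out: dict[str, list[ScoredCandidate]] = {}
    for qid, recs in by_query.items():
        ranked = rerank(combine(normalize_scores(recs), lineages[qid], weights))
        out[qid] = ranked[:top_k] if top_k is not None else ranked
    return out


_FRAME_COLUMNS = [
    "query_id", "short_inchikey", "molecule_name", "family", "genus", "species",
    "family_score", "genus_score", "species_score", "max_taxo_score",
    "score", "normalized_score", "combined_score", "rank_initial", "rank_final",
]


def scored_to_frame(
    scored: Mapping[str, Sequence[ScoredCandidate]] | Sequence[ScoredCandidate],
) -> pd.DataFrame:
    """Flatten scored candidates to a table mirroring the worked-example layout."""
    if isinstance(scored, Mapping):
        items: Iterable[ScoredCandidate] = (
            c for qid in scored for c in scored[qid]
        )
    else:
        items = scored
    rows = []
    for c in items:
        src = c.sources[0] if c.sources else TaxonLineage()
        ls = c.level_scores or LevelScores.zero()
        rows.append(
            {
                "query_id": c.query_id,
                "short_inchikey": c.short_ik,
                "molecule_name": c.molecule_name,
                "family": src.family,
                "genus": src.genus,
                "species": src.species,
                "family_score": ls.family_score,
                "genus_score": ls.genus_score,
                "species_score": ls.species_score,
                "max_taxo_score": ls.max_taxo_score,
                "score": c.raw_score,
                "normalized_score": c.normalized_score,
                "combined_score": c.combined_score,
                "rank_initial": c.initial_rank,
                "rank_final": c.final_rank,
            }
        )
    return pd.DataFrame(rows, columns=_FRAME_COLUMNS)
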