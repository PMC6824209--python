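"""Metadata degradation, the rank-1 objective and weight optimization."""

import numpy as np
import pytest

from taxorank.io import CandidateRecord, QueryRecord
from taxorank.optimize import (
    BLOCKS,
    Rank1Objective,
    degrade_metadata,
    objective_rank1_hits,
    optimize_weights,
    repeat_and_average,
)
from taxorank.synthetic import SimulationConfig, generate_benchmark_fixture
from taxorank.taxonomy import TaxonLineage, WeightVector


@pytest.fixture(scope="module")
def small_fixture():
    return generate_benchmark_fixture(
        SimulationConfig(seed=5, n_queries=24, candidates_per_query=8)
    )


class TestDegradeMetadata:
    def test_equal_blocks_and_determinism(self, small_fixture):
        fx = small_fixture
        d1, plan1 = degrade_metadata(fx.candidates, fx.queries, seed=3)
        d2, plan2 = degrade_metadata(fx.candidates, fx.queries, seed=3)
        assert plan1.block_assignment == plan2.block_assignment
        assert d1 == d2
        sizes = [len(plan1.queries_in(b)) for b in BLOCKS]
        assert sizes == [6, 6, 6, 6]

    def test_remainder_spreads_from_first_block(self):
        queries = [QueryRecord(f"Q{i}", lineage=TaxonLineage()) for i in range(10)]
        _, plan = degrade_metadata([], queries, seed=0)
        sizes = [len(plan.queries_in(b)) for b in BLOCKS]
        assert sizes == [3, 3, 2, 2]

    def test_different_seed_different_assignment(self, small_fixture):
        fx = small_fixture
        _, p1 = degrade_metadata(fx.candidates, fx.queries, seed=1)
        _, p2 = degrade_metadata(fx.candidates, fx.queries, seed=2)
        assert p1.block_assignment != p2.block_assignment

    def test_stripping_blanks_the_right_levels(self, small_fixture):
        fx = small_fixture
        degraded, plan = degrade_metadata(fx.candidates, fx.queries, seed=7)
        by_query = {}
        for c in degraded:
            by_query.setdefault(c.query_id, []).append(c)
        for qid, block in plan.block_assignment.items():
            for c in by_query[qid]:
                for src in c.sources:
                    if block == "strip_species":
                        assert src.species == "" and src.genus != ""
                    elif block == "strip_genus_species":
                        assert src.species == "" and src.genus == ""
                        assert src.family != ""
                    elif block == "strip_all":
                        assert (src.family, src.genus, src.species) == ("", "", "")

    def test_idempotent_and_pure(self, small_fixture):
        fx = small_fixture
        before = list(fx.candidates)
        once, _ = degrade_metadata(fx.candidates, fx.queries, seed=9)
        twice, _ = degrade_metadata(once, fx.queries, seed=9)
        assert once == twice
        assert fx.candidates == before  # originals untouched
        assert [c.short_ik for c in once] == [c.short_ik for c in before]
        assert [c.raw_score for c in once] == [c.raw_score for c in before]

    def test_strip_all_block_earns_no_bonus(self, small_fixture):
        fx = small_fixture
        degraded, plan = degrade_metadata(fx.candidates, fx.queries, seed=4)
        stripped_ids = set(plan.queries_in("strip_all"))
        obj = Rank1Objective(
            [c for c in degraded if c.query_id in stripped_ids],
            [q for q in fx.queries if q.query_id in stripped_ids],
        )
        # no candidate in the fully stripped block can match at any level
        assert all(not q["match"].any() for q in obj._queries)

    def test_empty_queries_rejected(self):
        with pytest.raises(ValueError):
            degrade_metadata([], [], seed=0)


QUERY_LINEAGE = TaxonLineage(family="Fam00", genus="Fam00Gen00",
                             species="Fam00Gen00 sp00")


def _two_query_species_rescue():
    """Tiny set where only a species-level match rescues each truth.

    The decoy matches at genus level and out-scores the truth by 0.9
    normalized units, so the truth wins only when
    w_species > w_genus + 0.9.
    """
    queries = [QueryRecord("Q1", "T" * 14, QUERY_LINEAGE),
               QueryRecord("Q2", "T" * 14, QUERY_LINEAGE)]
    genus_sibling = TaxonLineage(family="Fam00", genus="Fam00Gen00",
                                 species="Fam00Gen00 sp01")
    cands = []
    for qid in ("Q1", "Q2"):
        cands += [
            CandidateRecord(qid, "T" * 14, 0.1, sources=(QUERY_LINEAGE,)),
            CandidateRecord(qid, "D" * 14, 1.0, sources=(genus_sibling,)),
            CandidateRecord(qid, "E" * 14, 0.0),
        ]
    return cands, queries


class TestObjective:
    def test_zero_weights_equal_before_scoring_tp(self, small_fixture):
        fx = small_fixture
        from taxorank.benchmark import confusion_counts, rank_of_correct
        from taxorank.scoring import score_pipeline

        truth = {q.query_id: q.true_short_ik for q in fx.queries}
        scored = score_pipeline(fx.candidates, fx.queries, WeightVector.zero())
        before_tp = confusion_counts([
            rank_of_correct(r, truth[q], use_final=False)
            for q, r in scored.items()
        ]).tp
        assert objective_rank1_hits(
            WeightVector.zero(), fx.candidates, fx.queries) == before_tp

    def test_perfect_signal_all_rescued(self):
        """When the truth is the only taxonomic match and trails by less
        than the family weight, every query is correct after rescoring."""
        fx = generate_benchmark_fixture(
            SimulationConfig(
                seed=2, n_queries=30, candidates_per_query=6,
                p_true_source_species=1.0, p_true_source_genus=0.0,
                p_true_source_family=0.0, p_decoy_match=0.0,
                score_noise_sd=0.0, true_score_deficit=0.5,
            )
        )
        assert objective_rank1_hits(
            WeightVector.default(), fx.candidates, fx.queries) == 30
        assert objective_rank1_hits(
            WeightVector.zero(), fx.candidates, fx.queries) == 0

    def test_table1_with_optimized_weights(self, table1):
        query, cands = table1
        recs = [
            CandidateRecord(c.query_id, c.short_ik, c.raw_score, c.tool,
                            c.sources, c.molecule_name)
            for c in cands
        ]
        # raw scores re-normalised over 5 rows still leave the genus-level
        # matches on top under the optimized weights
        assert objective_rank1_hits(WeightVector.optimized(), recs, [query]) == 1

    def test_vectorised_evaluator_matches_pipeline(self, small_fixture):
        fx = small_fixture
        degraded, _ = degrade_metadata(fx.candidates, fx.queries, seed=1)
        obj = Rank1Objective(degraded, fx.queries)
        rng = np.random.default_rng(0)
        for _ in range(6):
            w = WeightVector(*rng.uniform(0, 3, size=3))
            assert obj(w) == objective_rank1_hits(w, degraded, fx.queries)


class TestOptimizeWeights:
    def test_grid_finds_species_dominant_optimum(self):
        cands, queries = _two_query_species_rescue()
        trace = optimize_weights(cands, queries, method="grid", grid_step=0.5)
        assert trace.best_value == 2
        assert trace.best_point.w_species > trace.best_point.w_genus

    def test_constant_objective_any_point_optimal(self):
        # truth absent from candidates -> objective identically zero
        queries = [QueryRecord("Q1", "T" * 14, QUERY_LINEAGE)]
        cands = [CandidateRecord("Q1", "D" * 14, 1.0)]
        trace = optimize_weights(cands, queries, method="grid", grid_step=1.0)
        assert trace.best_value == 0
        assert all(v == 0 for _, v in trace.points)

    def test_random_and_surrogate_respect_contract(self):
        cands, queries = _two_query_species_rescue()
        for method in ("random", "surrogate"):
            trace = optimize_weights(
                cands, queries, method=method, n_init=5, n_iter=10, seed=3)
            values = [v for _, v in trace.points]
            assert trace.best_value == max(values)
            assert len(trace.points) == 15
            lo, hi = trace.bounds
            assert all(lo <= x <= hi for pt, _ in trace.points for x in pt)

    def test_surrogate_matches_grid_objective_on_lattice(self):
        cands, queries = _two_query_species_rescue()
        grid = optimize_weights(cands, queries, method="grid", grid_step=1.0)
        obj = Rank1Objective(cands, queries)
        for pt, val in grid.points:
            assert obj(WeightVector(*pt)) == val

    @pytest.mark.parametrize("kwargs", [
        {"bounds": (3.0, 0.0)},
        {"method": "annealing"},
        {"method": "random", "n_init": 0},
        {"grid_step": 0.0},
    ])
    def test_invalid_arguments(self, kwargs):
        cands, queries = _two_query_species_rescue()
        with pytest.raises(ValueError):
            optimize_weights(cands, queries, **kwargs)


class TestRepeatAndAverage:
    def _trace(self, best):
        from taxorank.optimize import OptimizationTrace

        return OptimizationTrace(
            points=[(best, 1.0)], best_point=WeightVector(*best),
            best_value=1.0, method="grid", bounds=(0, 3), seed=0)

    def test_identical_runs(self):
        avg = repeat_and_average([self._trace((1, 2, 3))] * 2)
        assert avg.weights.as_tuple() == (1, 2, 3)
        assert avg.spread == (0, 0, 0)

    def test_componentwise_mean(self):
        avg = repeat_and_average(
            [self._trace((0.8, 1.6, 2.5)), self._trace((0.82, 1.64, 2.6))])
        assert avg.weights.as_tuple() == pytest.approx((0.81, 1.62, 2.55))

    def test_single_run_is_its_own_best(self):
        avg = repeat_and_average([self._trace((0.5, 1.0, 1.5))])
        assert avg.weights.as_tuple() == (0.5, 1.0, 1.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            repeat_and_average([])
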