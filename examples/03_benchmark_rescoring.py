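"""Quantify what taxonomic re-scoring buys on a synthetic benchmark.

Builds a 200-query benchmark with a realistic chemotaxonomic signal, scores
it with and without the taxonomic bonus, and prints rank-1 hit counts,
F1 and the top-k hit curve.
"""

from taxorank import (
    SimulationConfig,
    WeightVector,
    generate_benchmark_fixture,
    run_benchmark,
)

fixture = generate_benchmark_fixture(SimulationConfig(seed=1))
report = run_benchmark(
    {"generic": fixture.candidates}, fixture.queries, WeightVector.default(),
    k_max=5,
)
res = report.per_tool["generic"]
n = report.total_queries
print(f"{n} queries, {fixture.config.candidates_per_query} candidates each")
print(f"correct at rank 1:  {res.before.tp:4d} before  ->  {res.after.tp:4d} after")
print(f"F1:                 {res.prf_before.f1:.3f} before  ->  "
      f"{res.prf_after.f1:.3f} after")
print("top-k correct hits after re-scoring:",
      ", ".join(f"k={k}: {c}" for k, c in res.curve_after))
print(
    "\nThe bonus rescues queries whose correct structure was spectrally\n"
    "outranked but is the only candidate reported from the query's taxon."
)
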