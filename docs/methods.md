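# Methods

## Scoring model

For one query spectrum with candidates *i* = 1..n carrying tool-native
scores *s_i* (oriented so higher is better for every supported dialect,
including tools whose native scores are negative), the normalized score is

    ŝ_i = (s_i − min_j s_j) / (max_j s_j − min_j s_j).

Degenerate queries (a single candidate, or all scores equal) assign ŝ = 1
to every candidate: a lone candidate is the best candidate, and mapping it
to 0 would spuriously deny it any chance of keeping rank 1 against nothing.

Each candidate carries zero or more source lineages (kingdom → species;
empty string = unknown). A level *matches* iff both the query lineage and a
source carry a non-empty name there and the names compare equal after
canonicalisation (whitespace collapse, case-fold; placeholder tokens "NA",
"N/A", "-" are unknowns). Species comparison uses the full binomial string;
infraspecific ranks are not modelled — a documented simplification, since
how varieties and subspecies were matched in the original workflow is
unspecified. Matching is exact; no fuzzy or phylogenetic-distance matching.

Per-level indicators are OR-ed across a candidate's sources, multiplied by
the weight vector (w_f, w_g, w_s), and the maximum is added to ŝ. The sum
is not re-normalised, keeping the spectral and taxonomic components
independent and the weights interpretable: a bonus *b* overcomes a
normalized-score deficit of up to *b*.

Re-ranking sorts by descending combined score with a deterministic
two-stage tie-break — better initial rank first, then lexicographic short
InChIKey. The tie rule is this package's choice (the procedure itself does
not define one); it makes re-runs and the brute-force oracle reproducible.
Initial ranks are assigned by descending normalized score unless the input
already carries them (truncated candidate lists, like the shipped worked
example whose printed normalized scores derive from a full ~50-candidate
list, keep their published initial ranks).

`min_outranking_bonus(best, own) = max(0, best − own)` formalises the
derivation of the default weights. It uses the "reach" convention (a bonus
exactly closing the gap suffices); strict dominance would need any positive
increment more. The prose derivation mixes "ranked first" with "ranked
above"; we document rather than silently resolve this, and the resulting
preset (1, 2, 3) is unaffected.

## Dataset preparation

MGF libraries are read and written with `pyteomics.mgf`. Curation rules:
spectra with < 6 fragments are dropped; spectra with > 500 fragments keep
the 500 most intense (intensity ties at the cutoff keep the lower-m/z peak,
a determinism choice); parent masses outside [100, 1500] Da are dropped;
with `protonated_only` (default) any spectrum not annotated [M+H]+ —
including unannotated ones — is dropped. The adduct is looked up in
ADDUCT-like MGF fields and, failing that, as a "[M+H]+" token embedded in
NAME/TITLE, per common library dialects.

Formula masses are computed by `pyteomics.mass` (principal-isotope
composition); the wrapper validates Hill-notation syntax because an empty
formula must be a parse error, not 0 Da. Parent-mass QC compares the
precursor with monoisotopic(formula) + 1.007276 Da (proton) and flags
differences strictly exceeding 0.01 Da.

Benchmark construction joins spectra to structure–source rows on the
14-character short InChIKey (connectivity layer; stereoisomers are
deliberately conflated throughout). Source rows not resolved to species
level are dropped; structures with more than one distinct lineage are
dropped entirely; several spectra of one structure collapse to the first by
input order (the representative-spectrum rule is unspecified upstream; the
stable-first rule is ours and the discarded ids are reported).

Name resolution is table-driven and offline: a TSV mapping input names
(accepted names and synonyms) to accepted lineages replaces online taxonomy
services; unknown names yield an explicit unresolved outcome.

## Weight optimization

Candidate metadata is degraded in four equal random blocks *by query*
(earlier blocks absorb the remainder): species stripped / genus+species
stripped / family+genus+species stripped / intact. Assigning whole queries
rather than individual candidate rows keeps each query's candidate list
internally consistent, which makes the rank-1 objective well defined; the
alternative row-level reading of the original procedure is noted as an open
interpretation. Degradation is a pure function of (seed, sorted query ids).

The objective is the number of queries whose correct structure lands at
final rank 1. Three optimizers over [0, 3]³: an exhaustive lattice grid
(default step 0.25) — the auditable oracle; uniform random search; and a
sequential surrogate (scikit-learn Gaussian process, Matérn ν = 2.5,
expected-improvement acquisition over 256 uniformly drawn candidate points
per iteration, n_init random starts + n_iter acquisitions). The surrogate's
contract is behavioural — it returns the best *evaluated* point and its
evaluations agree with the grid oracle on lattice points — not a bitwise
reproduction of any particular Bayesian-optimization library. Grid
evaluations run through a vectorised evaluator that precomputes normalized
scores, initial ranks and per-level match indicators once; its agreement
with the plain pipeline objective is asserted in the test suite. Repeated
runs on replicate degradations are averaged component-wise, with the
per-axis spread reported.

## Synthetic benchmarks

The generator emulates the statistical shape of a plant-dominated spectral
library benchmark: one true candidate per query among uniform-scored
decoys, the true candidate's raw score sitting `true_score_deficit` (default
0.15) below the best decoy plus Gaussian noise (sd 0.1) — so the correct
structure wins on spectral score alone only occasionally, matching the
~10% rank-1 rates spectral matching achieves on real benchmarks. The true
candidate's source matches the query organism at species / genus / family
depth with probabilities 0.5 / 0.25 / 0.15 (the chemotaxonomic signal is
concentrated at the deep levels). Decoys share the query's family with
probability 0.25, half of them congeneric — real candidate lists are
taxonomically clustered (in the worked example all five candidates are
confamilial and three congeneric), and without congeneric decoys a
species-level match would never require a larger bonus than a genus-level
one, flattening the optimization landscape in the species direction.
Taxonomy names are structured (`Fam03` / `Fam03Gen02` / `Fam03Gen02 sp05`)
so match depth is readable off the strings while keeping binomials
consistent (the species string starts with the genus token); every tenth
species gains a synonym entry to exercise name resolution.

What the generator does **not** emulate: fragmentation chemistry (peaks are
placeholders), instrument or compound-class structure, inter-tool score
correlation, and the heavy-tailed candidate-count distribution of real
searches. Passing tests therefore demonstrate the correctness and the
qualitative behaviour of the scoring machinery, not the absolute
performance figures attainable on any real library.

Scales used by the default test and acceptance runs — chosen as the
smallest sizes at which the qualitative claims are stable across seeds:
120–200 queries with 10–20 candidates each for the before/after benchmarks,
and four degradation replicates with a 0.5-step grid (343 lattice points)
for weight-ordering recovery. The recovered ordering
w_family < w_genus < w_species is the reproduction target; the exact
optimized values depend on the metadata completeness of the training set
and are not asserted.

## Known limitations

- Infraspecific ranks and fuzzy name matching are unsupported; resolution
  quality is bounded by the user-supplied taxonomy table.
- F1 here uses the rank-1 convention (FN = correct present below rank 1;
  queries whose correct structure is absent are counted separately), so
  values are not comparable with retrieval-style F1 at other cutoffs. Both
  precision universes (queries with candidates vs all queries) can be
  recomputed from the reported counts.
- The "top-k hit curve" is the cumulative count of correct annotations at
  rank ≤ k — the standard surrogate for ranked-annotation ROC-style
  summaries, which are otherwise underspecified.
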