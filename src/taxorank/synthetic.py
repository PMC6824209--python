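"""Self-contained synthetic fixtures with controlled chemotaxonomic structure.

Generates taxonomies, structure-source tables, benchmark query sets,
candidate lists and MGF spectral files whose statistical shape mimics a
plant-dominated spectral-library benchmark: the correct candidate is often
spectrally outranked by decoys, and its recorded biological source matches
the query organism mostly at the genus or species level.  Everything is a
pure function of the configuration seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import CandidateRecord, QueryRecord, SpectrumEntry
from .scoring import ScoredCandidate
from .taxonomy import TaxonLineage, TaxonomyTable

__all__ = [
    "SimulationConfig",
    "SyntheticFixture",
    "generate_taxonomy",
    "generate_benchmark_fixture",
    "table1_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic benchmark generator.

    The depth probabilities say how often the true candidate's recorded
    source matches the query organism at exactly that level (deepest level
    counted); their sum may be below 1, the rest being taxonomically
    unrelated.  ``true_score_deficit`` places the true candidate's raw score
    below the best decoy's, in the decoys' [0, 1] raw-score units, so the
    before-rescoring failure mode — right structure, mediocre spectral score
    — is directly controlled.

    ``p_decoy_match`` is the probability that a decoy's source shares the
    query's family; half of those decoys are congeneric (same genus,
    different species), mirroring the near-miss candidates a structure
    database returns for genus-typical scaffolds.  Without congeneric decoys
    a species-level match would never need a larger bonus than a genus-level
    one.
    """

    seed: int = 0
    n_families: int = 8
    genera_per_family: int = 4
    species_per_genus: int = 4
    n_queries: int = 200
    candidates_per_query: int = 20
    p_true_source_species: float = 0.5
    p_true_source_genus: float = 0.25
    p_true_source_family: float = 0.15
    p_decoy_match: float = 0.25
    score_noise_sd: float = 0.1
    true_score_deficit: float = 0.15

    def __post_init__(self) -> None:
        probs = (
            self.p_true_source_species,
            self.p_true_source_genus,
            self.p_true_source_family,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs + (self.p_decoy_match,)):
            raise ValueError("probabilities must lie in [0, 1]")
        if sum(probs) > 1.0 + 1e-12:
            raise ValueError("depth probabilities must sum to at most 1")
        for name in ("n_families", "genera_per_family", "species_per_genus",
                     "n_queries", "candidates_per_query"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.score_noise_sd < 0:
            raise ValueError("score_noise_sd must be non-negative")


def _species_lineage(fam: int, gen: int, sp: int) -> TaxonLineage:
    genus = f"Fam{fam:02d}Gen{gen:02d}"
    return TaxonLineage(
        kingdom="Plantae",
        phylum="Tracheophyta",
        class_="Magnoliopsida",
        order=f"Ord{fam:02d}",
        family=f"Fam{fam:02d}",
        genus=genus,
        species=f"{genus} sp{sp:02d}",
    )


def generate_taxonomy(config: SimulationConfig) -> TaxonomyTable:
    """Deterministic synthetic taxonomy with ~10% synonym entries.

    Names are structured (``Fam03`` / ``Fam03Gen02`` / ``Fam03Gen02 sp05``)
    so the depth of any lineage match is readable off the strings.  Every
    tenth species is additionally emitted under a synonym name that resolves
    to the accepted lineage, exercising the synonymy path of name
    resolution.
    """
    table = TaxonomyTable()
    counter = 0
    for fam in range(config.n_families):
        for gen in range(config.genera_per_family):
            for sp in range(config.species_per_genus):
                lineage = _species_lineage(fam, gen, sp)
                table.add(lineage.species, lineage.species, lineage)
                if counter % 10 == 0:
                    table.add(f"Syn{counter:04d} obsoleta", lineage.species, lineage)
                counter += 1
    return table


def _make_inchikeys(rng: np.random.Generator, n: int) -> list[str]:
    letters = np.array(list(string.ascii_uppercase))
    keys: list[str] = []
    seen: set[str] = set()
    while len(keys) < n:
        ik = "".join(rng.choice(letters, size=14))
        if ik not in seen:
            seen.add(ik)
            keys.append(ik)
    return keys


@dataclass
class SyntheticFixture:
    """All artifacts of one synthetic benchmark, ready for every pipeline stage."""

    config: SimulationConfig
    taxonomy: TaxonomyTable
    queries: list[QueryRecord]
    candidates: list[CandidateRecord]
    source_table: list[tuple[str, TaxonLineage]]
    spectra: list[SpectrumEntry]


def _all_species(config: SimulationConfig) -> list[tuple[int, int, int]]:
    return [
        (f, g, s)
        for f in range(config.n_families)
        for g in range(config.genera_per_family)
        for s in range(config.species_per_genus)
    ]


def _true_source(
    rng: np.random.Generator, config: SimulationConfig, fam: int, gen: int, sp: int
) -> TaxonLineage:
    """Source lineage of the true candidate, at a drawn match depth."""
    u = rng.random()
    if u < config.p_true_source_species:
        return _species_lineage(fam, gen, sp)
    u -= config.p_true_source_species
    if u < config.p_true_source_genus:
        # same genus, different species (wrap if the genus has only one)
        other = (sp + 1) % config.species_per_genus
        if other == sp:
            other_lineage = _species_lineage(fam, gen, sp)
            return other_lineage.replace(species=f"{other_lineage.genus} sp99")
        return _species_lineage(fam, gen, other)
    u -= config.p_true_source_genus
    if u < config.p_true_source_family:
        other = (gen + 1) % config.genera_per_family
        if other == gen:
            return _species_lineage(fam, gen, sp).replace(
                genus=f"Fam{fam:02d}Gen99", species=f"Fam{fam:02d}Gen99 sp00"
            )
        return _species_lineage(fam, other, 0)
    # unrelated: a different family altogether
    other_fam = (fam + 1) % config.n_families
    if other_fam == fam:
        return TaxonLineage(
            kingdom="Plantae", family="Fam99", genus="Fam99Gen00",
            species="Fam99Gen00 sp00",
        )
    return _species_lineage(other_fam, 0, 0)


def _decoy_source(
    rng: np.random.Generator, config: SimulationConfig, fam: int, gen: int
) -> TaxonLineage:
    if rng.random() < config.p_decoy_match:
        # half congeneric (different species of the query's genus, like the
        # near-miss candidates of the worked example), half confamilial
        if rng.random() < 0.5:
            sp = int(rng.integers(config.species_per_genus))
            lineage = _species_lineage(fam, gen, sp)
            return lineage.replace(species=f"{lineage.genus} sp{90 + sp:02d}")
        other = int(rng.integers(config.genera_per_family))
        if other == gen:
            other = (gen + 1) % config.genera_per_family
        if other == gen:  # single-genus family: fabricate a sibling genus
            return _species_lineage(fam, gen, 0).replace(
                genus=f"Fam{fam:02d}Gen98", species=f"Fam{fam:02d}Gen98 sp00"
            )
        return _species_lineage(fam, other, int(rng.integers(config.species_per_genus)))
    other_fam = int(rng.integers(config.n_families))
    if other_fam == fam:
        other_fam = (fam + 1) % config.n_families
    if other_fam == fam:  # single-family taxonomy: fabricate an outside family
        return TaxonLineage(
            kingdom="Plantae", family="Fam99", genus="Fam99Gen00",
            species="Fam99Gen00 sp00",
        )
    return _species_lineage(
        other_fam,
        int(rng.integers(config.genera_per_family)),
        int(rng.integers(config.species_per_genus)),
    )


def generate_benchmark_fixture(config: SimulationConfig) -> SyntheticFixture:
    """Generate queries, candidates, sources and spectra for one benchmark.

    Each query spectrum has exactly one true candidate (short InChIKey equal
    to the query's truth) among ``candidates_per_query - 1`` decoys.  Decoy
    raw scores are uniform on [0, 1]; the true raw score sits
    ``true_score_deficit`` below the best decoy plus Gaussian noise.  Spectra
    carry >= 6 peaks, parent masses within 100-1500 Da and a [M+H]+ adduct
    annotation, so they pass the default library filters unchanged.
    """
    rng = np.random.default_rng(config.seed)
    taxonomy = generate_taxonomy(config)
    species = _all_species(config)
    n_decoys = config.candidates_per_query - 1
    iks = _make_inchikeys(rng, config.n_queries * config.candidates_per_query)
    ik_iter = iter(iks)

    queries: list[QueryRecord] = []
    candidates: list[CandidateRecord] = []
    source_table: list[tuple[str, TaxonLineage]] = []
    spectra: list[SpectrumEntry] = []
    for qi in range(config.n_queries):
        fam, gen, sp = species[int(rng.integers(len(species)))]
        lineage = _species_lineage(fam, gen, sp)
        qid = f"SYNLIB{qi:07d}"
        true_ik = next(ik_iter)
        queries.append(
            QueryRecord(query_id=qid, true_short_ik=true_ik, lineage=lineage)
        )
        source_table.append((true_ik, lineage))

        decoy_scores = rng.uniform(0.0, 1.0, size=n_decoys) if n_decoys else np.array([1.0])
        best_decoy = float(decoy_scores.max()) if n_decoys else 1.0
        true_score = best_decoy - config.true_score_deficit
        if config.score_noise_sd > 0:
            true_score += float(rng.normal(0.0, config.score_noise_sd))
        row: list[CandidateRecord] = []
        for di in range(n_decoys):
            row.append(
                CandidateRecord(
                    query_id=qid,
                    short_ik=next(ik_iter),
                    raw_score=float(decoy_scores[di]),
                    tool="generic",
                    sources=(_decoy_source(rng, config, fam, gen),),
                    molecule_name=f"decoy_{qi}_{di}",
                )
            )
        true_rec = CandidateRecord(
            query_id=qid,
            short_ik=true_ik,
            raw_score=true_score,
            tool="generic",
            sources=(_true_source(rng, config, fam, gen, sp),),
            molecule_name=f"truth_{qi}",
        )
        row.insert(int(rng.integers(len(row) + 1)), true_rec)
        candidates.extend(row)

        precursor = float(rng.uniform(150.0, 800.0))
        mzs = np.sort(rng.uniform(50.0, precursor, size=8))
        intensities = rng.uniform(10.0, 1000.0, size=8)
        spectra.append(
            SpectrumEntry(
                spectrum_id=qid,
                precursor_mz=precursor,
                adduct="[M+H]+",
                peaks=list(zip(map(float, mzs), map(float, intensities))),
            )
        )
    return SyntheticFixture(
        config=config,
        taxonomy=taxonomy,
        queries=queries,
        candidates=candidates,
        source_table=source_table,
        spectra=spectra,
    )


# --------------------------------------------------------------------------
# the printed worked example

_T1_QUERY_LINEAGE = TaxonLineage(
    kingdom="Plantae",
    phylum="Tracheophyta",
    class_="Magnoliopsida",
    order="Ranunculales",
    family="Papaveraceae",
    genus="Glaucium",
    species="Glaucium grandiflorum",
)

_T1_ROWS: list[tuple[str, str, str, str, str, float, float, int]] = [
    # short_ik, name, family, genus, species, raw, normalized, initial rank
    ("OUTYMWDDJORZOH", "Predicentrine",
     "Papaveraceae", "Glaucium", "Glaucium oxylobum", 0.36, 0.23, 9),
    ("QELDJEKNFOQJOY", "Isocorydine",
     "Papaveraceae", "Glaucium", "NA", 0.34, 0.22, 11),
    ("KDFKJOFJHSVROC", "Isocorypalmine",
     "Papaveraceae", "Glaucium", "Glaucium fimbrilligerum", 0.30, 0.14, 28),
    ("JADHMUPTWPBTMT", "Secosarcocapnidine Me ether, N-De-Me",
     "Papaveraceae", "Sarcocapnos", "Sarcocapnos crassifolia", 0.40, 0.32, 1),
    ("WNBUTZHPPULVTP", "Secocularidine Me ether, N-de-Me",
     "Papaveraceae", "Ceratocapnos", "Ceratocapnos claviculata", 0.39, 0.29, 2),
]

#: short InChIKey of predicentrine, the verified correct annotation
TABLE1_TRUTH = "OUTYMWDDJORZOH"


def table1_fixture() -> tuple[QueryRecord, list[ScoredCandidate]]:
    """The published worked example: a Glaucium grandiflorum feature.

    Returns the query (organism lineage ending Papaveraceae | Glaucium |
    Glaucium grandiflorum, truth = predicentrine) and its top-five candidate
    annotations with the printed normalized spectral scores and initial
    ranks.  The normalized scores and initial ranks come from the tool's
    full ~50-candidate list and cannot be re-derived from five rows, so they
    are taken as given; downstream combination and re-ranking are computed,
    not copied.
    """
    query = QueryRecord(
        query_id="feature_mz342.1670_rt1.42",
        true_short_ik=TABLE1_TRUTH,
        lineage=_T1_QUERY_LINEAGE,
    )
    cands = [
        ScoredCandidate(
            query_id=query.query_id,
            short_ik=ik,
            raw_score=raw,
            tool="isdb",
            sources=(
                TaxonLineage(family=fam, genus=gen, species=spe),
            ),
            molecule_name=name,
            normalized_score=norm,
            initial_rank=rank,
        )
        for ik, name, fam, gen, spe, raw, norm, rank in _T1_ROWS
    ]
    return query, cands
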