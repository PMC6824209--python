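"""Biological-source lineages and the taxonomic bonus.

Candidate structures in natural-products annotation carry the taxa they were
reported from; the query spectrum carries the taxonomy of the organism it was
acquired from.  Matching the two lineages at the family, genus and species
levels, and rewarding the deepest match, is the core chemotaxonomic signal
this package adds on top of spectral scores.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TaxonLineage",
    "WeightVector",
    "LevelScores",
    "LevelMatch",
    "TaxonomyTable",
    "UnresolvedNameError",
    "canonicalize_name",
    "comparison_form",
    "match_levels",
    "taxonomic_bonus",
    "resolve_lineage",
]

RANKS = ("kingdom", "phylum", "class_", "order", "family", "genus", "species")

#: tokens treated as "unknown" wherever a taxon name is expected
_PLACEHOLDERS = frozenset({"", "-", "na", "n/a", "nan", "none", "null"})

_WS_RUN = re.compile(r"\s+")


def canonicalize_name(raw: str) -> str:
    """Normalise a taxon name to its canonical display form.

    Leading/trailing whitespace is stripped and internal whitespace runs are
    collapsed to a single space.  Placeholder tokens ("NA", "N/A", "-", empty)
    map to the empty string, which means "unknown at this level" everywhere in
    this package.  Case is preserved for display; use :func:`comparison_form`
    for equality tests.
    """
    if raw is None:
        return ""
    name = _WS_RUN.sub(" ", str(raw).strip())
    if name.casefold() in _PLACEHOLDERS:
        return ""
    return name


def comparison_form(name: str) -> str:
    """Case-folded canonical form used for all taxon-name comparisons."""
    return canonicalize_name(name).casefold()


@dataclass(frozen=True)
class TaxonLineage:
    """A resolved lineage, kingdom down to species (full binomial).

    Empty string at any rank means unknown/degraded.  Fields are canonicalized
    on construction.  If both genus and species are present, the first token
    of the species binomial must equal the genus.
    """

    kingdom: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        for f in fields(self):
            object.__setattr__(self, f.name, canonicalize_name(getattr(self, f.name)))
        if self.species and self.genus:
            first = self.species.split()[0]
            if first.casefold() != self.genus.casefold():
                raise ValueError(
                    f"species binomial {self.species!r} does not start with "
                    f"genus {self.genus!r}"
                )

    @classmethod
    def from_pipe(cls, text: str) -> "TaxonLineage":
        """Parse a ``kingdom|phylum|class|order|family|genus|species`` string.

        Fields fill from the kingdom side; strings with fewer than seven
        fields (e.g. a family-level ``Plantae|Tracheophyta|Magnoliopsida|
        Ranunculales|Ranunculaceae``) leave the deeper ranks unknown.
        """
        parts = [p for p in text.split("|")]
        if len(parts) > len(RANKS):
            raise ValueError(f"lineage string has {len(parts)} fields, expected <= 7")
        parts += [""] * (len(RANKS) - len(parts))
        return cls(*parts)

    def to_pipe(self) -> str:
        return "|".join(getattr(self, r) for r in RANKS)

    def replace(self, **kwargs: str) -> "TaxonLineage":
        return replace(self, **kwargs)

    def is_empty(self) -> bool:
        return all(not getattr(self, r) for r in RANKS)


class LevelMatch(tuple):
    """Indicator triple (family, genus, species) of exact lineage matches."""

    __slots__ = ()

    def __new__(cls, family: bool, genus: bool, species: bool):
        return super().__new__(cls, (bool(family), bool(genus), bool(species)))

    @property
    def family(self) -> bool:
        return self[0]

    @property
    def genus(self) -> bool:
        return self[1]

    @property
    def species(self) -> bool:
        return self[2]


def match_levels(query: TaxonLineage, source: TaxonLineage) -> LevelMatch:
    """Exact-match indicators at the family, genus and species levels.

    A level matches iff both lineages carry a non-empty name there and the
    names compare equal case-insensitively.  An unknown on either side never
    matches.  Symmetric in its arguments.
    """

    def _eq(a: str, b: str) -> bool:
        return bool(a) and bool(b) and a.casefold() == b.casefold()

    return LevelMatch(
        _eq(query.family, source.family),
        _eq(query.genus, source.genus),
        _eq(query.species, source.species),
    )


@dataclass(frozen=True)
class WeightVector:
    """Per-taxa-level bonus scores (family, genus, species).

    The default preset (1, 2, 3) is the minimal-dominance construction: each
    weight is the smallest bonus letting a worst-scored candidate outrank a
    best-scored candidate already carrying the next-shallower bonus.  The
    optimized preset (0.81, 1.62, 2.55) is the published optimum found by
    black-box optimization on a degraded-metadata benchmark.
    """

    w_family: float = 1.0
    w_genus: float = 2.0
    w_species: float = 3.0

    def __post_init__(self) -> None:
        for name in ("w_family", "w_genus", "w_species"):
            v = float(getattr(self, name))
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
            object.__setattr__(self, name, v)

    @property
    def depth_monotone(self) -> bool:
        """True iff weights grow with taxonomic depth (family <= genus <= species)."""
        return self.w_family <= self.w_genus <= self.w_species

    @property
    def max_weight(self) -> float:
        return max(self.w_family, self.w_genus, self.w_species)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w_family, self.w_genus, self.w_species)

    @classmethod
    def default(cls) -> "WeightVector":
        return cls(1.0, 2.0, 3.0)

    @classmethod
    def optimized(cls) -> "WeightVector":
        return cls(0.81, 1.62, 2.55)

    @classmethod
    def zero(cls) -> "WeightVector":
        return cls(0.0, 0.0, 0.0)

    @classmethod
    def from_text(cls, text: str) -> "WeightVector":
        """Parse ``"F,G,S"`` or the preset names ``default`` / ``optimized``."""
        key = text.strip().lower()
        if key == "default":
            return cls.default()
        if key == "optimized":
            return cls.optimized()
        parts = [p for p in text.split(",") if p.strip()]
        if len(parts) != 3:
            raise ValueError(f"expected 'F,G,S' or a preset name, got {text!r}")
        return cls(*(float(p) for p in parts))


@dataclass(frozen=True)
class LevelScores:
    """Per-level bonuses of one candidate and their maximum.

    Each per-level score is either 0 (no source matched at that level) or the
    corresponding weight; ``max_taxo_score`` is what gets added to the
    normalized spectral score.
    """

    family_score: float = 0.0
    genus_score: float = 0.0
    species_score: float = 0.0
    max_taxo_score: float = 0.0

    @classmethod
    def zero(cls) -> "LevelScores":
        return cls()


def taxonomic_bonus(
    query: TaxonLineage,
    sources: Sequence[TaxonLineage],
    weights: WeightVector,
) -> LevelScores:
    """Taxonomic bonus of a candidate with the given recorded sources.

    A per-level indicator is the OR across sources (a candidate reported from
    several organisms matches at a level if any of them does); the weight is
    awarded where the indicator holds, and the maximum over the three levels
    is the bonus added to the spectral score.  No sources means no bonus.
    """
    fam = gen = spe = False
    for src in sources:
        m = match_levels(query, src)
        fam = fam or m.family
        gen = gen or m.genus
        spe = spe or m.species
        if fam and gen and spe:
            break
    fs = weights.w_family if fam else 0.0
    gs = weights.w_genus if gen else 0.0
    ss = weights.w_species if spe else 0.0
    return LevelScores(fs, gs, ss, max(fs, gs, ss))


class UnresolvedNameError(KeyError):
    """A biological-source name absent from the taxonomy table."""

    def __init__(self, raw_name: str):
        super().__init__(raw_name)
        self.raw_name = raw_name

    def __str__(self) -> str:
        return f"unresolved biological-source name: {self.raw_name!r}"


class TaxonomyTable:
    """Offline name-resolution table: input name -> (accepted name, lineage).

    Stands in for online taxonomy services; synonyms map to the accepted
    lineage.  Lookup is on the case-folded canonical form of the name.
    """

    COLUMNS = ("input_name", "accepted_name") + tuple(
        r.rstrip("_") for r in RANKS
    )

    def __init__(self, entries: Mapping[str, tuple[str, TaxonLineage]] | None = None):
        self._entries: dict[str, tuple[str, TaxonLineage]] = {}
        if entries:
            for name, (accepted, lineage) in entries.items():
                self.add(name, accepted, lineage)

    def add(self, input_name: str, accepted_name: str, lineage: TaxonLineage) -> None:
        self._entries[comparison_form(input_name)] = (
            canonicalize_name(accepted_name),
            lineage,
        )

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, name: str) -> bool:
        return comparison_form(name) in self._entries

    def resolve(self, raw_name: str) -> tuple[str, TaxonLineage]:
        key = comparison_form(raw_name)
        try:
            return self._entries[key]
        except KeyError:
            raise UnresolvedNameError(raw_name) from None

    def rows(self) -> Iterable[tuple[str, str, TaxonLineage]]:
        for key, (accepted, lineage) in sorted(self._entries.items()):
            yield key, accepted, lineage

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TaxonomyTable":
        table = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            missing = set(cls.COLUMNS) - set(reader.fieldnames or ())
            if missing:
                raise ValueError(
                    f"taxonomy table missing column(s): {', '.join(sorted(missing))}"
                )
            for row in reader:
                lineage = TaxonLineage(
                    *(row[r.rstrip("_")] or "" for r in RANKS)
                )
                table.add(row["input_name"], row["accepted_name"], lineage)
        return table

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(self.COLUMNS)
            for input_name, accepted, lineage in self.rows():
                writer.writerow(
                    [input_name, accepted] + [getattr(lineage, r) for r in RANKS]
                )


def resolve_lineage(raw_name: str, taxonomy_table: TaxonomyTable) -> TaxonLineage:
    """Resolve a raw organism name to its accepted lineage.

    Synonymy is handled through the table (synonym rows repeat the accepted
    lineage).  Raises :class:`UnresolvedNameError` carrying the raw name when
    the table has no entry; the caller decides whether to drop the record or
    keep it with an empty lineage.
    """
    _, lineage = taxonomy_table.resolve(raw_name)
    return lineage
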