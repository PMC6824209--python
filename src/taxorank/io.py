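"""Readers, writers and dataset-preparation rules.

Covers the standardized candidate/query tables exchanged between annotation
tools and the re-ranking pipeline, MGF spectral libraries and the filtering
rules applied to them, InChIKey handling, formula-mass QC of parent ions,
and the join that builds a benchmark set from spectra and structure-source
tables.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyteomics import mass as _pt_mass
from pyteomics import mgf as _pt_mgf
from pyteomics.auxiliary import PyteomicsError

from .taxonomy import RANKS, TaxonLineage

__all__ = [
    "CandidateRecord",
    "QueryRecord",
    "SpectrumEntry",
    "FilterReport",
    "BenchmarkBuildReport",
    "CandidateFormatError",
    "FormulaError",
    "PROTON_MASS",
    "DIALECTS",
    "shorten_inchikey",
    "read_candidates",
    "write_candidates",
    "read_queries",
    "write_queries",
    "read_mgf",
    "write_mgf",
    "filter_spectra",
    "formula_monoisotopic_mass",
    "flag_parent_mass_mismatch",
    "build_benchmark",
]

logger = logging.getLogger(__name__)

#: monoisotopic mass of a proton, Da ([M+H]+ = neutral monoisotopic + this)
PROTON_MASS = 1.007276

#: recognised candidate-table dialects; all orient scores as higher = better
#: (sirius native scores are <= 0 but already ordered that way)
DIALECTS = ("generic", "isdb", "msfinder", "sirius")

_SHORT_IK = re.compile(r"[A-Z]{14}")
_FULL_IK = re.compile(r"[A-Z]{14}-[A-Z]{10}-[A-Z]")
_FORMULA = re.compile(r"(?:[A-Z][a-z]?\d*)+")


class CandidateFormatError(ValueError):
    """A candidate table does not match the expected layout."""


class FormulaError(ValueError):
    """A molecular formula could not be parsed."""


@dataclass(frozen=True)
class CandidateRecord:
    """One query-candidate pair as returned by an annotation tool."""

    query_id: str
    short_ik: str
    raw_score: float
    tool: str = "generic"
    sources: tuple[TaxonLineage, ...] = ()
    molecule_name: str = ""

    def __post_init__(self) -> None:
        if not _SHORT_IK.fullmatch(self.short_ik):
            raise ValueError(f"not a 14-letter short InChIKey: {self.short_ik!r}")

    def with_sources(self, sources: Iterable[TaxonLineage]) -> "CandidateRecord":
        return replace(self, sources=tuple(sources))


@dataclass(frozen=True)
class QueryRecord:
    """A query spectrum: its truth (for benchmarking) and its organism."""

    query_id: str
    true_short_ik: str = ""
    lineage: TaxonLineage = field(default_factory=TaxonLineage)
    parent_mass: float | None = None
    molecular_formula: str | None = None

    def __post_init__(self) -> None:
        if self.true_short_ik and not _SHORT_IK.fullmatch(self.true_short_ik):
            raise ValueError(
                f"not a 14-letter short InChIKey: {self.true_short_ik!r}"
            )


@dataclass
class SpectrumEntry:
    """One MS/MS spectrum from an MGF library."""

    spectrum_id: str
    precursor_mz: float
    adduct: str | None = None
    peaks: list[tuple[float, float]] = field(default_factory=list)
    smiles: str | None = None
    inchi: str | None = None

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def shorten_inchikey(ik: str) -> str:
    """First 14 characters (connectivity block) of an InChIKey; idempotent.

    Stereochemistry lives in the second block, so candidate/truth comparison
    on the short key deliberately ignores stereoisomerism.
    """
    ik = ik.strip()
    if _FULL_IK.fullmatch(ik):
        return ik[:14]
    if _SHORT_IK.fullmatch(ik):
        return ik
    raise ValueError(f"not an InChIKey or 14-letter short InChIKey: {ik!r}")


# --------------------------------------------------------------------------
# candidate / query tables

_QUERY_ALIASES = ("query_id", "spectrum_id", "ccmslib", "cluster_id", "scan", "id")
_IK_ALIASES = (
    "short_inchikey",
    "short_ik",
    "inchikey_2d",
    "inchikey",
    "candidate_inchikey",
)
_SCORE_ALIASES = ("score", "raw_score", "candidate_score", "spectral_score")
_NAME_ALIASES = ("molecule_name", "compound_name", "name")
_SOURCE_ALIASES = ("sources", "source", "organism_taxonomy", "biological_source")

#: separator between several pipe-delimited lineages in one source cell
SOURCE_SEP = ";"


def _find_column(columns: Sequence[str], aliases: Sequence[str]) -> str | None:
    lowered = {c.lower(): c for c in columns}
    for a in aliases:
        if a in lowered:
            return lowered[a]
    return None


def _sep_for(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).lower().endswith(".csv") else "\t"


def _lineages_from_row(row: pd.Series, columns: Sequence[str]) -> tuple[TaxonLineage, ...]:
    lower = {c.lower(): c for c in columns}
    rank_cols = [r.rstrip("_") for r in RANKS]
    if all(r in lower for r in ("family", "genus", "species")):
        lin = TaxonLineage(
            *(str(row[lower[r]]) if r in lower and pd.notna(row.get(lower[r])) else ""
              for r in rank_cols)
        )
        return () if lin.is_empty() else (lin,)
    src_col = _find_column(columns, _SOURCE_ALIASES)
    if src_col is None or pd.isna(row.get(src_col)):
        return ()
    out = []
    for part in str(row[src_col]).split(SOURCE_SEP):
        part = part.strip()
        if part:
            lin = TaxonLineage.from_pipe(part)
            if not lin.is_empty():
                out.append(lin)
    return tuple(out)


def read_candidates(
    path: str | Path, dialect: str = "generic", sep: str | None = None
) -> list[CandidateRecord]:
    """Read a tool's candidate table into standardized records.

    The table must name a query identifier, an InChIKey (full keys are
    shortened on the fly) and a score; biological sources come either from
    dedicated ``kingdom``..``species`` columns or from a ``source`` column of
    pipe-delimited lineages (several per cell separated by ``;``).  Rows with
    unparseable scores are dropped with a row-numbered diagnostic; duplicate
    (query, candidate) pairs are merged, keeping the best score and the union
    of sources.
    """
    if dialect not in DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; valid dialects: {', '.join(DIALECTS)}"
        )
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str)
    cols = list(df.columns)
    q_col = _find_column(cols, _QUERY_ALIASES)
    ik_col = _find_column(cols, _IK_ALIASES)
    score_col = _find_column(cols, _SCORE_ALIASES + (f"{dialect}_score",))
    for needed, col in (("query id", q_col), ("InChIKey", ik_col), ("score", score_col)):
        if col is None:
            raise CandidateFormatError(
                f"{path}: no {needed} column found (looked for aliases of it)"
            )
    name_col = _find_column(cols, _NAME_ALIASES)

    merged: dict[tuple[str, str], CandidateRecord] = {}
    for i, row in df.iterrows():
        try:
            score = float(row[score_col])
        except (TypeError, ValueError):
            logger.warning(
                "%s row %d: unparseable score %r, row dropped",
                path, i + 2, row[score_col],
            )
            continue
        rec = CandidateRecord(
            query_id=str(row[q_col]),
            short_ik=shorten_inchikey(str(row[ik_col])),
            raw_score=score,
            tool=dialect,
            sources=_lineages_from_row(row, cols),
            molecule_name=(
                str(row[name_col]) if name_col and pd.notna(row.get(name_col)) else ""
            ),
        )
        key = (rec.query_id, rec.short_ik)
        prev = merged.get(key)
        if prev is None:
            merged[key] = rec
        else:
            merged[key] = replace(
                prev,
                raw_score=max(prev.raw_score, rec.raw_score),
                sources=tuple(dict.fromkeys(prev.sources + rec.sources)),
            )
    return list(merged.values())


def write_candidates(
    records: Iterable[CandidateRecord], path: str | Path, sep: str | None = None
) -> None:
    rows = []
    for r in records:
        row = {
            "query_id": r.query_id,
            "short_inchikey": r.short_ik,
            "score": r.raw_score,
            "tool": r.tool,
            "molecule_name": r.molecule_name,
            "sources": SOURCE_SEP.join(s.to_pipe() for s in r.sources),
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path, sep), index=False)


def read_queries(path: str | Path, sep: str | None = None) -> list[QueryRecord]:
    """Read a query-metadata table (one row per query spectrum)."""
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str)
    cols = list(df.columns)
    q_col = _find_column(cols, _QUERY_ALIASES)
    if q_col is None:
        raise CandidateFormatError(f"{path}: no query id column found")
    truth_col = _find_column(cols, ("true_short_inchikey", "true_short_ik") + _IK_ALIASES)
    out = []
    for _, row in df.iterrows():
        lineages = _lineages_from_row(row, cols)
        truth = ""
        if truth_col and pd.notna(row.get(truth_col)):
            truth = shorten_inchikey(str(row[truth_col]))
        pm = row.get(_find_column(cols, ("parent_mass", "precursor_mz", "pepmass")) or "")
        mf = row.get(_find_column(cols, ("molecular_formula", "formula")) or "")
        out.append(
            QueryRecord(
                query_id=str(row[q_col]),
                true_short_ik=truth,
                lineage=lineages[0] if lineages else TaxonLineage(),
                parent_mass=float(pm) if pd.notna(pm) and pm not in (None, "") else None,
                molecular_formula=str(mf) if pd.notna(mf) and mf not in (None, "") else None,
            )
        )
    return out


def write_queries(
    records: Iterable[QueryRecord], path: str | Path, sep: str | None = None
) -> None:
    rows = []
    for q in records:
        row = {"query_id": q.query_id, "true_short_inchikey": q.true_short_ik}
        for r in RANKS:
            row[r.rstrip("_")] = getattr(q.lineage, r)
        row["parent_mass"] = q.parent_mass
        row["molecular_formula"] = q.molecular_formula or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path, sep), index=False)


# --------------------------------------------------------------------------
# MGF spectral libraries

_ADDUCT_KEYS = ("adduct", "precursor_type", "precursortype", "ionmode_adduct")
_MH_TOKEN = re.compile(r"\[M\+H\]\+|\bM\+H\b")


def _extract_adduct(params: dict) -> str | None:
    for key in _ADDUCT_KEYS:
        if key in params and str(params[key]).strip():
            return str(params[key]).strip()
    # some library dialects embed the adduct in the NAME/TITLE field
    for key in ("name", "title"):
        if key in params and _MH_TOKEN.search(str(params[key])):
            return "[M+H]+"
    return None


def read_mgf(path: str | Path) -> list[SpectrumEntry]:
    """Parse an MGF spectral library into :class:`SpectrumEntry` objects."""
    entries = []
    with _pt_mgf.MGF(str(path), convert_arrays=0) as reader:
        for i, spec in enumerate(reader):
            params = {k.lower(): v for k, v in spec["params"].items()}
            sid = str(
                params.get("spectrumid")
                or params.get("spectrum_id")
                or params.get("title")
                or f"spectrum_{i}"
            )
            pepmass = params.get("pepmass", (0.0,))
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            peaks = sorted(
                zip((float(m) for m in spec["m/z array"]),
                    (float(x) for x in spec["intensity array"]))
            )
            entries.append(
                SpectrumEntry(
                    spectrum_id=sid,
                    precursor_mz=precursor,
                    adduct=_extract_adduct(params),
                    peaks=peaks,
                    smiles=str(params["smiles"]) if params.get("smiles") else None,
                    inchi=str(params["inchi"]) if params.get("inchi") else None,
                )
            )
    return entries


def write_mgf(entries: Iterable[SpectrumEntry], path: str | Path) -> None:
    spectra = []
    for e in entries:
        params = {"TITLE": e.spectrum_id, "PEPMASS": e.precursor_mz,
                  "SPECTRUMID": e.spectrum_id}
        if e.adduct:
            params["ADDUCT"] = e.adduct
        if e.smiles:
            params["SMILES"] = e.smiles
        if e.inchi:
            params["INCHI"] = e.inchi
        peaks = sorted(e.peaks)
        spectra.append(
            {
                "params": params,
                "m/z array": [p[0] for p in peaks],
                "intensity array": [p[1] for p in peaks],
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        _pt_mgf.write(spectra, fh)


@dataclass
class FilterReport:
    """Counts of spectra removed or altered by each library-filtering rule."""

    n_input: int = 0
    dropped_min_fragments: int = 0
    dropped_mass_range: int = 0
    dropped_adduct: int = 0
    truncated: int = 0
    n_kept: int = 0

    @property
    def n_dropped(self) -> int:
        return self.dropped_min_fragments + self.dropped_mass_range + self.dropped_adduct


def filter_spectra(
    entries: Sequence[SpectrumEntry],
    min_fragments: int = 6,
    max_fragments: int = 500,
    mass_low: float = 100.0,
    mass_high: float = 1500.0,
    protonated_only: bool = True,
) -> tuple[list[SpectrumEntry], FilterReport]:
    """Apply the spectral-library curation rules.

    Spectra with fewer than ``min_fragments`` peaks are dropped; spectra with
    more than ``max_fragments`` keep only the most intense ones (ties at the
    cutoff keep the lower-m/z peak); parent masses must lie in
    [``mass_low``, ``mass_high``]; with ``protonated_only``, anything not
    annotated as a [M+H]+ adduct (including unannotated spectra) is dropped.
    """
    report = FilterReport(n_input=len(entries))
    kept: list[SpectrumEntry] = []
    for e in entries:
        if e.n_peaks < min_fragments:
            report.dropped_min_fragments += 1
            continue
        if not (mass_low <= e.precursor_mz <= mass_high):
            report.dropped_mass_range += 1
            continue
        if protonated_only and not (e.adduct and _MH_TOKEN.search(e.adduct)):
            report.dropped_adduct += 1
            continue
        if e.n_peaks > max_fragments:
            top = sorted(e.peaks, key=lambda p: (-p[1], p[0]))[:max_fragments]
            e = replace(e, peaks=sorted(top))
            report.truncated += 1
        kept.append(e)
    report.n_kept = len(kept)
    return kept, report


# --------------------------------------------------------------------------
# formula masses and parent-mass QC

def formula_monoisotopic_mass(formula: str) -> float:
    """Monoisotopic (principal-isotope) mass of a Hill-notation formula, Da."""
    formula = (formula or "").strip()
    if not formula or not _FORMULA.fullmatch(formula):
        raise FormulaError(f"malformed molecular formula: {formula!r}")
    try:
        return float(_pt_mass.calculate_mass(formula=formula))
    except PyteomicsError as exc:  # unknown element symbol
        raise FormulaError(f"cannot compute mass of {formula!r}: {exc}") from exc


def flag_parent_mass_mismatch(
    entry: SpectrumEntry, formula: str, tolerance: float = 0.01
) -> tuple[bool, float]:
    """Compare an experimental [M+H]+ parent mass with the formula's exact mass.

    Returns ``(flagged, difference)`` where difference = observed precursor
    minus expected protonated mass; flagged iff |difference| exceeds the
    tolerance strictly.  Catches curation errors like spectra whose recorded
    parent ion is tens of Da away from the structure they claim to represent.
    """
    expected = formula_monoisotopic_mass(formula) + PROTON_MASS
    diff = entry.precursor_mz - expected
    return abs(diff) > tolerance, diff


# --------------------------------------------------------------------------
# benchmark construction

@dataclass
class BenchmarkBuildReport:
    """Row accounting for the spectra/structure/source join."""

    n_spectra: int = 0
    n_source_rows: int = 0
    dropped_incomplete_species: int = 0
    dropped_ambiguous_structures: int = 0
    duplicate_spectra_discarded: int = 0
    discarded_spectrum_ids: list[str] = field(default_factory=list)
    n_queries: int = 0


def build_benchmark(
    spectral_table: Sequence[tuple[str, str, float]],
    source_table: Sequence[tuple[str, TaxonLineage]],
) -> tuple[list[QueryRecord], BenchmarkBuildReport]:
    """Join spectra with structure-source rows into benchmark queries.

    Both tables are keyed by the 14-letter short InChIKey.  Source rows whose
    lineage is not resolved down to the species level are dropped; structures
    reported from more than one distinct lineage are dropped entirely (the
    benchmark requires an unambiguous organism per structure); several spectra
    of one structure collapse to the first by input order, with the discarded
    spectrum ids recorded.
    """
    report = BenchmarkBuildReport(
        n_spectra=len(spectral_table), n_source_rows=len(source_table)
    )
    by_ik: dict[str, list[TaxonLineage]] = {}
    for ik, lineage in source_table:
        ik = shorten_inchikey(ik)
        if not (lineage.family and lineage.genus and lineage.species):
            report.dropped_incomplete_species += 1
            continue
        bucket = by_ik.setdefault(ik, [])
        if lineage not in bucket:
            bucket.append(lineage)

    unambiguous: dict[str, TaxonLineage] = {}
    for ik, lineages in by_ik.items():
        if len(lineages) == 1:
            unambiguous[ik] = lineages[0]
        else:
            report.dropped_ambiguous_structures += 1

    queries: list[QueryRecord] = []
    seen_ik: set[str] = set()
    for spectrum_id, ik, precursor in spectral_table:
        ik = shorten_inchikey(ik)
        if ik not in unambiguous:
            continue
        if ik in seen_ik:
            report.duplicate_spectra_discarded += 1
            report.discarded_spectrum_ids.append(spectrum_id)
            continue
        seen_ik.add(ik)
        queries.append(
            QueryRecord(
                query_id=spectrum_id,
                true_short_ik=ik,
                lineage=unambiguous[ik],
                parent_mass=precursor,
            )
        )
    report.n_queries = len(queries)
    return queries, report
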