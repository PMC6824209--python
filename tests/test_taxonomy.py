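"""Lineage canonicalisation, level matching and the taxonomic bonus."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from taxorank.taxonomy import (
    TaxonLineage,
    TaxonomyTable,
    UnresolvedNameError,
    WeightVector,
    canonicalize_name,
    comparison_form,
    match_levels,
    resolve_lineage,
    taxonomic_bonus,
)

GLAUCIUM_QUERY = TaxonLineage(
    family="Papaveraceae", genus="Glaucium", species="Glaucium grandiflorum"
)


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("  Glaucium  ", "Glaucium"),
        ("Glaucium   grandiflorum", "Glaucium grandiflorum"),
        ("NA", ""),
        ("n/a", ""),
        ("-", ""),
        ("", ""),
        (None, ""),
    ],
)
def test_canonicalize_name(raw, expected):
    assert canonicalize_name(raw) == expected


def test_comparison_is_case_insensitive():
    assert comparison_form("papaveraceae") == comparison_form("Papaveraceae")


class TestTaxonLineage:
    def test_placeholder_species_becomes_unknown(self):
        lin = TaxonLineage(family="Papaveraceae", genus="Glaucium", species="NA")
        assert lin.species == ""

    def test_binomial_inconsistency_rejected(self):
        with pytest.raises(ValueError, match="binomial"):
            TaxonLineage(genus="Glaucium", species="Papaver somniferum")

    def test_pipe_roundtrip_and_partial_depth(self):
        full = GLAUCIUM_QUERY
        assert TaxonLineage.from_pipe(full.to_pipe()) == full
        partial = TaxonLineage.from_pipe(
            "Plantae|Tracheophyta|Magnoliopsida|Ranunculales|Ranunculaceae"
        )
        assert partial.family == "Ranunculaceae"
        assert partial.genus == "" and partial.species == ""


class TestMatchLevels:
    @pytest.mark.parametrize(
        "source, expected",
        [
            # genus-level neighbour species: family+genus match, species differ
            (TaxonLineage(family="Papaveraceae", genus="Glaucium",
                          species="Glaucium oxylobum"), (True, True, False)),
            (GLAUCIUM_QUERY, (True, True, True)),
            (TaxonLineage(family="Ranunculaceae", genus="Pulsatilla",
                          species="Pulsatilla cernua"), (False, False, False)),
            # unknown species on the source side can never match
            (TaxonLineage(family="Papaveraceae", genus="Glaucium"),
             (True, True, False)),
        ],
    )
    def test_examples(self, source, expected):
        assert tuple(match_levels(GLAUCIUM_QUERY, source)) == expected

    def test_symmetry(self):
        src = TaxonLineage(family="Papaveraceae", genus="Sarcocapnos",
                           species="Sarcocapnos crassifolia")
        assert match_levels(GLAUCIUM_QUERY, src) == match_levels(src, GLAUCIUM_QUERY)

    def test_case_insensitive_match(self):
        src = TaxonLineage(family="papaveraceae")
        assert match_levels(GLAUCIUM_QUERY, src).family


class TestTaxonomicBonus:
    OPT = WeightVector.optimized()

    def test_genus_level_match(self):
        src = TaxonLineage(family="Papaveraceae", genus="Glaucium",
                           species="Glaucium oxylobum")
        ls = taxonomic_bonus(GLAUCIUM_QUERY, [src], self.OPT)
        assert (ls.family_score, ls.genus_score, ls.species_score) == (0.81, 1.62, 0)
        assert ls.max_taxo_score == 1.62

    def test_family_level_match(self):
        src = TaxonLineage(family="Papaveraceae", genus="Sarcocapnos",
                           species="Sarcocapnos crassifolia")
        ls = taxonomic_bonus(GLAUCIUM_QUERY, [src], self.OPT)
        assert (ls.family_score, ls.genus_score, ls.species_score) == (0.81, 0, 0)
        assert ls.max_taxo_score == 0.81

    def test_no_sources_no_bonus(self):
        ls = taxonomic_bonus(GLAUCIUM_QUERY, [], self.OPT)
        assert ls == type(ls).zero()

    def test_multiple_sources_take_per_level_or(self):
        fam_only = TaxonLineage(family="Papaveraceae", genus="Sarcocapnos")
        sp_match = GLAUCIUM_QUERY
        ls = taxonomic_bonus(GLAUCIUM_QUERY, [fam_only, sp_match], self.OPT)
        assert ls.max_taxo_score == 2.55

    @given(st.lists(st.sampled_from([
        TaxonLineage(family="Papaveraceae", genus="Glaucium",
                     species="Glaucium oxylobum"),
        TaxonLineage(family="Papaveraceae", genus="Sarcocapnos"),
        GLAUCIUM_QUERY,
        TaxonLineage(family="Ranunculaceae"),
    ]), max_size=4), st.sampled_from([
        WeightVector.default(), WeightVector.optimized(), WeightVector(2, 1, 0.5)
    ]))
    def test_monotone_in_sources_and_max_in_weight_set(self, sources, weights):
        """Adding a source never lowers any level score; the max is one of
        {0, w_family, w_genus, w_species}."""
        base = taxonomic_bonus(GLAUCIUM_QUERY, sources, weights)
        extended = taxonomic_bonus(GLAUCIUM_QUERY, sources + [GLAUCIUM_QUERY], weights)
        assert extended.family_score >= base.family_score
        assert extended.genus_score >= base.genus_score
        assert extended.species_score >= base.species_score
        assert extended.max_taxo_score >= base.max_taxo_score
        assert base.max_taxo_score in {0.0, weights.w_family, weights.w_genus,
                                       weights.w_species}

    def test_deepest_level_wins_with_consistent_weights(self):
        w = WeightVector.default()
        ls = taxonomic_bonus(GLAUCIUM_QUERY, [GLAUCIUM_QUERY], w)
        assert ls.max_taxo_score == w.w_species


class TestWeightVector:
    def test_presets_and_consistency_flag(self):
        assert WeightVector.default().as_tuple() == (1, 2, 3)
        assert WeightVector.optimized().as_tuple() == (0.81, 1.62, 2.55)
        assert WeightVector.optimized().depth_monotone
        assert not WeightVector(3, 2, 1).depth_monotone

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            WeightVector(-0.1, 1, 2)

    @pytest.mark.parametrize("text, expected", [
        ("1,2,3", (1, 2, 3)),
        ("optimized", (0.81, 1.62, 2.55)),
        ("default", (1, 2, 3)),
    ])
    def test_from_text(self, text, expected):
        assert WeightVector.from_text(text).as_tuple() == expected


class TestResolveLineage:
    @pytest.fixture
    def table(self):
        cernua = TaxonLineage(
            kingdom="Plantae", family="Ranunculaceae", genus="Pulsatilla",
            species="Pulsatilla cernua",
        )
        t = TaxonomyTable()
        t.add("Pulsatilla cernua", "Pulsatilla cernua", cernua)
        t.add("Pulsatilla koreana", "Pulsatilla cernua", cernua)  # synonym
        return t

    def test_synonym_resolves_to_accepted_lineage(self, table):
        lin = resolve_lineage("Pulsatilla koreana", table)
        assert (lin.genus, lin.species) == ("Pulsatilla", "Pulsatilla cernua")

    def test_accepted_name_is_identity(self, table):
        lin = resolve_lineage("Pulsatilla cernua", table)
        assert lin.species == "Pulsatilla cernua"

    def test_lookup_is_canonicalized(self, table):
        assert resolve_lineage("  pulsatilla   KOREANA ", table).genus == "Pulsatilla"

    def test_unknown_name_raises_with_raw_name(self, table):
        with pytest.raises(UnresolvedNameError) as exc:
            resolve_lineage("Glaucium flavum", table)
        assert exc.value.raw_name == "Glaucium flavum"

    def test_tsv_roundtrip(self, table, tmp_path):
        path = tmp_path / "taxonomy.tsv"
        table.write_tsv(path)
        back = TaxonomyTable.read_tsv(path)
        assert len(back) == len(table)
        assert resolve_lineage("Pulsatilla koreana", back).species == "Pulsatilla cernua"
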