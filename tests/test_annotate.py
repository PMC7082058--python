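"""Annotation, taxon-specificity filtering, gene rollup, normalization, and
peptidome-sharing statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from taxopept.annotate import (
    TaxonFilter,
    annotate_peptides,
    apply_taxon_filter,
    genus_peptidome_stats,
    normalize_reference_pool,
    rollup_to_genes,
    shared_peptidome_fraction,
    strip_modifications,
)
from taxopept.digest import DigestParams
from taxopept.pcdb import create_pcdb, index_pcdb
from taxopept.proteomes import ProteinRecord
from taxopept.taxonomy import TaxonomyIndex


@pytest.fixture
def two_species_index():
    """Minimal taxonomy: human-like (9606) and mouse-like (10090) species
    under distinct genera."""
    idx = TaxonomyIndex()
    rows = [
        (1, 1, "no rank", "root"),
        (2, 1, "superkingdom", "Eukaryota"),
        (9605, 2, "genus", "Homo"),
        (9606, 9605, "species", "Homo sapiens"),
        (10088, 2, "genus", "Mus"),
        (10090, 10088, "species", "Mus musculus"),
    ]
    for tax_id, parent, rank, name in rows:
        idx.parent_of[tax_id] = parent
        idx.rank_of[tax_id] = rank
        idx.name_of[tax_id] = name
    return idx


@pytest.fixture
def toy_db(tmp_path, toy_records):
    return index_pcdb(create_pcdb(toy_records, DigestParams(), tmp_path / "t.pcdb"))


@pytest.fixture
def annotated(toy_db, two_species_index):
    table = pd.DataFrame(
        {
            "Sequence": ["HAPPYWDAYK", "NLCEMEATK", "SHAREDPEPTLDEK"],
            "Reporter intensity 0": [3.0, 5.0, 7.0],
            "Reporter intensity 1": [1.0, 2.0, 4.0],
        }
    )
    return annotate_peptides(table, toy_db, two_species_index, ["species"])


def test_strip_modifications_dialects():
    assert strip_modifications("PEPT(+79.97)IDEK") == "PEPTIDEK"
    assert strip_modifications("_M(ox)AGICK_") == "MAGICK"
    assert strip_modifications("AC[Carbamidomethyl]DK") == "ACDK"


class TestAnnotate:
    def test_uniqueness_flags_on_planted_fixture(self, annotated):
        assert annotated["Matched"].tolist() == [True, True, True]
        assert annotated["Unique species"].tolist() == [True, True, False]
        assert annotated["Taxa species"].tolist() == [
            "Homo sapiens",
            "Mus musculus",
            "Homo sapiens;Mus musculus",
        ]

    def test_quant_columns_untouched(self, annotated):
        assert annotated["Reporter intensity 0"].tolist() == [3.0, 5.0, 7.0]

    def test_empty_table(self, toy_db, two_species_index):
        out = annotate_peptides(
            pd.DataFrame({"Sequence": []}), toy_db, two_species_index, ["species"]
        )
        assert len(out) == 0 and "Unique species" in out.columns

    def test_isoleucine_spelling_still_matches(self, toy_db, two_species_index):
        table = pd.DataFrame({"Sequence": ["SHAREDPEPTIDEK"]})
        out = annotate_peptides(table, toy_db, two_species_index, ["species"])
        assert out["Matched"].all()

    def test_modified_sequence_matches_via_stripping(self, toy_db, two_species_index):
        table = pd.DataFrame({"Sequence": ["HAPPYW(+15.99)DAYK"]})
        out = annotate_peptides(table, toy_db, two_species_index, ["species"])
        assert out["Matched"].all()

    def test_unmatched_rows_retained_with_flag(self, toy_db, two_species_index):
        table = pd.DataFrame({"Sequence": ["HAPPYWDAYK", "QQQQQQQQK"]})
        out = annotate_peptides(table, toy_db, two_species_index, ["species"])
        assert out["Matched"].tolist() == [True, False]

    def test_missing_sequence_column_names_expectation(self, toy_db, two_species_index):
        with pytest.raises(KeyError, match="Sequence"):
            annotate_peptides(
                pd.DataFrame({"pep": ["AAK"]}), toy_db, two_species_index, ["species"]
            )


class TestTaxonFilter:
    def test_method2_drops_shared_peptide(self, annotated, two_species_index):
        filt = TaxonFilter(rank="species", include=("Homo sapiens",), require_unique=True)
        out = apply_taxon_filter(annotated, filt, two_species_index)
        assert out["Sequence"].tolist() == ["HAPPYWDAYK"]
        assert out["Assigned taxon"].tolist() == ["Homo sapiens"]

    def test_method1_default_taxon_keeps_and_attributes_shared(
        self, annotated, two_species_index
    ):
        filt = TaxonFilter(
            rank="species",
            default_taxon="Homo sapiens",
            exclude=("Mus musculus",),
            require_unique=False,
        )
        out = apply_taxon_filter(annotated, filt, two_species_index)
        assert out["Sequence"].tolist() == ["HAPPYWDAYK", "SHAREDPEPTLDEK"]
        assert set(out["Assigned taxon"]) == {"Homo sapiens"}
        # shared peptide attributed to the human gene only
        assert out["Assigned genes"].tolist() == ["GH1", "GH1"]

    def test_exclude_only_drops_pure_mouse_hits(self, annotated, two_species_index):
        filt = TaxonFilter(rank="species", exclude=("Mus musculus",))
        out = apply_taxon_filter(annotated, filt, two_species_index)
        assert "NLCEMEATK" not in out["Sequence"].tolist()

    def test_method2_subset_of_method1(self, annotated, two_species_index):
        m2 = apply_taxon_filter(
            annotated,
            TaxonFilter(rank="species", include=("Homo sapiens",), require_unique=True),
            two_species_index,
        )
        m1 = apply_taxon_filter(
            annotated,
            TaxonFilter(rank="species", default_taxon="Homo sapiens"),
            two_species_index,
        )
        assert set(m2.index) <= set(m1.index)

    def test_ambiguous_configuration_rejected(self):
        with pytest.raises(ValueError):
            TaxonFilter(
                rank="species",
                include=("A", "B"),
                default_taxon="A",
                require_unique=True,
            )
        with pytest.raises(ValueError):
            TaxonFilter(rank="species", include=("A",), exclude=("A",))


class TestRollup:
    def _filtered(self, annotated, index):
        return apply_taxon_filter(
            annotated,
            TaxonFilter(rank="species", default_taxon="Homo sapiens"),
            index,
        )

    def test_additivity(self, annotated, two_species_index):
        filtered = self._filtered(annotated, two_species_index)
        genes = rollup_to_genes(filtered, ["Reporter intensity 0"])
        # HAPPYWDAYK (3.0) and SHAREDPEPTLDEK (7.0) both map to GH1
        assert genes.loc["GH1", "Reporter intensity 0"] == 10.0
        assert genes.loc["GH1", "Peptide count"] == 2

    def test_conservation_of_column_sums(self, annotated, two_species_index):
        filtered = self._filtered(annotated, two_species_index)
        cols = ["Reporter intensity 0", "Reporter intensity 1"]
        genes = rollup_to_genes(filtered, cols)
        for c in cols:
            assert genes[c].sum() == filtered[c].sum()

    def test_zero_peptide_genes_absent(self, annotated, two_species_index):
        filtered = self._filtered(annotated, two_species_index)
        genes = rollup_to_genes(filtered, ["Reporter intensity 0"])
        assert "GM1" not in genes.index

    def test_multi_gene_rows_dropped_and_counted(self):
        table = pd.DataFrame(
            {
                "Assigned genes": ["A", "A;B", ""],
                "I": [1.0, 2.0, 3.0],
            }
        )
        genes = rollup_to_genes(table, ["I"])
        assert genes["I"].sum() == 1.0
        assert genes.attrs["n_dropped_ambiguous_gene"] == 2

    def test_missing_quant_column_is_schema_error(self, annotated, two_species_index):
        filtered = self._filtered(annotated, two_species_index)
        with pytest.raises(KeyError, match="Nope"):
            rollup_to_genes(filtered, ["Nope"])


class TestNormalization:
    def test_output_channels_have_median_zero_sd_one(self, rng):
        table = pd.DataFrame(
            {c: [rng.lognormvariate(8, 1) for _ in range(30)] for c in "RABC"}
        )
        out = normalize_reference_pool(table, "R")
        assert list(out.columns) == ["A", "B", "C"]
        assert np.allclose(out.median(), 0.0, atol=1e-9)
        assert np.allclose(out.std(ddof=0), 1.0, atol=1e-9)

    def test_reference_ratio_to_itself_is_zero_before_scaling(self):
        # x/x = 1, log2 1 = 0, median-centering keeps 0
        table = pd.DataFrame({"R": [2.0, 4.0, 8.0]})
        ratios = np.log2(table["R"] / table["R"])
        centered = ratios - ratios.median()
        assert (centered == 0).all()

    def test_five_gene_hand_worked_example(self):
        """Hand-traced through ratio -> log2 -> median-center -> SD-scale."""
        table = pd.DataFrame(
            {
                "ref": [2.0, 4.0, 8.0, 16.0, 2.0],
                "c1": [4.0, 4.0, 4.0, 32.0, 1.0],
                "c2": [2.0, 8.0, 16.0, 8.0, 8.0],
            },
            index=list("ABCDE"),
        )
        out = normalize_reference_pool(table, "ref")
        # c1: ratios (2,1,.5,2,.5) -> log2 (1,0,-1,1,-1), median 0,
        #     pop-SD sqrt(0.8) -> +-1/sqrt(0.8)
        s1 = 1 / math.sqrt(0.8)
        assert np.allclose(out["c1"], [s1, 0.0, -s1, s1, -s1])
        # c2: ratios (1,2,2,.5,4) -> log2 (0,1,1,-1,2), median 1,
        #     centered (-1,0,0,-2,1) with mean -0.4,
        #     pop-SD sqrt(6/5 - 0.4^2) = sqrt(1.04)
        s2 = 1 / math.sqrt(1.04)
        assert np.allclose(out["c2"], [-s2, 0.0, 0.0, -2 * s2, s2])

    def test_nonpositive_reference_genes_dropped_and_counted(self):
        table = pd.DataFrame({"ref": [2.0, 0.0, 4.0], "c": [1.0, 1.0, 2.0]})
        out = normalize_reference_pool(table, "ref")
        assert len(out) == 2
        assert out.attrs["n_dropped_no_reference"] == 1

    def test_fewer_than_two_genes_rejected(self):
        table = pd.DataFrame({"ref": [2.0], "c": [1.0]})
        with pytest.raises(ValueError):
            normalize_reference_pool(table, "ref")


class TestSharedPeptidome:
    def _pair(self, seq_a, seq_b, gene="G"):
        a = [ProteinRecord("A1", gene, 9606, seq_a)]
        b = [ProteinRecord("B1", gene, 10090, seq_b)]
        return a, b

    def test_identical_homologs_share_everything(self):
        a, b = self._pair("MHAPPYWDAYKSTRANGEPEPK", "MHAPPYWDAYKSTRANGEPEPK")
        table, summary = shared_peptidome_fraction(a, b)
        assert (table["fraction"] == 1.0).all()
        assert summary == 1.0

    def test_engineered_two_of_five_fraction(self):
        # five fragments, first two shared; 0-missed digest makes it exact
        shared = ["AAADDFFK", "CCCEEGGR"]
        only_a = ["HHHLLNNK", "PPPQQSSR", "TTTVVWWK"]
        only_b = ["DDDFFHHK", "EEEGGLLR", "NNNPPQQK"]
        a, b = self._pair("".join(shared + only_a), "".join(shared + only_b))
        params = DigestParams(max_missed_cleavages=0, nterm_met_excision=False)
        table, _ = shared_peptidome_fraction(a, b, params)
        assert table.loc["G", "n_peptides"] == 5
        assert table.loc["G", "fraction"] == pytest.approx(0.4)

    def test_fully_divergent_pair_shares_nothing(self):
        a, b = self._pair("MHAPPYWDAYKSTRANGEPEPK", "MNNGGEECCTKFFDDLLSSWK")
        table, summary = shared_peptidome_fraction(a, b)
        assert (table["fraction"] == 0.0).all()
        assert summary == 0.0

    def test_gene_absent_in_b_scores_zero_and_flagged(self):
        a = [ProteinRecord("A1", "ONLYA", 9606, "MHAPPYWDAYKSTRANGEPEPK")]
        table, _ = shared_peptidome_fraction(a, [])
        assert table.loc["ONLYA", "fraction"] == 0.0
        assert not table.loc["ONLYA", "gene_in_b"]


class TestGenusPeptidomeStats:
    def test_engineered_shared_peptide_between_two_genera(
        self, tmp_path, toy_records, two_species_index
    ):
        handle = index_pcdb(
            create_pcdb(toy_records, DigestParams(), tmp_path / "g.pcdb")
        )
        stats = genus_peptidome_stats(handle, two_species_index)
        # the planted SHAR|EDPEPTLDEK block spans Homo and Mus and yields
        # exactly two shared distinct peptides: EDPEPTLDEK and the 1-missed
        # SHAREDPEPTLDEK (SHAR alone is below the length floor)
        assert stats.loc["Homo", "total"] - stats.loc["Homo", "unique"] == 2
        assert stats.loc["Mus", "total"] - stats.loc["Mus", "unique"] == 2
        assert stats.loc["Homo", "fraction_shared"] == pytest.approx(
            2 / stats.loc["Homo", "total"]
        )

    def test_single_genus_database_all_unique(self, tmp_path, two_species_index):
        records = [
            ProteinRecord("P1", "G1", 9606, "MHAPPYWDAYKSTRANGEPEPK"),
            ProteinRecord("P2", "G2", 9606, "MNNGGEECCTKFFDDLLSSWK"),
        ]
        handle = index_pcdb(create_pcdb(records, DigestParams(), tmp_path / "s.pcdb"))
        stats = genus_peptidome_stats(handle, two_species_index)
        assert list(stats.index) == ["Homo"]
        assert stats.loc["Homo", "fraction_shared"] == 0.0

    def test_unique_partition_bound(self, tmp_path, toy_records, two_species_index):
        handle = index_pcdb(
            create_pcdb(toy_records, DigestParams(), tmp_path / "b.pcdb")
        )
        stats = genus_peptidome_stats(handle, two_species_index)
        n_distinct = handle.conn.execute(
            "SELECT COUNT(DISTINCT hash_peptide) FROM Reference"
        ).fetchone()[0]
        assert stats["unique"].sum() <= n_distinct
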