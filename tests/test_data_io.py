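import gzip

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from opstoich import load_table1_kinetics
from opstoich.data_io import (
    CONFIDENCE_MODES,
    filter_confident,
    read_gff3,
    read_operon_annotation,
    read_quant_table,
    sequence_coverage,
    write_table,
)
from opstoich.errors import CrossReferenceError, SchemaError, UsageError, ValidationError


class TestReadQuantTable:
    def test_round_trip_preserves_rows_and_order(self, quant_frame, tmp_path):
        path = tmp_path / "q.tsv"
        write_table(quant_frame, path)
        back = read_quant_table(path, "protein_quant")
        pd.testing.assert_frame_equal(back, quant_frame)

    def test_gzip_round_trip(self, quant_frame, tmp_path):
        path = tmp_path / "q.tsv.gz"
        with gzip.open(path, "wt") as fh:
            quant_frame.to_csv(fh, sep="\t", index=False)
        back = read_quant_table(path, "protein_quant")
        assert list(back["intensity"]) == [10.0, 20.0, 30.0]

    def test_missing_intensity_column_is_schema_error(self, quant_frame, tmp_path):
        path = tmp_path / "q.tsv"
        write_table(quant_frame.drop(columns=["intensity"]), path)
        with pytest.raises(SchemaError, match="intensity"):
            read_quant_table(path, "protein_quant")

    def test_negative_value_reports_row_number(self, quant_frame, tmp_path):
        quant_frame.loc[1, "intensity"] = -5.0
        path = tmp_path / "q.tsv"
        write_table(quant_frame, path)
        with pytest.raises(ValidationError, match="row 3"):
            read_quant_table(path, "protein_quant")

    def test_duplicate_gene_rows_rejected(self, quant_frame, tmp_path):
        quant_frame.loc[2, "gene_name"] = "g1"
        path = tmp_path / "q.tsv"
        write_table(quant_frame, path)
        with pytest.raises(ValidationError, match="duplicate"):
            read_quant_table(path, "protein_quant")

    def test_unknown_schema(self, tmp_path):
        with pytest.raises(SchemaError):
            read_quant_table(tmp_path / "x.tsv", "nope")


class TestKineticsFixture:
    def test_argb_row_has_both_parameters(self):
        recs = {r.enzyme_gene: r for r in load_table1_kinetics()}
        argb = recs["ArgB"]
        assert argb.K_M == 1.3
        assert argb.k_cat == 4.9
        assert argb.k_cat_organism == "S. cerevisiae"
        assert argb.K_M_organism == "E. coli"

    def test_all_records_have_at_least_one_parameter(self):
        for rec in load_table1_kinetics():
            assert rec.k_cat is not None or rec.K_M is not None

    def test_km_only_enzymes_parse_without_kcat(self):
        recs = {r.enzyme_gene: r for r in load_table1_kinetics()}
        assert recs["AceB"].k_cat is None
        assert recs["AceB"].K_M == 0.022
        assert recs["CysD + CysN"].K_M_organism == "Thiobacillus denitrificans"


class TestFilterConfident:
    @pytest.mark.parametrize(
        "unique,length,mode,kept",
        [
            (1, 6, "relaxed", True),
            (0, 6, "relaxed", False),
            (1, 5, "relaxed", False),
            (1, 7, "stringent", False),
            (2, 6, "stringent", False),
            (2, 7, "stringent", True),
        ],
    )
    def test_boundaries(self, unique, length, mode, kept):
        df = pd.DataFrame(
            {
                "protein_id": ["p"],
                "gene_name": ["g"],
                "intensity": [1.0],
                "n_unique_peptides": [unique],
                "min_peptide_length": [length],
            }
        )
        out = filter_confident(df, mode)
        assert (len(out) == 1) == kept

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.integers(4, 12)), min_size=1, max_size=30
        )
    )
    def test_stringent_subset_of_relaxed(self, evidence):
        df = pd.DataFrame(
            {
                "protein_id": [f"p{i}" for i in range(len(evidence))],
                "gene_name": [f"g{i}" for i in range(len(evidence))],
                "intensity": [1.0] * len(evidence),
                "n_unique_peptides": [u for u, _ in evidence],
                "min_peptide_length": [l for _, l in evidence],
            }
        )
        stringent = set(filter_confident(df, "stringent")["gene_name"])
        relaxed = set(filter_confident(df, "relaxed")["gene_name"])
        assert stringent <= relaxed

    def test_unknown_mode(self, quant_frame):
        with pytest.raises(UsageError):
            filter_confident(quant_frame, "medium")

    def test_modes_match_documented_thresholds(self):
        assert CONFIDENCE_MODES == {"relaxed": (1, 6), "stringent": (2, 7)}


class TestSequenceCoverage:
    @pytest.mark.parametrize(
        "peptides,protein,expected",
        [
            (["ABC"], "ABCDEF", 0.5),
            (["ABC", "CDE"], "ABCDEF", 5 / 6),  # brute-force position marking
            ([], "ABCDEF", 0.0),
            (["AB"], "ABAB", 1.0),  # all occurrences of a repeated peptide
            (["ABCDEFGH"], "ABC", 0.0),  # peptide longer than protein
        ],
    )
    def test_examples(self, peptides, protein, expected):
        assert sequence_coverage(peptides, protein) == pytest.approx(expected)

    def test_overlaps_counted_once_against_brute_force(self):
        protein = "MKVLAAGMKVL"
        peptides = ["MKVL", "VLAA", "AGMK"]
        # independent oracle: mark every matched position naively
        marks = set()
        for pep in peptides:
            for i in range(len(protein) - len(pep) + 1):
                if protein[i : i + len(pep)] == pep:
                    marks.update(range(i, i + len(pep)))
        assert sequence_coverage(peptides, protein) == pytest.approx(
            len(marks) / len(protein)
        )


class TestOperonAnnotation:
    def _write(self, tmp_path, operon_rows, gff_genes):
        op_path = tmp_path / "operons.tsv"
        with open(op_path, "w") as fh:
            fh.write("operon_id\tgene_ids\n")
            for oid, genes in operon_rows:
                fh.write(f"{oid}\t{','.join(genes)}\n")
        gff_path = tmp_path / "genes.gff3"
        with open(gff_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gid, start, end, strand in gff_genes:
                fh.write(
                    f"chr1\ttest\tCDS\t{start}\t{end}\t.\t{strand}\t0\tID={gid}\n"
                )
        return op_path, gff_path

    def test_plus_strand_order(self, tmp_path):
        op, gff = self._write(
            tmp_path, [("o1", ["gB", "gA"])],
            [("gA", 100, 400, "+"), ("gB", 500, 900, "+")],
        )
        operons, ann = read_operon_annotation(op, gff)
        assert operons[0].gene_ids == ("gA", "gB")
        assert ann["gA"].cds_length_nt == 301

    def test_minus_strand_mirror(self, tmp_path):
        op, gff = self._write(
            tmp_path, [("o1", ["gA", "gB"])],
            [("gA", 100, 400, "-"), ("gB", 500, 900, "-")],
        )
        operons, _ = read_operon_annotation(op, gff)
        assert operons[0].gene_ids == ("gB", "gA")

    def test_reordering_is_idempotent(self, tmp_path):
        op, gff = self._write(
            tmp_path, [("o1", ["gB", "gA"])],
            [("gA", 100, 400, "+"), ("gB", 500, 900, "+")],
        )
        once, ann = read_operon_annotation(op, gff)
        from opstoich.data_io import _order_operon_genes

        twice, _ = _order_operon_genes(once[0].gene_ids, ann)
        assert twice == once[0].gene_ids

    def test_unknown_gene_named_in_error(self, tmp_path):
        op, gff = self._write(
            tmp_path,
            [("o1", ["gA", "gX"])],
            [("gA", 100, 400, "+")],
        )
        with pytest.raises(CrossReferenceError, match="gX"):
            read_operon_annotation(op, gff)

    def test_mixed_strands_rejected(self, tmp_path):
        op, gff = self._write(
            tmp_path, [("o1", ["gA", "gB"])],
            [("gA", 100, 400, "+"), ("gB", 500, 900, "-")],
        )
        with pytest.raises(ValidationError, match="strand"):
            read_operon_annotation(op, gff)

    def test_rank_dialect(self, tmp_path):
        path = tmp_path / "ranked.tsv"
        with open(path, "w") as fh:
            fh.write("operon_id\tgene_id\trank\n")
            fh.write("o1\tgB\t2\no1\tgA\t1\n")
        from opstoich.data_io import read_operon_table

        assert read_operon_table(path) == [("o1", ["gA", "gB"])]

    def test_gff3_gzip(self, tmp_path):
        gff_path = tmp_path / "genes.gff3.gz"
        with gzip.open(gff_path, "wt") as fh:
            fh.write("##gff-version 3\n")
            fh.write("chr1\tt\tCDS\t10\t30\t.\t+\t0\tID=gZ\n")
        genes = read_gff3(gff_path)
        assert genes["gZ"].interval0() == (9, 30)
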