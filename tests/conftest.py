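import pandas as pd
import pytest

from opstoich.data_io import GeneAnnotation, Operon, ValueTable


@pytest.fixture
def two_gene_annotation():
    """gA at 100-400, gB at 500-900 (1-based inclusive) on one contig."""
    return {
        "gA": GeneAnnotation("gA", "chr1", 100, 400, "+", 301, 99),
        "gB": GeneAnnotation("gB", "chr1", 500, 900, "+", 401, 132),
    }


@pytest.fixture
def quant_frame():
    return pd.DataFrame(
        {
            "protein_id": ["p1", "p2", "p3"],
            "gene_name": ["g1", "g2", "g3"],
            "intensity": [10.0, 20.0, 30.0],
            "n_unique_peptides": [1, 2, 3],
            "min_peptide_length": [6, 7, 8],
            "strain": ["s"] * 3,
            "replicate": ["r1"] * 3,
        }
    )


def value_table(mapping, kind="copies"):
    return ValueTable(pd.Series(mapping, dtype=float), kind)


@pytest.fixture
def make_value_table():
    return value_table


@pytest.fixture
def simple_operon():
    return Operon("op1", ("gA", "gB", "gC"), "+")
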