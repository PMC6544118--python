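"""opstoich: stoichiometry analysis of bacterial operon gene products.

Calibrates label-free MS intensities to protein copies per cell, measures
within-operon expression variation against a reshuffled null, contrasts
Complex- and Pathway-type operons, relates stoichiometry to operon length,
gene intervals and enzyme kinetics, and validates every stage on synthetic
data with known ground truth.
"""

from importlib import resources

from .data_io import KineticsRecord, read_kinetics_table

__version__ = "0.1.0"


def load_table1_kinetics() -> list[KineticsRecord]:
    """The packaged enzyme-kinetics reference table (k_cat s^-1, K_M mM)."""
    path = resources.files("opstoich.data").joinpath("table1_kinetics.tsv")
    with resources.as_file(path) as p:
        return read_kinetics_table(p)
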