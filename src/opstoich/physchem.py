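"""Protein physicochemical features and quantified-vs-unquantified tests.

Shotgun MS detectability depends on a protein's physical chemistry: very
basic, short, unstable or hydrophobic proteins ionize, digest or extract
poorly. This module computes the four classic sequence features — length,
GRAVY hydropathy, isoelectric point and instability index — and compares
their distributions between protein sets.

GRAVY is the mean Kyte-Doolittle hydropathy per residue. The instability
index is the Guruprasad dipeptide-weight sum, (10/L) * sum of weights over
the L-1 dipeptides. The isoelectric point is the pH at which the net
charge of the free termini and the D/E/C/Y/H/K/R side chains (Bjellqvist
pKa set, shipped in ``data/pka_bjellqvist.json``) crosses zero, located by
bisection.

Ambiguous residues (B, J, O, U, X, Z) are rejected by default; with
``skip_ambiguous=True`` they are dropped from the sequence before any
computation (they then contribute to no mean).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from Bio.SeqUtils.ProtParam import ProtParamData

from .errors import StatisticError, ValidationError
from .operon_cv import DistributionComparison, compare_distributions

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Kyte-Doolittle hydropathy scale (shared with the field's calculators)
KYTE_DOOLITTLE: Mapping[str, float] = dict(ProtParamData.kd)

#: Guruprasad dipeptide instability weights, DIWV[first][second]
DIWV: Mapping[str, Mapping[str, float]] = ProtParamData.DIWV


@lru_cache(maxsize=1)
def pka_set() -> dict:
    """The packaged Bjellqvist pKa table (positive and negative groups)."""
    text = resources.files("opstoich.data").joinpath("pka_bjellqvist.json").read_text()
    return json.loads(text)


@dataclass(frozen=True)
class PhyschemRecord:
    protein_id: str
    length_aa: int
    gravy: float
    isoelectric_point: float
    instability_index: float


def _clean(seq: str, skip_ambiguous: bool) -> str:
    seq = seq.upper()
    bad = [c for c in seq if c not in CANONICAL_AA]
    if bad and not skip_ambiguous:
        raise ValidationError(f"non-canonical residue(s) {sorted(set(bad))} in sequence")
    if bad:
        seq = "".join(c for c in seq if c in CANONICAL_AA)
    if not seq:
        raise ValidationError("empty sequence after removing ambiguous residues")
    return seq


def gravy(seq: str, skip_ambiguous: bool = False) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    seq = _clean(seq, skip_ambiguous)
    return float(np.mean([KYTE_DOOLITTLE[c] for c in seq]))


def net_charge(seq: str, pH: float, skip_ambiguous: bool = False) -> float:
    """Net charge of the peptide at a given pH under the packaged pKa set."""
    seq = _clean(seq, skip_ambiguous)
    pka = pka_set()
    charge = 0.0
    counts: dict[str, int] = {}
    for c in seq:
        counts[c] = counts.get(c, 0) + 1
    for group, pk in pka["positive"].items():
        if group == "Nterm":
            n, pk = 1, pka["nterm_by_residue"].get(seq[0], pk)
        else:
            n = counts.get(group, 0)
        charge += n / (1.0 + 10.0 ** (pH - pk))
    for group, pk in pka["negative"].items():
        if group == "Cterm":
            n, pk = 1, pka["cterm_by_residue"].get(seq[-1], pk)
        else:
            n = counts.get(group, 0)
        charge -= n / (1.0 + 10.0 ** (pk - pH))
    return charge


def isoelectric_point(seq: str, skip_ambiguous: bool = False, tol: float = 1e-4) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    # net_charge is strictly decreasing in pH: positive at pH 0, negative at 14
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid, skip_ambiguous) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def instability_index(seq: str, skip_ambiguous: bool = False) -> float:
    """Guruprasad instability index: (10/L) * sum of dipeptide weights."""
    seq = _clean(seq, skip_ambiguous)
    if len(seq) < 2:
        raise ValidationError("instability index needs >= 2 residues")
    total = sum(DIWV[a][b] for a, b in zip(seq, seq[1:]))
    return 10.0 * total / len(seq)


def physchem_record(
    protein_id: str, seq: str, skip_ambiguous: bool = False
) -> PhyschemRecord:
    cleaned = _clean(seq, skip_ambiguous)
    return PhyschemRecord(
        protein_id=protein_id,
        length_aa=len(cleaned),
        gravy=gravy(cleaned),
        isoelectric_point=isoelectric_point(cleaned),
        instability_index=instability_index(cleaned),
    )


FEATURES = ("length_aa", "gravy", "isoelectric_point", "instability_index")


def compare_feature_distributions(
    quantified: Sequence[PhyschemRecord],
    unquantified: Sequence[PhyschemRecord],
) -> dict[str, tuple[DistributionComparison, float]]:
    """Per-feature two-sided Mann-Whitney test plus direction of shift.

    Returns, per feature, the test result and the median difference
    (unquantified minus quantified), so e.g. a positive pI difference reads
    as the unquantified set being more alkalic.
    """
    if len(quantified) < 3 or len(unquantified) < 3:
        raise StatisticError("each protein set needs >= 3 records")
    out = {}
    for feat in FEATURES:
        a = [float(getattr(r, feat)) for r in quantified]
        b = [float(getattr(r, feat)) for r in unquantified]
        cmp = compare_distributions(a, b, "mann_whitney_u")
        out[feat] = (cmp, float(np.median(b) - np.median(a)))
    return out
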