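"""Synthetic E. coli-like datasets with known ground truth.

The generator emulates the inputs of the whole analysis — genome
annotation, operon membership, protein and RNA quantification, three prior
copy-number scales, enzyme kinetics — under named expression regimes so
every pipeline stage can be validated against a planted truth:

* **stoichiometric**: every cistron of an operon expresses at the operon's
  base level, times multiplicative log-normal within-operon noise; the
  regime of Complex operons by default.
* **staircase**: expression decays geometrically with the gene's rank in
  the operon (retention ``staircase_decay`` per cistron), emulating the
  staircase-like decay described for polycistronic transcripts; the
  default regime of Pathway operons.
* **independent**: every cistron draws its own level from the
  between-operon distribution; operon membership carries no abundance
  information, so real and reshuffled CV distributions must coincide.

Operon base levels are log-normal across operons; RNA follows the operon
base (one transcript per operon) with small noise. Measured intensities
are true copies divided by a planted conversion factor ``k_true`` with
log-normal measurement noise on two replicates; the three prior scales are
true copies with independent log-normal noise. Detection dropout removes
low-abundance proteins with probability logistic in log10 copies,
emulating MS detectability. Pathway operons receive planted kinetics with
K_M proportional to copies^gamma (gamma > 0: less active enzymes more
abundant), optionally sign-flipped for a fraction of operons as negative
controls.

Every generator is fully deterministic under the configured seed
(independent child streams per stage), so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import (
    GeneAnnotation,
    KineticsRecord,
    Operon,
    ValueTable,
    write_fasta,
    write_table,
    write_value_table,
)
from .enzyme_efficiency import PathwayGraph, Reaction
from .errors import GenerationError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the simulated conditions."""

    seed: int = 0
    n_operons: int = 300
    #: probability of an operon having 1/2/3/4/>=5 genes
    size_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"1": 0.30, "2": 0.25, "3": 0.20, "4": 0.15, "5plus": 0.10}
    )
    fraction_complex: float = 0.4
    regime_per_class: Mapping[str, str] = field(
        default_factory=lambda: {
            "Complex": "stoichiometric",
            "Pathway": "staircase",
            "Mono": "independent",
        }
    )
    staircase_decay: float = 0.5  # per-cistron multiplicative retention
    base_log10_mean: float = 3.0  # median ~1000 copies/cell
    between_operon_log10_sd: float = 1.0
    within_noise_log10_sd: float = 0.1
    measurement_noise_log10_sd: float = 0.05
    rna_noise_log10_sd: float = 0.05
    k_true: float = 1000.0  # copies per intensity unit
    #: per-class gene-interval distribution, nt (mean, sd)
    interval_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"Complex": (5.0, 15.0), "Pathway": (80.0, 40.0)}
    )
    interval_floor_nt: int = -30
    detection_dropout: float = 0.1
    protein_length_range_aa: tuple[int, int] = (100, 400)
    kinetics_gamma: float = 1.0
    kinetics_log10_sd: float = 0.2
    kinetics_flip_fraction: float = 0.0
    rna_library_size: int = 2_000_000

    def validate(self) -> None:
        if abs(sum(self.size_distribution.values()) - 1.0) > 1e-9:
            raise GenerationError("size_distribution probabilities must sum to 1")
        for name in (
            "between_operon_log10_sd",
            "within_noise_log10_sd",
            "measurement_noise_log10_sd",
            "rna_noise_log10_sd",
        ):
            if getattr(self, name) < 0:
                raise GenerationError(f"{name} must be >= 0")
        if not 0 < self.staircase_decay <= 1:
            raise GenerationError("staircase_decay must be in (0, 1]")
        if not 0 <= self.detection_dropout < 1:
            raise GenerationError("detection_dropout must be in [0, 1)")
        if self.k_true <= 0:
            raise GenerationError("k_true must be positive")
        if not 0 <= self.fraction_complex <= 1:
            raise GenerationError("fraction_complex must be in [0, 1]")


@dataclass
class SyntheticGenome:
    annotation: dict[str, GeneAnnotation]
    operons: list[Operon]
    class_labels: dict[str, str]  # operon_id -> Complex | Pathway | Mono


@dataclass
class SyntheticMeasurement:
    d_rep1: ValueTable
    d_rep2: ValueTable
    d_mean: ValueTable
    reference: pd.DataFrame  # gene_name, copies_iBAQ, copies_emPAI, copies_APEX
    detected: set[str]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: SyntheticGenome
    true_copies: ValueTable
    true_rna: ValueTable
    regimes: dict[str, str]  # operon_id -> regime
    measurement: SyntheticMeasurement
    kinetics: list[KineticsRecord]
    pathway_graph: PathwayGraph
    flipped_operons: set[str]
    complex_membership: dict[str, set[str]]
    protein_seqs: dict[str, str]
    rna_counts: dict[str, int]


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _sample_size(rng: np.random.Generator, dist: Mapping[str, float]) -> int:
    keys = list(dist)
    pick = rng.choice(len(keys), p=[dist[k] for k in keys])
    key = keys[pick]
    return int(rng.integers(5, 9)) if key == "5plus" else int(key)


def simulate_genome(config: SimulationConfig, rng: np.random.Generator | None = None) -> SyntheticGenome:
    """Lay genes on one contig, grouped into operons with class labels.

    Within-operon intergenic intervals follow the class's normal
    distribution truncated at ``interval_floor_nt`` (overlapping ORFs are
    allowed via negative intervals); operons are separated by larger gaps
    and each operon sits on a random strand.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo_aa, hi_aa = config.protein_length_range_aa
    annotation: dict[str, GeneAnnotation] = {}
    operons: list[Operon] = []
    class_labels: dict[str, str] = {}
    cursor = 0
    for i in range(config.n_operons):
        oid = f"op{i:04d}"
        n_genes = _sample_size(rng, config.size_distribution)
        if n_genes == 1:
            label = "Mono"
        else:
            label = "Complex" if rng.random() < config.fraction_complex else "Pathway"
        class_labels[oid] = label
        strand = "+" if rng.random() < 0.5 else "-"
        lengths = [
            3 * int(rng.integers(lo_aa, hi_aa + 1)) + 3 for _ in range(n_genes)
        ]  # CDS incl. stop codon, multiple of 3
        if n_genes > 1:
            mean, sd = config.interval_params[label]
            intervals = [
                max(int(round(rng.normal(mean, sd))), config.interval_floor_nt)
                for _ in range(n_genes - 1)
            ]
        else:
            intervals = []
        gene_ids = [f"{oid}g{j}" for j in range(n_genes)]
        # place genomically left-to-right; for - strand the transcript runs
        # right-to-left, so the genomic order is the reversed transcript order
        genomic_order = list(range(n_genes)) if strand == "+" else list(range(n_genes))[::-1]
        gaps = intervals if strand == "+" else intervals[::-1]
        starts0: dict[int, int] = {}
        pos = cursor
        for rank, j in enumerate(genomic_order):
            starts0[j] = pos
            pos += lengths[j]
            if rank < n_genes - 1:
                pos += gaps[rank]
        for j, gid in enumerate(gene_ids):
            s0 = starts0[j]
            annotation[gid] = GeneAnnotation(
                gene_id=gid,
                contig="chr1",
                start=s0 + 1,
                end=s0 + lengths[j],
                strand=strand,
                cds_length_nt=lengths[j],
                protein_length_aa=lengths[j] // 3 - 1,
            )
        operons.append(Operon(operon_id=oid, gene_ids=tuple(gene_ids), strand=strand))
        cursor = pos + int(rng.integers(100, 301))
    return SyntheticGenome(annotation=annotation, operons=operons, class_labels=class_labels)


def simulate_expression(
    config: SimulationConfig,
    genome: SyntheticGenome,
    rng: np.random.Generator | None = None,
) -> tuple[ValueTable, ValueTable, dict[str, str]]:
    """True protein copies and RNA per gene under each operon's regime."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    copies: dict[str, float] = {}
    rna: dict[str, float] = {}
    regimes: dict[str, str] = {}
    for op in genome.operons:
        label = genome.class_labels[op.operon_id]
        regime = config.regime_per_class[label]
        regimes[op.operon_id] = regime
        base = 10.0 ** rng.normal(config.base_log10_mean, config.between_operon_log10_sd)
        for j, g in enumerate(op.gene_ids):
            if regime == "stoichiometric":
                level = base
            elif regime == "staircase":
                level = base * config.staircase_decay**j
            elif regime == "independent":
                level = 10.0 ** rng.normal(
                    config.base_log10_mean, config.between_operon_log10_sd
                )
            else:
                raise GenerationError(f"unknown regime {regime!r}")
            copies[g] = level * 10.0 ** rng.normal(0.0, config.within_noise_log10_sd)
            # one transcript per operon: RNA follows the operon base
            rna[g] = base * 10.0 ** rng.normal(0.0, config.rna_noise_log10_sd)
    return (
        ValueTable(pd.Series(copies), "copies"),
        ValueTable(pd.Series(rna), "copies"),
        regimes,
    )


def simulate_measurement(
    config: SimulationConfig,
    true_copies: ValueTable,
    rng: np.random.Generator | None = None,
) -> SyntheticMeasurement:
    """Noisy intensities (two replicates), prior scales and dropout mask."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    genes = list(true_copies.values.index)
    c = true_copies.values.to_numpy(dtype=float)
    sd = config.measurement_noise_log10_sd

    def noisy(scale: float = 1.0) -> np.ndarray:
        return scale * c * 10.0 ** rng.normal(0.0, sd, size=c.size)

    d1 = noisy(1.0 / config.k_true)
    d2 = noisy(1.0 / config.k_true)
    b, p, a = noisy(), noisy(), noisy()
    # detection dropout, logistic in log10 copies around the median:
    # scaled so the expected dropped fraction is about `detection_dropout`
    log10c = np.log10(c)
    mid = np.median(log10c)
    p_drop = np.clip(
        2.0 * config.detection_dropout * (1.0 - 1.0 / (1.0 + np.exp(-(log10c - mid) / 0.5))),
        0.0,
        1.0,
    )
    detected_mask = rng.random(c.size) >= p_drop
    detected = {g for g, keep in zip(genes, detected_mask) if keep}
    idx = [g for g in genes if g in detected]
    sel = detected_mask
    reference = pd.DataFrame(
        {"gene_name": genes, "copies_iBAQ": b, "copies_emPAI": p, "copies_APEX": a}
    )
    t1 = ValueTable(pd.Series(d1[sel], index=idx), "intensity")
    t2 = ValueTable(pd.Series(d2[sel], index=idx), "intensity")
    tm = ValueTable(pd.Series((d1[sel] + d2[sel]) / 2.0, index=idx), "intensity")
    return SyntheticMeasurement(
        d_rep1=t1, d_rep2=t2, d_mean=tm, reference=reference, detected=detected
    )


def simulate_kinetics(
    config: SimulationConfig,
    genome: SyntheticGenome,
    true_copies: ValueTable,
    rng: np.random.Generator | None = None,
) -> tuple[list[KineticsRecord], PathwayGraph, set[str]]:
    """Planted kinetics and a linear reaction chain per Pathway operon.

    K_M is proportional to copies^gamma with log-normal scatter — less
    active enzymes (higher K_M) are planted to be more abundant — and
    k_cat inversely proportional to K_M. A ``kinetics_flip_fraction`` of
    Pathway operons has the exponent sign flipped (negative controls).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    records: list[KineticsRecord] = []
    reactions: list[Reaction] = []
    flipped: set[str] = set()
    for op in genome.operons:
        if genome.class_labels[op.operon_id] != "Pathway":
            continue
        flip = rng.random() < config.kinetics_flip_fraction
        if flip:
            flipped.add(op.operon_id)
        gamma = -config.kinetics_gamma if flip else config.kinetics_gamma
        for j, g in enumerate(op.gene_ids):
            km = 1e-3 * true_copies[g] ** gamma * 10.0 ** rng.normal(
                0.0, config.kinetics_log10_sd
            )
            records.append(
                KineticsRecord(
                    enzyme_gene=g,
                    k_cat=1.0 / km,
                    K_M=km,
                    k_cat_organism="E. coli",
                    K_M_organism="E. coli",
                )
            )
            reactions.append(
                Reaction(
                    substrate=f"{op.operon_id}_m{j}",
                    product=f"{op.operon_id}_m{j + 1}",
                    enzyme_gene=g,
                )
            )
    return records, PathwayGraph(reactions=reactions), flipped


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate a complete synthetic study from one configuration."""
    if config is None:
        config = SimulationConfig()
    config.validate()
    rngs = _child_rngs(config.seed, 6)
    genome = simulate_genome(config, rngs[0])
    true_copies, true_rna, regimes = simulate_expression(config, genome, rngs[1])
    measurement = simulate_measurement(config, true_copies, rngs[2])
    kinetics, graph, flipped = simulate_kinetics(config, genome, true_copies, rngs[3])

    seq_rng = rngs[4]
    protein_seqs = {
        g: "".join(
            seq_rng.choice(list(AA_ALPHABET), size=ann.protein_length_aa)
        )
        for g, ann in genome.annotation.items()
    }

    count_rng = rngs[5]
    rna = true_rna.values
    expected = rna / rna.sum() * config.rna_library_size
    rna_counts = {
        g: int(count_rng.poisson(expected[g])) for g in rna.index
    }

    complex_membership = {
        g: {f"CPX_{op.operon_id}"}
        for op in genome.operons
        if genome.class_labels[op.operon_id] == "Complex"
        for g in op.gene_ids
    }
    return SyntheticDataset(
        config=config,
        genome=genome,
        true_copies=true_copies,
        true_rna=true_rna,
        regimes=regimes,
        measurement=measurement,
        kinetics=kinetics,
        pathway_graph=graph,
        flipped_operons=flipped,
        complex_membership=complex_membership,
        protein_seqs=protein_seqs,
        rna_counts=rna_counts,
    )


# ---------------------------------------------------------------------------
# writers: emit the dataset in the pipeline's on-disk input formats
# ---------------------------------------------------------------------------

def write_gff3(annotation: Mapping[str, GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in sorted(annotation.values(), key=lambda a: (a.contig, a.start)):
            fh.write(
                "\t".join(
                    [
                        ann.contig,
                        "opstoich",
                        "CDS",
                        str(ann.start),
                        str(ann.end),
                        ".",
                        ann.strand,
                        "0",
                        f"ID={ann.gene_id}",
                    ]
                )
                + "\n"
            )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every standard-format input plus ground_truth.json.

    Returns a name -> path map of everything written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["gff"] = outdir / "genome.gff3"
    write_gff3(dataset.genome.annotation, paths["gff"])

    paths["operons"] = outdir / "operons.tsv"
    ops = dataset.genome.operons
    write_table(
        pd.DataFrame(
            {
                "operon_id": [o.operon_id for o in ops],
                "gene_ids": [",".join(o.gene_ids) for o in ops],
            }
        ),
        paths["operons"],
    )

    pep_rng = np.random.default_rng(dataset.config.seed + 7)
    for rep_name, table in (("rep1", dataset.measurement.d_rep1),
                            ("rep2", dataset.measurement.d_rep2)):
        genes = list(table.values.index)
        df = pd.DataFrame(
            {
                "protein_id": [f"P_{g}" for g in genes],
                "gene_name": genes,
                "intensity": table.values.values,
                "n_unique_peptides": pep_rng.integers(2, 30, size=len(genes)),
                "min_peptide_length": pep_rng.integers(7, 12, size=len(genes)),
                "strain": "synthetic",
                "replicate": rep_name,
            }
        )
        paths[f"quant_{rep_name}"] = outdir / f"protein_quant_{rep_name}.tsv"
        write_table(df, paths[f"quant_{rep_name}"])

    paths["reference"] = outdir / "reference_abundance.tsv"
    write_table(dataset.measurement.reference, paths["reference"])

    paths["rna_counts"] = outdir / "rna_counts.tsv"
    write_table(
        pd.DataFrame(
            {"key": list(dataset.rna_counts), "value": list(dataset.rna_counts.values()),
             "value_kind": "read_count"}
        ),
        paths["rna_counts"],
    )

    paths["kinetics"] = outdir / "kinetics.tsv"
    write_table(
        pd.DataFrame(
            {
                "enzyme_gene": [k.enzyme_gene for k in dataset.kinetics],
                "k_cat": [k.k_cat for k in dataset.kinetics],
                "K_M": [k.K_M for k in dataset.kinetics],
                "k_cat_organism": [k.k_cat_organism for k in dataset.kinetics],
                "K_M_organism": [k.K_M_organism for k in dataset.kinetics],
            }
        ),
        paths["kinetics"],
    )

    paths["reactions"] = outdir / "pathway_reactions.tsv"
    write_table(
        pd.DataFrame(
            {
                "substrate": [r.substrate for r in dataset.pathway_graph.reactions],
                "product": [r.product for r in dataset.pathway_graph.reactions],
                "enzyme_gene": [r.enzyme_gene for r in dataset.pathway_graph.reactions],
            }
        ),
        paths["reactions"],
    )

    paths["complexes"] = outdir / "complex_membership.tsv"
    rows = [
        (g, cpx) for g, cpxs in dataset.complex_membership.items() for cpx in sorted(cpxs)
    ]
    write_table(
        pd.DataFrame(rows, columns=["gene_id", "complex_id"]), paths["complexes"]
    )

    paths["fasta"] = outdir / "proteins.faa"
    write_fasta(dataset.protein_seqs, paths["fasta"])

    paths["true_copies"] = outdir / "true_copies.tsv"
    write_value_table(dataset.true_copies, paths["true_copies"])

    paths["ground_truth"] = outdir / "ground_truth.json"
    truth = {
        "seed": dataset.config.seed,
        "k_true": dataset.config.k_true,
        "class_labels": dataset.genome.class_labels,
        "regimes": dataset.regimes,
        "flipped_operons": sorted(dataset.flipped_operons),
        "detected": sorted(dataset.measurement.detected),
        "config": {
            k: v for k, v in asdict(dataset.config).items()
            if isinstance(v, (int, float, str))
        },
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths
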