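"""End-to-end orchestration of the operon-stoichiometry analysis.

``run_all`` executes every stage in order — replicate QC, copy-number
calibration, within-operon CVs plus the reshuffled null, Complex/Pathway
classification, null-median split, functional enrichment, gene intervals,
enzyme-kinetics concordance, physicochemical comparison, RNA quantification
— and returns a machine-readable report. Every stage records its input and
output counts; every randomized result carries its seed, so the report is
reproducible bit-for-bit from the same configuration.

The pipeline runs either on a synthetic dataset generated in memory from
the ``simulate`` section of the configuration, or on file inputs named in
an ``inputs`` section. All analysis constants (top_n, null permutations,
complex fraction threshold, ribosome footprint, rpkM read floor, alpha
levels, confidence filter mode) are configuration keys.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import copy_number, operon_classes, operon_cv, physchem, rna_quant, structure_features
from .data_io import (
    Operon,
    ValueTable,
    filter_confident,
    read_fasta,
    read_kinetics_table,
    read_operon_annotation,
    read_quant_table,
    read_value_table,
    write_table,
)
from .enzyme_efficiency import (
    PathwayGraph,
    Reaction,
    branch_free_candidates,
    concordance,
    sign_test_summary,
)
from .errors import OpstoichError, ValidationError
from .synthetic_data import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

DEFAULT_PARAMS: dict[str, Any] = {
    "seed": 0,
    "top_n": 500,
    "n_permutations": 1000,
    "cv_min_n": 2,
    "group_by": "quantified",
    "complex_fraction_threshold": 0.9,
    "footprint_nt": 40,
    "rpkm_min_reads": 10,
    "alpha": 0.01,
    "alpha_report": 0.001,
    "filter_mode": "stringent",
    "reproducibility_bounds_log10": [2.0, 3.5],
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("pipeline config must be a YAML mapping")
    return cfg


def default_synthetic_config(seed: int = 0) -> dict:
    """The default configuration: simulate, then analyse."""
    return {**DEFAULT_PARAMS, "seed": seed, "simulate": {"seed": seed}}


def coverage_summary(
    quant_genes: set[str],
    translatome: set[str],
    localization: Mapping[str, str] | None,
    operons: list[Operon] | None = None,
) -> dict:
    """Fractions of the translatome (and its cytosolic part) quantified.

    When operons are supplied, also reports the fraction of translating
    polycistronic operons with at least one and at least two quantified
    proteins.
    """
    if not translatome:
        raise ValidationError("empty translatome")
    out: dict[str, Any] = {
        "n_translatome": len(translatome),
        "fraction_quantified": len(quant_genes & translatome) / len(translatome),
    }
    if localization is not None:
        cyto = {g for g in translatome if localization.get(g) == "cytosolic"}
        out["n_cytosolic"] = len(cyto)
        out["fraction_cytosolic_quantified"] = (
            len(quant_genes & cyto) / len(cyto) if cyto else float("nan")
        )
    if operons is not None:
        poly = [
            op for op in operons
            if op.is_polycistronic and any(g in translatome for g in op.gene_ids)
        ]
        if poly:
            out["fraction_operons_ge1_quantified"] = sum(
                1 for op in poly if sum(g in quant_genes for g in op.gene_ids) >= 1
            ) / len(poly)
            out["fraction_operons_ge2_quantified"] = sum(
                1 for op in poly if sum(g in quant_genes for g in op.gene_ids) >= 2
            ) / len(poly)
    return out


def _load_inputs(cfg: dict) -> dict:
    """Assemble the analysis substrate from files or from the simulator."""
    if "simulate" in cfg:
        sim_cfg = SimulationConfig(**(cfg.get("simulate") or {}))
        ds = simulate_dataset(sim_cfg)
        cds_lengths = {
            g: a.cds_length_nt for g, a in ds.genome.annotation.items()
        }
        return {
            "operons": ds.genome.operons,
            "annotation": ds.genome.annotation,
            "rep1": ds.measurement.d_rep1,
            "rep2": ds.measurement.d_rep2,
            "intensities": ds.measurement.d_mean,
            "reference": ds.measurement.reference,
            "rna_counts": ds.rna_counts,
            "cds_lengths": cds_lengths,
            "kinetics": ds.kinetics,
            "pathway_graph": ds.pathway_graph,
            "complex_membership": ds.complex_membership,
            "protein_seqs": ds.protein_seqs,
            "dataset": ds,
        }
    if "inputs" not in cfg:
        raise ValidationError("config needs a 'simulate' or an 'inputs' section")
    paths = cfg["inputs"]
    for key in ("operons", "gff", "quant_rep1", "quant_rep2", "reference"):
        if key not in paths:
            raise ValidationError(f"inputs section missing {key!r}")
        if not Path(paths[key]).exists():
            raise OpstoichError(f"input file not found: {paths[key]}")
    operons, annotation = read_operon_annotation(paths["operons"], paths["gff"])
    mode = cfg.get("filter_mode", DEFAULT_PARAMS["filter_mode"])
    reps = {}
    for rep in ("quant_rep1", "quant_rep2"):
        df = filter_confident(read_quant_table(paths[rep], "protein_quant"), mode)
        reps[rep] = ValueTable(
            pd.Series(df["intensity"].values, index=df["gene_name"].values), "intensity"
        )
    shared = sorted(reps["quant_rep1"].keys() | reps["quant_rep2"].keys())
    mean = pd.Series(
        [
            np.mean(
                [t[g] for t in (reps["quant_rep1"], reps["quant_rep2"]) if g in t.keys()]
            )
            for g in shared
        ],
        index=shared,
    )
    out: dict[str, Any] = {
        "operons": operons,
        "annotation": annotation,
        "rep1": reps["quant_rep1"],
        "rep2": reps["quant_rep2"],
        "intensities": ValueTable(mean, "intensity"),
        "reference": read_quant_table(paths["reference"], "reference_abundance"),
        "cds_lengths": {g: a.cds_length_nt for g, a in annotation.items()},
    }
    if "rna_counts" in paths:
        counts = read_value_table(paths["rna_counts"], "read_count")
        out["rna_counts"] = {g: int(v) for g, v in counts.values.items()}
    if "kinetics" in paths:
        out["kinetics"] = read_kinetics_table(paths["kinetics"])
    if "reactions" in paths:
        df = pd.read_csv(paths["reactions"], sep="\t")
        out["pathway_graph"] = PathwayGraph(
            reactions=[
                Reaction(str(r["substrate"]), str(r["product"]), str(r["enzyme_gene"]))
                for _, r in df.iterrows()
            ]
        )
    if "complexes" in paths:
        df = pd.read_csv(paths["complexes"], sep="\t")
        membership: dict[str, set[str]] = {}
        for _, r in df.iterrows():
            membership.setdefault(str(r["gene_id"]), set()).add(str(r["complex_id"]))
        out["complex_membership"] = membership
    if "fasta" in paths:
        out["protein_seqs"] = read_fasta(paths["fasta"])
    return out


def run_all(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run every stage and return (and optionally write) the report."""
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    params = {**DEFAULT_PARAMS, **{k: v for k, v in cfg.items() if k in DEFAULT_PARAMS}}
    seed = int(params["seed"])
    data = _load_inputs(cfg)
    operons: list[Operon] = data["operons"]
    report: dict[str, Any] = {
        "params": params,
        "tool": "opstoich",
        "stages": {},
    }
    stages = report["stages"]

    # --- replicate QC -----------------------------------------------------
    lo, hi = params["reproducibility_bounds_log10"]
    qc = copy_number.replicate_reproducibility(data["rep1"], data["rep2"], (lo, hi))
    stages["reproducibility"] = asdict(qc)

    # --- calibration ------------------------------------------------------
    k, copies = copy_number.calibrate(
        data["reference"], data["intensities"], top_n=int(params["top_n"])
    )
    stages["calibration"] = {
        "k": k.k,
        "n_matched": k.n_matched,
        "top_n_requested": k.top_n_requested,
        "n_proteins_converted": len(copies),
    }

    # --- within-operon CV + permutation null ------------------------------
    real = operon_cv.compute_operon_cvs(operons, copies, group_by=params["group_by"])
    null = operon_cv.randomize_null(
        operons,
        copies,
        n_permutations=int(params["n_permutations"]),
        seed=seed,
        group_by=params["group_by"],
    )
    real_vals = operon_cv.cv_values(real)
    null_vals = operon_cv.cv_values(null)
    mwu = operon_cv.compare_distributions(real_vals, null_vals, "mann_whitney_u")
    ks = operon_cv.compare_distributions(real_vals, null_vals, "kolmogorov_smirnov")
    stages["cv"] = {
        "seed": seed,
        "n_permutations": int(params["n_permutations"]),
        "n_real_operons": len(real),
        "mean_real_cv": float(np.mean(real_vals)),
        "mean_null_cv": float(np.mean(null_vals)),
        "median_real_cv": float(np.median(real_vals)),
        "median_null_cv": float(np.median(null_vals)),
        "real_vs_null_mwu_p": mwu.p_value,
        "real_vs_null_ks_p": ks.p_value,
    }

    # --- classification + null-median split -------------------------------
    membership = data.get("complex_membership", {})
    labels = operon_classes.classify_operons(
        [op for op in operons if op.is_polycistronic], membership
    )
    class_of = {oid: lab.label for oid, lab in labels.items()}
    hl_labels, null_medians = operon_classes.split_by_null_median(real, null)
    stages["classification"] = {
        "n_complex": sum(1 for v in class_of.values() if v == "Complex"),
        "n_pathway": sum(1 for v in class_of.values() if v == "Pathway"),
        "null_medians": null_medians,
        "n_low": sum(1 for v in hl_labels.values() if v.startswith("L")),
        "n_high": sum(1 for v in hl_labels.values() if v.startswith("H")),
    }

    # --- per-class CV comparison and size regression ----------------------
    complex_cvs = [r.cv_percent for r in real if class_of.get(r.operon_id) == "Complex"]
    pathway_cvs = [r.cv_percent for r in real if class_of.get(r.operon_id) == "Pathway"]
    if len(complex_cvs) >= 3 and len(pathway_cvs) >= 3:
        cmp = operon_cv.compare_distributions(complex_cvs, pathway_cvs, "mann_whitney_u")
        stages["class_cv"] = {
            "median_complex_cv": float(np.median(complex_cvs)),
            "median_pathway_cv": float(np.median(pathway_cvs)),
            "complex_vs_pathway_mwu_p": cmp.p_value,
        }
    groups = {
        g: operon_cv.cv_values(real, g)
        for g in operon_cv.SIZE_GROUPS
        if len(operon_cv.cv_values(real, g)) >= 3
    }
    if len(groups) >= 2:
        stages["pairwise_mwu"] = structure_features.pairwise_mwu_matrix(groups)
    try:
        reg = structure_features.cv_vs_size_regression(real)
        stages["cv_size_regression"] = asdict(reg)
    except OpstoichError as exc:
        stages["cv_size_regression"] = {"skipped": str(exc)}

    # --- enrichment -------------------------------------------------------
    poly_genes = {g for op in operons if op.is_polycistronic for g in op.gene_ids}
    background = poly_genes & copies.keys()
    low_operons = {oid for oid, v in hl_labels.items() if v.startswith("L")}
    subset = {
        g
        for op in operons
        if op.operon_id in low_operons
        for g in op.gene_ids
    } & background
    terms: dict[str, set[str]] = {}
    for g, cpxs in membership.items():
        for cpx in cpxs:
            terms.setdefault(cpx, set()).add(g)
    for oid, lab in class_of.items():
        op = next(o for o in operons if o.operon_id == oid)
        terms.setdefault(f"class:{lab}", set()).update(op.gene_ids)
    if terms and subset:
        enr = operon_classes.fisher_enrichment(
            subset, background, terms, alpha=float(params["alpha"])
        )
        stages["enrichment"] = {
            "n_terms": len(enr),
            "n_significant": sum(e.significant for e in enr),
            "n_insignificant_at_report_alpha": sum(
                1 for e in enr if e.p_value > float(params["alpha_report"])
            ),
            "top_terms": [
                {"term": e.term_id, "p": e.p_value} for e in enr[:5]
            ],
        }

    # --- gene intervals + scanning classes --------------------------------
    intervals = structure_features.all_gene_intervals(operons, data["annotation"])
    iv_by_class: dict[str, list[int]] = {"Complex": [], "Pathway": []}
    for iv in intervals:
        lab = class_of.get(iv.operon_id)
        if lab in iv_by_class:
            iv_by_class[lab].append(iv.interval_nt)
    footprint = int(params["footprint_nt"])
    stages["intervals"] = {
        "n_intervals": len(intervals),
        "fraction_coupled": float(
            np.mean(
                [
                    structure_features.scanning_class(iv.interval_nt, footprint)
                    == "coupled_70S_scanning"
                    for iv in intervals
                ]
            )
        )
        if intervals
        else float("nan"),
    }
    if all(len(v) >= 3 for v in iv_by_class.values()):
        ks_iv = operon_cv.compare_distributions(
            iv_by_class["Complex"], iv_by_class["Pathway"], "kolmogorov_smirnov"
        )
        stages["intervals"].update(
            {
                "median_complex_interval": float(np.median(iv_by_class["Complex"])),
                "median_pathway_interval": float(np.median(iv_by_class["Pathway"])),
                "complex_vs_pathway_ks_p": ks_iv.p_value,
            }
        )

    # --- RNA quantification + RNA-protein correlation ----------------------
    rna_table = None
    if "rna_counts" in data:
        rna_records = rna_quant.quantify_rna(
            data["rna_counts"], data["cds_lengths"], min_reads=int(params["rpkm_min_reads"])
        )
        rna_table = rna_quant.rna_value_table(rna_records)
        stages["rna"] = {
            "n_genes": len(rna_records),
            "n_quantifiable": sum(r.quantifiable for r in rna_records),
        }
        for lab in ("Complex", "Pathway"):
            genes = {
                g
                for op in operons
                if class_of.get(op.operon_id) == lab
                for g in op.gene_ids
            }
            try:
                corr = structure_features.rna_protein_correlation(rna_table, copies, genes)
                stages["rna"][f"r_squared_{lab.lower()}"] = corr.r_squared
            except OpstoichError as exc:
                stages["rna"][f"r_squared_{lab.lower()}"] = None
                logger.info("RNA-protein correlation (%s) skipped: %s", lab, exc)

    # --- enzyme kinetics concordance ---------------------------------------
    if "kinetics" in data and "pathway_graph" in data:
        candidates = branch_free_candidates(
            operons, copies, data["pathway_graph"], data["kinetics"]
        )
        verdicts = []
        for oid in candidates:
            op = next(o for o in operons if o.operon_id == oid)
            try:
                verdicts.append(concordance(op, copies, rna_table, data["kinetics"]))
            except OpstoichError as exc:
                logger.info("concordance for %s skipped: %s", oid, exc)
        stages["enzymes"] = {
            "n_candidates": len(candidates),
            **sign_test_summary(verdicts),
            "n_rna_protein_inverted": sum(v.rna_protein_inverted for v in verdicts),
        }

    # --- physicochemical comparison of detected vs undetected ---------------
    if "protein_seqs" in data:
        seqs = data["protein_seqs"]
        detected = copies.keys()
        quant_recs = [
            physchem.physchem_record(g, s) for g, s in seqs.items() if g in detected
        ]
        unquant_recs = [
            physchem.physchem_record(g, s) for g, s in seqs.items() if g not in detected
        ]
        if len(quant_recs) >= 3 and len(unquant_recs) >= 3:
            feats = physchem.compare_feature_distributions(quant_recs, unquant_recs)
            stages["physchem"] = {
                feat: {"p": cmp.p_value, "median_shift_unquant_minus_quant": shift}
                for feat, (cmp, shift) in feats.items()
            }

    # --- coverage ----------------------------------------------------------
    translatome = set(data["annotation"])
    stages["coverage"] = coverage_summary(
        copies.keys(), translatome, {g: "cytosolic" for g in translatome}, operons
    )

    # --- outputs -----------------------------------------------------------
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_table(
            pd.DataFrame(
                [
                    {**asdict(r), "hl_label": hl_labels.get(r.operon_id),
                     "class": class_of.get(r.operon_id)}
                    for r in real
                ]
            ),
            out_dir / "operon_cvs.tsv",
        )
        write_table(pd.DataFrame([asdict(iv) for iv in intervals]), out_dir / "gene_intervals.tsv")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=float)
    return report
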