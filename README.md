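# opstoich

Stoichiometry analysis of bacterial operon gene products from label-free
proteome quantification.

More than half of the protein-coding genes of a typical bacterium are
organized in polycistronic operons. Whether the operon arrangement actually
enforces *stoichiometric* expression — equal molar abundance of the
encoded proteins — is a quantitative question that requires deep,
calibrated proteome measurements. `opstoich` provides the downstream
analysis for that question as a tested, reusable library and CLI, aimed at
proteomics/systems-biology researchers who already have protein
quantification tables (e.g. a DIA protein pivot report), an operon
catalogue and a gene annotation.

## What it computes

**Copies per cell.** Measured intensities D_i are rescaled to protein
copies per cell with a single conversion coefficient fitted on the most
abundant proteins against three prior label-free copy-number scales
(iBAQ B_i, emPAI P_i, APEX A_i):

```
k = geomean_i[(B_i + P_i + A_i)/3] / geomean_i[D_i]        copies_i = k · D_i
```

**Within-operon variation.** For every operon with ≥ 2 quantified
products, the coefficient of variation

```
CV% = 100 · s / x̄ ,   s = sqrt( Σ (x_i − x̄)² / (n − 1) )
```

is compared against a reshuffled null in which the quantified values of
all polycistronic-operon genes are permuted over the same gene slots.
Because CV is scale-invariant, the statistic does not depend on k.

**Operon classes and structure.** Operons with ≥ 90% of their genes in
one protein complex are labelled *Complex*, the rest *Pathway*; CV records
are split at the per-size-group null median (L/H subgroups) and fed into a
generic one-sided Fisher-exact overrepresentation test. Gene intervals
(stop codon of one cistron to start codon of the next; negative for
overlapping ORFs) classify each junction as coupled 70S-scanning
reinitiation (interval < 40 nt) or independent 30S initiation.

**Enzyme kinetics.** For Pathway operons whose quantified enzymes form a
branch-free reaction chain, the package tests whether less active enzymes
(higher K_M) are expressed in higher amounts (positive Spearman rank
correlation of K_M vs copies). The enzyme kinetics reference table
(k_cat, K_M, source organism, homology) ships with the package.

**Synthetic data.** A first-class generator emulates an E. coli-like
genome with multi-gene operons under stoichiometric, staircase-decay and
independent expression regimes, log-normal measurement noise on two
replicates, three correlated prior abundance scales, abundance-dependent
detection dropout and planted kinetics — so every stage is validated
against known ground truth without any downloads.

## Worked example

Run the default synthetic study (300 operons, 1000 null permutations)
end to end:

```
$ opstoich run-all --seed 1 --out results/
```

or equivalently in Python:

```python
from opstoich.pipeline import run_all, default_synthetic_config
report = run_all(default_synthetic_config(seed=1), out_dir="results")
print(report["stages"]["calibration"]["k"])          # 1006.42  (planted k = 1000)
print(report["stages"]["cv"]["median_real_cv"])      # 49.37 %
print(report["stages"]["cv"]["median_null_cv"])      # 129.87 %
print(report["stages"]["class_cv"])                  # Complex 20.02 % vs Pathway 69.46 %
print(report["stages"]["intervals"]["median_complex_interval"])   # 4 nt
print(report["stages"]["intervals"]["median_pathway_interval"])   # 83 nt
```

Reading the output: the conversion coefficient recovers the planted value
within 1%; real within-operon CVs sit far below the reshuffled null
(Mann–Whitney p ≈ 2 × 10⁻⁷², i.e. operons do unify expression);
Complex operons are much tighter than Pathway operons; and Complex gene
junctions are short enough (median 4 nt) for coupled 70S-scanning
reinitiation while Pathway junctions (median 83 nt) are not.
`results/report.json` holds the full machine-readable report, and
`operon_cvs.tsv` / `gene_intervals.tsv` the per-operon records.

The kinetics worked examples use the packaged reference table:

```python
from opstoich import load_table1_kinetics
from opstoich.enzyme_efficiency import kinetic_ratio
recs = {r.enzyme_gene: r for r in load_table1_kinetics()}
kinetic_ratio(recs["ArgB"], recs["ArgC"], "K_M")    # (3.25, 0.5119)
kinetic_ratio(recs["BioC"], recs["BioF"], "k_cat")  # (1688.1, 3.2274)
```

ArgB binds its substrate 3.25× more weakly than ArgC, and BioC turns over
more than three orders of magnitude faster than BioF — the abundance
ordering of these enzymes in vivo runs opposite to their efficiency.

## Layout

| module | role |
| --- | --- |
| `opstoich.data_io` | table/GFF3/FASTA readers, validation, confidence filters |
| `opstoich.copy_number` | conversion coefficient k, copies per cell, replicate QC |
| `opstoich.operon_cv` | CV statistic, reshuffled null, distribution tests |
| `opstoich.operon_classes` | Complex/Pathway labels, null-median split, enrichment |
| `opstoich.structure_features` | gene intervals, scanning classes, regressions |
| `opstoich.enzyme_efficiency` | branch-free pathways, kinetics-abundance concordance |
| `opstoich.physchem` | GRAVY, pI, instability index, detectability comparison |
| `opstoich.rna_quant` | rpkM and the read-count quantifiability filter |
| `opstoich.synthetic_data` | ground-truth simulator and standard-format writers |
| `opstoich.pipeline` / `opstoich.cli` | orchestration, report, `opstoich` CLI |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
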