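# Methods

This note documents the statistical model behind `opstoich`, the defaults
and units of the parameters that matter, what the synthetic-data generator
does and does not emulate, and the numerical and design choices that were
genuinely open.

## Copy-number calibration

Label-free MS intensities are proportional to protein amount but on an
arbitrary scale. The pipeline assumes one global proportionality constant
per experiment and estimates it against three prior copy-number scales
(iBAQ, emPAI, APEX copies per cell) for the most abundant proteins:

    k = geomean_i[(B_i + P_i + A_i)/3] / geomean_i[D_i]

computed in log space (log-sum accumulation) so products over ~500
proteins cannot overflow. "Most abundant" is operationalized as the top
`top_n` (default **500**) reference genes ranked by the mean of the three
prior scales, ties broken by gene name; the set is then intersected with
genes detected (D_i > 0) in the intensity table. Genes with a non-positive
value on any scale are excluded — the geometric mean is undefined for
them — and the exclusion count is logged. Calibration defaults to the mean
intensity across replicates; per-replicate calibration is available by
passing a single replicate's table.

Assumptions: a single multiplicative scale suffices (no
intensity-dependent response curve), and the prior scales are unbiased on
average over the top proteins. Because every downstream dispersion
statistic is scale-invariant, errors in k displace absolute copy numbers
but not any CV, rank correlation or interval result.

## Within-operon CV and the reshuffled null

For an operon with n ≥ 2 quantified products with abundances x_1..x_n,

    CV% = 100 · sd(x; n−1 denominator) / mean(x)

on **linear-scale** quantities (the statistic is defined on abundances,
not their logs). Undetected genes are dropped, not zero-filled: a missing
protein is an instrument limit, not a measured zero. The operon's size
group (2 / 3 / 4 / 5plus) follows the number of *quantified* genes by
default (`group_by="quantified"`); `group_by="annotated"` switches the
bucket to the genomic gene count. The same operation applies unchanged to
any per-gene quantity (e.g. protein half-lives).

The null model removes all operon-membership information while preserving
everything else: the quantified values of all genes belonging to
polycistronic operons are permuted uniformly at random over those same
gene slots — jointly across operons, then extracted per operon — so the
value multiset, the detection pattern and every operon's quantified size
are invariant. The pipeline default is **1000** permutations with the null
medians taken from the pooled null CVs, which stabilizes the per-size-group
L/H split. All distribution comparisons (Mann–Whitney U,
Kolmogorov–Smirnov, Kruskal–Wallis) are two-sided.

One caveat is documented deliberately: CV records from many permutations
of one value multiset are dependent samples. For the null *validity*
check (independent-regime data, where real and reshuffled CVs must be
statistically indistinguishable) the acceptance machinery therefore uses a
single reshuffle, which keeps the KS test's independence assumption
honest; the large pooled null is used only where its role is to provide a
stable median or an orders-of-magnitude location contrast.

## Complex vs Pathway classification and the L/H split

A polycistronic operon is *Complex* when the best single complex covers
≥ **90%** of its annotated genes (boundary inclusive; the denominator is
the annotated gene count, not the detected subset — classification is a
genome property). Everything else is *Pathway*. Within each size group,
operons below the null median CV are labelled `L<size>`, the rest
`H<size>`; an operon exactly at the median goes high.

Functional overrepresentation of a gene subset against a background is a
one-sided Fisher exact test per term (upper hypergeometric tail
P[X ≥ k]). No multiple-testing correction is applied by default, mirroring
the raw-threshold convention of the workflow this implements; a
Benjamini–Hochberg option exists (`bh_correct=True`). Both printed
thresholds are exposed: `alpha` (default **0.01**) flags significance and
`alpha_report` (default **0.001**) masks weak hits at report time.

## Gene intervals and 70S scanning

Coordinates are 1-based inclusive on disk (GFF3) and converted to 0-based
half-open internally; the gene interval of two transcript-adjacent
cistrons is the count of nucleotides strictly between the upstream CDS end
(past the stop codon) and the downstream CDS start — 0 means abutting
ORFs, negative means overlap. This convention (stop codon inside the
upstream CDS, start codon outside the interval) is stated prominently
because ±3 nt offsets are common between annotation tools; the minus
strand is the exact mirror computation, and both translation and
strand-mirror invariance are property-tested.

A terminating 70S ribosome covers ≈ 40 nt of mRNA. A junction is classed
as coupled 70S-scanning reinitiation when the interval is *strictly*
smaller than the footprint (default **40 nt**, configurable); overlapping
ORFs are maximal proximity and always coupled.

## Enzyme kinetics concordance

Candidate operons must (a) have ≥ 2 quantified proteins acting in one
pathway (one connected component of the reaction graph), (b) span a
branch-free sub-path — every metabolite on the directed path between
consecutive quantified enzymes has exactly one producing and one consuming
reaction in the whole graph — and (c) have kinetic parameters for all
quantified enzymes with at least one value measured in the reference
organism (default "E. coli").

Concordance is formalized as a strictly positive Spearman rank correlation
between K_M (mM; the activity proxy, with k_cat reported alongside as
order-of-magnitude context) and protein copies over the operon's enzymes;
with exactly two enzymes this reduces to a pairwise order check, with ties
counting as non-concordant. "RNA–protein inversion" is a negative Spearman
correlation of within-operon RNA and protein ranks. These rank-based
formalizations were an open design choice; a two-sided binomial sign test
across operon verdicts is provided as a convenience summary and is clearly
the package's own construction, not a field-standard statistic.

Cross-organism kinetics values are used as-is but carry their source
organism and percent homology, so criterion (c) and stricter same-organism
filters can be enforced downstream.

## Physicochemical features

GRAVY is the mean Kyte–Doolittle hydropathy per residue; the instability
index is the Guruprasad dipeptide-weight sum (10/L)·Σ weights; both use
the standard constant tables. The isoelectric point is found by bisection
(to 10⁻⁴ pH; the defining property |net charge| < 0.01 is tested) on the
Bjellqvist pKa set shipped as `data/pka_bjellqvist.json` — including the
residue-specific terminal pKa adjustments — so the implementation and its
test oracle share one constant source. Ambiguous residues (B, J, O, U, X,
Z) are rejected by default; `skip_ambiguous=True` drops them before any
mean. Quantified-vs-unquantified comparisons use two-sided Mann–Whitney
tests per feature with the median difference as the direction-of-shift
summary.

## RNA quantification

rpkM = count / ((CDS length/10³) · (library/10⁶)), where the library size
is the number of reads mapped to coding sequence (defaulting to the sum of
the supplied counts). Genes with ≥ **10** mapped reads are quantifiable;
rpkM is still reported below the floor, flagged. Multi-mapping policy is
upstream of this package: counts are taken as given.

## Synthetic data: what it emulates, and what it does not

The generator lays `n_operons` (default **300**) operons on one contig
(size distribution 30/25/20/15/10% for 1/2/3/4/≥5 genes; ≥5 drawn
uniformly from 5–8), assigns 40% of polycistronic operons to the Complex
class, and draws within-operon intergenic intervals from class-specific
normal distributions (Complex mean 5 nt, Pathway mean 80 nt, floor
−30 nt) — short Complex junctions and long Pathway junctions being the
structural contrast the interval statistics must resolve. CDS lengths are
multiples of 3 for 100–400 aa proteins.

Expression: operon base levels are log-normal (median 10³ copies/cell,
between-operon sd **1.0** in log10). Complex operons are stoichiometric
(each cistron = base × log-normal within-noise, sd **0.1**), Pathway
operons staircase (retention **0.5** per cistron rank), monocistronic
genes independent. RNA follows the operon base (one transcript per
operon) with sd 0.05. Measurement: intensities = copies / k_true
(k_true **1000** copies per intensity unit) × log-normal noise (sd
**0.05**) on two replicates; the three prior scales get independent noise
of the same size; detection dropout (expected fraction **0.1**) is
logistic in log10 copies around the median, emulating MS detectability.
Kinetics: for each Pathway operon a linear reaction chain with K_M ∝
copies^γ (γ **1.0**, log10 scatter **0.2**), and an optional sign-flipped
fraction as negative controls. Every stage draws from an independent child
stream of one seed; outputs are byte-identical across runs.

Deliberately *not* emulated: peptide-level measurement (spectra, digestion,
missed cleavages), intensity-dependent noise, shared operon promoters
beyond a single base level, inter-operon regulatory structure, branched
pathway graphs, protein turnover differences, and real E. coli sequence
composition (FASTA sequences are uniform-random over the 20 residues).
Consequently, passing tests demonstrate that the statistics recover planted
structure under realistic noise and dropout — not that any particular
biological dataset will show that structure, nor that peptide-level
artifacts are handled.

## Numerical choices and degenerate inputs

- Geometric means in log space; CV undefined (error) for n < 2 or
  non-positive mean; regressions require ≥ 3 points and a non-degenerate
  predictor.
- Duplicate gene rows in quantification tables are an error, never
  silently aggregated; identifier joins are case-sensitive by gene name.
- Null-median split ties go high; classification boundary (exactly 90%)
  is inclusive; the scanning rule at exactly the footprint is independent.
- Complex-fraction ties between complexes break deterministically on the
  complex id.
- The default pipeline problem size (300 operons, 1000 permutations,
  ~700 quantified proteins) runs in a few seconds on one CPU; acceptance
  simulations use 10 seeds at the same operon counts.

## Known limitations

- The branch-free test assumes at most one reaction per enzyme in the
  supplied graph and linear (non-cyclic beyond trivial) sub-paths; complex
  stoichiometric reactions (multiple substrates/products) must be reduced
  to their main chain upstream.
- The Fisher enrichment treats terms as flat sets: no ontology-DAG
  propagation.
- How genes quantified in only one replicate are handled is a genuine
  ambiguity: the pipeline exposes both replicates and defaults to the mean
  over the replicates in which a gene was detected; this default is a
  package choice, documented here rather than asserted as field practice.
- With two-enzyme operons the concordance verdict is a single pairwise
  comparison and correspondingly fragile to measurement noise.
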