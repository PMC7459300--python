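# Methods

This note documents the models implemented in `trex`, the parameters that
matter, what the synthetic-data generator does and does not emulate, and the
design choices made where more than one reasonable convention exists.

## Demultiplexing model

Pooled droplets are assigned in three passes.

**Pass 1 — TCR genotype and sex.** A barcode becomes iNKT when any productive,
high-confidence TRA chain uses TRAV11 (or its duplicate segment TRAV11D, which
encodes the same Vα14 chain and is collapsed before comparison) with TRAJ18;
MAIT when any TRA uses a TRAV1-family V (TRAV1 and dialect names such as
TRAV1-1, after stripping allele suffixes like `*01`) with TRAJ33 **and** its
summed raw UMIs over the Y-gene list (*Ddx3y*, *Eif2s3y*, *Uty*, *Kdm5d*) are
zero; γδ when it carries at least one productive TRG and one productive TRD.
"Not expressing Y-chromosomal genes" is operationalized as an exact zero
because Y transcripts are near-binary in droplet data; `DemuxRules.y_tolerance`
raises the cutoff if ambient contamination makes that too strict. A strictness
flag (`require_male_inkt`) optionally also demands Y expression for iNKT
assignment; it is off by default since the canonical α chain alone is already
essentially specific in this design.

**Doublet removal.** Any barcode with both a productive TRA and TRD, or with
both canonical α rearrangements, is removed regardless of its pass-1 label.
These two signatures are the only doublet classes identifiable from TCR
content alone; same-type doublets and iNKT+MAIT doublets in which one member
carries a non-canonical α are not detectable by this rule and are not claimed
to be.

**Pass 2 — cluster-majority rescue.** For each transcriptome cluster whose
most abundant *assigned* type strictly exceeds `majority_threshold`
(default 0.80), unassigned members adopt the majority type and
assigned-but-minority members are removed as putative doublets. The
denominator of the majority fraction is ambiguous in principle (all cells vs
assigned cells); this implementation uses assigned cells only, on the grounds
that unassigned cells are exactly the ones whose identity is in question, and
records the convention in the run summary for auditability. The threshold
comparison is strict (`>`), so a cluster at exactly 80% is left untouched.

**Pass 3 — TCR fallback.** In clusters that were not rescued ("mixed"),
still-unassigned cells expressing any TRAV1-family α become MAIT and cells
with V segments for both TCRγ and TCRδ become γδ. Cluster-level removals of
known artifact populations (e.g. double-positive thymocyte clusters) are the
`drop_clusters` option of `demultiplex` rather than hard-coded biology:
their non-doublet members end unassigned and take no part in rescue.

The five outcome labels (iNKT, MAIT, gdT, unassigned, removed_doublet)
partition the input barcodes; this is asserted in the test suite together with
order-independence of the passes.

## QC and normalization

Cells with fewer than `min_umi` = 1000 total UMIs or more than `max_mito` =
10% mitochondrial UMIs are excluded; both thresholds are exposed because the
appropriate values are dataset-dependent (they were originally chosen by
outlier inspection, not first principles). A cell failing both rules is
reported once, as `low_umi`. Mitochondrial genes are recognized by a prefix
list (default `mt-`), Y genes by an explicit list.

Size factors are per-cell library sizes scaled to mean 1. Pooled-deconvolution
factors (scran-style) are deliberately not re-implemented; the `factors`
argument of `lognormalize` accepts an externally computed vector, so the
normalization contract — value(g,c) = log2(raw(g,c)/factor(c) + 1), zeros
preserved — is independent of how factors are obtained. The pseudocount of 1
makes the transform monotone per cell and sparsity-preserving.

## Clonotypes and repertoire statistics

A clonotype is the full set of a cell's usable chains, keyed by
(chain, V, J, CDR3) tuples sorted lexicographically. CDR3 identity defaults to
the **nucleotide** level (the 10x convention — junctional nucleotide diversity
distinguishes independent rearrangements that converge on one amino-acid
sequence); `level="aa"` switches to amino-acid identity. Cells carrying
multiple productive chains of one locus keep all of them in the key.

*Percent formatting.* Reported percentages are truncated (floored) at the
printed precision rather than rounded: 17/1760 prints as 0.96% and 359/1665 as
21%, both of which are floors of the exact values. Full-precision fractions
are always available alongside.

*Shannon equitability.* E = (−Σ pᵢ ln pᵢ)/ln S over the S clonotypes of a
cluster, in [0, 1]; S = 1 is defined as 0 (a single clonotype is trivially
maximally uneven). Natural logarithms; the normalization makes the base
irrelevant. Permutation- and scale-invariance are asserted as property tests.

*Sharing.* Clonotypes present in two disjoint cluster regions are counted
with their table-wide cell totals; the "repetitive cells" denominator is the
number of cells whose clonotype has size ≥ 2.

*Repeat thresholds.* "Repeated more than three times" means clone size ≥ 4;
the bar-plot convention "repeated 3 or more" is a distinct display parameter
and both are exposed separately.

*Logo matrices.* Only sequences of exactly the modal CDR3 length contribute;
a modal tie is broken toward the shorter length (logged). Residues carry the
WebLogo hydrophobicity classes (hydrophilic RKDENQ, neutral SGHTAP,
hydrophobic CVLIMFWY). Rendering is out of scope; the matrix is the product.

*Canonical classification.* A cell is non-canonical-α when no TRA matches the
type's canonical pair, and non-oligoclonal-β when it has ≥1 TRB and none uses
a configured oligoclonal V segment. The default oligoclonal Vβ sets —
iNKT {TRBV13-1/2/3, TRBV29, TRBV1} (Vβ8.1–8.3, Vβ7, Vβ2) and MAIT {TRBV19,
TRBV13-1/2/3} (Vβ6, Vβ8) — encode the standard biased-usage biology and must
be overridden when other conventions apply. Cells without a TRB are excluded
from β denominators. The four-class Venn partition (canonical_only /
nc_alpha_only / nob_beta_only / both) is exhaustive and disjoint over cells
with ≥1 TRA, and the classification supports the contamination-control
re-analysis that drops the `both` class and recomputes per-cluster fractions.

## Signature scores

Each signature gene is standardized across cells of the analyzed matrix
(population SD, ddof = 0 — fixed for bit-reproducibility; immaterial at
n ≫ 1), and the cell's score is the mean of the standardized values. Constant
genes contribute 0 with a warning rather than NaN. Whether Z-scores are taken
within one cell type's matrix or globally is a choice the caller makes by
passing the corresponding matrix; per-type matrices are the default usage.
Start-cell selection is the arg-max of the score within a cluster, ties broken
toward the lexicographically smallest barcode (logged) so runs are
reproducible.

## DEG-overlap resampling test

Given DEG sets A and B from two subsets, the null distribution of their
overlap is simulated by R independent pairs of uniform without-replacement
samples of sizes |A| and |B| from the gene universe. The universe is the
**intersection of genes tested in both tables**, not the genome: overlap
probability must condition on testability. The empirical p-value uses the
add-one rule (1 + #{null ≥ k})/(R + 1), which avoids zero p-values at the cost
of slight conservatism; the analytic hypergeometric upper tail
P(X ≥ k | N, |A|, |B|) is reported alongside, and the two agree within
Monte-Carlo error (asserted at R = 10,000 in the test suite). The alternative
is one-sided ("greater") throughout. The direction-consistent variant counts
k_dir = |A↑∩B↑| + |A↓∩B↓| and preserves all four set sizes in the null by
drawing each subset's combined set and splitting it; both the directed and
undirected constructions are implemented because either could be the variant
used in any given figure. DEG extraction defaults to padj ≤ 0.05 with no
fold-change floor; both knobs are exposed since published cut-offs are often
unstated.

The category comparison computes Spearman (default; Pearson by flag)
correlation of log2 fold changes inside a gene category versus outside and a
one-sided permutation p for Δr = r_in − r_out under random label
reassignment. Strata need ≥3 genes and non-constant vectors.

## Synthetic cohort generator

The generator emulates the pooling design: equal numbers of iNKT (male), MAIT
(female) and γδ T cells (mixed sex) in one run, with designed cross-type
doublets added as extra barcodes merging two freshly drawn cells.

*Counts* are negative-binomial per gene (gamma-Poisson, dispersion 0.3 — the
standard droplet noise model) around a lognormal baseline expression profile,
with per-cluster marker blocks (default 15 genes at +2 log2FC per cluster, two
clusters per type). Y genes are structural zeros in female cells and a small
positive share (0.4% of depth) in males. The mitochondrial UMI share is
Beta-distributed around 4% for ordinary cells, and a configurable share of
cells (default 5%) draws a violating share in 15–35% so the QC rule has true
positives; an optional `low_umi_rate` plants sub-1000-UMI cells.

*Clone sizes* are drawn iid from a discrete power law P(s) ∝ s^(−shape)
truncated at `max_clone_size` (observed repeat spectra are heavy-tailed).
`shape_for_singleton_cell_fraction` inverts the closed form — the expected
fraction of cells in singleton clones is 1/Σ s^(1−a) — so a target singleton
share can be dialed in; the default shape 2.5 gives moderately repetitive
repertoires. All cells of a clone share one chain set, back-translated to
nucleotides with random codon choices once per clone, so nucleotide-level
clonotypes reproduce junctional diversity (canonical α chains share their
amino-acid CDR3 but differ in nt across clones).

*TCRs.* Canonical α rearrangements (TRAV11–TRAJ18 with CVVGDRGSALGRLHF;
TRAV1–TRAJ33 with CAVRDSNYQLIW) are replaced, at the configured per-clone
rates (default 10%), by draws from a decoy pool that includes TRAV10–TRAJ50 so
the non-canonical classification paths are exercised. β chains are present in
90% of αβ clones and use the oligoclonal Vβ pools except at the configured
non-oligoclonal rate. γδ clones draw Vγ from {Vγ1, Vγ4, Vγ6, Vγ7} with narrow
per-Vγ CDR3γ length windows (Vγ6 fetal-invariant) and broad CDR3δ lengths
(10–20 aa). Barcodes are unique 16-mers with the `-1` suffix.

*Scale.* Default cohorts use 2,000 genes and ~3,000 mean UMIs per cell — a
deliberately compact gene space that keeps the full pipeline and its tests
fast while preserving every statistical feature the downstream stages consume
(QC margins, Y-gene discreteness, cluster separability, clonal structure).

*What it does not model*, and what passing tests therefore do not show:
ambient RNA and empty droplets (no emptyDrops stage), batch effects, read- or
UMI-level error, within-type doublets, transcriptional similarity between the
real effector subsets, or realistic gene–gene correlation beyond cluster
shifts. Demultiplexing accuracy on synthetic cohorts is an upper bound: real
data add contig dropout and ambient Y counts that the tolerance knobs exist
for. Per-type clonal-size parameters are calibrated only qualitatively; the
published per-cluster equitability values (0.98/0.92/0.73/0.34 in γδ
clusters) depend on the real repertoire and are not reproduced from synthetic
data.

## Numerical conventions and degenerate inputs

Percent truncation adds 1e-9 before flooring to absorb binary representation
error. Empty matrices, empty clonotype sets, zero-total cells, non-positive
size factors, unknown clusters, empty signature intersections, sets outside
the universe and constant correlation strata all raise `ValueError` naming the
offending object; malformed contig rows are dropped with their row numbers in
a warning. All randomness flows through `numpy.random.Generator` objects
seeded per run; fixed seeds give byte-identical outputs (asserted for both the
generator and the pipeline summary).

## Problem sizes

The default test suite runs cohorts of 40–500 cells per type; the acceptance
script uses 3×500 cells with 5% doublets, R = 10,000 Monte-Carlo replicates
for the overlap grid, and 1,000 simulated null datasets at R = 200 for the
type-I-error calibration (universe 500, set sizes 150 — chosen so the discrete
hypergeometric null has an achievable level near 0.05).
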