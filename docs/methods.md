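# Methods

## Problem and model

The pipeline decides in which cell types a GWAS locus is plausibly
regulatory.  Its unit of inference is a (locus, cell type, category)
triple, tested with an exact hypergeometric draw: of the N background
SNPs in the locus window, K lie in the chromatin category; if risk SNPs
were exchangeable with background SNPs, the number k of the n risk SNPs
in the category would follow Hypergeometric(N, K, n), and the reported
p-value is the upper tail P(X ≥ k).  The model's assumptions are worth
stating plainly:

* the background is *local* — all panel SNPs inside the window around
  the index SNP, including the risk SNPs themselves (they are window
  SNPs; draws are without replacement, so risk ⊆ background is
  enforced);
* risk SNPs are treated as exchangeable draws, i.e. LD clustering among
  surrogates is not modelled.  Surrogates travel on the same haplotypes
  and are positionally clustered, which makes the test anti-conservative
  in principle; the all-null calibration study (below) measures the
  realized false-positive rate instead of assuming it away;
* a SNP's regulatory state is binary per category and cell type, taken
  from the rules-based segmentation.

## LD expansion

r² is computed from phased haplotype frequencies, not genotype dosage:
r² = D²/(p_A q_A p_B q_B), D = p_AB − p_A p_B.  This is algebraically
the squared Pearson correlation of the binary haplotype vectors, and the
test suite holds the two routes equal to 1e−12.  Unphased or missing
genotypes are rejected rather than approximated — phase is what makes
D well defined.  Monomorphic panel variants have undefined LD and are
skipped.  The window is read as a total span of 1 Mb centred on the
index SNP (±500 kb), clipped at chromosome ends, and is configurable;
the alternative reading (±1 Mb) is obtained by doubling `window_bp`.
Only biallelic SNPs enter either the risk or the background set; indels
and multiallelic records are excluded so that the background is
well-defined.  No allele-frequency filter is applied to background
SNPs.  Index SNPs whose expansion yields no surrogate beyond the index
itself are dropped from enrichment, each with a logged reason.

## Segmentation

Rules in decreasing precedence: H3K4me3 bases are promoters; H3K4me1
bases outside promoters are enhancers; each peak is active (PAR/EAR)
when it overlaps H3K27ac by at least one base, else poised (PPR/EPR).
Two resolution choices were genuinely open and are fixed as follows:
activity is decided at the *peak* level (a single base of H3K27ac
overlap activates the whole peak), while promoter precedence is decided
*base-wise* where the two methylation marks overlap.  A consequence
worth knowing: when an enhancer peak's only H3K27ac support lies under
an overlapping promoter peak, the enhancer remnant is still active —
re-deriving peaks from the emitted segmentation and reclassifying can
therefore change such labels once, after which the output is a fixed
point (tested).  Peaks are merged per mark before classification;
coordinates are BED 0-based half-open throughout, with VCF positions
converted by pos−1.  Four states plus NONE are exposed; no three-way
grouping of the states is imposed since none is canonical.

## Enrichment and multiple testing

Tail probabilities are evaluated with a direct hypergeometric tail
summation that preserves relative precision at extreme tails (validated
against exact integer enumeration for all N ≤ 60 at 1e−10 relative
error).  The pooled EAR&PAR category counts a SNP once if its label is
either state.  Benjamini–Hochberg adjustment is applied within a
configurable family: all (cell type × category) tests of one locus
(default), or all (locus × category) tests of one cell type.  The
within-locus default reflects the per-locus question the pipeline
answers; both choices are exposed because reasonable analysts disagree
here.  Loci with fewer than two risk SNPs are skipped and logged.  The
heatmap matrix stores −ln q by default (−ln p available), missing tests
as 0, and q is floored at 1e−300 before the logarithm.

## Clustering

Euclidean distances between rows (cell types) and columns (loci) of the
−ln q matrix, UPGMA merge trees via scipy's average-linkage
implementation, validated against a naive O(n³) agglomeration oracle on
random instances.  scipy's tie handling is deterministic for a fixed
input, and reruns are bit-identical; ties between equal inter-cluster
distances are broken by scipy's internal ordering rather than a label
sort.  The heatmap reorders both axes by dendrogram leaf order under a
white-to-red colormap anchored at 0.

## Motif disruption

The match score is the weighted sum of per-position log-ratios
log(p_j(base)/bg(base)), min–max scaled by the column-wise extremes so
the consensus scores 1 and the anti-consensus 0.  This is this
package's own definition of weighted-sum scoring; other scanners'
"weighted sum" variants may differ in scaling, so absolute scaled
scores should not be compared across tools.  Match p-values
P(score of a random background window ≥ x) are exact up to
discretization: per-position scores are shifted non-negative, rounded
to bins of width 1e−3 of the raw-score range, and convolved across
positions; the induced score error is at most width·bin, far below any
gap that matters at the 5×10⁻⁵ cutoff (the test suite brackets the DP
against exhaustive 4^w enumeration).  The background is uniform by
default and configurable.  Both strands of every window overlapping the
SNP are scored for both alleles; the best window/strand per (motif,
SNP) by min(ref_p, alt_p) is kept, and reported when that minimum
reaches the cutoff.  The strong/weak effect label uses a scaled-score
difference threshold of 0.4 — an operational default with no claim of
biological calibration.  Windows containing non-ACGT bases are skipped
and logged.  Plots are drawn for calls below a stricter 1e−5 threshold
on min(ref_p, alt_p).

## eQTL linking

The eQTL stage consumes a *pre-computed* association table; no
association testing happens here.  Records are subset to the risk-SNP
rsids at p ≤ 2.5×10⁻⁵ and cross-referenced with enrichment through a
user-supplied cell-type ↔ expression-tissue map — tissue ontologies of
epigenome and expression panels differ, and guessing a mapping would
manufacture concordance.  Effect direction is carried as a sign only.
An optional pre-filter on the source table (p ≤ 0.05 before LD
enlargement) is available; it exists to mirror upstream association
lists that are thresholded at nominal significance before proxy
expansion.

## Synthetic data: what it emulates, what it does not

The generator plants truth at every stage: surrogate columns drawn from
the four-cell haplotype distribution with p_AB = p_A p_B + D chosen to
hit a target r² (feasibility checked against the Fréchet bound
p_AB ≤ min(p_A, p_B)); fixed-width (1 kb) enhancer peaks covering a
configurable window fraction (default 0.1), with planted (locus,
tissue) pairs forcing the configured fraction of risk SNPs (default
study: 0.8) into active peaks; random genomes with PWM consensus sites
written in, each carrying a SNP whose alternate allele is the
lowest-probability base at the most informative column; and eQTL tables
with planted significant triples among uniform noise.  Defaults are the
study conditions: 8 loci × 10 tissues, 1 Mb windows, 400 haplotypes,
background SNP density 5×10⁻⁴/bp (~500 window SNPs, the order of
common-SNP density), 15 surrogates per locus at target r² 0.9–0.99.

What it does *not* emulate: recombination-map LD structure (LD is
planted pairwise against the index only, so surrogate–surrogate LD is
indirect), realistic allele-frequency spectra, peak-width and
chromatin-domain heterogeneity, or sequence composition biases.
Passing the recovery tests therefore shows the machinery is correct and
calibrated under exchangeable backgrounds — not that real LD-clustered
risk sets cannot inflate the hypergeometric tail.

All randomness flows from one seed through named substreams
(genome/panel/peaks/motifs/eQTL), so emitted files are byte-identical
across runs and partial regeneration is stable.

## Validation studies and problem sizes

* Planted-enrichment recovery: 8 loci × 10 tissues, one planted pair at
  0.8 vs 0.1, 50 seeds; the planted pair must attain the study-wide
  minimum q in ≥ 90% of seeds (observed: 100%).
* All-null calibration: 4 loci × 5 tissues, 200 seeds (4,000 pairs),
  background density 2×10⁻⁴ — a deliberately lighter scenario, since
  the null study needs many replicates, not large windows; the fraction
  of pairs at q < 0.05 must stay ≤ 0.05 within 3 binomial SE
  (observed: ~0.002; the hypergeometric's discreteness makes BH
  conservative here).
* Motif-break recovery: both planted disrupting SNPs recovered at the
  5×10⁻⁵ cutoff with negative allele difference.
* End-to-end determinism: two full runs on the default scenario produce
  byte-identical result tables.

## Known limitations

* The hypergeometric background treats surrogates as independent draws;
  see the model assumptions above.
* The segmentation uses three marks only; states requiring repressive
  or transcription marks (heterochromatin, polycomb, transcribed) are
  out of scope, so NONE conflates "no data" with "other chromatin".
* Motif p-values assume a zeroth-order background; dinucleotide
  composition is not modelled.
* Per-stage CLI subcommands run the (cheap, idempotent) full pipeline
  up to their outputs rather than consuming intermediate files.
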