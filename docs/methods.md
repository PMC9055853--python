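# Methods

## Problem and model

3'-biased scRNA-seq libraries (10x, Drop-seq, CEL-seq) sample only the 3'
end of each transcript, which makes them a natural readout of alternative
polyadenylation (APA): a gene using a proximal pA site produces a short
3'-UTR isoform, a distal site a long one, and the balance between them can
shift between cell types. `scutr` identifies such genes in three stages.

**Padding.** Each read overlapping an annotated 3'-UTR is extended from the
UTR's 5' start (transcript position 1) to the read's 3'-most aligned base,
so the stack of padded intervals reconstructs the coverage a full-length
library would show. Padded coverage is non-increasing along the transcript
by construction; it is normalised to counts-per-million of the cluster's
total usable reads. The normalisation scale cancels within a gene's fit and
is fixed only for reproducibility of reported abundances.

**Change-point quantification.** For a gene of UTR length L expressing a
short isoform ending at proximal site P and a long isoform ending at L, the
expected padded coverage is a step function with value w_S + w_L on
positions 1..P and w_L on P+1..L. For each candidate P the best
non-negative (w_L, w_S) is a two-variable non-negative least-squares
problem solved in closed form (w_L = mean tail coverage, w_S = mean head −
mean tail, with explicit evaluation of the two boundary cases when a sign
constraint activates). One proximal site per gene is estimated by
minimising the residual summed over cell clusters; ties break toward the
smallest P. Candidate sites exclude a flank of max(50 nt, 5% of L) at each
end to avoid degenerate end solutions. The long-isoform proportion
PDUI = w_L / (w_L + w_S) is the gene's APA state per cluster.

A cluster is considered to genuinely express two isoforms ("two-site") when
the minor isoform carries ≥ 1% of the abundance and the two-isoform fit
reduces the residual by ≥ 5% over the best single-isoform (constant) fit.
Both thresholds are configuration options; the defaults were chosen so that
flat or single-step noiseless profiles are classified correctly and are not
tuned to any dataset.

**>2 sites.** Coverage of a gene with several pA sites satisfies C = M W,
where M is the upper-triangular matrix of ones (an isoform of length l
covers positions 1..l) and row l of W holds the abundance of the isoform
ending at l in each cluster. Sparse non-negative W is recovered by an
L1-penalised least-squares fit (coordinate descent with non-negative soft
thresholding; the prefix-sum structure of M makes a sweep O(L)). The
penalty is either user-set, increased along a logarithmic path until at
most `max_sites` (default 4) rows stay active, or chosen by BIC.

**Internal priming.** Reverse transcription can prime inside genomic
A-rich tracts, mimicking a pA site. A called site is flagged when the 10 nt
immediately 3' of it (sense strand) contain a run of more than 7 adenines
with up to one mismatch, i.e. any 8-base window with ≥ 7 A. 'N' counts as a
mismatch. Flagged genes are excluded from the final significant set by
default (toggle `exclude_internal_priming`).

## Statistical testing

Reads are classified long (padded end > P) or short (end ≤ P) and
aggregated per cluster. Genes are filtered before modelling: two-site
detection in ≥ 3 clusters, across-cluster mean CPM > 10 for the long and
the short isoform separately, and clusters with < 20 raw reads are dropped
(genes left with < 2 clusters are dropped).

The long/short counts are modelled by a binomial GLM for the log-odds of
distal usage with **weighted effect coding** of the cell-type factor:
category i's column is 1 for cluster i, −n_i/n_ref for the reference
cluster and 0 otherwise, with n_i the cluster read totals. Each coefficient
is then the deviation of cluster i's log-odds from the read-weighted grand
mean, and in a saturated fit the intercept equals Σ n_i logit_i / N — an
estimate anchored to all cells that unbalanced cluster sizes do not
distort. (The intercept coincides with the logit of the pooled long-isoform
proportion in symmetric tables; in general it is the count-weighted mean of
the cluster logits.) The reference level carries no column, so the model is
fitted twice with two references to give every cluster a coefficient and
standard error; coefficients shared between the two fits agree to numerical
precision.

Across-cell-type APA is tested by the likelihood-ratio test of the
cell-type model against the intercept-only null (with confounders: full
model against confounder-only model). On saturated cell-type-only fits this
equals the G-test of independence of the 2 × K table. P-values are BH
adjusted; a gene is called **significant APA** when q < 0.05 *and* at least
one cluster passes the effect-size gate |log2 OR| > 0.25 against the grand
mean. The gate is part of the caller's definition of a significant gene,
not an optional post-filter: without it, statistically detectable but
biologically negligible shifts in deeply sequenced genes dominate the call
set. (A literal odds-ratio > 0.25 rule is vacuously true; the gate is
therefore implemented on the log2 scale and is configurable.)

Cluster-specific calls use Wald tests of the per-cluster coefficients, BH
adjusted within each cell type across the significant genes, plus a 2-fold
rule: OR ≥ 2 → lengthening, OR ≤ 0.5 → shortening (fold configurable).
Separation or non-convergence triggers one retry with 0.5 added to every
aggregated cell of the gene's table (Haldane–Anscombe), logged.

With more than two detected sites the binomial model generalises to a
baseline-category multinomial logit on per-site counts with the same
coding; with exactly two categories it reproduces the binomial LRT.

## Simulation platform

The benchmark works at the cluster level, where the statistical component
operates. Defaults are 5,000 genes, 3,000 cells in 5 clusters, 100
repetitions per condition.

- **Counts.** Per-gene means are log-normal(meanlog 1.0, sdlog 1.2); each
  cell contributes a negative-binomial count (gamma–Poisson, dispersion
  0.2) scaled by a log-normal cell size factor (sdlog 0.25); cells are
  summed within clusters. These moments give per-cluster gene totals in the
  10²–10⁴ range typical of collapsed 10x data; only the cluster-level
  totals matter downstream, so the generator makes no attempt to reproduce
  cell-level structure (dropout profiles, gene–gene correlation, batch).
- **PDUI matrix.** Each gene's across-cluster dispersion of the
  long-isoform proportion (SD_isoprop) is the control variable: APA genes
  receive a high target (default 0.127), non-APA genes a low one (0.009).
  Rows are built by centring K standard normals, rescaling to unit sample
  SD, multiplying by the target and adding a Uniform(0.05, 0.95) mean; rows
  leaving [0, 1] are redrawn. The rescaling makes the sample SD of every
  row *exactly* its target (machine precision), so SD_isoprop is a testable
  row property rather than an expectation. Infeasible targets error after
  bounded retries.
- **Splitting.** long = round(total × PDUI), short = total − long; exact
  conservation, integer tables.
- **Scoring.** Per repetition the PDUI matrix is regenerated while the
  count matrix stays fixed; the caller (vectorised G-test ≡ logistic LRT,
  BH, effect gate) and a Pearson chi-square comparator (which returns no
  p-value whenever a zero appears in the table, mirroring R's `chisq.test`,
  and is scored non-significant there) are evaluated against the truth
  labels as sensitivity and specificity.

Because every row of the null configuration still carries dispersion
0.009, large-count genes make that dispersion statistically detectable:
the bare LRT+BH path rejects far more than 5% of all-null genes, and it is
the effect-size gate that keeps the false-discovery proportion low. The
all-null benchmark therefore scores the caller's full significance
definition.

What passing simulations does *not* show: robustness to misestimated
proximal sites, to internal-priming contamination, or to within-cluster
heterogeneity — the read-level fixture pipeline covers the first two at
small scale, the third is out of scope.

## Coordinates and conventions

Genomic coordinates are 0-based half-open (BED); transcript coordinates are
1..L with position 1 at the UTR's 5' start (so "1 < P < L" is literal).
GTF input (1-based closed) is converted on load. The per-gene UTR is the
union span of all annotated 3'-UTR features of the gene ("longest UTR");
overlapping genes on the same strand each receive the reads they overlap.
pA-site catalogs collapse intervals to their midpoint. Annotation-support
curves use an inclusive ± d boundary and require matching strand (a
strand-blind mode exists). Reads are assumed deduplicated upstream; a naive
exact-duplicate drop over (gene, position, barcode, UMI) is available
behind a flag. Reads aligning past the annotated UTR 3' end are clamped to
L rather than dropped.

## Problem sizes used in the shipped checks

The packaged tests run the simulator at its full default width (5,000
genes, 5 clusters) with 10 repetitions per condition and a 15-level
dispersion sweep from 0.06 to 0.18; read-level checks use a 4-gene,
4-cluster fixture with 300 reads per gene and cluster. These sizes give
Monte-Carlo standard errors small enough for the properties asserted while
keeping the default test run fast.
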