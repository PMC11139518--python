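# Methods

`temporade` analyzes bulk RNA-seq time courses with several biological
conditions observed at a common set of time points, the first of which
(t0) is a reference state — typically the basal state of the cells before
a stimulus.  This note documents the models, the defaults and the
numerical choices, in the order the pipeline applies them.

## Design model and contrast families

A design is a set of samples annotated with (condition, time, replicate)
triples; the (condition, time) pairs are the *cells* of the layout.  Two
contrast families are enumerated:

* **temporal** ("horizontal"): ti vs t0 within each condition, giving
  C × (T−1) analyses (20 for the reference 4 × 6 shape);
* **condition** ("vertical"): each unordered condition pair at each time,
  giving T × C(C−1)/2 pairwise contrasts (36 for the 4 × 6 shape).

On top of the vertical family, one *specificity analysis* is carried out
per (condition, time), i.e. C × T analysis units (24 for the 4 × 6 shape).
Both the 24 and the 36 are reported: the former counts the per-condition
questions asked, the latter the statistical tests underneath them.  Time
labels with a numeric part ("t0", "t1", "4h") sort numerically; purely
textual labels keep the sample sheet's declared order, and the first time
in order is t0.

## Normalization

Median-of-ratios size factors: the reference expression of a gene is its
geometric mean across samples, computed over genes with strictly positive
counts everywhere (a single zero removes a gene from the reference — this
keeps the reference in positive space and is the classical convention of
the DESeq lineage).  A sample's factor is the median of its ratios to the
reference; the median of an even number of ratios is the midpoint of the
two central values.  The implementation agrees with pydeseq2's estimator
to 1e-6 on shared inputs (checked in the test suite).  Note that scaling
one sample's column by c rescales the geometric-mean reference by c^(1/S),
so only *ratios* of size factors are exactly equivariant — the property
tests assert that form.

Downstream exploratory analyses work on log2(normalized + pseudocount),
pseudocount 1 by default (configurable).

## Exploratory structure

PCA is computed by SVD of the samples × genes matrix after centering and
(by default) scaling each gene by its sample standard deviation (n−1
denominator); constant genes are dropped with a warning when scaling.
Components follow a deterministic sign convention: each loading vector is
oriented so its largest-magnitude entry is positive.  Explained-variance
fractions are squared singular values over their total, so they sum to 1
at full rank.

HCPC applies Ward linkage to the leading principal-component coordinates.
The automatic cut exploits the fact that for Ward linkage the merge
heights are exactly the increments of within-cluster inertia: the selected
k (searched in [2, min(10, S−1)]) maximizes the ratio of the height of the
merge that would reduce k clusters to k−1 over the next one — the cut just
before the largest relative loss of inertia.  An optional k-means
consolidation step (started from the cut's cluster means, off by default)
refines labels.

The two heatmap substrates are the sample × sample correlation matrix
(Pearson by default, Spearman optional; a zero-variance sample is an
error naming the sample) and the gene-scaled expression matrix (each gene
row standardized to mean 0, sd 1 with the n−1 denominator; constant genes
dropped with a warning).  Rendering is deliberately out of scope — all
outputs are plot-ready tables.

## Temporal profile clustering

For one condition, a gene's profile is its per-time mean log-normalized
expression, row-standardized so clustering groups response *shapes*
rather than expression levels; flat profiles carry no shape and are
dropped with a warning.  Clustering is a from-scratch fuzzy c-means with
Euclidean distance: memberships u[g,c] ∝ d(g,c)^(−2/(m−1)) normalized per
gene, centroids are u^m-weighted means, and iteration stops when the
largest membership change falls below 1e-6 (default) or after 300
iterations.  The objective Σ u^m d² is non-increasing by construction and
is tracked per run.  A profile exactly coincident with a centroid takes
membership 1 for that cluster (the limit value, avoiding division by
zero).  Centroids initialize from k profiles sampled without replacement
with the caller's seed — reproducible and simple.

The fuzzifier defaults to m = 2.  The optional data-driven estimate uses
the Schwämmle–Jensen relation between the minimal meaningful fuzzifier
and the data dimensions (the same relation Mfuzz's `mestimate` uses),
clipped to (1, 5].

Automatic k selection runs fuzzy c-means over a k range and tracks the
minimum pairwise centroid distance d(k): once k exceeds the number of
genuine profile groups, two centroids land in the same group and d(k)
collapses, so the elbow is the k with the largest drop ratio
d(k)/d(k+1).  Both distances are regularized by an additive floor of 1%
of the largest observed d — beyond the true k, successive minima are all
near zero and their raw ratio is meaningless noise.

## Differential expression engine

Counts follow a negative binomial with variance μ + αμ²; sample j of
gene g has mean s_j · μ_{g,cell(j)} with s_j the size factor.  The model
is parameterized directly by **cell means** (one coefficient per
(condition, time) group) rather than factorial coding: every contrast of
interest is a two-cell difference, the MLE of a cell mean is the closed
form Σ counts / Σ size factors over the cell's samples, and the Wald
standard error is explicit.  Cells entering a contrast must have at least
two replicates.

Dispersion is estimated in three stages, per the empirical-Bayes scheme
standard for NB count models:

1. **Genewise:** maximum of the Cox–Reid adjusted likelihood given the
   fitted cell means, bounded to [1e-8, 10].  The CR adjustment
   (0.5 · Σ_cells log I_cell added to the negative log-likelihood)
   corrects the downward bias of plain ML when cell means are estimated
   from the same few replicates; without it the null tests are visibly
   anti-conservative at 4 replicates.
2. **Trend:** α_tr(μ) = a₁/μ + a₀ fitted over genes with genewise
   α > 1e-6 by iteratively reweighted least squares with gamma-style
   weights (1/fitted²), coefficients clamped non-negative.  If fewer than
   10 usable genes remain or the fit degenerates, a constant trend at the
   median genewise value is used with a warning.
3. **Shrinkage:** the posterior mode of log α under a normal prior
   centered at the trend.  The prior variance is the squared scaled MAD
   of the log residuals minus the expected sampling variance of the log
   genewise estimate (trigamma(df/2) with df = samples − cells), floored
   at 0.25.  Genes whose residual exceeds two prior standard deviations
   above the trend keep their genewise value and are flagged outliers
   (no refitting — flagging only).

All optimizations over log α use a vectorized three-round grid zoom
(40 + 2 × 15 evaluations per gene, shared across genes), giving ~1e-3
relative precision — ample under the shrinkage that follows.

The Wald test of a contrast floors both cell means at a pseudo-mean
0.5 / mean(s) to avoid infinite fold changes, takes
log2FC = log2(μ_a/μ_b), computes the standard error from the observed
Fisher information of the two-cell model
(I_cell = Σ_j s_j μ/(1 + α s_j μ)), and reports the two-sided normal tail
of log2FC/SE.  Genes with all-zero counts in both cells are untestable
(NaN p-value, tracked).  On null simulations at 4 + 4 replicates and
α = 0.1 the empirical type-I error at nominal 0.05 is ≈ 0.06 (range
0.04–0.08 over seeds), at parity with pydeseq2 on identical data — a
small anti-conservative bias intrinsic to plug-in-dispersion Wald tests
at this sample size.

Multiple testing uses Benjamini–Hochberg step-up within each contrast;
untestable genes stay absent and do not count toward the number of tests.
Optional independent filtering by base-mean quantile is off by default.
No log-fold-change shrinkage is applied: fold changes are raw MLEs.
Default DE call: adjusted p < 0.05 with no fold-change cutoff, both
configurable.

## Specific and signature genes

All set logic operates on the boolean decision matrix (genes × contrasts,
entry = adjusted p < α AND |log2FC| ≥ min_lfc).  Untestable genes are
not-DE in the logic, with the mask carried to outputs.

* A gene is **specific** to condition A at time ti iff it is DE between A
  and *every* other condition at ti, and *no* pair of the other
  conditions is DE at ti.  For C ≥ 3 specific sets at one time are
  provably disjoint.  With C = 2 the second clause is vacuous, so any DE
  gene is specific to both conditions; a warning marks the call as
  uninformative there.
* A gene is a **signature** gene of A iff at some non-reference time ti
  it is simultaneously specific to A at ti and temporally DE (ti vs t0)
  in A.  Specificity at t0 is computed and reported but can never
  contribute (there is no temporal contrast at t0).  A looser reading —
  DE at some time and specific at some possibly different time — is
  available as a non-default option (`same_time=False`).
* The **activation cluster** of a gene in a condition is its first DE
  time against t0 in time order, or "never".
* Alluvial flow tables count DE-state transitions of ever-activated genes
  between consecutive non-reference times, stratified by activation
  cluster; per time pair the counts partition the activated genes.

## Enrichment

Over-representation uses the exact hypergeometric upper tail
P(X ≥ overlap) with the universe as population, BH-adjusted across the
gene sets of a user-supplied GMT file.  The default universe is the set
of genes testable in the run.  No annotation is ever downloaded.  Writers
for RNK (signed Wald statistic by default, sorted descending), GCT 1.2
and categorical CLS (classes = design cells) are byte-deterministic: no
timestamps enter data files, and reruns with the same inputs are
byte-identical.

## Synthetic data

The simulator draws NB counts (Poisson when α = 0) around
μ_{g,cell} = baseline_g · 2^(Σ effects), with baselines
log-normal(log 100, 1), per-sample size factors log-uniform in [0.5, 2],
and an explicit effect grammar (gene, condition, time, log2 shift).
Truth labels are *not* bookkept independently: they are obtained by
running the package's own set logic on the true fold changes with
threshold |log2FC| > 0, so truth semantics and calling semantics coincide
by construction (this identity is itself tested).

The reference preset mirrors the supported study shape — 4 conditions ×
6 times × 4 replicates, 2000 genes — with 5% temporal-DE genes (a ±2
log2 shift shared by all conditions from a random onset time onward) and
2% specific genes per condition (the same shift in exactly one
condition), dispersion α = 0.1.  These are the conditions under which the
statistical guarantees are stated: null type-I ≈ 0.05–0.07, planted-DE
sensitivity ≥ 0.8 at observed FDR ≤ 0.1, and end-to-end specific-gene
recovery with sensitivity and precision ≥ 0.8.

What the simulator does *not* emulate: GC/length biases, batch effects,
correlated genes, outlier samples, library-size confounding beyond scalar
factors, or realistic annotation structure.  Passing recovery tests
therefore demonstrates the correctness and calibration of the machinery
under the stated NB model, not robustness to those real-data artifacts.

## Problem sizes

The test suite and the reproduction script run entirely on simulated
data: 1000-gene null designs, a 2000-gene planted-effect design, the
2000-gene reference preset end-to-end, and 200–1000 random decision
matrices for the set-logic oracles.  These sizes were chosen to make the
statistical bands tight while keeping a full run on a laptop-class single
core in a few minutes.

## Known limitations

* The Wald test is mildly anti-conservative at very small replicate
  counts (see above); likelihood-ratio or t-reference alternatives are
  out of scope.
* Cook's-style outlier refitting is not performed; outlier dispersions
  are only flagged.
* Fuzzy c-means finds a local optimum; results are reproducible via the
  seed but not guaranteed globally optimal.
* Specificity with two conditions is uninformative by construction.
* The GO step is deliberately offline: a GMT file must be supplied.
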