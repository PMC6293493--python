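# Methods

## The problem

A single-cell RNA-seq expression matrix X (genes x cells) contains many
zeros, of two very different kinds: *biological* zeros (the gene really is
not expressed in that cell) and *dropouts* (capture or amplification
failed; the missing rate can approach 30% even after noise reduction).
Imputing all zeros indiscriminately corrupts real biology, so the package
decomposes imputation into three questions: **where** is the data missing,
**how much** is missing, and **what** were the values.

## The three-stage model

### 1. Where — element-wise linear classification (LLC)

Genes are split into a *richly expressed* set (operationally: housekeeping
genes, expected to be expressed in essentially every cell) and the rest.
Every element x[i, j] becomes a sample whose features are the same gene's
values in the other n−1 cells and whose label is sgn(x[i, j]) (+1 if
positive, −1 if zero).  Under the model's hypothesis a zero at a richly
expressed gene is a dropout, so the richly set is a labelled training set
and the remaining genes are the test set: the classifier predicts, for
each zero element, whether it "should" be nonzero.

The classifier is an L2-regularized linear model, either logistic
regression

    min_w  1/2 w'w + C Σ log(1 + exp(−y_i w's_i))

or an L2-loss (squared-hinge) SVM

    min_w  1/2 w'w + C Σ max(0, 1 − y_i w's_i)².

Solvers come from scikit-learn (lbfgs / liblinear); the module's contract
is the objective value, which the tests verify against an independent
general-purpose convex minimizer to 1e-6 relative on small instances.  A
bias is carried as an augmented constant feature, so it is regularized
like any other weight and the objective includes b²/2.  The tie rule
sign(0) = −1 is deliberate: an exactly-zero decision never flags a
position as missing.

The classifier's positive rate over the test-set zeros defines the
threshold

    eta = (# zero elements predicted missing) / (# zero elements),

which is then applied to the other two detectors.

### 2. How much — refinement by intersection

Two independent detectors score the same zero elements:

**Zero-inflated mixture (ZIM).**  For pairs of cells within one
subpopulation, each gene's count pair (r_i, r_j) follows a three-component
mixture: dropout in c_i (r_i ~ Poisson(λ₀), λ₀ = 0.1), amplified (both
negative binomial), dropout in c_j.  Component priors are multinomial
logistic in the mixing covariate m = log(r_i + 1) + log(r_j + 1) (the
pseudocount keeps the log defined at zero counts).  The model is fitted by
EM; both M-step pieces (logistic coefficients, shared NB dispersion)
maximize the expected complete-data log-likelihood, so the observed
log-likelihood is non-decreasing — the dispersion is updated by a bounded
1-D search rather than moments precisely to preserve that guarantee, with
a fallback to the current value if the search returns a worse point.
Because the amplified NB is stated only through its counterpart count, the
amplified component links each side's NB mean to the other cell's count
scaled by the library-size ratio, and the non-dropped side of a dropout
component uses a saturated NB factor (mean = observed count) — a
profile-likelihood reading of an underdetermined specification.  Genes
whose posterior argmax is "amplified" in at least 20% of a
subpopulation's comparisons form the amplified set; the dropout posterior
of a zero element, averaged over the fitted pairs involving that cell, is
its ZIM missing probability.  ZIM requires count-like data and refuses
RPKM input unless forced.

**False-negative curves (FNC).**  Per cell, detection (value > 0) of the
housekeeping genes is regressed logistically on log μ*, where μ*_g is the
gene's expected expression conditioned on detection (mean of its nonzero
values across cells).  The per-cell curve F_c(μ) is the cell's technical
detection efficiency; 1 − F_c(μ*_g) is the missing probability of a zero
at (g, c).  Per-cell fits use a moderate ridge (C = 10): with ~10²
housekeeping points spanning a narrow μ* range, unregularized per-cell
fits suffer the classic near-separation slope inflation, and a moderate
ridge keeps the estimates stable (the recovery test checks the fitted
slope against a known generating curve).
Cells whose housekeeping genes are all detected (or all undetected), or
with fewer than 5 usable points, get a degenerate constant curve at the
observed detection rate clipped to [0.01, 0.99].

Each probability matrix is cut at its top ceil(eta·D) elements (D = the
detector's available zero elements; ties broken by position for
determinism).  The final missing set is the strict intersection of the
available detectors' candidate sets — the LLC contributes its
positive-predicted zeros directly.  Intersection trades recall for
specificity: a position is only declared missing when every view agrees.
When counts are unavailable the ZIM is skipped and the intersection runs
over LLC and FNC only.  A lenient mode intersects, per element, only the
detectors that cover it.

### 3. What — linear support vector regression

The richly-expressed samples are reused with value labels and an
ε-insensitive L2-regularized linear SVR

    min_w  1/2 w'w + C Σ max(0, |y_i − w's_i| − ε)^p ,  p ∈ {1, 2}

(L1-loss dual, L2-loss primal or dual, matching the three liblinear
variants).  Values at the intersected positions are the SVR predictions
clamped at zero; observed nonzero values are never modified.

## Feature and label scale

By default the pipeline feeds log1p-transformed values to the classifier
and the SVR, trains the SVR on log1p labels, and maps imputed values back
with expm1.  Expression spans several decades; on the raw scale the
element-wise classifier degenerates (its decision is dominated by a few
high-magnitude features and it flags essentially every zero, eta → 1) and
the raw-scale SVR systematically overshoots at dropout positions, which
have below-average true values, to the point of being worse than leaving
the zeros in place.  On the log scale both behave as intended.  The
transform is a config flag (`RunConfig.log1p`); the sample-builder default
remains untransformed for users who want the literal raw-value contract.

## Baseline smoother

The comparison method replaces a missing value at (g, c) by the mean of
gene g in the up-to-γ preceding and following cells along a supplied
trajectory ordering (γ = 3 default, truncated at the ends; neighbor zeros
included unless `exclude_zeros`).  The package never computes pseudotime
itself.

## Synthetic data generator

`misc_impute.synthetic.generate` draws seeded datasets emulating the
structure the detectors assume:

* gene means log-uniform on (log 0.3, log 80); negative-binomial counts
  with shared dispersion 2; 3 subpopulations, each shifting a random 30%
  of non-housekeeping genes by a lognormal factor (sd 0.8);
* per-cell detection-efficiency curves: an expressed element survives with
  probability sigmoid(a_c + 1.2·log truth), with per-cell intercepts
  a_c ~ N(−1.1, 0.7²).  Between-cell efficiency variation is the premise
  of the FNC model; without it the per-cell curves have nothing to
  estimate.  The intercept/slope defaults were calibrated analytically so
  that ~30% of expressed elements drop out, the regime that motivates
  imputation;
* dropped entries are replaced by Poisson(0.1) background counts (mostly
  zeros);
* 100 of 2,000 genes are housekeeping: drawn from the top quarter of the
  mean range, exempt from group shifts, and given a +1 logit efficiency
  boost, so their detection is near-ubiquitous (~97%) and their zero rate
  is lower than other genes' at matched expression.

Default scale is 2,000 genes x 300 cells — large enough for all stages to
operate (hundreds of pair fits per subpopulation, ~10⁵ zero elements) and
small enough that a 10-trial benchmark runs on one CPU in minutes.  What
the generator does **not** emulate: batch effects, doublets, ambient RNA,
UMI saturation, gene–gene correlation beyond group structure, and
cell-cycle or library-size confounding.  Passing tests therefore show the
machinery is correct under the model's own assumptions, not that the
method is well-calibrated on any particular real dataset.

## Numerical choices

* Classifier/SVR tolerance 1e-4 relative by default, max 1,000 iterations
  with a logged warning on non-convergence; oracle tests run at 1e-12.
* EM: tolerance 1e-6 relative log-likelihood, max 100 iterations;
  responsibilities initialized by a hard rule (count < 1 starts on its
  dropout side, else amplified); NB means floored at 0.1; dispersion
  bounded in [0.05, 1e4].
* Pair budget: all pairs when affordable, otherwise random perfect
  matchings until the budget (pipeline default 150 per subpopulation) so
  every cell is covered by roughly equally many pairs.
* Candidate ranking ties break by ascending (gene, cell); reruns with the
  same seed and config are byte-identical.
* Degenerate inputs error early with the offending identifier: all-zero
  cells in pair fits, single-class training sets, cells absent from a
  trajectory ordering, non-zero positions in a missing set.

## Known limitations

* The FNC score 1 − F_c(μ*) is monotone decreasing in μ*, so on the gene
  axis it ranks low-expression zeros (mostly biological) above
  high-expression zeros (mostly dropouts); its discriminative content on
  data of this structure is the per-cell efficiency axis.  The ensemble
  treats it as one voice among three for exactly this reason.
* eta is derived from the classifier's positive rate, which depends on
  how unbalanced the richly-expressed training labels are; with very
  clean housekeeping genes eta is high and the refinement leans on the
  intersection rather than the individual thresholds.
* The ZIM NB parameterization is one defensible reading of an
  underdetermined model; alternatives (cross-fitted expected magnitudes)
  are out of scope.
* All-zero genes have undefined μ* and never receive FNC probabilities;
  genes outside the amplified set never receive ZIM probabilities.  Under
  strict intersection such elements cannot be called missing.
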