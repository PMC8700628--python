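# Methods

`ibdclass` implements a two-stage latent-variable classifier that separates
Crohn's disease (CD) from ulcerative colitis (UC) using bulk RNA-seq counts
from endoscopic biopsies. This note records the model, the conventions the
package pins down, the synthetic-data design, and the limits of what the
test suite demonstrates.

## Problem structure

Each sample is a biopsy labelled by disease (CD / UC) and inflammation
status (inflamed / normal), giving four analysis classes. The clinically
interesting contrast is CD-inflamed vs UC-inflamed. The complication is a
sampling confound: normal-tissue biopsies come predominantly from different
gut segments in the two diseases (terminal ileum in CD, rectum in UC), so
genes that separate the *normal* classes largely reflect anatomy. The
pipeline therefore (1) learns the normal-vs-normal axis, (2) removes the
genes that dominate it, and (3) builds the inflamed-tissue classifier on
the remaining genes.

## Preprocessing

Counts are processed once, jointly over all samples:

1. **Low-count filter.** A gene is kept if its CPM exceeds the cutoff
   implied by `min_count = 10` at the median library size in at least `k`
   samples, `k` being the smallest of the four class sizes, and its total
   count is at least `min_total = 15`. This pins the "default filtering"
   convention of the edgeR workflow; we deliberately omit edgeR's
   `large.n`/`min.prop` damping of `k` (it only matters for k > 10 and
   makes the contract harder to state).
2. **TMM normalization.** Composition factors are the weighted trimmed
   mean of gene-wise log2 CPM ratios against a reference sample (the one
   whose upper-quartile count fraction is closest to the mean), with 30%
   two-sided trimming on M-values, 5% on average abundance A, inverse
   delta-method variance weights, pairwise removal of genes with a zero in
   either column, a factor of exactly 1 when all |M| < 1e-6, and a final
   rescale to geometric mean 1. These are the documented defaults of the
   tool this workflow emulates; the implementation reproduces its output
   to ~1e-15 on hand-checked fixtures.
3. **log2-CPM.** `value = log2((count + p_s) / (N_s + 2 p_s) * 1e6)` on
   effective library sizes `N_s` (depth x TMM factor), with the prior
   count `p_s = 2 * N_s / mean(N)` scaled per sample so equal counts at
   equal depth transform identically. Note the prior is invariant to a
   *global* depth rescaling, so log-CPM is exactly scale-free only when
   the prior count is rescaled with depth; at a fixed prior the drift is
   bounded by one log2 unit (attained at zero counts).

## PLS-DA

Class labels are encoded as an n x 2 indicator matrix Y, centered. For a
two-class problem the centered indicator columns are exact negatives, so
the NIPALS inner loop collapses to a closed form per component h:

    w_h ∝ X_h' y_c        (cross-covariance direction, unit norm)
    t_h = X_h w_h
    p_h = X_h' t_h / t_h't_h ,  c_h = Y_h' t_h / t_h't_h
    X_{h+1} = X_h − t_h p_h' ,  Y_{h+1} = Y_h − t_h c_h'   (regression mode)

Genes are centered and scaled to unit variance (ddof = 1) before fitting —
the convention of the multivariate toolkit this mirrors — with `scale`
exposed as a flag. Component signs are fixed (largest-|w| entry positive)
so output is identical across linear-algebra backends. Fits agree with
scikit-learn's `PLSRegression` and with an independent SVD-based
implementation to 1e-6 up to sign.

**Prediction.** Default `max_score`: a new sample takes the class whose
reconstructed indicator value `x' R C' + ȳ` is largest; `centroid`
(nearest class mean in score space) is available. Ties go to the
alphabetically first label, deterministically. With unbalanced classes
`max_score` is biased toward the majority class — visible in the stage-1
trench errors, which sit near the majority rate once the signal is pruned
away.

**Pruning statistic.** With d the unit vector connecting the two class
mean score vectors, gene g scores `|Σ_h p_{gh} d_h|` — the absolute
projection of its loading vector on the inter-centroid direction in
*latent* space (the gene-space reading of "direction connecting the class
means" is the natural alternative; the latent reading is what a
score-space centroid plot suggests and is recorded in the report).
Pruning at fraction f removes the top ⌊f·n⌋ scorers, ties broken by gene
identifier; quartile fractions {1/4, 1/2, 3/4} form the "trench" table and
f = 1/2 is the default for stage 2.

## Sparse PLS-DA and keepX tuning

Per component the dense weight vector is soft-thresholded at its
(keepX+1)-th largest magnitude so exactly keepX genes stay nonzero
(identifier tie-break; exactly tied survivors are kept at half the
smallest surviving magnitude so the support size is exact), then
renormalized; deflation is unchanged. Sparsity lives in the weight
vectors, which is what the signature export reports; the projection
loadings used for deflation and prediction remain dense, as they must.
With keepX = n_genes the sparse fit equals the dense fit to 1e-9.

keepX is tuned sequentially: component 1's grid is searched with repeated
stratified 5-fold CV (100 repeats by default), the minimizer of the mean
balanced error rate is fixed, then component 2 is searched, and so on.
Ties go to the smaller keepX (parsimony — also the behavior of the
toolkit this mirrors). Balanced error is the default criterion because
the inflamed classes (29 vs 20 by default) are mildly unbalanced;
`tune_criterion="oer"` switches to overall error. Fold streams are shared
across grid values so candidates are compared on identical splits, and a
single-value grid with `repeats=1` reproduces one plain 5-fold CV exactly.

A consequence worth knowing: when the signal is strong enough that several
grid values tie at zero CV error, parsimony selects the smallest of them.
A planted 20-gene signature whose per-gene effect is ~3 within-sample SDs
is in this regime, so the tuned model recovers only about half the planted
genes even though its prediction error is ~0 — sensitivity of recovery and
parsimony of tuning genuinely trade off here.

## Cross-validation and error rates

Folds are stratified per class (round-robin after a seeded shuffle; class
fold sizes differ by ≤ 1). Stratification is a deliberate strengthening of
"random splits": with a 13-sample class, unstratified 5-fold splitting can
produce test folds with no member of one class, leaving the per-class
error undefined. Within a repeat, fold predictions are pooled before
computing the overall error rate (OER, misclassified/total) and balanced
error rate (BER, mean of per-class errors); both are then averaged over
repeats. Anything the fitter does — including gene selection — happens
inside each training fold.

The final evaluation refits the sparse model in every training fold with
the *tuned keepX held fixed*; re-tuning keepX inside every fold is the
stricter nested alternative and is flagged in the report. The trench-table
CVs reuse one fold stream per stage across fractions so the three errors
differ only through the gene set.

## Synthetic cohort

The generator emulates the study design: class sizes 29/65/20/13, a
2000-gene universe (desk-scale stand-in for ~19.6k protein-coding genes),
negative-binomial counts (Gamma–Poisson; variance μ + φμ², single
φ = 0.1 shared across genes), gene baselines log2-normal (mean 5, sd 2,
i.e. typical counts of tens), and log-normal library-size factors
(sd 0.3 ≈ 2-fold depth spread) applied to the means — so the TMM stage is
actually exercised. Three disjoint planted sets, each half up / half down
(alternating signs so sign is independent of magnitude):

| set | default size | default log2FC | perturbs |
|---|---|---|---|
| inflammation | 300 | 2.0 constant | both inflamed classes, equally |
| disease | 20 | 1.5 constant | CD-inflamed vs UC-inflamed (±FC/2) |
| segment | 1000 | 1.5 graded | CD-normal vs UC-normal (±FC/2) |

The segment set is large and *graded* (geometric decay from the full
effect to 5% of it): real inter-segment expression differences span much
of the transcriptome with a heavy-tailed magnitude profile, and that
spread is what makes progressively deeper pruning progressively more
harmful — removing the top quartile of discriminators still leaves a
weaker second echelon, exactly the monotone trench behavior the analysis
is designed around. A small constant-effect segment set cannot reproduce
this even qualitatively: the first quartile cut would already remove it
entirely. Disease and inflammation sets stay constant-effect so recovery
analyses remain interpretable.

What the generator does **not** model: gene–gene correlation networks,
batch effects, gene-length biases, isoform structure, per-gene dispersion
trends, or class-specific sequencing depth. Passing the synthetic suite
therefore shows the *procedure* is correct and well-calibrated under the
assumed four-class NB structure; it says nothing about how large the
CD/UC signal is in real mucosa, and the cohort-specific error rates of
the motivating study are not reproduction targets.

## Numerical and scale choices

- All randomness flows from a single integer seed per entry point; child
  seeds are drawn below 2^31. Identical inputs and seed give byte-identical
  TSV/JSON outputs.
- Degenerate inputs fail loudly: all-zero samples, a fully filtered gene
  set, ncomp beyond the data rank, coincident class centroids, classes
  smaller than the fold count, fractions ≥ 1.
- Default analysis sizes follow the study protocol (trenches {1/4, 1/2,
  3/4}, 5-fold CV, 10 repeats for model-level checks, 100 for tuning and
  the final evaluation, keepX grid 1–300, up to 4 stage-2 components).
  The acceptance script and test suite run the same pipeline with a
  log-spaced keepX sub-grid ({5,10,20,50,100}(,200,300)) — the package's
  desk-scale default for a 2000-gene universe, where neighboring grid
  points are statistically indistinguishable anyway.
- Stage-2 component count is the minimizer of mean CV overall error over
  1..4 (ties toward fewer components).

## Known limitations

- Two-class PLS-DA only; no multiclass or orthogonal-PLS variants.
- `max_score` prediction inherits a majority-class bias under imbalance;
  BER is reported alongside OER for that reason.
- The filter is approximately, not exactly, idempotent (library sizes are
  recomputed from the surviving genes), though on realistic matrices the
  fixed point is reached after one pass.
- Tuning minimizes prediction error, not recovery: under very strong
  signal it deliberately returns fewer genes than were planted (see the
  sparse-tuning section above).
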