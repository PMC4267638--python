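# Methods

## Problem setting

An scSNV is a single nucleotide substitution inside a splicing consensus
region: positions −3..+8 around the 5′ (donor) splice site or −12..+2
around the 3′ (acceptor) splice site of an intron, with no position zero.
Negative offsets are exonic at the donor and intronic at the acceptor. The
invariant GT (donor +1,+2) and AG (acceptor −2,−1) positions are excluded
throughout: variants there almost always disrupt splicing and need no
model. Each intron therefore exposes 9 donor + 12 acceptor mutable
positions; with 3 alternative alleles per position a two-exon transcript
yields exactly 63 potential scSNVs.

## Splice-site models

**PWM.** Per-position base frequencies with an additive pseudocount
(default 0.5 per cell, so frequencies stay positive under small training
sets): f = (count + pc) / (n + 4·pc). A sequence's log-likelihood
Σ_p log f_p(s_p) is min-max normalized to [0, 100] using the per-position
extreme log-frequency sums, the Shapiro–Senapathy convention. The 0–100
scale gives the tool a finite score range, which is what the absolute
score variation downstream divides by. The score is monotone: substituting
a base by one with higher frequency at that position can never lower it.

**Maximum entropy.** The model is the maximum-entropy distribution over
window sequences subject to matching empirical marginals on a constraint
set: all singleton positions (order 1), plus adjacent pairs (order 2,
default) or adjacent triples (order 3). Because the constraint subsets form
a chain, the entropy maximizer has a closed form — the Markov chain of
order (constraint_order − 1) assembled from the pseudocounted pair/triple
tables. Uniform per-cell pseudocounts make adjacent tables agree exactly on
shared marginals, so the constraints are coherent and the fit is exact; no
iterative scaling is needed, and the `tol`/`max_iter` parameters back a
post-fit residual check rather than an optimization loop. Tests verify the
chain solution against independent iterative proportional fitting over the
fully enumerated 4^L table (total variation < 1e-15 at L = 4). Scores are
log₂(P_model / P_background); the background is uniform by default and can
be the training composition or a custom per-position table. Restricting
constraints to adjacent subsets keeps fitting exact and desk-scale; it
covers the dominant neighbor dependencies of splice signals but not
longer-range couplings.

Sequence handling: lowercase is uppercased; N and IUPAC ambiguity codes are
rejected with the offending position, never imputed. Models serialize to
versioned JSON.

## Score variations

For a tool emitting wild-type score w and mutant score m: the difference is
signed, d = w − m, so loss of splice-site signal is positive. Signal gains
(negative variations) are deliberately preserved rather than folded into an
absolute value — site-loss is the dominant mechanism within consensus
regions and the classifiers can use the sign. relative = d/w (undefined
when w = 0, which is recorded as *missing*: a zero wild-type score means
the tool failed to find the true site); absolute = d/(hi − lo) only for
tools with a finite range (lo, hi). Tools with missing rate above the 5%
threshold are screened out. The retained feature order is frozen —
pwm_rel, pwm_abs, mes_rel, nnsplice_rel, nnsplice_abs, hsf_rel, hsf_abs,
optionally followed by phylop_placental, phylop_primate, cadd_raw,
cadd_phred — so serialized models remain portable.

## Ensemble classifiers

**Boosting** (the `ada_score`). An additive model F(x) of depth-2 decision
trees, n_iter = 50 rounds by default. The *gentle* variant fits a weighted
least-squares regression tree to the ±1 response each round; the *real*
variant fits a weighted classification tree and contributes half the
log-odds of its leaf probabilities. The default loss is logistic
(weights 1/(1 + e^{2yF})); exponential weighting is available. The
probability output is 1/(1 + e^{−2F}), the standard logistic link for
additive margin models. Each round is accepted at the largest step in
{1, ½, ¼, ⅛} that does not increase the training loss, so the recorded loss
path is non-increasing by construction (a plain Newton-style round can
overshoot under the logistic weighting). Missing feature values are routed
per split to the child chosen during training and the route is replayed at
prediction, so boosting scores exist for incomplete rows. Relative
importance is the frequency with which each feature is selected for a
split, normalized to sum to 1.

**Random forest** (the `rf_score`). A standard random forest — 500 trees,
⌊√p⌋ features per split, bootstrap sampling — wrapped so the reported
probability is the fraction of trees voting positive and out-of-bag (OOB)
accuracy is exposed. Incomplete rows are dropped at training (with a
recorded count) and refused at prediction; the pipeline-level scorer
returns NaN for them instead. Importance is OOB permutation mean decrease
in accuracy: per tree, accuracy on its OOB rows minus accuracy after
permuting one feature, averaged over trees.

**Calls.** A variant is splice-altering when a score strictly exceeds the
cutoff (default 0.6). The *either* rule fires on one score; the *both* rule
requires both and returns "missing" if one is unavailable.

## Evaluation protocol

10-fold stratified cross-validation (stratification guarantees both classes
in every fold under the 1164/1795 imbalance). Per fold: fit on the other
nine folds, choose the accuracy-maximizing cutoff *on the training folds*
(candidates are midpoints between adjacent sorted unique scores plus ±∞;
ties break toward highest sensitivity+specificity, then the smallest
cutoff; a score counts positive when strictly above the cutoff), then
measure AUC and confusion metrics on the held-out fold. AUC is the
trapezoid integral of the ROC curve with tied scores grouped into single
steps, which equals the Mann–Whitney statistic with ties counted ½. The ten
fold curves are vertically averaged on a fixed 101-point FPR grid and fold
quantities are averaged arithmetically. Rows a method cannot score (missing
for that tool/model) are discarded from that method's evaluation only. Two
methods sharing a fold assignment are compared with the cross-validated
paired t-test: t = mean(d)·√k / sd(d), df = k − 1, two-sided; identical
AUCs give t = 0, p = 1, and zero-variance nonzero differences are reported
as the p → 0 limit.

## Enrichment statistics

The trend test is the Cochran–Armitage chi-squared test for trend in
proportions with group scores 1..k and no continuity correction (matching
the common statistical-environment default); its p-value is invariant under
affine rescaling of the scores, and with k = 2 the statistic reduces to the
uncorrected Pearson chi-square. The 2×2 test is uncorrected Pearson by
default with a Yates flag, since whether the original analysis corrected is
unknowable from the printed output and at the analyzed counts the
conclusion is insensitive. p-values below 2.2e-16 are displayed with that
conventional floor next to the raw float.

## Genome database

Coordinates are 1-based inclusive at the module surface (matching VCF and
the db dialect). Minus-strand transcripts are walked in transcript
orientation and mapped back to plus-strand coordinates, so stored ref/alt
are always plus-strand bases; enumeration on a minus-strand gene equals the
reverse-complement construction (property-tested). A variant inside two
transcripts' windows produces one row keyed by (chrom, pos, ref, alt) with
the transcript list merged; when sites conflict the first-seen site
identity is kept and scoring uses the maximum-variation site. The dialect
is tab-delimited with header
`#chr pos ref alt refseq_tx ensembl_tx site offset ada_score rf_score`,
"." for missing; `region_side` is derivable from (site, offset) and is
reconstructed on read, making write→read→write byte-identical. GTF/GFF
parsing is backed by gffutils, refFlat by direct column parsing (its starts
are 0-based half-open and converted), FASTA access by pyfaidx, and VCF
annotation by pysam.

## Synthetic data

The curated variant table behind the real analysis cannot be
redistributed, so the generator emulates its statistical shape. Features
are class-conditional Gaussians with a shared latent factor (within-class
correlation ρ = 0.5 by default): the seven variations measure the same
underlying disruption of one variant, so independent features would make
ensemble-vs-single comparisons meaningless. The positive-class mean shift
per feature is calibrated in closed form from the target single-feature
AUC, δ = √2·σ·Φ⁻¹(AUC), with default targets (0.95, 0.95, 0.94, 0.90,
0.91, 0.93, 0.93) for the seven variations and 0.80 for the four
conservation/functional extras, default class sizes 1164/1795, and
per-feature missing rates near the real tools' (≈2–3%). The toy genome
plants multi-exon genes on both strands with canonical GT/AG at intron ends
in transcription orientation. Recurrence calls draw per-bin positives at
configurable proportions (defaults 0.707/0.742/0.845) over desk-scale bin
totals (4000/300/130).

What the generator does not emulate: bounded/skewed tool-score
distributions, missingness correlated with weak sites, real inter-tool
complementarity, linkage between variants, and COSMIC's gene-level
structure. Tests passing on synthetic tables validate the machinery and
qualitative orderings (ensembles above single scores; 11-feature models at
or above 7-feature ones), not published performance numbers.

## Problem sizes and numerical choices

Tests and the acceptance script run everything at full training-table scale
(2959 rows) but desk-scale genomes (hundreds of bases) and 4^L
enumerations at L ≤ 5; the ensemble seed sweep uses 5 seeds of 10-fold CV.
Probabilities entering log-odds are clipped at 1e-6; PWM log-frequencies
are floored at 1e-300 so zero-pseudocount models stay finite; all
stochastic fits take explicit seeds and are bit-for-bit reproducible given
them.

## Known limitations

Branch points, exonic/intronic splicing enhancers/silencers and
trans-acting factors are out of scope, as are indels and variants outside
the consensus windows. The boosting defaults (50 rounds, depth-2 trees) are
documented assumptions standing in for unpublished implementation defaults.
Training-set AUC of an unregularized booster is optimistically biased (it
partially memorizes); all reported performance is therefore
cross-validated.
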