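# Methods

This note documents the models, defaults and numerical choices behind
`methylstage`, and what the synthetic experiments do and do not demonstrate.

## Feature construction

**Presence/coverage filter.** A cytosine enters the analysis only if it has
≥ `min_coverage` (default 4) reads in *every* sample. This is strict
completeness: no imputation, so downstream matrices never contain missing
cells. The default restricts to CpG context (`context="CG"`); passing
`context=None` admits CHG/CHH as well.

**Regions.** Retained cytosines are clustered per chromosome by a greedy
scan: a region grows while the next cytosine is ≤ `gap_max` (default 100) bp
from the previous member, and is kept if it has ≥ `min_cytosines` (default 4)
members. Region widths therefore vary with the local cytosine landscape
rather than being fixed 100-bp bins; a fixed tiling cannot produce the
\>100-bp features this procedure is meant to generate, which is why the
gap-based reading was chosen. Both knobs are exposed.

**Levels.** Cytosine feature value = m/(m+u). Region value = unweighted mean
of member levels (a coverage-weighted mean is available via
`coverage_weighted=True`; with equal coverages the two coincide). Feature ids
print 1-based coordinates (`chr_4_31092165`, `chr_3_9331371_9331488`);
internally all intervals are 0-based half-open, converted once at the IO
boundary. Plus- and minus-strand CpGs are not merged.

## Classifiers

**Random forest** (scikit-learn): 100 trees, `sqrt` features per split,
bootstrap sampling; prediction by majority vote with ties broken toward the
lowest class index in the canonical stage order
(paradormancy < endodormancy < ecodormancy). Feature importance is total
impurity (Gini) decrease.

**Gradient boosting** (xgboost, `hist`): the regularized objective
L = Σ l(ŷ,y) + Σ γT + ½λ‖w‖². Defaults are a *boosted-stump*
configuration — `max_depth=1`, `learning_rate=0.05`, `n_rounds=900`,
`colsample_bytree=0.15`, `reg_gamma=0.1`, `reg_lambda=1` — rather than the
library defaults (depth 6, η 0.3). Rationale: with far more features than
samples and per-locus (additive) signal, deep fast-learning boosters converge
after splitting on a handful of the informative loci and pad trees with
spurious interaction splits, which makes a non-zero-gain criterion both
incomplete and noisy. Depth-1 trees can only encode marginal effects; the
slow learning rate keeps residuals alive long enough, and per-tree column
subsampling forces the booster to visit redundant informative loci; the
minimum split gain γ discards stumps whose gain is at the noise level.
Importance is split gain. All stochastic steps take explicit seeds.

## Exact Shapley attribution

The attribution for feature i of one prediction is the Shapley value over
feature subsets with the restricted model defined interventionally against a
background dataset Z: f_S(x) = E_{z∼Z} f(x_S, z_{F∖S}). For tree ensembles
this is computed *exactly*, leaf by leaf: for each foreground/background pair
the leaf's path conditions partition its features into U (x's branch
required) and V (z's branch required); features outside U∪V are null players,
so the Shapley weights collapse to (|U|−1)!|V|!/(|U|+|V|)! for i∈U and
−|U|!(|V|−1)!/(|U|+|V|)! for i∈V. No sampling is involved; local accuracy
(Σφ + base = model output) holds to float64 accumulation error, and the
implementation is verified against exhaustive 2^|F| subset enumeration in the
tests. The attributed output is the class probability for RF (additive over
trees) and the per-class margin for XGBoost (class probabilities are not
additive over boosted trees). The default background is the training matrix.
Global importance = mean |φ| over samples and classes.

## Consensus ("integrated") selection

A feature is kept iff it has strictly positive importance in all four views
(RF Gini, XGB gain, mean |φ| under RF, mean |φ| under XGB). The threshold is
exactly zero with no epsilon: tree importances and exact attributions are
exact sums, so zero means the feature was never used / never moved any
prediction. Output is ordered by mean rank across the four views.

Selection is performed on the **full labeled matrix** by default, matching
the protocol this pipeline reimplements. That choice leaks label information
into any subsequent CV of the selected features, so measured "selected"
accuracies are optimistic. `evaluate.nested_benefit_pvalue` performs the
honest variant — selection recomputed inside each training fold — and is what
the null-calibration analysis uses; under permuted labels its benefit-test
p-values are uniform, which full-matrix selection cannot achieve.

## Cross-validation and metrics

Repeated stratified k-fold (scikit-learn splitter) with 3 folds for the
3-stage scenario (the 9-sample minority class yields exactly 3 paradormancy
samples per fold) and 10 folds for the 2-stage scenario; `n_repeats` defaults
to 10 where not otherwise stated (the evaluation scale used in the bundled
analyses is 5 repeats, chosen as the package's reference problem size).
Metrics come from the fold confusion matrix with the 0/0 → 0 convention
(warned); macro averaging for multiclass precision/recall/F1 (weighted
averaging available); AUC is one-vs-rest macro on probability outputs. The
selection benefit is a two-sided *paired* t-test on per-fold accuracies under
identical fold assignments; a zero-variance difference vector returns p = 1
(all-zero differences) or p = 0 (constant non-zero shift), flagged
degenerate, never NaN.

## Synthetic methylomes

The generator emulates the structure of a multi-cultivar dormancy WGBS study;
**no published noise model exists for these data, so every distributional
choice is a stand-in**, chosen once as field-typical and documented here:

* 8 chromosomes (1.0 → 0.3 Mb), 5000 cytosines placed mostly in CpG-dense
  clumps (≈70 % in clumps of mean size 6 within 150 bp) so region clustering
  has realistic material;
* context mix 0.4/0.3/0.3 (CG/CHG/CHH) with baseline methylation 0.5/0.3/0.1
  — plant-typical absolute levels;
* coverage ~ NegativeBinomial(mean 20, size 20), i.e. variance/mean = 2, the
  mild overdispersion of a ~20× WGBS run; with 71 samples the presence
  filter then retains ≈98 % of sites, acting as mild QC rather than a
  second selection step;
* methylated reads ~ Binomial(coverage, p) with
  logit(p) = logit(base) + stage_effect·coef(locus, stage)
  + cultivar_effect·sign(locus)·1[cultivar match];
* 71 samples (9/36/26 by stage) over 4 cultivars assigned round-robin within
  stage, so cultivar is orthogonal to stage by design;
* 1 % of cytosines (50) are stage-informative CG loci, each with per-stage
  coefficients from a random permutation of (−1, 0, +1); placement is
  enriched 3× inside TE/QTL intervals. 5 % are cultivar-confounder CG loci
  (disjoint from the informative set) shifted by ±3.5 logits for one
  cultivar's samples.

**Effect-size calibration.** `stage_effect = 0.6` makes each informative
locus individually weak (≈0.17 shift in level between extreme stages against
per-sample binomial noise of ≈0.11) while the 50-locus aggregate is strongly
discriminative, and `cultivar_effect = 3.5` makes confounder loci swing
almost rail-to-rail. This places the default design in the regime the
pipeline is about: raw data groups by cultivar (leave-one-out nearest-centroid
score ≈1.0 for cultivar vs ≈0.8 for stage), full-feature CV accuracy is
mediocre, and consensus selection recovers most planted loci, flips the
grouping to stage, and lifts RF accuracy by >10 points. With a much larger
stage effect the full-feature model is already perfect and selection is moot;
with a much smaller one nothing is recoverable.

**What passing synthetic tests does not show.** Real methylomes have
spatially correlated methylation, strand and batch effects, missing data
patterns tied to mappability, non-additive locus interactions, and biological
replicate structure; none of these are modeled. Synthetic results validate
the machinery (filters, selection, attribution, evaluation, annotation), not
biological effect sizes or the transferability of selected loci.

## Annotation conventions

Promoter = 2 kb upstream of the TSS, downstream = 2 kb past the TTS, both
strand-aware and clipped at chromosome bounds. Overlap = ≥ 1 shared bp.
Primary context follows the precedence TE > promoter > gene body >
downstream > intergenic (configurable), which makes the categories mutually
exclusive; the gene-relative context repeats the rule without the TE layer
for the TE-class cross-tabulation. TE class for a feature = class of the TE
with the largest overlap, ties to the first by coordinate. Introns are
inferred as gene minus exons when absent from the GFF3. Density windows tile
each chromosome from 0 in 1-Mb steps and count features by their start, so
boundary-crossing regions are not double-counted. The genome TE fraction uses
union (overlap-merged) semantics and is invariant under duplication or
splitting of intervals.

## Problem sizes of the bundled analyses

The reference study runs at 5000 cytosines × 71 samples with 5 CV repeats;
the null calibration runs 50 permutation seeds at 500 cytosines with nested
per-fold selection and reduced ensembles (60 trees / 150 rounds). These sizes
are the package's reference experimental design; all are configurable.

## Known limitations

* Full-matrix selection before CV (the replicated protocol) is optimistically
  biased; use the nested mode for honest estimates on new data.
* CpG sites on opposite strands are treated as distinct features.
* Chromosome name matching is exact-string.
* The interventional Shapley cost grows with
  (foreground × background × leaves); for very large backgrounds pass a
  subsample as `background`.
* Feature-id parsing assumes `<prefix>_<number>` chromosome names (or purely
  numeric names); a chromosome name like `chr4` would make region ids
  ambiguous with cytosine ids on an underscore-containing chromosome.
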