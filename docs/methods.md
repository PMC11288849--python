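# Methods

`selstack` implements a two-level stacked-generalization pipeline for genomic
prediction in family-structured breeding populations, together with the
phenotype-adjustment stage that precedes it and a synthetic trial generator
that makes the whole pipeline testable without any external data.

## Phenotypic model and adjusted phenotypes

Repeated yearly records are analyzed with the linear mixed model

    y = X u + Z g + W p + V r + T b + R i + e

where `u` holds fixed year means and the random terms are progeny genetic
effects `g ~ N(0, I sigma_g^2)`, individual permanent-environment effects
`p`, population effects `r`, plot effects `b`, year-by-progeny interactions
`i`, and the residual `e`, each with its own variance component. Variance
components are estimated by EM-REML on Henderson's mixed-model equations:
each sweep solves the MME at the current variance ratios and updates
`sigma_k^2 = (u_k' u_k + sigma_e^2 tr(C^kk)) / q_k`, with the residual from
the weighted residual sum of squares over `n - rank(X)`. Components are
floored at 1e-10 and iteration stops when the largest relative change drops
below 1e-8 (at most 500 sweeps).

Plain EM approaches a boundary component (a variance whose REML maximum is
zero) geometrically, which can exhaust the iteration budget without meeting
the relative tolerance. The fitter therefore applies Aitken extrapolation to
each component every eighth sweep, jumping to the projected limit of the
geometric tail and flooring projections below 1e-6 of the phenotypic
variance. The plain-EM path, whose restricted likelihood is provably
non-decreasing, is used whenever the likelihood path is tracked
(`track_loglik=True`); the monotonicity invariant is asserted there. The
implementation reproduces `lme4::lmer` REML estimates on the same data to at
least five decimals.

Individual heritability is `sigma_g^2 / (sigma_g^2 + sigma_p^2 + sigma_r^2 +
sigma_i^2 + sigma_e^2)`; the plot variance is excluded from the denominator
by convention here, with `include_plot=True` to add it. The adjusted
phenotype y* of an individual is the mean over its records of
`y - u_year - b_plot - i_yearxprogeny` — only year, plot and year-by-progeny
effects are removed, so genetic, permanent-environment and population signal
remain in the prediction target. An alternative `genetic_blup` mode returns
the progeny-plus-permanent-environment BLUP instead.

Note that the subtracted year effect is the generalized-least-squares
estimate, which equals the arithmetic year mean only when no random
structure is present.

## Base learners (level 0)

All fourteen learners regress y* on allele-dosage markers (0/1/2 counts of
the alternate allele; missing calls are mean-imputed to `2p` beforehand).

**GBLUP.** Markers are centered as `W = M - 2p` with training-set allele
frequencies, and the VanRaden relationship matrix is `G = W W' / sum 2p(1-p)`
(an n-by-n kernel). The model `y* = 1b + u + e`, `u ~ N(0, G sigma_g^2)`, is
fitted by REML on the spectral decomposition of the projected kernel,
profiling over the variance ratio with a 49-point log grid refined by
bounded scalar minimization. Test individuals are centered with the
*training* frequencies (no leakage) and predicted by the BLUP extension
`u_test = K_test,train K_train^-1 u_train` (ridge 1e-8 on the inverse).

**Regression trees, RF, QRF.** Trees grow by exhaustive recursive binary
splitting: every candidate feature and every midpoint between consecutive
distinct values is scored by the two-region residual sum of squares; ties go
to the lowest feature index, then the smallest threshold. Nodes stop
splitting below `2 * min_node` rows (default `min_node=5`), on constant
response, or when no split reduces the RSS; no pruning. The random forest
(500 trees by default, `mtry = ceil(v/3)` fresh candidate features per node,
bootstrap resamples of size n) averages leaf means. The quantile random
forest keeps each leaf's training observations, bootstrap multiplicities
included: a query gets weight `1/(leaf size * T)` per co-resident
observation per tree, the weighted empirical CDF defines
`Q_tau(x) = inf {y : F(y|x) >= tau}`, and the nine quantile learners
(tau = 0.1 ... 0.9) share a single trained forest because the weights do not
depend on tau. The split search is compiled with numba; a pure-numpy
fallback with identical semantics is selected automatically if numba is
unavailable, and the two are cross-checked in the test suite.

**MARS.** Degrees 1-3. The forward pass greedily adds reflected hinge pairs
`(x_j - t)+ / (t - x_j)+` (knots at observed feature values, thinned to at
most 32 quantile-spaced candidates for very fine-grained features) times an
existing parent term, choosing the pair with the largest joint RSS reduction
computed against the orthonormalized current basis; no term may multiply two
hinges of the same feature, and products are capped at the model degree.
The default term budget is `min(21, 2*ceil(m/10)+1)`, floored at 3. The
backward pass deletes one term at a time (never the intercept), keeping the
submodel minimizing `GCV = (RSS/N) / (1 - C(M)/N)^2` with
`C(M) = M + d(M-1)/2` and penalty `d = 3`. Least squares uses pivoted QR
with collinear columns dropped at tolerance 1e-10. On dosage data the knots
are effectively {0, 1, 2}, so degree-1 MARS is close to a segmented linear
model in each marker.

## Stacking (level 1)

Level-1 metadata are the base learners' out-of-fold predictions from an
inner 5-fold split of the training set; learners are then refitted on the
full training set for test-time use. The literal recipe — in-sample
predictions of the refitted learners — leaks training information and is
available behind `naive_level1=True` for comparison. Four variants are
assembled: all fourteen columns (GEBV-BL); plus the centered SNP block
(+SNP); only learners whose inner predictive ability strictly exceeds the
across-learner mean (Best, computed from inner folds only, so test data
never influence selection; if no learner exceeds the mean, all are kept with
a warning); and Best+SNP.

Six meta-learners combine the metadata. The mean- and weight-based
combiners (SSM, SWR) operate on the prediction columns only — a sum-to-one
weighting of raw SNP dosages has no meaning — so their GEBV-BL and +SNP
outputs coincide; the SNP block enters the regression-, forest- and
kernel-based combiners. SSM (unweighted mean), SR (ordinary
least squares with intercept; collinear columns fall back to the min-norm
pseudo-inverse solution with a warning), SWR (non-negative least squares
with weights normalized to sum to one — the classic stacked-regressions
constraint), SRR (ridge on standardized columns, penalty chosen by inner
5-fold CV over a 50-point log grid from 1e-4 to 1e4), SRF (random forest on
the metadata), and, for +SNP variants only, S2KGBLUP: a two-kernel GBLUP
whose first kernel is the VanRaden matrix of the SNP block and whose second
is the standardized cross-product of the prediction columns
(`K = P P' / q`), fitted by EM-REML with the same Aitken safeguards.
Predictions for test individuals extend both kernels with cross-blocks
built from training-frequency-centered test dosages and training-
standardized prediction columns.

## Evaluation protocol

Individuals are split 70/30 uniformly at random (train size `floor(0.7 n)`;
136/59 at n=195), 10 times. Predictive ability is the Pearson correlation
between predicted GEBVs and y* on the test side; its standard error across
replicates is SD/sqrt(reps); MSE is the mean squared difference. Method
agreement is summarized on test GEBVs pooled over replicates: pairwise
Spearman correlations and the top-decile coincidence
(`|top-k(a) & top-k(b)| / k`, `k = ceil(0.1 n)`, ties broken by stable index
order). Gains are reported as the plain percentage ratio of mean PAs against
GBLUP. Reports serialize deterministically: rerunning the pipeline from one
master seed reproduces the CSVs byte for byte.

## Synthetic trial generator

The generator emulates a perennial progeny trial: two pools of three founders
are crossed into 13 full-sib families of 15 (195 individuals), genotyped at
biallelic SNPs placed on 11 chromosomes of 100 cM with founder alt-allele
frequencies uniform in [0.05, 0.5]. Meiosis uses Haldane's map function (no
interference). QTL effects are drawn from standard normals for additive,
dominance (heterozygosity-coded) and pairwise additive-by-additive epistatic
(product-coded) components, then rescaled so the realized variance shares
match the configuration exactly. Phenotypes follow the analysis model above:
fixed year means drawn once (grand mean 10, year SD 1), plot membership
assigned once at planting (15 plots), progenies alternated over two
population labels, and every random term drawn from a centered normal. When
a target heritability is given instead of explicit components, the
non-genetic denominator budget is split 15/5/20/60 percent among permanent-
environment, population, year-by-progeny and residual variance, with a plot
variance of 5 percent of the phenotypic total (plot is outside the h2
denominator). A second generator draws records directly from the
variance-component model (progeny effects as normal draws rather than from
markers); it is the oracle for REML recovery checks.

Two heritability-like quantities coexist and should not be conflated. The
generator's `target_h2` is an *individual-level genomic* ratio: the variance
of true genetic values over the per-record phenotypic variance, matched
exactly by construction. The analysis model's heritability uses the
*between-progeny* variance as its numerator, so it sits well below the
genomic target whenever much of the genetic variance is within-family —
which is pronounced here because the families descend from only six
founders (several families even share both parents) and because epistatic
variance transmits to the family mean only fractionally. REML recovery
checks therefore use the component-level generator, where the progeny
variance is drawn directly and the estimand matches the estimator.

What the generator does *not* emulate: genotyping error, linkage
disequilibrium inherited from a deep founder history (founders are drawn at
linkage equilibrium), selection across generations, spatial field trends,
and the check-variety structure of augmented block designs (a generic plot
effect stands in). Passing tests therefore demonstrate correctness of the
machinery and the qualitative behavior of the methods on family-structured
data, not calibration to any particular real crop dataset.

## Numerical choices and scale

Kernel diagonals get a 1e-8 ridge before inversion; kinship matrices are
validated symmetric to 1e-10 and PSD to -1e-8. The QRF CDF threshold uses a
1e-12 slack when locating `F >= tau`. Forward-pass MARS stops when the RSS
reduction falls below 1e-10. Variance components are floored at 1e-10.
Master seeds spawn independent named child streams per stage (population,
effects, trials, splits, folds, learners), so stages can be re-run in
isolation and everything is bitwise reproducible.

The bundled experiment configurations (acceptance script and end-to-end
tests) run the 195 x 500 design with 300 trees per forest and 10 holdout
replicates — sizes chosen so a complete run finishes in a few minutes on one
CPU while leaving the library defaults (500 trees) untouched.

## Known limitations

REML heritability ratios carry a small Jensen-type downward bias (about
0.01-0.02 at these design sizes) because the ratio of nearly unbiased
variance estimates is not itself unbiased; variance terms with very few
levels (e.g. a 2-level population factor) are boundary-truncated and can
absorb progeny variance. The SWR weight normalization after non-negative
least squares is a convention, not an optimum. Exhaustive split search on
dosage data considers at most two thresholds per marker, so forests are
fast but cannot exploit within-genotype dosage gradations. The stacking
shuffle-invariance of metrics holds exactly for deterministic learners only;
bootstrap-based learners depend on row order through their resampling
streams.
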