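# Methods

## Problem and model

A turtle's shell shape is summarised by K homologous 3D landmarks per
specimen.  Ontogenetic series of many species, each spanning a broad range
of straight carapace lengths (SCL), are analysed jointly: the package asks
at what fraction of a species' maximum recorded SCL the shell stops
changing shape in any practically relevant way, so that comparative studies
can subsample "adult" specimens with a single size rule.

The underlying model is classical ontogenetic allometry: within a species,
shape moves along an approximately one-dimensional trajectory in shape
space as size increases, fast in juveniles and flattening toward an adult
asymptote.  The trajectory score is extracted from the data (CAC or
multivariate shape, below); its dependence on SCL is modelled as a Gompertz
curve because shape change, like somatic growth, decelerates
asymmetrically — rapid early change, long slow approach to a plateau.

## Superimposition and ordination

Generalized Procrustes analysis follows the classic Gower/Rohlf–Slice
scheme: centre each configuration, scale to unit centroid size, and
iteratively rotate all configurations to the running mean, which is itself
re-centred and rescaled to unit size each round.  Convergence is the root
mean squared change of the consensus coordinates falling below 1e-8
(maximum 100 iterations).  Rotations come from the SVD of the
cross-covariance matrix with the determinant forced positive: reflections
are never allowed, because the left/right anatomical identity of shell
landmarks is meaningful.  Degenerate configurations (zero centroid size)
are rejected at input validation.

Aligned shapes are orthogonally projected onto the tangent hyperplane at
the consensus before PCA and before all downstream shape-space operations
(`tangent=True` throughout; a flag disables it for sensitivity checks).
At the shape distances observed here the projection is nearly inert, but
it makes the Euclidean geometry of the ordination exact.  PCA is a plain
SVD of the centred flattened shapes with n−1 variance denominators; after
GPA and projection at most 3K − 7 non-trivial axes remain.

## Allometric regression and trajectory scores

Shape-on-size models use log₁₀ centroid size as the predictor.  The F
statistic pools sums of squares across all coordinates
(F = (SS_model/df_model)/(SS_res/df_res)).  Inference is by residual
randomization (RRPP): residuals of the reduced model are permuted across
specimens and added back to the reduced fitted values.  For the
single-predictor model the reduced model is the intercept, which makes the
permutation equivalent to shuffling the predictor.  The permutation count
defaults to 999 (p resolution 0.001); passing `n_perm=None` enumerates all
n! orderings, which is exact and feasible for n ≤ 8.  The effect size is
Z = (ln F_obs − mean(ln F_perm))/sd(ln F_perm), computed over the permuted
distribution; conventions that pool the observed value into the
distribution shift Z by a small amount and are not used here.

The shape ~ size + sex model evaluates terms sequentially (type-I):
the size term against the intercept-only reduced model, the sex term
against the size-only model, each with its own residual randomization and
the full-model residual in the F denominator.  Unknown-sex specimens are
excluded from sex models (with a warning) but retained everywhere else;
both sexes must keep at least two specimens.

Two one-dimensional trajectory scores are provided:

* **CAC** — axis ∝ Yᶜᵀsᶜ/(sᶜᵀsᶜ) normalised to unit length (Yᶜ centred
  flattened shapes, sᶜ centred log size); scores are Yᶜ·axis.
* **Multivariate shape (PredLine)** — PC1 scores of the model's fitted
  shape values.

Both are sign-oriented so they correlate non-negatively with size, making
growth curves rise.  Note an intrinsic asymmetry: PredLine scores are by
construction an affine function of the model's predictor (log centroid
size), so their curve against SCL inherits the log-shaped size geometry
and plateaus less sharply than CAC, which projects the *actual* shapes and
preserves any nonlinearity of shape in size.  On synthetic data with a
planted sigmoid trajectory the CAC-based threshold is therefore the
estimator that recovers the truth; the multivariate-shape threshold runs
systematically later.  The same qualitative asymmetry (better plateauing of
CAC-based curves) is expected, and reported, for real shells.

## Growth curves and adult-size thresholds

The Gompertz curve f(x) = c + (d − c)·exp(−exp(−k(x − x₀))) is fitted by
Levenberg–Marquardt least squares with a free lower plateau c (trajectory
scores can be negative; `fix_lower` pins c = 0).  Self-start values:
c₀ = min score, d₀ = max score, x₀₀ = the SCL midpoint of the steepest
finite-difference slope between size-ordered neighbours, and
k₀ = e/IQR(SCL) (at the inflection the slope is k(d−c)/e, so the range
covered over one interquartile spread fixes the scale).  Eight starts (the
self-start plus seven seeded jitters) are tried and the lowest-RSS
converged fit wins; fits whose covariance is non-finite, whose RSS exceeds
the null (constant-mean) RSS, or whose rate is negative are flagged
`converged=False` and propagated, never silently dropped.

**Asymptote threshold.**  With L = d − z·SE(d) the lower bound of the
two-sided `ci_level` (default 90%) Wald interval on the asymptote, the
crossing SCL is the closed form x = x₀ − (1/k)·ln(−ln((L − c)/(d − c))).
No threshold is reported when L ≤ c, L ≥ d, or SE(d) is not finite — the
curve shows no usable plateau.

**85%-distance threshold.**  Scores are predicted at 1000 evenly spaced
SCL values from the smallest sampled specimen to the species' largest
recorded size; shapes are predicted from scores by linear shape-on-score
regression; and the threshold is the smallest grid SCL at which the
Procrustes distance from the smallest predicted shape reaches 85% of its
final value.  The distance profile is monotonised by running maximum first
so numerical noise cannot create spurious early crossings.  The trajectory
regression of score on SCL is **Gompertz by default**: a straight-line
trajectory would make the distance profile linear in SCL and force every
threshold to min + 0.85·(max − min) ≈ 86–88% of maximum SCL regardless of
the data, which contradicts both the observed 55–75% range and the purpose
of the statistic.  The linear variant remains available
(`trajectory="linear"`) for sensitivity analysis.

Thresholds are reported as percentages of the maximum recorded SCL per
sex.  Strong sexual size dimorphism is a user-supplied per-species flag
(with the larger sampled sex named), not auto-detected; when absent, the
species record (the larger of the two sexes' maxima) is the headline
denominator.

## Stages and disparity

Within each species the trajectory score and SCL are standardised to zero
mean and unit variance (SCL in mm would otherwise dominate), and
Ward-linkage hierarchical clustering on the pairwise Euclidean distances is
cut at k = 3; clusters are labelled 'small', 'intermediate', 'large' by
ascending mean SCL.  Standardisation and linkage are config-exposed since
other defensible readings exist.

Pooled across species, two disparity metrics are compared across stages:
sum of ranges (SoR) over all pooled PC axes, and Procrustes variance (mean
squared distance of group members to the group mean shape).  Groups are
bootstrapped (default 1000 replicates, 95% percentile CIs); SoR is also
rarefied to the smallest stage's n, because range statistics grow with
sample size and the stages are unequal.  Pairwise stage differences use an
overlapping-confidence-interval z statistic: each CI's half-width is read
as z·SE, and the statistic is |m_a − m_b|/√(SE_a² + SE_b²) with a
two-sided normal p; values above 1.96 indicate non-overlapping 95% CIs.
The original Zou (2007) asymmetric overlap construction is available
behind `method="zou2007"`; the two agree exactly for symmetric bootstrap
CIs.  P-values are Bonferroni-adjusted over the three pairs per metric.

## Synthetic data: what it emulates and what it does not

Each synthetic species is a 20-landmark half-ellipsoid carapace (rim +
dome points; landmark 1 anteriormost, landmark 12 posteriormost, so SCL
can be measured between them).  A specimen of size x has flattened shape
base + g(x)·a + sex terms + ε, where g is a Gompertz function of SCL, a is
a unit deformation axis, and ε is isotropic Gaussian noise
(`noise_sd = 0.005` per coordinate by default, i.e. a few percent of the
0.12 Procrustes-unit ontogenetic change — chosen as realistic digitising +
individual variation for shells).  The axis is constructed orthogonal to
the translation, rotation and scaling directions at the base shape, so the
random digitising transform applied afterwards (rotation, translation, and
scale fixed so the landmark-1-to-12 distance equals the specimen's SCL) is
removed exactly by GPA.  The default axis stretches the shell
anteroposteriorly and narrows it transversely, the dominant real trend;
panel species blend this common axis with fixed species-specific
components so juveniles are similar across species while adults diverge.
Default sampling is 25 specimens per species drawn uniformly over the SCL
range (a size-biased sampler mimicking museum collections is available),
with optional sexual size dimorphism (a female size shift) decoupled from
shape dimorphism (an explicit shape offset).

The generator's Gompertz makes every species' 85%-distance threshold
solvable in closed form, giving exact ground truth.  What passing recovery
tests do **not** show: real shells deform nonlinearly (not along one fixed
axis), landmark noise is anisotropic and landmark-specific, species share
phylogenetic covariance, and real size sampling is far patchier — so
recovery accuracy on synthetic panels is an upper bound on real-data
accuracy, not an estimate of it.

One geometric subtlety: because aligned shapes live on the unit
centroid-size sphere, the generator's linear deformation appears very
slightly compressed after superimposition (relative distortion ≤ g²/2
≈ 1%).  Zero-noise threshold recovery is therefore exact only to about two
grid steps (≈ 0.5 mm at default resolution) rather than one.

## Problem sizes and reproducibility

The shipped analysis and the acceptance script use a 10-species panel with
25 specimens each (planted thresholds 55–75% of maximum SCL), 999
permutations and 1000 bootstrap replicates — ample resolution for every
statistic reported while keeping a full run in the seconds range.  All
randomness flows from one seed through per-species, per-stage independent
streams keyed by species name, so adding or removing a species never
perturbs another species' permutations, and reruns are bit-identical.

## Known limitations

* Only the Gompertz growth family is implemented; species whose shape
  change does not decelerate are flagged by non-convergent or
  plateau-free fits rather than fitted with an alternative model.
* Wald CIs on the asymptote can be optimistic for poorly constrained fits;
  profile-likelihood intervals are out of scope.
* Sliding semilandmarks, missing-landmark estimation and phylogenetic
  corrections are out of scope; the landmark scheme is fixed points only.
* The stage clustering is per-species and two-variable by design; it is a
  device for pooling ontogenetic classes, not a general stage classifier.
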