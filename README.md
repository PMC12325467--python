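# shellont — ontogenetic shell-shape analysis

Turtle shells change shape as they grow: hatchlings are rounded, adults are
relatively longer and narrower, and species-specific features appear during
post-natal growth.  Comparative morphometric studies therefore need a
defensible rule for deciding when a museum specimen's shell can be treated
as "adult".  `shellont` implements a complete pipeline for deriving such a
rule from 3D landmark data: given landmark configurations and straight
carapace lengths (SCL) for growth series of many species, it estimates each
species' allometric shape trajectory, fits a growth curve to the trajectory
score, and reports the minimum SCL — as a percentage of the species'
maximum recorded SCL — at which the shell has effectively reached adult
shape.  It is written for evolutionary morphologists working with geometric
morphometric data, but every stage is a plain function over numpy arrays.

## Method

1. **Superimposition.** All specimens enter one generalized Procrustes
   analysis (GPA): configurations are centred, scaled to unit centroid size
   CS = √Σᵢ‖xᵢ − x̄‖², and iteratively rotated (proper rotations only) to
   the consensus.  Aligned shapes are orthogonally projected into the
   tangent space at the consensus before ordination.
2. **Allometry.** Per species, flattened shape Y is regressed on
   log₁₀ CS.  Significance uses residual randomization in a permutation
   procedure (RRPP): p = (1 + #{F* ≥ F}) / (1 + n_perm) and effect size
   Z = (ln F − mean ln F*) / sd ln F*.  Two one-dimensional trajectory
   scores are extracted: the **common allometric component**
   (CAC ∝ Yᶜᵀ sᶜ, the unit direction of size-associated shape change) and
   **multivariate shape** (PC1 of the model's fitted values, the PredLine
   construction).  A shape ~ size + sex model quantifies sexual shape
   dimorphism where both sexes are sampled.
3. **Shape-growth curves.** Each proxy score is fitted against SCL with a
   Gompertz curve f(x) = c + (d − c)·exp(−exp(−k(x − x₀))) by multi-start
   nonlinear least squares.
4. **Adult-size thresholds.** (a) the SCL where f(x) crosses the lower 90%
   Wald bound of the asymptote d, via the closed form
   x = x₀ − (1/k)·ln(−ln((L − c)/(d − c))); (b) the SCL at which the
   predicted shape covers 85% of the Procrustes distance between the
   smallest specimen's shape and the shape predicted at the largest
   recorded SCL.  Both are reported as % of maximum recorded SCL per sex.
5. **Stages and disparity.** Ward clustering of the standardised (score,
   SCL) pairs defines 'small', 'intermediate' and 'large' stages per
   species; pooled stage disparity is measured as the sum of ranges over PC
   axes (bootstrapped and rarefied) and as Procrustes variance, with
   pairwise overlapping-confidence-interval z tests, Bonferroni-adjusted.

Because suitable multi-species growth series are rare, the package ships a
synthetic-data module: schematic 20-landmark shells deforming along
species-specific axes by a Gompertz function of SCL, with every species'
true threshold known in closed form.

## Worked example

```bash
python analysis/01_simulate_panel.py     # writes results/panel/
python analysis/02_allometry.py
python analysis/03_growth_thresholds.py
python analysis/04_stages_disparity.py
```

The first script plants ten species whose true adult-size thresholds span
55–75% of maximum SCL.  The remaining drivers print, for seed 1:

```
allometric regressions: 10/10 species significant at 0.05
R2 range 0.44-0.61, Z range 5.42-6.24
sex models (10 species): median Z(size) 5.74 vs median Z(sex) -0.03
...
median absolute recovery error: 2.04 points
summary [cac]: median 67.0% (range 56.5-74.2%)
summary [multivariate]: median 72.5% (range 70.1-78.1%)
...
  sor small-large              7.96  p=5.12e-15 *
  pv  small-large             23.63  p=5.19e-123 *
```

Every species' shape change with size is detected; the per-species
85%-distance thresholds recover the planted truths with ~2 percentage
points median error; and pooled disparity rises from the 'small' to the
'large' stage with non-overlapping bootstrap CIs — juvenile shells are more
similar to each other than adult shells are.

The same pipeline runs on real data from a YAML config
(`shellont run --config cfg.yaml`); see `shellont --help` and
`PipelineConfig` for the file formats (TPS or long CSV landmarks, metadata
TSV with specimen_id/species/sex/scl_mm, and a per-species maximum-SCL
table).

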