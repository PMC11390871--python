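# Methods

## Within-pair proximity scores

The score for a twin pair in one data domain is a Gaussian-kernel
similarity, `K(x_i, x_j) = exp(−D(x_i, x_j) / 2σ²)`, of a distance
computed in principal-component space. After the domain matrix is
standardized (each feature mean 0, sd 1), a full-rank PCA is fitted on
all individuals pooled — co-twins of both zygosities together, the only
choice that puts MZ and DZ scores on one scale. With ω_k the fraction of
inertia carried by component k, each component is scaled to unit
variance and the pair distance is `D = Σ_k ω_k Δ_k²` over the scaled
component differences Δ_k (weighted Manhattan variant `Σ_k ω_k |Δ_k|`).
σ defaults to 1.

**Rank deficiency.** When p ≥ n, at most n − 1 components carry
variance; the scorer retains all positive-variance components
(components with variance below 1e−12 of total inertia are dropped as
numerical noise) and renormalizes ω over them, preserving Σω = 1 over
100% of realized inertia.

**Algebraic identity.** Because PCA is an orthogonal rotation of the
centered data and the ω-weighting exactly cancels the per-component
scaling (`ω_k / λ_k = 1/Σλ`), the squared-Euclidean form of D reduces to
`‖z_i − z_j‖² / Σλ`: the squared Euclidean distance between the
standardized feature rows divided by the total inertia. The PCA route is
therefore a normalized Euclidean distance in disguise and, contrary to
the intuition that the rotation de-weights correlated features, cannot
down-weight redundant information beyond what the global normalization
already does. The package implements the stated sequential procedure
verbatim, exposes the closed form as `oracle_distance`, and enforces
their agreement (within 1e−10) as a property test. Users who want true
redundancy control should consider a truncated PCA or a Mahalanobis
kernel, both out of scope here.

**Identity detection.** A score of exactly 1 is assigned iff the two
preprocessed rows are identical under exact comparison (`identity_tol=0`
by default). Identical rows arise structurally — co-resident pairs share
one household geocode record — not by floating-point coincidence, so a
tolerance would only blur the sensitivity analyses that key on score = 1.
A tolerance override exists for data where near-duplicates are expected.

## Preprocessing

Recipes by domain (configurable): proteome — missingness filter →
minimum imputation → standardize; metabolome — the same plus an
inverse-normal rank transform before standardization; epigenetic age
acceleration (EAA) and external exposome — standardize only.

* Features with **more than 10%** missing values are excluded (fraction
  strictly greater than the threshold; ties retained).
* Missing cells are imputed by the feature's **observed minimum**
  (left-censored intensity data convention).
* The **inverse-normal transform** uses the Blom offset:
  `Φ⁻¹((r − 3/8)/(n + 1/4))` with average ranks for ties. Ranks are
  sample-relative, so the transformer recomputes them on the data it is
  applied to.
* Standardization uses the sample sd (divisor n − 1) throughout,
  including the PC scaling inside the scorer; constant features raise an
  error naming the feature.
* The **PC outlier screen** flags individuals whose standardized score
  on any of the first 3 components exceeds 5 sd in absolute value
  (defaults as commonly used for omics QC).
* **EAA** is defined as the residual of epigenetic age regressed on
  chronological age (OLS with intercept) — the standard direction, in
  which a constant clock offset is absorbed and residuals average zero.
  The literature occasionally words this with the variables swapped;
  the swapped regression yields residuals in years-of-chronological-age
  and breaks the acceleration interpretation, so it is not offered.
* **Lifestyle dichotomization** maps frequency categories to 0
  (≤ once a month) or 1 (≥ once a week). Categories strictly between the
  two modalities (e.g. 2–3 times a month) default to missing because the
  two printed modalities do not cover them; a `gap` switch forces them
  low or high for sensitivity. The category map is user-replaceable
  since ordinal scales differ across questionnaires.
* **Discordance** per pair and variable is the XOR of the two binary
  responses; any missing co-twin response makes the pair missing.

## Association layers

All models are OLS with intercept and classical t inference.

* **Covariate models**: each domain's WPPS on zygosity (MZ = 1), sex
  (F = 1) and the pair's age at separation from the familial home,
  jointly; pairs missing the separation age are dropped per model.
* **Cross-domain models**: for each of the 6 domain pairs, the
  higher-priority domain (exposome → EAA → proteome → metabolome) is the
  dependent variable; the absolute within-pair difference in age at
  blood sampling is the covariate (absolute value because the score is
  symmetric in twin order); fitted on pairs with both scores present,
  skipped below 10 overlapping pairs.
* **Zygosity comparison**: both scores are standardized to mean 0, sd 1
  within each zygosity subsample, the model refitted per subsample, and
  `z = (bMZ − bDZ)/√(seMZ² + seDZ²)` tested one-sided
  (`p = 1 − Φ(z)`); genetic effects can only inflate the MZ slope. This
  is the standard equality-of-coefficients z-test; standardization makes
  the comparison scale-free (verified by a property test).
* **ExWAS**: each domain's WPPS on each binary discordance indicator
  plus the age-difference covariate; variables with fewer than 2
  discordant or 2 concordant pairs are skipped. BH-FDR is applied within
  each domain's family of 14 tests (the natural family given each
  domain is interpreted separately); a `pooled` mode corrects across all
  56 at once. Discoveries are flagged at q < 0.2, the conventional
  screening threshold for exposome scans.

## Sensitivity analyses

The exposome score distribution is left-skewed with a point mass at 1,
which strains linear modeling. Two reruns: (1) remap scores linearly
from the theoretical range [0, 1] onto [0.025, 0.975] and apply the
logit — the source interval is fixed at [0, 1] rather than the observed
range so the transform is dataset-independent and a score of 1 lands
exactly on 0.975 (logit ≈ 3.66); an observed-range mode exists behind a
flag; (2) exclude pairs with an exposome score of exactly 1 from all
analyses including that domain.

## Synthetic cohort generator

Defaults emulate a young-adult same-sex twin cohort: 257 pairs
(140 MZ / 117 DZ, 63% female), blood-sampling age 22.3 ± 0.6 years with
co-twins sampled the same day three quarters of the time (otherwise up
to 160 days apart, mean gap ≈ 20 days over all pairs), co-residence
probability 0.32, and four domains of 439 / 140 / 8 / 65 features.

Per domain, q latent factors per individual follow the ACE
decomposition `F = a·A + c·C + e·E` with C shared within pair, A shared
exactly for MZ and with correlation 0.5 for DZ
(`A₂ = 0.5 A₁ + √0.75 A′`, the exact half-sharing construction), and E
independent — giving within-pair latent correlations a² + c² (MZ) and
0.5 a² + c² (DZ), the closed forms the recovery tests check. Features
are unit-variance linear mixtures of the factors plus independent
feature noise. Omics domains default to a² = 0.5, c² = 0.2, e² = 0.3
with q = 10/8/3 factors; the exposome is purely environmental
(a² = 0, c² = 0.6, e² = 0.4, q = 3, 5% noise) and co-resident pairs
receive byte-identical exposome rows. The small factor counts are
deliberate: score spread is governed by the effective dimension, and
q = 3–10 reproduces the wide, left-skewed score distributions real
domains show (synthetic exposome: mean ≈ 0.78, sd ≈ 0.22, skew ≈ −0.6,
~80/250 pairs at 1), whereas hundreds of independent dimensions would
concentrate every pair's score.

Lifestyle items are generated directly at the dichotomized (binary)
level; discordance for variable v is Bernoulli with
`logit p = logit(baseline) + Σ_d β_{v,d} z_d`, where z_d is the pair's
standardized within-pair Euclidean distance in domain d. Default
baselines (0.20–0.30) match discordant-pair counts of roughly 42–94 per
257 pairs; substance-use items couple positively to exposome distance
(strongest: drinking to intoxication, β = 0.6), reproducing a negative
score–discordance association of realistic size. Co-resident pairs'
separation age is censored at the sampling age; 5% of other pairs have
it missing. All randomness flows from one `numpy` Generator seeded by
the config, so identical seeds give bit-identical cohorts.

What the generator does **not** emulate: raw acquisition artifacts
(batch effects, detection limits — missingness enters only through the
preprocessing tests' own constructions), cross-domain latent coupling
(domains are generated independently; couplings exist only through
zygosity, co-residence and the lifestyle logit), population
stratification, opposite-sex pairs, and real exposure geographies.
Passing recovery tests therefore demonstrates that the pipeline
measures what was planted under the stated structure, not that real
data meet that structure.

## Test and calibration problem sizes

Recovery and calibration checks run on scaled-down cohorts chosen to
keep Monte-Carlo error well below the tested margins: ACE recovery uses
100 replicates of a 250-pair, 60-feature domain; the ExWAS recovery
plants a score-scale slope of −0.15 (the magnitude of the strongest
reported lifestyle association in cohorts of this type) in 100
replicates of a 250-pair exposome domain, where the two-group design
gives that slope a z of ≈ 5 and q < 0.2 detection with high
probability; the full-null family rate uses 400 domain-families; null
calibration of the cross-domain t-test uses 1000 replicates of two
independent, purely environmental (a² = 0) domains — with a² > 0 the
zygosity mixture is a genuine common cause of two domains' scores, so
the full null requires no additive-genetic component. Closed-form ACE
correlations are verified at 2000 pairs within 3 Monte-Carlo standard
errors.

## Pipeline configuration

`PipelineConfig` / YAML keys: `out_dir`, `data_dir` or `simulate` +
`seed`, `sigma`, `metric`, `max_missing`, `priority`, `fdr_family`
(`per-domain`/`pooled`), `q_threshold`, `recipes` (domain → step list),
`sensitivity_logit`, `sensitivity_exclude_unity`, `unity_domain`,
covariate codings (`zygosity_code`, `sex_code`, echoed in the run log).
The run log records the seed, the full config, and per-stage pair and
feature counts so complete-case attrition per domain is auditable. CLI
exit codes: 0 success, 2 configuration error, 3 data error.

## Known limitations

* The PCA-weighted distance is algebraically a normalized Euclidean
  distance (see above); the Manhattan variant applies the same ω weights
  to |Δ_k|, a weighted form chosen here since no canonical weighting
  exists for it.
* Classical OLS inference treats pairs as independent units (they are)
  but scores bounded in (0, 1] make residuals non-normal; calibration
  holds at n ≈ 250 by the CLT, and the logit sensitivity rerun guards
  the worst case.
* The generator's cross-domain independence means cross-domain
  regression recovery is exercised with directly constructed score
  vectors rather than through a planted inter-domain latent channel.
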