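# twinprox

Within-pair proximity scores (WPPS) for twin cohorts: a Gaussian-kernel
similarity that collapses a high-dimensional data domain (plasma
proteome, plasma metabolome, epigenetic age acceleration, external
exposome) into one number per twin pair describing how alike the two
co-twins are, plus the downstream inference that makes the score
useful — zygosity and covariate models, cross-domain similarity
regressions with MZ/DZ comparison, and an exposome-wide association
study (ExWAS) of within-pair lifestyle discordance.

It is aimed at twin-study and exposome researchers who want a
"whole-dataset" view of co-twin resemblance where classical univariate
twin correlations do not scale, and at methodologists who want a fully
synthetic, structurally faithful twin cohort to test such pipelines on.

## The score

For a domain with p standardized features:

1. a full-rank PCA is fitted on all individuals; ω_k denotes the
   fraction of total inertia (variance) carried by component k, with
   Σ_k ω_k = 1;
2. each component is scaled to unit variance;
3. the distance between co-twins i and j is
   D(x_i, x_j) = Σ_k ω_k [PC_k(x_i) − PC_k(x_j)]²
   (a weighted Manhattan variant Σ_k ω_k |Δ_k| is also available);
4. the score is the Gaussian kernel K(x_i, x_j) = exp(−D / 2σ²) with
   σ = 1.

Scores lie in (0, 1]; a score of 1 marks co-twins with identical
preprocessed rows (e.g. co-resident twins sharing one household
geocode record). A pair whose squared scaled-PC differences average one
standard deviation has a score below exp(−1/2) ≈ 0.61.

Downstream, each domain's WPPS is regressed on zygosity, sex and the
pair's age at separation; domain pairs are regressed on one another
(dependent variable chosen by the priority exposome → EAA → proteome →
metabolome, adjusting for the co-twins' age difference at sampling),
with zygosity-stratified standardized slopes compared by a one-sided
z-test for bMZ > bDZ; and each domain's WPPS is tested against 14
binary lifestyle-discordance indicators with Benjamini–Hochberg FDR
per domain (q < 0.2 flagged).

## Worked example

```python
from twinprox import (
    default_config, simulate_cohort, compute_wpps, pivot_wpps,
    build_discordance_table, exwas, standardize_features,
)

cohort = simulate_cohort(default_config(seed=3))      # 257 pairs, 140 MZ / 117 DZ
mat = standardize_features(cohort.domains["exposome"])
wpps = compute_wpps(mat, cohort.pairs, domain="exposome")
print(wpps["wpps"].mean().round(3), (wpps["wpps"] == 1).sum())

disc = build_discordance_table(cohort.lifestyle, cohort.pairs)
res = exwas(pivot_wpps(wpps), disc, cohort.pairs)
hit = res[res["independent"] == "drinking_to_intoxication"].iloc[0]
print(hit["estimate"].round(3), hit["q_fdr"].round(6))
```

prints

```
0.779 93
-0.145 1e-05
```

— the synthetic exposome WPPS averages 0.78 with 93 pairs at exactly 1
(co-resident pairs), and twin pairs discordant for frequent drinking to
intoxication have exposome scores lower by 0.145 on average, a
discovery at q ≪ 0.2.

The same analysis end-to-end, from a shell:

```bash
wpps simulate --seed 3 --out data/
wpps run --config pipeline.yaml        # see docs/methods.md for keys
```

## Layout

- `twinprox.simulate` — ACE-structured synthetic twin-cohort generator
- `twinprox.prep` — preprocessing transformers (sklearn-compatible) and
  lifestyle discordance coding
- `twinprox.wpps` — `WPPSScorer` and the kernel/distance primitives
- `twinprox.association` — covariate, cross-domain, z-test and ExWAS layers
- `twinprox.sensitivity` — logit remap and unity-pair exclusion
- `twinprox.pipeline` / `twinprox.cli` — end-to-end driver and `wpps` CLI

See `docs/methods.md` for the model, parameter defaults, numerical
choices and known limitations.
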