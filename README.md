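# crabflow

Crop-to-wild introgression and spatial genetic structure analysis for
codominant (microsatellite-style) genotypes, exercised end to end on a
synthetic data generator with known truth.

The package covers the full landscape-genetics workflow:

- **`crabflow.genio`** — GENEPOP read/write (2/3-digit encodings, `0` =
  missing), metadata/landscape/visitor CSVs, per-individual missingness
  filtering (strict `< 20%` retained by default).
- **`crabflow.synth`** — F-model gene pools (K wild clusters + 1 crop pool),
  pure/hybrid genotype sampling with per-gamete ancestry, a spatially explicit
  pedigree with Gaussian pollen/seed dispersal (produces isolation by
  distance), correlated landscape covariates with covariate-linked
  introgression probabilities, and order-structured flower-visitor records.
- **`crabflow.admixture`** — Gibbs sampler for the admixture model (latent
  source clusters per gene copy, conjugate Dirichlet updates for cluster
  frequencies and ancestry), deviance-based model evidence, the
  second-difference (delta-K) table over replicate runs, label-switching
  alignment (exact for K ≤ 8, greedy otherwise), and consensus memberships.
- **`crabflow.introgression`** — cumulative wild membership, 0.9/0.1 threshold
  classification (pure wild / hybrid / misidentified crop), both introgression
  rate variants (hybrid fraction and mean crop ancestry), and 0.55-threshold
  population assignment.
- **`crabflow.diversity`** — observed/unbiased expected heterozygosity,
  Weir–Cockerham F-statistics (ratio of summed variance components) with
  permutation p-values, a one-sided heterozygote-deficit permutation test, and
  rarefaction-standardized allelic and private allelic richness.
- **`crabflow.spatial`** — Loiselle pairwise kinship, kinship-vs-ln(distance)
  regression with a coordinate-permutation test, and the Sp statistic
  `-b / (1 - F_N)`.
- **`crabflow.landscape`** — quasi-Poisson GLMs by IRLS with sequential
  analysis-of-deviance F-tests; the three study models (orchard number /
  orchard area x apple density on introgression; management intensity +
  insect order on visitor diversity).
- **`crabflow.pipeline`** — one-config orchestration
  (simulate → validate → admix → classify → diversity → sgs → glm) with a
  schema-validated CSV/JSON report and a hash manifest; deterministic under a
  fixed seed.

## CLI

```sh
crabflow simulate --config pipeline.yaml --out data/ --seed 1
crabflow validate data/genotypes.gen --meta data/metadata.csv
crabflow admix data/genotypes.gen --k-range 2..8 --replicates 10 \
    --sweeps 2000 --burnin 500 --seed 1 --out admix/
crabflow classify admix/q_K6.csv --wild-clusters 1,2,3,4,5 \
    --meta data/metadata.csv --out classified/
crabflow diversity data/genotypes.gen --meta data/metadata.csv --out div/
crabflow sgs data/genotypes.gen --meta data/metadata.csv --max-d 10 \
    --perms 9999 --seed 1 --out sgs/
crabflow glm --model 3 --visitors data/visitors.csv --granularity taxa --out glm/
crabflow run --config pipeline.yaml --out report/ --seed 1
```

`crabflow run` accepts a YAML config; every field of
`crabflow.pipeline.PipelineConfig` (and a nested `simulation:` section for
`SimulationConfig`) can be set there. Exit codes: 0 ok, 2 validation error,
3 inference error.

## Notes

- Thresholds follow the strict-inequality convention: pure wild `w > 0.9`,
  misidentified crop `w < 0.1`, boundary values go to hybrid.
- Threshold classification uses the posterior mean assignment fraction
  (`AdmixtureFit.Z_fraction`) rather than the Dirichlet-smoothed `Q`; the
  latter is biased toward the prior for backcross-level ancestry.
- The expected-heterozygosity estimator uses Nei's unbiased small-sample
  correction; multilocus heterozygosity/richness are unweighted means over
  loci while F-statistics are ratios of summed variance components.
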