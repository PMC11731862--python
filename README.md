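# lookalike

Data fusion of two independent person/incident-level datasets — a
population survey and an administrative service dataset — treated as a
missing-data problem. The recipient dataset's missing variable(s) are
mass-imputed from the donor via chained-equations multiple imputation over a
harmonized "comparison vector" of shared covariates, producing a combined
synthetic dataset. Validation regressions (OLS / logistic / negative
binomial), Rubin's-rules pooling, count-family selection, and
donor-vs-synthetic concordance reporting are built in.

Because the real survey and service datasets are access-restricted, the
package ships a seeded synthetic generator with two profiles —
`csew` (survey-like, n = 1,232) and `rcew` (service-like, n = 6,102) —
parameterized from the published marginal tables, so every stage is testable
offline.

## Layout

- `lookalike.harmonization` — declarative recode rules onto a shared typed
  schema, drop-code and minimum-age filters, complete-case selection.
- `lookalike.synthetic` — population profiles (categorical marginals,
  truncated-normal age, moment-matched negative-binomial dependant counts),
  outcome models (gaussian / bernoulli / overdispersed count), fusion
  scenarios with truth records.
- `lookalike.mice` — chained-equations imputation with proper parameter
  draws per family (`bayes_linear`, `logistic`, `multinomial`, `pmm`,
  `negbin_draw`), chain diagnostics.
- `lookalike.fusion` — stack recipient + donor, mass-impute the donor-only
  targets, return m synthetic copies of the recipient.
- `lookalike.inference` — OLS / logistic / NB2 regressions,
  Poisson-vs-negbin selection on AIC/BIC, Rubin pooling with Barnard–Rubin
  degrees of freedom.
- `lookalike.reporting` / `lookalike.pipeline` / `lookalike.cli` —
  three-column comparison tables, concordance metrics, end-to-end runs.

## CLI

```sh
# draw a synthetic population
lookalike simulate --profile rcew --n 6102 --seed 1 --out scratch/rcew

# recode a raw CSV onto the shared schema (default packaged rules)
lookalike harmonize --data raw.csv --out scratch/harmonized

# mass-impute donor-only variables into a recipient
lookalike fuse --recipient scratch/A --donor scratch/B \
    --config fusion.yaml --out scratch/fused --seed 7

# fit one regression
lookalike analyze --data scratch/fused --outcome age --family ols \
    --predictors sv_type,gender --out scratch/fit.json

# full validation exercise on the shipped profiles (mask -> fuse -> fit ->
# pool -> compare); targets: age, gender, health_impact, frequency
lookalike replicate-paper --target age --seed 1 --out scratch/replication

# re-run any pipeline bit-identically from its manifest
lookalike rerun --manifest scratch/replication/manifest.json --out scratch/again
```

`replicate-paper --direction-swapped` exchanges donor and recipient roles
(the robustness exercise); the fused output then has the survey-like size.

## Notes

- Every generator and imputation routine is deterministic in its seed;
  independent RNG sub-streams are spawned per imputation.
- Categorical marginals in `src/lookalike/config/profiles.yaml` are the
  published percentages; the loader renormalizes. Age is drawn from a
  left-truncated (≥ 16) normal whose parent parameters are calibrated so the
  realized truncated moments match the published mean/SD.
- Pooled total variance is W + (1 + 1/m)·B; significance stars are
  `*** p<0.001`, `** p<0.01`, `* p<0.05` from the pooled t reference.
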