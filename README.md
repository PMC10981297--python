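# esmnet

Temporal and contemporaneous symptom networks from daily experience-sampling
(ESM) data, estimated with a multilevel lag-1 vector autoregression (VAR).

The package covers the full workflow for long-format daily-diary panels
(one row per person per day, ordinal 1–7 symptom ratings, attention check):

- **`esmnet.synthetic`** — hierarchical VAR(1) generator: person-specific
  means and temporal matrices drawn around population values with mutually
  independent ("orthogonal") random effects, Gaussian innovations, optional
  Likert discretization (round half-away-from-zero, clip to bounds), and
  cell-level MCAR missingness injection.
- **`esmnet.preprocess`** — attention-check filtering, moving-average
  imputation (expanding window), lag-1 design construction restricted to
  consecutive calendar days, listwise deletion, within-person centering,
  level-stationarity KPSS testing (Bartlett-kernel long-run variance), and
  per-day Cronbach's alpha.
- **`esmnet.mlvar`** — node-wise multilevel regressions (statsmodels
  `MixedLM`): each symptom at day *t* on all centered lagged symptoms at
  day *t−1*, person random intercept plus uncorrelated random slopes
  (diagonal variance components). Wald p-values with the normal reference.
  Contemporaneous network from residual-on-residual regressions with the
  sign-consistent combination `sign(b_jk)·sqrt(b_jk·b_kj)` and the "and"
  rule (both coefficients significant).
- **`esmnet.networks`** — significance-masked temporal (directed, with
  self-loop autocorrelations) and contemporaneous (undirected partial
  correlation) networks, edge counting, feedback-loop (directed cycle)
  enumeration, GraphML / node-link JSON export.
- **`esmnet.centrality`** — raw-score Out-strength / In-strength (absolute
  significant edge weights, self-loops excluded) and contemporaneous
  strength, plus rankings.
- **`esmnet.pipeline` / `esmnet.cli`** — end-to-end orchestration, YAML
  configuration, run manifest with checksums, and the listwise-vs-imputation
  robustness comparison.
- **`esmnet.calibration`** — simulation studies: per-edge type-I error under
  a null generator and fixed-effect recovery / Wald coverage at study scale.

Note on edge selection: each temporal edge comes from a single node-wise
regression, so temporal edges are thresholded by that one test at α; the
two-regression "and" rule applies to contemporaneous edges, where a pair is
estimated from both directions.

## CLI

```bash
# simulate a study-scale panel (115 persons x 50 days x 8 symptoms)
esmnet simulate --persons 115 --days 50 --seed 1 --missing-rate 0.0248 --out data.csv

# preprocess into a centered lag-1 design (listwise or impute)
esmnet preprocess --in data.csv --mode listwise --kpss-out kpss.tsv --out design.csv

# node-wise multilevel VAR fit
esmnet fit --in design.csv --alpha 0.05 --random orthogonal --out fit.json

# networks and centralities
esmnet networks --in design.csv --out-dir nets/
esmnet centrality --in design.csv --out centrality.tsv

# everything at once, with a manifest
esmnet pipeline --in data.csv --mode listwise --out-dir results/run1

# robustness of the two missing-data strategies
esmnet compare --in data.csv --out compare.json
```

Generator parameters can be supplied as YAML (`esmnet simulate --config
params.yaml ...`); see `esmnet.synthetic.VarParameters.to_yaml`.

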