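# nichepack

Trait-based community assembly analysis for site-by-species metacommunities.

From individual morphometric records (10 measurements per specimen) the
package derives species-level functional traits (ratio transformation,
1.5×IQR outlier screening, per-species averaging), builds a Gower distance
matrix and a PCoA trait space, and computes two community metrics per site:

- **FRic** — convex-hull functional richness in the reduced trait space;
- **MNND** — mean nearest-neighbour Gower distance (niche packing).

Observed values are compared against identity-randomization null models
(richness held fixed) under four variants — unconstrained/constrained ×
total/regional species pool, where the constrained variant restricts the
pool to species inside the focal community's empirical trait hull — and
summarized as standardized effect sizes (SES). Inference includes exact
Wilcoxon signed-rank tests of SES against zero, type-II ANCOVA of SES on
richness × ecoregion, and correlation analyses (SES vs richness per
ecoregion; functional centrality vs average abundance). A synthetic
metacommunity generator (neutral / environmental-filtering /
limiting-similarity scenarios with a between-region dispersal barrier)
makes the whole pipeline testable end to end.

## CLI

```bash
# generate a synthetic metacommunity (specimens.csv, sites.csv, truth.json)
nichepack synth --scenario filtering --seed 1 --out-dir data/

# run the null-model sweep (4 variants, per-cell seeded, deterministic)
nichepack nulls --specimens data/specimens.csv --sites data/sites.csv \
    --pool both --variant both --nperm 1000 --seed 42 --out results.csv

# Wilcoxon + ANCOVA summaries per metric/pool/variant
nichepack stats --results results.csv --sites data/sites.csv --out stats.csv
```

`nulls` optionally takes `--sessions sessions.csv` to apply
single-season trapping-session selection first, and `--config run.yaml`
for the full `RunConfig` (axes, hull tolerance, FRic standardization, …).

## Python API

```python
import nichepack as nv

ds = nv.generate_dataset(nv.ScenarioConfig(scenario="filtering", seed=1))
cfg = nv.RunConfig(n_permutations=1000, seed=42)
results, space, community = nv.run_pipeline(ds.records, ds.site_meta, cfg)

ses_vals = [r.ses for r in results if r.metric == "FRic" and r.pool == "total"]
print(nv.wilcoxon_signed_rank(ses_vals))
```

## Layout

- `src/nichepack/io_model.py` — CSV ingest, session selection, community matrix, results I/O, config
- `src/nichepack/traits.py` — ratio traits, IQR outlier screening, species aggregation, Gower distances
- `src/nichepack/funcspace.py` — PCoA trait space, hull volumes, FRic, MNND, hull membership
- `src/nichepack/nullmodels.py` — pools, randomization, constrained pools, SES, the full sweep
- `src/nichepack/inference.py` — Wilcoxon, type-II ANCOVA, correlations, occupancy
- `src/nichepack/synth.py` — scenario generator and recovery experiment
- `src/nichepack/pipeline.py`, `src/nichepack/cli.py` — orchestration and CLI
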