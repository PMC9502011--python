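# nitronet

Co-occurrence network and nitrogen-efficiency analysis for soil-microbiome
fertilization experiments.

`nitronet` is for microbial ecologists and agronomists studying how
fertilization regimes — e.g. controlled-release urea (CRU) with or without
an organic synergist such as fulvic acid (FA) — reshape the soil bacterial
community and the nitrogen cycle. From an OTU count table, sample
metadata, environmental covariates and per-replicate agronomic records it
computes:

- **Community preprocessing** — seeded rarefaction (multivariate
  hypergeometric subsampling), Good's coverage, relative abundance,
  taxonomic aggregation, and the >1% mean-abundance filter that defines
  the network node set.
- **Ordination** — Bray–Curtis dissimilarity, PCoA, and ANOSIM with a
  seeded permutation test.
- **Co-occurrence networks** — all-pairs Spearman ρ with BH false
  discovery control (default q ≤ 0.001), a correlation cutoff selected by
  random-matrix theory (the GOE→Poisson transition of the eigenvalue
  nearest-neighbour spacing distribution of the thresholded matrix),
  signed edges, Louvain modules (Mod1..Modk) with modularity Q, per-sample
  module abundances, and Gephi-compatible GraphML/GEXF export.
- **Association** — module × environment Pearson correlation tables with
  significance stars, per-OTU enrichment/depletion calls between
  treatments (Welch's t on log relative abundance, BH-adjusted; output
  ready for Manhattan plots), and simple/partial Mantel tests linking
  guild-level community distances (nitrifiers, denitrifiers, N-fixers,
  ammonia oxidizers) to environmental factors.
- **Agronomy** — nitrogen use/agronomic/physiological efficiency

      NUE (%) = (AN − AN0)/SN × 100
      NAE (kg kg⁻¹) = (GN − GN0)/SN
      NPE (kg kg⁻¹) = (YN − YN0)/(AN − AN0)

  percent changes versus a reference treatment (half-up, one decimal),
  and one-way ANOVA with Duncan's multiple-range letter display.
- **Synthetic data** — a generator that emulates the full study design
  (36 samples = treatments × days × replicates, 20,000 reads/sample, taxa
  in correlated modules shifting with treatment and day, environment
  linearly coupled to module abundances, agronomic records with treatment
  effects) with known ground truth, so the whole chain is testable
  without sequencing data.

See `docs/methods.md` for the models, numerical conventions and
limitations.

## Worked example

```python
from nitronet import simulate, community, network, agronomy

config = simulate.SimulationConfig(n_taxa=60, n_modules=5, depth=2000, seed=1)
counts, taxonomy, truth = simulate.simulate_community(config)
rel = community.to_relative_abundance(counts)

corr = network.spearman_matrix(rel, q_cut=0.001)
threshold, diagnostics = network.rmt_threshold(corr)
graph = network.build_network(corr, threshold, q_cut=0.001)
partition = network.detect_modules(graph, seed=1)
print(f"RMT threshold: {threshold}")
print(f"modules: {len(set(partition.module_of))}, modularity Q = {partition.modularity:.3f}")

agronomic = simulate.simulate_agronomy(config, residual_cv=0.0)
yields = agronomic.groupby("treatment")["grain_yield"].mean()
print(f"yield increase CRU+FA vs CRU: {agronomy.percent_change(yields['CRU+FA'], yields['CRU'])}%")
eff = agronomy.efficiency_table(agronomic, reference="CRU")
print(eff[["NUE", "NAE", "NUE_change_vs_CRU"]].round(2).to_string())
```

prints

```
RMT threshold: 0.44
modules: 5, modularity Q = 0.780
yield increase CRU+FA vs CRU: 22.1%
         NUE   NAE  NUE_change_vs_CRU
CRU     35.4  6.98                0.0
CRU+FA  50.0  9.84               41.2
```

The RMT scan found the correlation cutoff (0.44) at which the thresholded
Spearman matrix's eigenvalue spacing turns Poisson — random correlations
removed — and Louvain recovered the five planted modules. The agronomic
block reports a 22.1% grain-yield gain and a 41.2% NUE gain for CRU+FA
over CRU alone, computed from the per-replicate records.

The same chain runs end to end from a single config:

```sh
nitronet run --outdir my_run --seed 1        # full synthetic pipeline
nitronet simulate --outdir data --seed 1     # just the generator
nitronet network --relabund filtered.tsv --fdr-cut 0.001 \
    --rmt-grid 0.30:0.95:0.01 --outdir net   # just the network stage
```

Every run writes a `manifest.json` recording the seed, parameters and
input checksums; identical config + seed reproduce byte-identical
outputs.

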