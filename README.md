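# sadnet

Statistical pipeline for OTU count tables: maximum-likelihood species
abundance distribution (SAD) model selection, MIC-based co-occurrence
networks, Chao1 diversity, and environmental richness modelling — plus a
synthetic-data generator with known ground truth so the whole pipeline is
testable without any external data.

## What it does

- **io_tables** — QIIME-classic TSV OTU tables (`#OTU ID` header, optional
  taxonomy column), sample metadata and environmental covariate CSVs;
  rarefaction without replacement, strict `> 0.001 %` relative-abundance
  filtering, pooling of abundances by site or region.
- **sad** — zero-truncated Poisson-lognormal (mode-centred Gauss–Hermite
  quadrature) and negative-binomial pmfs, Nelder–Mead ML fitting with
  moment-based multi-starts, Akaike weights (wPLN/wNB), Preston-style octave
  binning (`floor(log2 n)`) and prominence-based multimodality scoring.
- **diversity** — Chao1 (bias-corrected default, classic variant),
  individual-based rarefaction curves via log-gamma hypergeometrics, Pearson
  richness correlations across domains.
- **network** — maximal information coefficient (MINE-style: equipartitioned
  fixed axis, exact clump-boundary dynamic programme on the free axis,
  both orientations; numba-accelerated when available), per-pair permutation
  p-values, BH/Bonferroni correction, filtered co-occurrence networks with
  Cytoscape-compatible exports and undirected topology summaries, and a
  permutation test for excess co-occurrence.
- **richness** — pruning of co-correlated covariates (|R| > 0.6), Gaussian
  and negative-binomial (log link, profile-ML dispersion) regression with
  optional natural cubic spline terms, stepwise AIC selection with forced
  terms (e.g. region), Table-1-style best-model summaries.
- **synthetic** — PLN/NB/mixture community simulation, multinomial
  "sequencing" with lognormal overdispersion, planted positive/negative
  co-occurrence, environment tables with known richness effects, and a full
  two-region / nine-site / three-domain fixture bundle.
- **pipeline / cli** — end-to-end orchestration from a YAML config with a
  single deterministically-split master seed and byte-identical reruns.

## CLI

```sh
sadnet simulate --seed 1 --outdir fixture
sadnet rarefy fixture/otu_table_bacteria.tsv --depth 7000 --seed 1 --out rare.tsv
sadnet sadfit rare.tsv --metadata fixture/metadata_bacteria.csv --scale regional
sadnet chao1 rare.tsv --out chao1.tsv
sadnet network rare.tsv --mic-threshold 0.8 --p-threshold 0.001 --n-perm 999
sadnet model fixture/env.csv --response chao1.tsv --family negative_binomial
sadnet all --seed 1 --outdir results/run1        # full pipeline
```

`sadnet all` accepts `--config pipeline.yaml`; keys mirror
`sadnet.pipeline.PipelineConfig` (rarefaction depths per domain, filter
threshold, SAD scales, MIC parameters, permutation count, model families,
master seed).

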