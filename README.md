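# orgbench

Benchmarking framework for asking how faithfully an in-vitro differentiation
time-course recapitulates a reference developmental transcriptome series.
It implements the full analysis surface of such a benchmark — co-expression
module discovery and hub ranking, stage-wise differential expression,
module/gene-set overlap statistics, reference-based bulk deconvolution,
cross-dataset module-eigengene projection, and stage-correlation
heterochronicity analysis — and exercises everything end-to-end on synthetic
data with known ground truth.

## Modules

| module | contents |
| --- | --- |
| `orgbench.simulate` | synthetic reference/query time-courses with planted co-expression modules (monotone, U-shaped, inverted-U, flat), NB counts, donor/batch structure, a controllable time-warp factor τ, a synthetic single-cell reference, and bulk mixtures of known proportions |
| `orgbench.preprocess` | TSV/MTX dataset I/O, CPM/FPKM, TMM normalization factors, expression/biotype filters, CV-percentile gene selection, stage means |
| `orgbench.coexpr` | biweight midcorrelation, signed soft-threshold adjacency, topological overlap, dendrogram module detection (simplified hybrid dynamic tree cut + PAM), module eigengenes, module–trait correlation, intramodular connectivity |
| `orgbench.netstat` | top-hub sub-network export, weighted degree / closeness / betweenness / eigenvector centralities |
| `orgbench.dea` | NB GLM with covariates and LRT, Cox–Reid dispersion estimation with trend + shrinkage, stage-wise DEA, consecutive-comparison quadrants, tissue-specific DEG subtraction |
| `orgbench.overlap` | hypergeometric set overlap with odds ratios, overlap matrices with significance masks, GO enrichment (classic + elim decorrelation over a child→parent DAG) |
| `orgbench.deconv` | single-cell QC (metric thresholds + assignment-certainty filter), CPM basis construction, weighted NNLS deconvolution, population grouping |
| `orgbench.benchmark` | reference-standardized eigengene projection, query-vs-reference stage-correlation maps with time-warp (τ̂) estimation, signature profiling, sample PCA with top-loading extraction |
| `orgbench.cli` | pipeline orchestration over a strict YAML config |

## CLI

```bash
# full synthetic benchmark (simulate → network → DEA → overlap → enrich →
# deconvolution → projection/warp → report), ~30 s on one CPU
orgbench all -o scratch/run
cat scratch/run/report.json

# individual stages, custom config (unknown keys are hard errors)
orgbench simulate -c myconfig.yaml
orgbench network  -c myconfig.yaml
orgbench report   -c myconfig.yaml
```

The bundled config is `src/orgbench/configs/synthetic.yaml`; any subset of
its keys can be overridden from a user YAML. Every run writes a
`manifest.json` with seed, config hash and artifact checksums; `report.json`
collates module-recovery, calibration, deconvolution and heterochronicity
checks against the planted truth.

## Conventions worth knowing

- NB parameterization everywhere: mean μ, dispersion φ, `Var = μ + φμ²`.
- Quantiles use linear interpolation between order statistics; the CV
  threshold is strict (`>`).
- "log-transformed" means `log2(x + 1)`.
- Network input is log2 TMM-normalized CPM; adjacency/TOM are dense
  (`build_network` refuses > 20,000 genes without `force=True`).
- Path-based centralities use the distance transform `d = 1/w`;
  betweenness is unnormalized.
- Eigengene projection standardizes query genes with *reference* mean/sd and
  renormalizes the restricted loading vector to unit L2 norm.
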