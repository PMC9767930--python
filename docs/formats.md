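# File formats

## Expression dataset (TSV trio)

A dataset named `<name>` is three tab-separated files:

- `<name>.matrix.tsv` — first column `gene_id`, header row = sample ids,
  cells = expression values (unit tracked by the caller: counts, CPM,
  RPKM/FPKM, or log2).
- `<name>.samples.tsv` — first column `sample_id`; columns `stage_label`,
  `stage_numeric` (PCW or day), `line`, `batch` (extra columns preserved).
- `<name>.genes.tsv` — first column `gene_id`; columns `symbol`, `biotype`,
  optional `length_bp`.

Read/write with `orgbench.dataset.ExpressionDataset.read/write`.

## Single-cell input

Either a dense genes x cells TSV (as written by the simulator) or an MTX
triplet directory (`matrix.mtx`, `features.tsv` or `genes.tsv`,
`barcodes.tsv`), read with `orgbench.io.read_mtx`.

## Gene sets (GMT)

One set per line: `name <TAB> description <TAB> gene1 <TAB> gene2 ...`
(`orgbench.io.read_gmt` / `write_gmt`).

## Term annotation and DAG

- Annotation: two-column TSV `gene <TAB> term`, no header
  (`orgbench.io.read_annotation`).
- Optional ontology structure: two-column TSV `child_term <TAB> parent_term`,
  no header (`orgbench.io.read_dag`); required by the `elim` enrichment
  method.

## Truth JSON

`SyntheticTruth.to_json` writes:

```json
{
  "module_of_gene": {"G00000": 1, ...},        // 0 = background
  "template_of_module": {"1": "up", ...},      // template names
  "tau": 1.0,                                   // time-warp factor
  "seed": 1,
  "true_proportions": {"index": [...], "columns": [...], "values": [[...]]},
  "gene_params": {"index": [...], "columns": ["b", "lam", "phi"], "values": [[...]]}
}
```

`true_proportions` / `gene_params` are null when not applicable.

## Network projection JSON

`CoexpressionNetwork.save_projection_json` stores everything projection
needs without the dense matrices: `beta`, per-gene module `labels`,
per-gene reference `gene_mean` / `gene_sd`, per-module unit-L2 `loadings`,
`var_explained`, and the stored eigengene table `me`.
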