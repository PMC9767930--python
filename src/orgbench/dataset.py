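"""Expression dataset container with unit tagging and TSV persistence.

An :class:`ExpressionDataset` couples a genes x samples matrix with
per-sample metadata (stage, line, batch) and per-gene metadata (symbol,
biotype, length).  The matrix unit is tracked explicitly so that
operations can assert they receive the scale they expect.

On disk a dataset is a trio of TSV files sharing a prefix::

    <name>.matrix.tsv    first column gene id, header = sample ids
    <name>.samples.tsv   sample metadata, first column sample id
    <name>.genes.tsv     gene metadata, first column gene id
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Recognized matrix units.
UNITS = ("counts", "CPM", "RPKM", "FPKM", "log2")

#: Expected sample metadata columns (extra columns are preserved).
SAMPLE_META_COLUMNS = ("stage_label", "stage_numeric", "line", "batch")


def strip_gene_version(ids) -> pd.Index:
    """Strip Ensembl-style ``.N`` version suffixes from gene identifiers."""
    return pd.Index([i.split(".", 1)[0] if isinstance(i, str) else i for i in ids])


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix plus aligned metadata.

    Parameters
    ----------
    matrix:
        DataFrame indexed by gene id with one column per sample.
    unit:
        One of :data:`UNITS`.
    sample_meta:
        DataFrame indexed by sample id; rows align 1:1 with matrix columns.
    gene_meta:
        DataFrame indexed by gene id; rows align 1:1 with matrix rows.
    """

    matrix: pd.DataFrame
    unit: str
    sample_meta: pd.DataFrame
    gene_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(index=self.matrix.index)
        if self.matrix.index.has_duplicates:
            dupes = self.matrix.index[self.matrix.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}...")
        if not self.matrix.columns.equals(self.sample_meta.index):
            raise ValueError("sample_meta rows must align 1:1 with matrix columns")
        if not self.matrix.index.equals(self.gene_meta.index):
            raise ValueError("gene_meta rows must align 1:1 with matrix rows")
        if self.unit != "log2" and (self.matrix.to_numpy() < 0).any():
            raise ValueError(f"negative values in a {self.unit} matrix")

    # ------------------------------------------------------------------ shape

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def samples(self) -> pd.Index:
        return self.matrix.columns

    # ------------------------------------------------------------- derivation

    def with_matrix(self, matrix: pd.DataFrame, unit: str | None = None) -> "ExpressionDataset":
        """Return a dataset with a replaced matrix (metadata realigned)."""
        return ExpressionDataset(
            matrix=matrix,
            unit=unit if unit is not None else self.unit,
            sample_meta=self.sample_meta.loc[matrix.columns],
            gene_meta=self.gene_meta.loc[matrix.index],
        )

    def subset_genes(self, gene_ids) -> "ExpressionDataset":
        """Restrict to ``gene_ids``, preserving current gene order."""
        keep = self.matrix.index.isin(set(gene_ids))
        return self.with_matrix(self.matrix.loc[keep])

    def subset_samples(self, sample_ids) -> "ExpressionDataset":
        return self.with_matrix(self.matrix.loc[:, list(sample_ids)])

    def log2(self, pseudocount: float = 1.0) -> "ExpressionDataset":
        """log2(x + pseudocount) transform (tagged ``log2``)."""
        if self.unit == "log2":
            return self
        return self.with_matrix(np.log2(self.matrix + pseudocount), unit="log2")

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            self.matrix.copy(), self.unit, self.sample_meta.copy(), self.gene_meta.copy()
        )

    # -------------------------------------------------------------------- I/O

    def write(self, prefix: str | Path) -> None:
        """Write the ``<prefix>.matrix/samples/genes.tsv`` trio."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.matrix.rename_axis("gene_id").to_csv(f"{prefix}.matrix.tsv", sep="\t")
        self.sample_meta.rename_axis("sample_id").to_csv(f"{prefix}.samples.tsv", sep="\t")
        self.gene_meta.rename_axis("gene_id").to_csv(f"{prefix}.genes.tsv", sep="\t")

    @classmethod
    def read(cls, prefix: str | Path, unit: str) -> "ExpressionDataset":
        """Read a dataset written by :meth:`write`."""
        prefix = Path(prefix)
        matrix = pd.read_csv(f"{prefix}.matrix.tsv", sep="\t", index_col=0)
        sample_meta = pd.read_csv(f"{prefix}.samples.tsv", sep="\t", index_col=0)
        genes_path = Path(f"{prefix}.genes.tsv")
        gene_meta = (
            pd.read_csv(genes_path, sep="\t", index_col=0) if genes_path.exists() else None
        )
        sample_meta.index = sample_meta.index.astype(str)
        matrix.columns = matrix.columns.astype(str)
        for frame in (matrix, sample_meta) + ((gene_meta,) if gene_meta is not None else ()):
            frame.index.name = None
            frame.columns.name = None
        return cls(matrix=matrix, unit=unit, sample_meta=sample_meta, gene_meta=gene_meta)
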