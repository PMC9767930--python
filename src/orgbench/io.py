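"""Readers and writers for auxiliary text formats.

Covers GMT gene sets, two-column gene/term annotations, child->parent DAG
edges, MTX single-cell triplets, and the synthetic-truth JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from scipy.io import mmread


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: ``name <tab> description <tab> gene...`` per line."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column gene<TAB>term mapping into gene -> {terms}."""
    ann: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    for gene, term in zip(df["gene"], df["term"]):
        ann.setdefault(gene, set()).add(term)
    return ann


def write_annotation(ann: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(ann):
            for term in sorted(ann[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_dag(path: str | Path) -> dict[str, set[str]]:
    """Read child<TAB>parent edges into child -> {parents}."""
    dag: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["child", "parent"], dtype=str)
    for child, parent in zip(df["child"], df["parent"]):
        dag.setdefault(child, set()).add(parent)
    return dag


def read_mtx(directory: str | Path) -> pd.DataFrame:
    """Read an MTX triplet directory into a dense genes x cells DataFrame.

    Expects ``matrix.mtx`` plus ``features.tsv`` (or ``genes.tsv``) and
    ``barcodes.tsv``; the first column of each annotation file is used.
    """
    directory = Path(directory)
    mat = mmread(directory / "matrix.mtx").toarray()
    feat_path = directory / "features.tsv"
    if not feat_path.exists():
        feat_path = directory / "genes.tsv"
    genes = pd.read_csv(feat_path, sep="\t", header=None).iloc[:, 0].astype(str)
    cells = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None).iloc[:, 0].astype(str)
    return pd.DataFrame(mat, index=genes.to_numpy(), columns=cells.to_numpy())


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
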