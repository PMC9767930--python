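"""Reference-based bulk deconvolution by weighted non-negative least squares.

Single-cell QC (hard metric thresholds plus a correlation-based assignment
certainty filter), basis construction from CPM-normalized per-type means,
and an iteratively re-weighted NNLS proportion estimator.  Similarities are
computed on ``log2(CPM + 1)``; the NNLS itself runs on linear CPM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from orgbench.dataset import strip_gene_version

logger = logging.getLogger(__name__)

__all__ = [
    "CellQCThresholds",
    "DeconvolutionModel",
    "ProportionEstimate",
    "qc_cells",
    "qc_assignment",
    "build_basis",
    "wnnls_deconvolve",
    "deconvolve_dataset",
    "group_proportions",
]


@dataclass(frozen=True)
class CellQCThresholds:
    """Strict-inequality QC bounds on per-cell metrics."""

    max_mito_frac: float = 0.05
    max_ribo_frac: float = 0.50
    min_detected_genes: int = 450
    max_detected_genes: int = 3000
    min_umi: int = 750
    max_umi: int = 10000


def _cell_metrics(counts: pd.DataFrame) -> pd.DataFrame:
    umi = counts.sum(axis=0)
    mito = counts.index.str.startswith("MT-")
    ribo = counts.index.str.startswith(("RPL", "RPS"))
    return pd.DataFrame(
        {
            "umi_count": umi,
            "detected_genes": (counts > 0).sum(axis=0),
            "mito_frac": counts.loc[mito].sum(axis=0) / umi.clip(lower=1),
            "ribo_frac": counts.loc[ribo].sum(axis=0) / umi.clip(lower=1),
        }
    )


def qc_cells(
    counts: pd.DataFrame,
    cell_meta: pd.DataFrame | None = None,
    thresholds: CellQCThresholds = CellQCThresholds(),
) -> pd.Index:
    """Cells passing all metric thresholds (all inequalities strict).

    Metrics are taken from ``cell_meta`` when the columns are present,
    otherwise computed from the counts (mitochondrial/ribosomal fractions
    via the ``MT-``/``RPL``/``RPS`` gene-name prefixes).  Removal counts
    per criterion are logged.
    """
    needed = ["umi_count", "detected_genes", "mito_frac", "ribo_frac"]
    if cell_meta is not None and all(c in cell_meta for c in needed):
        metrics = cell_meta[needed]
    else:
        metrics = _cell_metrics(counts)
    t = thresholds
    checks = {
        "mito_frac": metrics["mito_frac"] < t.max_mito_frac,
        "ribo_frac": metrics["ribo_frac"] < t.max_ribo_frac,
        "detected_low": metrics["detected_genes"] > t.min_detected_genes,
        "detected_high": metrics["detected_genes"] < t.max_detected_genes,
        "umi_low": metrics["umi_count"] > t.min_umi,
        "umi_high": metrics["umi_count"] < t.max_umi,
    }
    keep = pd.Series(True, index=metrics.index)
    for name, ok in checks.items():
        n_removed = int((~ok).sum())
        if n_removed:
            logger.info("qc_cells: %d cell(s) fail %s", n_removed, name)
        keep &= ok
    return metrics.index[keep]


def _log_cpm(counts: pd.DataFrame) -> np.ndarray:
    cpm = counts.to_numpy(dtype=float)
    cpm = cpm / np.maximum(cpm.sum(axis=0, keepdims=True), 1.0) * 1e6
    return np.log2(cpm + 1.0)


def qc_assignment(
    counts: pd.DataFrame,
    labels: pd.Series,
    qc_threshold: float = 0.65,
    min_similarity: float = 0.2,
) -> pd.Index:
    """Remove cells with uncertain type assignment.

    Per cell, similarity to each type centroid is ``max(0, Pearson r)`` on
    ``log2(CPM+1)`` after centering every gene by its global mean profile
    (without the centering all centroids share the baseline expression
    pattern and no cell can reach a decisive weight); the assignment weight
    is the labeled type's share of the total similarity.  Cells are removed
    when the weight falls below ``qc_threshold`` or when the similarity to
    their own centroid falls below ``min_similarity`` (a cell orthogonal to
    its centroid is uncertain no matter how poor the competitors are).
    """
    labels = labels.loc[counts.columns]
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    x = _log_cpm(counts)
    x = x - x.mean(axis=1, keepdims=True)
    centroids = np.column_stack([x[:, (labels == t).to_numpy()].mean(axis=1) for t in types])

    xc = x - x.mean(axis=0, keepdims=True)
    cc = centroids - centroids.mean(axis=0, keepdims=True)
    xn = np.linalg.norm(xc, axis=0)
    cn = np.linalg.norm(cc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xc / np.where(xn == 0, 1, xn)).T @ (cc / np.where(cn == 0, 1, cn))
    sim = np.maximum(corr, 0.0)  # cells x types

    total = sim.sum(axis=1)
    type_idx = np.array([types.index(t) for t in labels])
    own = sim[np.arange(len(labels)), type_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        weight = np.where(total > 0, own / np.where(total == 0, 1, total), 0.0)
    zero = total == 0
    if zero.any():
        logger.info("qc_assignment: %d cell(s) with all-zero similarity removed", zero.sum())
    keep = (weight >= qc_threshold) & (own >= min_similarity) & ~zero
    return counts.columns[keep]


@dataclass
class DeconvolutionModel:
    """Basis matrix (genes x types, CPM scale), within-type variance, QC state."""

    basis: pd.DataFrame
    variance: pd.DataFrame
    kept_cells: pd.Index
    grouping: dict[str, str] = field(default_factory=dict)


def build_basis(
    counts: pd.DataFrame,
    labels: pd.Series,
    grouping: dict[str, str] | None = None,
    min_cells: int = 20,
) -> DeconvolutionModel:
    """Per-type mean of CPM-normalized counts over QC-passed cells.

    ``grouping`` maps raw labels to final type names; grouped columns are
    the mean over all cells of the group.  Genes never expressed in the
    reference are dropped.
    """
    labels = labels.loc[counts.columns]
    if grouping:
        labels = labels.map(lambda t: grouping.get(t, t))
    types = sorted(labels.unique())
    cpm = counts.to_numpy(dtype=float)
    cpm = cpm / np.maximum(cpm.sum(axis=0, keepdims=True), 1.0) * 1e6

    expressed = cpm.sum(axis=1) > 0
    basis, var = {}, {}
    for t in types:
        cols = (labels == t).to_numpy()
        if cols.sum() < min_cells:
            raise ValueError(f"type {t!r} has {cols.sum()} cells (< {min_cells})")
        block = cpm[np.ix_(expressed, cols)]
        basis[t] = block.mean(axis=1)
        var[t] = block.var(axis=1, ddof=1)
    genes = counts.index[expressed]
    return DeconvolutionModel(
        basis=pd.DataFrame(basis, index=genes),
        variance=pd.DataFrame(var, index=genes),
        kept_cells=counts.columns,
        grouping=dict(grouping or {}),
    )


@dataclass
class ProportionEstimate:
    """Simplex proportion vector for one bulk sample."""

    proportions: pd.Series
    residual_norm: float
    iterations: int
    fallback: bool = False


def wnnls_deconvolve(
    y: pd.Series,
    model: DeconvolutionModel,
    max_iter: int = 10,
    tol: float = 1e-5,
    min_shared_genes: int = 200,
) -> ProportionEstimate:
    """Weighted NNLS proportion estimate for one bulk expression vector.

    Iterates NNLS with weights ``w_g = 1 / (r_g^2 + delta)`` where ``r`` is
    the current residual and ``delta = median(r^2)``, starting from unit
    weights; stops when the L1 change of the normalized proportions falls
    below ``tol``.  ``y`` can be on any linear scale (the estimate is
    scale-invariant after normalization).
    """
    y_ids = strip_gene_version(y.index)
    b_ids = strip_gene_version(model.basis.index)
    shared = y_ids.intersection(b_ids)
    if len(shared) < min_shared_genes:
        raise ValueError(f"only {len(shared)} genes shared with the basis (< {min_shared_genes})")
    yv = pd.Series(y.to_numpy(), index=y_ids).loc[shared].to_numpy(dtype=float)
    b = pd.DataFrame(model.basis.to_numpy(), index=b_ids, columns=model.basis.columns)
    bm = b.loc[shared].to_numpy(dtype=float)

    w = np.ones(len(shared))
    prev = None
    fallback = False
    iterations = 0
    p = np.zeros(bm.shape[1])
    for iterations in range(1, max_iter + 1):
        sw = np.sqrt(w)
        try:
            p, _ = nnls(bm * sw[:, None], yv * sw)
        except Exception:  # pragma: no cover - solver failure path
            logger.warning("weighted NNLS failed; falling back to unweighted")
            p, _ = nnls(bm, yv)
            fallback = True
            break
        r = yv - bm @ p
        r2 = r**2
        delta = np.median(r2)
        w = 1.0 / (r2 + max(delta, 1e-12))
        total = p.sum()
        p_norm = p / total if total > 0 else np.full_like(p, 1.0 / len(p))
        if prev is not None and np.abs(p_norm - prev).sum() < tol:
            break
        prev = p_norm

    total = p.sum()
    p_norm = p / total if total > 0 else np.full_like(p, 1.0 / len(p))
    residual = float(np.linalg.norm(yv - bm @ p))
    return ProportionEstimate(
        proportions=pd.Series(p_norm, index=model.basis.columns),
        residual_norm=residual,
        iterations=iterations,
        fallback=fallback,
    )


def deconvolve_dataset(
    bulk: pd.DataFrame, model: DeconvolutionModel, **kwargs
) -> pd.DataFrame:
    """Apply :func:`wnnls_deconvolve` to every column of a bulk matrix."""
    rows = {s: wnnls_deconvolve(bulk[s], model, **kwargs).proportions for s in bulk.columns}
    return pd.DataFrame(rows).T.rename_axis("sample")


def group_proportions(
    estimates: pd.DataFrame, grouping: dict[str, str]
) -> tuple[pd.DataFrame, bool]:
    """Sum proportion columns within groups.

    ``grouping`` maps every estimated type to a group name (or ``None`` to
    drop the type); types missing from the map raise.  If dropped types
    carried mass, rows are renormalized to 1 and the returned flag is True.
    """
    unknown = set(estimates.columns) - set(grouping)
    if unknown:
        raise ValueError(f"grouping does not cover type(s): {sorted(unknown)}")
    kept = [t for t in estimates.columns if grouping[t] is not None]
    sub = estimates[kept]
    grouped = sub.T.groupby(sub.columns.map(grouping)).sum().T
    sums = grouped.sum(axis=1)
    renormalized = bool((np.abs(sums - 1.0) > 1e-9).any())
    if renormalized:
        grouped = grouped.div(sums, axis=0)
    return grouped, renormalized
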