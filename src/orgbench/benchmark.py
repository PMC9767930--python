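"""Cross-dataset comparison: eigengene projection, stage-correlation
mapping with time-warp estimation, signature profiling, and sample PCA.

Projection standardizes query genes with the *reference* per-gene mean/sd
stored in the network (self-consistency: projecting the source dataset
reproduces its stored eigengene).  Missing genes are handled by rescaling
the restricted loading vector to unit L2 norm rather than zero-filling, so
projected eigengene scale stays comparable across queries with different
gene coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from orgbench.coexpr import CoexpressionNetwork
from orgbench.dataset import ExpressionDataset, strip_gene_version
from orgbench.dea import DEAResult

logger = logging.getLogger(__name__)

__all__ = [
    "EigengeneProjection",
    "StageCorrelationMap",
    "project_eigengene",
    "stage_correlation",
    "signature_profile",
    "sample_pca",
]


@dataclass
class EigengeneProjection:
    """Projected module eigengene for a query dataset."""

    module: int
    me: pd.Series  # per query sample
    genes_used: list[str]
    genes_missing: list[str]
    renorm_factor: float
    stage_medians: pd.Series | None = None


def project_eigengene(
    network: CoexpressionNetwork,
    module: int,
    query: ExpressionDataset,
    min_coverage: float = 0.5,
) -> EigengeneProjection:
    """Project a reference module eigengene onto a query dataset.

    Query genes are standardized with the reference per-gene mean/sd; the
    eigengene is the standardized block times the loading vector restricted
    to shared genes, the restriction rescaled to unit L2 norm, divided by
    the square root of the number of genes used (the same convention as the
    stored eigengene).
    """
    if query.unit != "log2":
        raise ValueError("project_eigengene expects a log2 query")
    if module not in network.eigengenes.loadings:
        raise ValueError(f"module {module} not in network")
    loading = network.eigengenes.loadings[module]

    q_ids = strip_gene_version(query.genes)
    module_ids = strip_gene_version(loading.index)
    id_map = dict(zip(module_ids, loading.index))
    shared_ids = [g for g in module_ids if g in set(q_ids)]
    missing = [g for g in module_ids if g not in set(q_ids)]
    coverage = len(shared_ids) / len(module_ids)
    if coverage < min_coverage:
        raise ValueError(
            f"module {module}: only {coverage:.0%} of genes present (< {min_coverage:.0%})"
        )

    shared_orig = [id_map[g] for g in shared_ids]
    qmat = pd.DataFrame(query.matrix.to_numpy(), index=q_ids, columns=query.samples)
    block = qmat.loc[shared_ids].to_numpy(dtype=float)  # genes x samples
    mean = network.eigengenes.gene_mean.loc[shared_orig].to_numpy()
    sd = network.eigengenes.gene_sd.loc[shared_orig].to_numpy()
    z = (block - mean[:, None]) / sd[:, None]

    v = loading.loc[shared_orig].to_numpy()
    norm = np.linalg.norm(v)
    renorm = 1.0 / norm if norm > 0 else 1.0
    me = z.T @ (v * renorm) / np.sqrt(len(shared_orig))
    me = pd.Series(me, index=query.samples, name=f"ME{module}")

    stage_medians = None
    if "stage_numeric" in query.sample_meta:
        stage_medians = me.groupby(query.sample_meta["stage_numeric"]).median()
    return EigengeneProjection(
        module=module,
        me=me,
        genes_used=shared_orig,
        genes_missing=missing,
        renorm_factor=float(renorm),
        stage_medians=stage_medians,
    )


@dataclass
class StageCorrelationMap:
    """Query-sample x reference-stage Spearman map with warp estimate."""

    rho: pd.DataFrame  # samples x stages
    best_match: pd.Series  # per-sample stage numeric (ties -> earliest)
    tau_hat: float
    tau_se: float
    n_used: int


def stage_correlation(
    query: ExpressionDataset,
    ref_stage_means: pd.DataFrame,
    ref_stage_numeric: pd.Series | None = None,
    min_shared_genes: int = 500,
) -> StageCorrelationMap:
    """Spearman correlation of each query sample against reference stage means.

    ``ref_stage_means`` is genes x stages (columns in stage order);
    ``ref_stage_numeric`` gives the numeric time of each stage column
    (defaults to 0..n-1).  The warp factor ``tau_hat`` is the OLS slope of
    the per-sample best-match stage time on the query's own stage time;
    samples whose best match is the final reference stage are excluded from
    the fit when enough earlier matches exist (they are censored by the
    warp's saturation), falling back to all samples otherwise.  ``tau_hat``
    is an extension of the visual stage-mapping readout, not a published
    estimator.
    """
    q_ids = strip_gene_version(query.genes)
    r_ids = strip_gene_version(ref_stage_means.index)
    shared = q_ids.intersection(r_ids)
    if len(shared) < min_shared_genes:
        raise ValueError(f"only {len(shared)} shared genes (< {min_shared_genes})")
    qmat = pd.DataFrame(query.matrix.to_numpy(), index=q_ids, columns=query.samples).loc[shared]
    rmat = pd.DataFrame(
        ref_stage_means.to_numpy(), index=r_ids, columns=ref_stage_means.columns
    ).loc[shared]

    # single rank transform, then Pearson via matrix product
    qr = qmat.rank(axis=0).to_numpy()
    rr = rmat.rank(axis=0).to_numpy()
    qr = (qr - qr.mean(axis=0)) / qr.std(axis=0)
    rr = (rr - rr.mean(axis=0)) / rr.std(axis=0)
    rho = pd.DataFrame(
        qr.T @ rr / len(shared), index=query.samples, columns=ref_stage_means.columns
    )

    stage_numeric = (
        ref_stage_numeric.reindex(ref_stage_means.columns)
        if ref_stage_numeric is not None
        else pd.Series(np.arange(rho.shape[1], dtype=float), index=ref_stage_means.columns)
    )
    best_idx = rho.to_numpy().argmax(axis=1)  # argmax takes the first (earliest) max
    best_match = pd.Series(
        stage_numeric.iloc[best_idx].to_numpy(), index=query.samples, name="best_stage"
    )

    tau_hat, tau_se, n_used = _fit_warp_slope(
        query.sample_meta["stage_numeric"].astype(float), best_match, stage_numeric
    )
    return StageCorrelationMap(
        rho=rho, best_match=best_match, tau_hat=tau_hat, tau_se=tau_se, n_used=n_used
    )


def _fit_warp_slope(
    query_time: pd.Series, best_match: pd.Series, stage_numeric: pd.Series
) -> tuple[float, float, int]:
    """Warp slope from per-day median best matches with saturation hinge.

    A warp factor > 1 saturates at the end of the reference axis, so the
    day -> best-match relation is linear-then-flat.  The fit scans every
    candidate breakpoint whose plateau mean lies at the top of the
    reference axis (at or above the second-to-last stage) and takes the
    slope of the ordinary-least-squares line over the rising part of the
    SSE-minimizing model; with no admissible plateau this reduces to plain
    OLS over all days.  Per-day medians tame stage-grid snapping noise.
    """
    by_day = pd.DataFrame({"d": query_time.to_numpy(float), "y": best_match.to_numpy(float)})
    med = by_day.groupby("d")["y"].median()
    day = med.index.to_numpy()
    y = med.to_numpy()
    if np.ptp(day) == 0 or len(day) < 2:
        return float("nan"), float("nan"), len(day)

    def ols(mask: np.ndarray) -> tuple[float, float, np.ndarray]:
        design = np.column_stack([np.ones(int(mask.sum())), day[mask]])
        coef, res, *_ = np.linalg.lstsq(design, y[mask], rcond=None)
        sse = float(res[0]) if len(res) else 0.0
        return float(coef[1]), sse, design

    slope_full, sse_full, design_full = ols(np.ones(len(day), dtype=bool))
    best = (sse_full, slope_full, len(day), design_full, np.ones(len(day), dtype=bool))
    sat_floor = stage_numeric.iloc[-2] if len(stage_numeric) >= 2 else stage_numeric.iloc[-1]
    for k in range(2, len(day) - 1):
        rise = day <= day[k]
        flat = ~rise
        if y[flat].mean() < sat_floor:
            continue
        slope, sse, design = ols(rise)
        sse += float(((y[flat] - y[flat].mean()) ** 2).sum())
        if sse < best[0]:
            best = (sse, slope, int(rise.sum()), design, rise)

    sse, slope, n_used, design, mask = best
    dof = max(n_used - 2, 1)
    resid = y[mask] - design @ np.linalg.lstsq(design, y[mask], rcond=None)[0]
    sigma2 = float((resid**2).sum()) / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    return slope, float(np.sqrt(cov[1, 1])), n_used


def signature_profile(
    ds: ExpressionDataset,
    signatures: dict[str, set[str]],
    stage_key: str = "stage_label",
    dea_results: list[DEAResult] | None = None,
) -> pd.DataFrame:
    """Per-gene per-stage mean log2 expression for named signatures.

    Adds a DE flag per gene: ``"**"`` if the gene passes FDR < 0.05 in any
    stage-wise comparison, ``"*"`` if only nominal p < 0.05, else ``""``.
    Signatures with no matched genes are skipped (and reported).
    """
    if ds.unit != "log2":
        raise ValueError("signature_profile expects log2 expression")
    ids = strip_gene_version(ds.genes)
    lookup = pd.DataFrame(ds.matrix.to_numpy(), index=ids, columns=ds.samples)
    stage_order = (
        ds.sample_meta.groupby(stage_key)["stage_numeric"].min().sort_values().index
        if "stage_numeric" in ds.sample_meta
        else pd.Index(ds.sample_meta[stage_key].unique())
    )

    flags: dict[str, str] = {}
    if dea_results:
        for res in dea_results:
            t = res.table
            for g in t.index:
                gid = g.split(".", 1)[0]
                if t.loc[g, "fdr"] < 0.05:
                    flags[gid] = "**"
                elif t.loc[g, "p"] < 0.05 and flags.get(gid) != "**":
                    flags[gid] = "*"

    rows = []
    for name, genes in signatures.items():
        matched = [g for g in sorted(genes) if g in set(ids)]
        if not matched:
            logger.warning("signature %r matched no genes; skipped", name)
            continue
        for gene in matched:
            profile = lookup.loc[gene].groupby(ds.sample_meta[stage_key]).mean()
            for stage in stage_order:
                rows.append(
                    {
                        "signature": name,
                        "gene": gene,
                        "stage": stage,
                        "mean_log2": float(profile[stage]),
                        "de_flag": flags.get(gene, ""),
                    }
                )
    return pd.DataFrame(rows)


def sample_pca(
    ds: ExpressionDataset, top_k: int = 300, n_components: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Centered, unscaled sample PCA via SVD.

    Returns ``(scores, loadings, top_genes)``: sample scores and per-gene
    loadings for the first ``n_components`` PCs, plus the ``top_k`` genes
    with the most positive and most negative loadings per PC (ties by gene
    id).  A dataset with fewer than ``2 * top_k`` genes yields shorter
    lists (with a warning).
    """
    if ds.unit != "log2":
        raise ValueError("sample_pca expects log2 expression")
    x = ds.matrix.to_numpy(dtype=float).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    scores = pd.DataFrame(
        u[:, :k] * s[:k], index=ds.samples, columns=[f"PC{i+1}" for i in range(k)]
    )
    loadings = pd.DataFrame(
        vt[:k].T, index=ds.genes, columns=[f"PC{i+1}" for i in range(k)]
    )
    if ds.n_genes < 2 * top_k:
        logger.warning("only %d genes for top-%d loading selection", ds.n_genes, top_k)
    top: dict[str, list[str]] = {}
    for pc in scores.columns:
        load = loadings[pc]
        pos = sorted(load.index, key=lambda g: (-load[g], g))[:top_k]
        neg = sorted(load.index, key=lambda g: (load[g], g))[:top_k]
        top[f"{pc}_pos"] = pos
        top[f"{pc}_neg"] = neg
    return scores, loadings, top
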