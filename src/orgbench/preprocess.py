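"""Normalization, gene filtering, and CV-based gene selection.

Conventions pinned down here (they matter for reproducing the analytic
gene counts downstream):

- quantiles use linear interpolation between order statistics,
  ``h = (n - 1) * p / 100 + 1`` in 1-based rank space;
- the CV threshold is strict (``>``), so for ``n`` distinct values the
  retained count is ``n - floor(h)`` when ``h`` is fractional and
  ``n - h`` when it is an integer;
- "log-transformed" always means ``log2(x + 1)``.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from orgbench.dataset import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "to_cpm",
    "to_fpkm",
    "filter_by_expression",
    "filter_by_biotype",
    "select_high_cv",
    "cv_retained_count",
    "tmm_factors",
    "tmm_log2_cpm",
    "stage_means",
]


def to_cpm(ds: ExpressionDataset, libsize: pd.Series | None = None) -> ExpressionDataset:
    """Counts-per-million: ``counts / libsize * 1e6`` per sample.

    ``libsize`` defaults to the current column sums; passing the original
    library sizes makes CPM commute with identity-only gene filters.
    """
    if ds.unit != "counts":
        raise ValueError(f"to_cpm expects counts, got {ds.unit}")
    colsums = libsize if libsize is not None else ds.matrix.sum(axis=0)
    if (colsums <= 0).any():
        bad = colsums.index[colsums <= 0].tolist()
        raise ValueError(f"zero library size for sample(s) {bad}")
    return ds.with_matrix(ds.matrix / colsums * 1e6, unit="CPM")


def to_fpkm(ds: ExpressionDataset, lengths: pd.Series | None = None) -> ExpressionDataset:
    """Fragments per kilobase per million: counts / (libsize/1e6) / (len/1e3)."""
    if ds.unit != "counts":
        raise ValueError(f"to_fpkm expects counts, got {ds.unit}")
    if lengths is None:
        if "length_bp" not in ds.gene_meta:
            raise ValueError("gene lengths unavailable (no length_bp in gene_meta)")
        lengths = ds.gene_meta["length_bp"]
    lengths = lengths.reindex(ds.genes)
    if lengths.isna().any() or (lengths <= 0).any():
        bad = lengths.index[lengths.isna() | (lengths <= 0)].tolist()
        raise ValueError(f"missing/zero length for gene(s) {bad[:5]}")
    colsums = ds.matrix.sum(axis=0)
    if (colsums <= 0).any():
        raise ValueError("zero library size")
    fpkm = ds.matrix.div(colsums / 1e6, axis=1).div(lengths / 1e3, axis=0)
    return ds.with_matrix(fpkm, unit="FPKM")


def filter_by_expression(
    ds: ExpressionDataset,
    min_value: float,
    min_fraction_or_count: float,
    unit: str,
    mode: str = "ge",
) -> ExpressionDataset:
    """Keep genes exceeding ``min_value`` in enough samples.

    ``min_fraction_or_count`` is a sample fraction when in (0, 1] and an
    absolute sample count when >= 1 (integers >= 1 are counts; use e.g.
    0.25 for "a quarter of the samples").  ``mode`` selects the boundary
    semantics: ``"ge"`` for *at least* rules, ``"gt"`` for *higher than*
    rules.
    """
    if ds.unit != unit:
        raise ValueError(f"dataset unit {ds.unit} does not match requested {unit}")
    if mode not in ("ge", "gt"):
        raise ValueError("mode must be 'ge' or 'gt'")
    if min_fraction_or_count <= 0:
        raise ValueError("min_fraction_or_count must be positive")
    if min_fraction_or_count < 1:
        n_required = math.ceil(min_fraction_or_count * ds.n_samples)
    else:
        n_required = int(min_fraction_or_count)
    values = ds.matrix.to_numpy()
    hits = (values >= min_value) if mode == "ge" else (values > min_value)
    keep = hits.sum(axis=1) >= n_required
    return ds.with_matrix(ds.matrix.loc[keep])


def filter_by_biotype(ds: ExpressionDataset, keep: set[str]) -> ExpressionDataset:
    """Keep genes whose biotype is in ``keep``."""
    if "biotype" not in ds.gene_meta:
        raise ValueError("gene_meta has no biotype column")
    mask = ds.gene_meta["biotype"].isin(keep)
    if not mask.any():
        raise ValueError(f"no genes left after biotype filter {sorted(keep)}")
    return ds.with_matrix(ds.matrix.loc[mask.to_numpy()])


def cv_retained_count(n: int, percentile: float) -> int:
    """Closed-form count of distinct values strictly above the percentile.

    With ``h = (n - 1) * p / 100 + 1`` (1-based linear-interpolation rank),
    exactly ``n - floor(h)`` values exceed the threshold when ``h`` is
    fractional, and ``n - h`` when ``h`` is an integer.
    """
    h = (n - 1) * percentile / 100.0 + 1.0
    return n - math.floor(h)


def select_high_cv(ds: ExpressionDataset, percentile: float) -> ExpressionDataset:
    """Keep genes whose CV of log2 expression is strictly above a percentile.

    CV is ``sd / mean`` on the log2 values (sample sd, denominator n-1).
    Genes with non-positive mean log-expression are excluded before ranking
    (division hazard) and reported through the run log.
    """
    if ds.unit != "log2":
        raise ValueError("select_high_cv expects a log2 dataset")
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    values = ds.matrix.to_numpy()
    means = values.mean(axis=1)
    positive = means > 0
    n_excluded = int((~positive).sum())
    if n_excluded:
        logger.info("select_high_cv: excluded %d genes with non-positive mean", n_excluded)
    sub = values[positive]
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 genes with positive mean")
    cv = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    threshold = np.percentile(cv, percentile, method="linear")
    keep = cv > threshold
    if np.unique(cv).size == 1:
        logger.warning("select_high_cv: all CV values identical; %d genes retained", keep.sum())
    kept_genes = ds.matrix.index[positive][keep]
    return ds.subset_genes(kept_genes)


def tmm_factors(
    ds: ExpressionDataset, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors.

    The reference sample is the column whose upper quartile of library-
    scaled counts is closest to the mean upper quartile.  For each sample,
    M and A values against the reference are computed over genes positive
    in both; the lowest and highest ``floor(n * trim_m)`` genes by M and
    ``floor(n * trim_a)`` by A are discarded, and the factor is
    ``2**(weighted mean M)`` with inverse asymptotic-variance weights.
    Factors are rescaled to geometric mean 1.
    """
    if ds.unit != "counts":
        raise ValueError("tmm_factors expects counts")
    if ds.n_samples < 2:
        raise ValueError("need at least 2 samples")
    counts = ds.matrix.to_numpy(dtype=float)
    libsizes = counts.sum(axis=0)
    scaled = counts / libsizes
    uq = np.array([np.percentile(scaled[:, j][scaled[:, j] > 0], 75) for j in range(ds.n_samples)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(ds.n_samples)
    yr, nr = counts[:, ref], libsizes[ref]
    for j in range(ds.n_samples):
        if j == ref:
            continue
        ys, ns = counts[:, j], libsizes[j]
        both = (ys > 0) & (yr > 0)
        if not both.any():
            raise ValueError(f"sample {ds.samples[j]} shares no positive genes with reference")
        m = np.log2((ys[both] / ns) / (yr[both] / nr))
        a = 0.5 * np.log2((ys[both] / ns) * (yr[both] / nr))
        w = 1.0 / (
            (ns - ys[both]) / (ns * ys[both]) + (nr - yr[both]) / (nr * yr[both])
        )
        n = m.size
        keep = np.ones(n, dtype=bool)
        for vals, trim in ((m, trim_m), (a, trim_a)):
            k = math.floor(n * trim)
            if k > 0:
                order = np.argsort(vals, kind="stable")
                keep[order[:k]] = False
                keep[order[-k:]] = False
        if not keep.any():
            keep[:] = True
        factors[j] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=ds.samples, name="tmm_factor")


def tmm_log2_cpm(ds: ExpressionDataset) -> ExpressionDataset:
    """log2(TMM-normalized CPM + 1), the standard network/PCA input.

    TMM-corrected effective library sizes resist composition shifts (large
    co-regulated gene groups changing between stages), which plain CPM does
    not.
    """
    factors = tmm_factors(ds)
    eff = ds.matrix.sum(axis=0) * factors
    return ds.with_matrix(np.log2(ds.matrix / eff * 1e6 + 1.0), unit="log2")


def stage_means(ds: ExpressionDataset, group_key: str = "stage_label") -> pd.DataFrame:
    """Per-group gene means, columns ordered by stage_numeric.

    Returns a genes x groups DataFrame; column order follows the minimum
    ``stage_numeric`` within each group when available, otherwise the order
    of first appearance.
    """
    if group_key not in ds.sample_meta:
        raise ValueError(f"{group_key!r} not in sample metadata")
    groups = ds.sample_meta[group_key]
    if groups.isna().any():
        raise ValueError("empty/missing group labels")
    means = ds.matrix.T.groupby(groups).mean().T
    if "stage_numeric" in ds.sample_meta:
        order = (
            ds.sample_meta.groupby(groups)["stage_numeric"].min().sort_values().index
        )
        means = means[order]
    return means
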