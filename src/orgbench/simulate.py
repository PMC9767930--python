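"""Synthetic time-course, single-cell, and bulk-mixture generators.

Every generator draws all randomness from a single integer seed through one
:class:`numpy.random.Generator`; identical configs give byte-identical
output.  Ground truth (planted module labels, trend templates, time-warp
factor, mixing proportions) is returned alongside the data so downstream
stages can be scored without external references.

Count model
-----------
Counts are negative binomial with mean ``mu`` and dispersion ``phi`` such
that ``Var = mu + phi * mu**2`` (gamma-Poisson sampling).  The per-gene,
per-sample log2 mean is::

    log2 mu[g, s] = b[g] + lam[g] * f_{m(g)}(t[s]) + delta[m(g), s]

where ``b`` is the baseline, ``lam`` the module loading (0 for background
genes), ``f`` the module's trend template on normalized time ``t in [0,1]``
and ``delta`` a per-(module, sample) normal random effect that induces
within-module co-expression beyond the shared trend.  The resulting mean is
multiplied by a log-normal per-sample library-size factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from orgbench.dataset import ExpressionDataset
from orgbench.io import write_json, read_json

__all__ = [
    "TrendTemplate",
    "TEMPLATES",
    "GeneratorConfig",
    "SingleCellConfig",
    "BulkMixtureConfig",
    "SyntheticTruth",
    "simulate_reference",
    "simulate_query",
    "simulate_sc_reference",
    "simulate_bulk_mixtures",
    "module_gene_sets",
    "default_stages",
    "default_days",
]


# ---------------------------------------------------------------- templates


@dataclass(frozen=True)
class TrendTemplate:
    """Named trend on normalized time ``t in [0, 1]`` with values in [-1, 1]."""

    name: str
    f: Callable[[np.ndarray], np.ndarray]

    def __call__(self, t):
        return self.f(np.asarray(t, dtype=float))


TEMPLATES: dict[str, TrendTemplate] = {
    "up": TrendTemplate("up", lambda t: 2.0 * t - 1.0),
    "down": TrendTemplate("down", lambda t: 1.0 - 2.0 * t),
    "u_shape": TrendTemplate("u_shape", lambda t: np.cos(2.0 * np.pi * t)),
    "inverted_u": TrendTemplate("inverted_u", lambda t: -np.cos(2.0 * np.pi * t)),
    "flat": TrendTemplate("flat", lambda t: np.zeros_like(t)),
}

#: Order in which templates are assigned to planted modules 1, 2, 3, ...
_TEMPLATE_CYCLE = ("up", "down", "u_shape", "inverted_u", "flat")


def default_stages(n: int = 10, lo: float = 8.0, hi: float = 37.0) -> tuple:
    """Reference-style stage grid: ``n`` stages labeled PCW<t> over [lo, hi]."""
    times = np.linspace(lo, hi, n)
    return tuple((f"PCW{t:g}", float(t)) for t in np.round(times, 1))


def default_days(n: int = 10, lo: float = 25.0, hi: float = 200.0) -> tuple:
    """Query-style stage grid: differentiation days over [lo, hi].

    Geometrically spaced (dense early, sparse late), matching how organoid
    time-courses are sampled and keeping resolution in the fast-evolving
    phase when a warp factor > 1 compresses the program.
    """
    times = np.unique(np.round(np.geomspace(lo, hi, n)).astype(int))
    return tuple((f"Day{d}", float(d)) for d in times)


# ------------------------------------------------------------------ configs


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters for bulk time-course simulation.

    ``stages`` is an ordered sequence of (label, numeric time) pairs; the
    numeric values are min-max normalized to ``t in [0, 1]`` before template
    evaluation, making templates dataset-agnostic.
    """

    n_genes: int = 1000
    n_modules: int = 5
    genes_per_module: int = 150
    stages: Sequence[tuple[str, float]] = field(default_factory=default_stages)
    samples_per_stage: int = 4
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    loading_range: tuple[float, float] = (1.5, 2.5)
    dispersion_range: tuple[float, float] = (0.05, 0.2)
    libsize_log_mean: float = 0.0
    libsize_log_sd: float = 0.2
    module_effect_sd: float = 0.35
    flat_module_effect_sd: float = 1.2
    tau: float = 1.0
    n_lines: int = 2
    n_batches: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.samples_per_stage <= 0 or len(self.stages) == 0:
            raise ValueError("non-positive dimensions")
        if self.n_modules * self.genes_per_module > self.n_genes:
            raise ValueError("module genes exceed n_genes")
        labels = [s[0] for s in self.stages]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate stage labels")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if min(self.dispersion_range) <= 0:
            raise ValueError("dispersion must be positive")


@dataclass(frozen=True)
class SingleCellConfig:
    """Parameters for the synthetic single-cell reference."""

    n_types: int = 3
    cells_per_type: int = 200
    n_genes: int = 2000
    n_mito: int = 20
    n_ribo: int = 60
    base_log2_mean: float = 0.0
    base_log2_sd: float = 1.2
    type_effect_sd: float = 0.8
    dispersion: float = 0.3
    depth_log_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_types < 2:
            raise ValueError("need at least 2 cell types")
        if self.cells_per_type < 20:
            raise ValueError("need at least 20 cells per type")
        if self.n_mito + self.n_ribo >= self.n_genes:
            raise ValueError("special genes exceed n_genes")


@dataclass(frozen=True)
class BulkMixtureConfig:
    """Parameters for NB bulk mixtures of single-cell type means."""

    libsize: float = 1e6
    libsize_log_sd: float = 0.1
    dispersion: float = 0.1
    seed: int = 0


# -------------------------------------------------------------------- truth


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated dataset.

    ``module_of_gene`` maps every gene to a module id (0 = background);
    ``gene_params`` stores the per-gene baseline ``b``, loading ``lam`` and
    dispersion ``phi`` so that query datasets re-use the exact reference
    gene parameters.
    """

    module_of_gene: pd.Series
    template_of_module: dict[int, TrendTemplate]
    tau: float
    true_proportions: pd.DataFrame | None
    seed: int
    gene_params: pd.DataFrame | None = None

    def module_sets(self) -> dict[int, set[str]]:
        """Planted module id -> gene-id set (background excluded)."""
        out: dict[int, set[str]] = {}
        for gene, mod in self.module_of_gene.items():
            if mod != 0:
                out.setdefault(int(mod), set()).add(gene)
        return out

    def to_json(self, path: str | Path) -> None:
        obj = {
            "module_of_gene": {g: int(m) for g, m in self.module_of_gene.items()},
            "template_of_module": {str(m): t.name for m, t in self.template_of_module.items()},
            "tau": self.tau,
            "seed": self.seed,
            "true_proportions": None
            if self.true_proportions is None
            else {
                "index": list(self.true_proportions.index),
                "columns": list(self.true_proportions.columns),
                "values": self.true_proportions.to_numpy().tolist(),
            },
            "gene_params": None
            if self.gene_params is None
            else {
                "index": list(self.gene_params.index),
                "columns": list(self.gene_params.columns),
                "values": self.gene_params.to_numpy().tolist(),
            },
        }
        write_json(obj, path)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        obj = read_json(path)
        props = obj["true_proportions"]
        params = obj["gene_params"]
        return cls(
            module_of_gene=pd.Series(obj["module_of_gene"]),
            template_of_module={
                int(m): TEMPLATES[name] for m, name in obj["template_of_module"].items()
            },
            tau=obj["tau"],
            true_proportions=None
            if props is None
            else pd.DataFrame(props["values"], index=props["index"], columns=props["columns"]),
            seed=obj["seed"],
            gene_params=None
            if params is None
            else pd.DataFrame(params["values"], index=params["index"], columns=params["columns"]),
        )


def module_gene_sets(truth: SyntheticTruth, prefix: str = "module") -> dict[str, set[str]]:
    """Named planted gene sets, e.g. ``{"module1_up": {...}, ...}``."""
    out = {}
    for mod, genes in sorted(truth.module_sets().items()):
        out[f"{prefix}{mod}_{truth.template_of_module[mod].name}"] = genes
    return out


# ------------------------------------------------------------------ helpers


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Gamma-Poisson NB draw with Var = mu + phi mu^2 (phi broadcast over mu)."""
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    lam = np.where(
        phi > 1e-12,
        rng.gamma(shape=1.0 / np.maximum(phi, 1e-12), scale=np.maximum(phi, 1e-12) * mu),
        mu,
    )
    return rng.poisson(lam)


def _normalize_times(times: np.ndarray) -> np.ndarray:
    """Min-max map numeric stage values to [0, 1] (constant -> all 0.5)."""
    lo, hi = float(np.min(times)), float(np.max(times))
    if hi == lo:
        return np.full_like(times, 0.5, dtype=float)
    return (times - lo) / (hi - lo)


def _assign_modules(config: GeneratorConfig) -> tuple[pd.Index, np.ndarray, dict]:
    genes = pd.Index([f"G{i:05d}" for i in range(config.n_genes)])
    module_of_gene = np.zeros(config.n_genes, dtype=int)
    template_of_module: dict[int, TrendTemplate] = {}
    for m in range(1, config.n_modules + 1):
        start = (m - 1) * config.genes_per_module
        module_of_gene[start : start + config.genes_per_module] = m
        template_of_module[m] = TEMPLATES[_TEMPLATE_CYCLE[(m - 1) % len(_TEMPLATE_CYCLE)]]
    return genes, module_of_gene, template_of_module


def _draw_gene_params(rng: np.random.Generator, config: GeneratorConfig, module_of_gene):
    n = config.n_genes
    b = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    lam = rng.uniform(*config.loading_range, size=n)
    lam[module_of_gene == 0] = 0.0
    phi = rng.uniform(*config.dispersion_range, size=n)
    return b, lam, phi


def _simulate_counts(
    rng: np.random.Generator,
    config: GeneratorConfig,
    genes: pd.Index,
    module_of_gene: np.ndarray,
    template_of_module: Mapping[int, TrendTemplate],
    b: np.ndarray,
    lam: np.ndarray,
    phi: np.ndarray,
    t_norm: np.ndarray,
) -> ExpressionDataset:
    """Shared sampling core for reference and query simulation."""
    stages = list(config.stages)
    n_samples = len(stages) * config.samples_per_stage
    stage_labels, stage_numeric = [], []
    for label, numeric in stages:
        stage_labels += [label] * config.samples_per_stage
        stage_numeric += [numeric] * config.samples_per_stage
    t_sample = np.repeat(t_norm, config.samples_per_stage)

    # per-gene template value at each sample
    fvals = np.zeros((config.n_genes, n_samples))
    for m, tmpl in template_of_module.items():
        fvals[module_of_gene == m, :] = tmpl(t_sample)[None, :]

    # per-(module, sample) random effect; background genes get none
    delta = np.zeros((config.n_genes, n_samples))
    sds = {
        m: (config.flat_module_effect_sd if tmpl.name == "flat" else config.module_effect_sd)
        for m, tmpl in template_of_module.items()
    }
    if any(sd > 0 for sd in sds.values()):
        for m in sorted(template_of_module):
            eff = rng.normal(0.0, sds[m], size=n_samples)
            delta[module_of_gene == m, :] = eff[None, :]

    log2_mu = b[:, None] + lam[:, None] * fvals + delta
    lib = np.exp(rng.normal(config.libsize_log_mean, config.libsize_log_sd, size=n_samples))
    mu = np.exp2(log2_mu) * lib[None, :]
    counts = _nb_sample(rng, mu, phi[:, None])

    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    lines = [f"line{(i % config.n_lines) + 1}" for i in range(n_samples)]
    batches = [f"batch{((i // config.n_lines) % config.n_batches) + 1}" for i in range(n_samples)]
    sample_meta = pd.DataFrame(
        {
            "stage_label": stage_labels,
            "stage_numeric": stage_numeric,
            "line": lines,
            "batch": batches,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    gene_meta = pd.DataFrame(
        {
            "symbol": genes,
            "biotype": "protein_coding",
            "length_bp": rng.integers(500, 5000, size=config.n_genes),
        },
        index=genes,
    )
    matrix = pd.DataFrame(counts, index=genes, columns=sample_meta.index)
    return ExpressionDataset(matrix=matrix, unit="counts", sample_meta=sample_meta, gene_meta=gene_meta)


# --------------------------------------------------------------- simulators


def simulate_reference(config: GeneratorConfig) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Simulate the multi-stage reference series with planted modules."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, module_of_gene, template_of_module = _assign_modules(config)
    b, lam, phi = _draw_gene_params(rng, config, module_of_gene)
    t_norm = _normalize_times(np.array([s[1] for s in config.stages], dtype=float))
    ds = _simulate_counts(
        rng, config, genes, module_of_gene, template_of_module, b, lam, phi, t_norm
    )
    truth = SyntheticTruth(
        module_of_gene=pd.Series(module_of_gene, index=genes),
        template_of_module=template_of_module,
        tau=1.0,
        true_proportions=None,
        seed=config.seed,
        gene_params=pd.DataFrame({"b": b, "lam": lam, "phi": phi}, index=genes),
    )
    return ds, truth


def simulate_query(
    truth: SyntheticTruth,
    config: GeneratorConfig,
    tau: float,
    attenuation: Mapping[int, float] | None = None,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Simulate a query time-course re-using the reference gene parameters.

    The query sample at day ``d`` evaluates the reference template at
    ``min(1, tau * d / d_max)``: ``tau > 1`` compresses the program
    (saturating at the end of the reference axis), ``tau < 1`` slows it.
    ``attenuation`` multiplies the template amplitude of the given modules
    (a value of 0 flattens the module entirely).
    """
    config.validate()
    if truth.gene_params is None:
        raise ValueError("truth must come from simulate_reference (gene_params missing)")
    if tau <= 0:
        raise ValueError("tau must be positive")
    attenuation = dict(attenuation or {})
    known = set(truth.template_of_module)
    unknown = set(attenuation) - known
    if unknown:
        raise ValueError(f"unknown module id(s) in attenuation: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    genes = truth.module_of_gene.index
    module_of_gene = truth.module_of_gene.to_numpy()
    b = truth.gene_params["b"].to_numpy()
    lam = truth.gene_params["lam"].to_numpy().copy()
    phi = truth.gene_params["phi"].to_numpy()
    for m, a in attenuation.items():
        lam[module_of_gene == m] *= float(a)

    days = np.array([s[1] for s in config.stages], dtype=float)
    d_max = float(days.max())
    t_norm = np.minimum(1.0, tau * days / d_max)

    qconfig = replace(config, n_genes=len(genes))
    ds = _simulate_counts(
        rng, qconfig, genes, module_of_gene, truth.template_of_module, b, lam, phi, t_norm
    )
    new_truth = SyntheticTruth(
        module_of_gene=truth.module_of_gene.copy(),
        template_of_module=dict(truth.template_of_module),
        tau=float(tau),
        true_proportions=None,
        seed=config.seed,
        gene_params=pd.DataFrame({"b": b, "lam": lam, "phi": phi}, index=genes),
    )
    return ds, new_truth


def simulate_sc_reference(
    config: SingleCellConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a typed single-cell reference.

    Returns ``(counts, cell_meta, type_means)`` where ``counts`` is a dense
    genes x cells DataFrame, ``cell_meta`` carries per-cell type label, UMI
    count, detected genes and mitochondrial/ribosomal fractions, and
    ``type_means`` is the linear-scale generator mean per type (the basis
    ground truth).  Gene names are prefixed ``MT-``/``RPL``/``RPS`` for the
    configured mitochondrial and ribosomal subsets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = []
    names += [f"MT-{i}" for i in range(1, config.n_mito + 1)]
    n_rpl = config.n_ribo // 2
    names += [f"RPL{i}" for i in range(1, n_rpl + 1)]
    names += [f"RPS{i}" for i in range(1, config.n_ribo - n_rpl + 1)]
    names += [f"G{i:05d}" for i in range(config.n_genes - len(names))]
    genes = pd.Index(names)

    base = rng.normal(config.base_log2_mean, config.base_log2_sd, size=config.n_genes)
    effect = rng.normal(0.0, config.type_effect_sd, size=(config.n_genes, config.n_types))
    type_names = [f"type{k + 1}" for k in range(config.n_types)]
    type_means = pd.DataFrame(np.exp2(base[:, None] + effect), index=genes, columns=type_names)

    n_cells = config.n_types * config.cells_per_type
    cell_type = np.repeat(np.arange(config.n_types), config.cells_per_type)
    # mean-one log-normal depth factors so empirical means converge to type_means
    sd = config.depth_log_sd
    depth = np.exp(rng.normal(-0.5 * sd * sd, sd, size=n_cells))
    mu = type_means.to_numpy()[:, cell_type] * depth[None, :]
    counts_arr = _nb_sample(rng, mu, config.dispersion)

    cells = pd.Index([f"C{i:05d}" for i in range(n_cells)], name="cell_id")
    counts = pd.DataFrame(counts_arr, index=genes, columns=cells)
    umi = counts_arr.sum(axis=0)
    mito_mask = genes.str.startswith("MT-")
    ribo_mask = genes.str.startswith(("RPL", "RPS"))
    with np.errstate(invalid="ignore"):
        cell_meta = pd.DataFrame(
            {
                "cell_type": [type_names[k] for k in cell_type],
                "umi_count": umi,
                "detected_genes": (counts_arr > 0).sum(axis=0),
                "mito_frac": counts_arr[np.asarray(mito_mask)].sum(axis=0) / np.maximum(umi, 1),
                "ribo_frac": counts_arr[np.asarray(ribo_mask)].sum(axis=0) / np.maximum(umi, 1),
            },
            index=cells,
        )
    return counts, cell_meta, type_means


def simulate_bulk_mixtures(
    type_means: pd.DataFrame,
    proportions: Sequence[Sequence[float]],
    config: BulkMixtureConfig,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """NB bulk mixtures of the type means at known proportions."""
    props = np.asarray(proportions, dtype=float)
    if props.ndim != 2 or props.shape[1] != type_means.shape[1]:
        raise ValueError("proportion vectors must match the number of types")
    if (props < 0).any():
        raise ValueError("negative proportions")
    if not np.allclose(props.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("proportion vectors must each sum to 1")

    rng = np.random.default_rng(config.seed)
    mix = type_means.to_numpy() @ props.T  # genes x samples
    frac = mix / mix.sum(axis=0, keepdims=True)
    lib = config.libsize * np.exp(rng.normal(0.0, config.libsize_log_sd, size=props.shape[0]))
    mu = frac * lib[None, :]
    counts_arr = _nb_sample(rng, mu, config.dispersion)

    samples = pd.Index([f"M{i:03d}" for i in range(props.shape[0])], name="sample_id")
    sample_meta = pd.DataFrame(
        {
            "stage_label": "mixture",
            "stage_numeric": np.arange(props.shape[0], dtype=float),
            "line": "mix",
            "batch": "mix",
        },
        index=samples,
    )
    gene_meta = pd.DataFrame(
        {"symbol": type_means.index, "biotype": "protein_coding"}, index=type_means.index
    )
    ds = ExpressionDataset(
        matrix=pd.DataFrame(counts_arr, index=type_means.index, columns=samples),
        unit="counts",
        sample_meta=sample_meta,
        gene_meta=gene_meta,
    )
    truth = SyntheticTruth(
        module_of_gene=pd.Series(0, index=type_means.index),
        template_of_module={},
        tau=1.0,
        true_proportions=pd.DataFrame(props, index=samples, columns=type_means.columns),
        seed=config.seed,
        gene_params=None,
    )
    return ds, truth
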