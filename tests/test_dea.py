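import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from orgbench import dea
from orgbench.dea import DEAResult

from conftest import make_dataset


def bh_oracle(pvals):
    """Brute-force BH step-up: adjusted p_i = min over j>=rank(i) of p_(j)*n/j."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        adjusted[idx] = running
    return adjusted


class TestBhFdr:
    def test_matches_oracle_exactly(self, rng):
        p = rng.uniform(size=200)
        np.testing.assert_array_equal(dea.bh_fdr(p), bh_oracle(p))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1, max_size=40,
        )
    )
    def test_oracle_property(self, pvals):
        np.testing.assert_allclose(dea.bh_fdr(np.array(pvals)), bh_oracle(pvals))

    def test_nan_passthrough(self):
        p = np.array([0.01, np.nan, 0.5])
        out = dea.bh_fdr(p)
        assert np.isnan(out[1])
        # NaN excluded from the family: n = 2
        np.testing.assert_allclose(out[[0, 2]], bh_oracle([0.01, 0.5]))

    def test_monotone_step_up(self, rng):
        p = rng.uniform(size=100)
        out = dea.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(out[order]) >= -1e-12).all()


def _nb_counts(rng, mu, phi, shape):
    return rng.poisson(rng.gamma(1.0 / phi, phi * mu * np.ones(shape)))


@pytest.fixture(scope="module")
def null_fit():
    """Shared null simulation: 2000 genes, 4+4, phi=0.1."""
    rng = np.random.default_rng(7)
    n_genes, n = 2000, 8
    mu = rng.lognormal(5, 1, size=n_genes)
    y = _nb_counts(rng, mu[:, None], 0.1, (n_genes, n))
    counts = pd.DataFrame(
        y, index=[f"g{i}" for i in range(n_genes)], columns=[f"s{j}" for j in range(n)]
    )
    x = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], 4)])
    factors = pd.Series(1.0, index=counts.columns)
    disp = dea.estimate_dispersions(counts, x, factors)
    res = dea.nb_glm_lrt(counts, x, 1, factors, disp.shrunken)
    return rng, counts, x, factors, disp, res, mu


class TestEstimateDispersions:
    def test_poisson_counts_give_small_phi(self, rng):
        mu = rng.lognormal(5, 1, size=2000)
        y = rng.poisson(mu[:, None] * np.ones((2000, 8)))
        counts = pd.DataFrame(y, index=[f"g{i}" for i in range(2000)],
                              columns=[f"s{j}" for j in range(8)])
        x = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
        disp = dea.estimate_dispersions(counts, x, pd.Series(1.0, index=counts.columns))
        assert disp.shrunken.median() <= 0.05

    def test_nb_phi_02_recovered(self, rng):
        mu = rng.lognormal(5, 1, size=2000)
        y = _nb_counts(rng, mu[:, None], 0.2, (2000, 8))
        counts = pd.DataFrame(y, index=[f"g{i}" for i in range(2000)],
                              columns=[f"s{j}" for j in range(8)])
        x = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
        disp = dea.estimate_dispersions(counts, x, pd.Series(1.0, index=counts.columns))
        assert 0.1 <= disp.shrunken.median() <= 0.4

    def test_constant_counts_floored(self):
        counts = pd.DataFrame(
            np.full((20, 6), 50.0),
            index=[f"g{i}" for i in range(20)], columns=[f"s{j}" for j in range(6)],
        )
        x = np.ones((6, 1))
        disp = dea.estimate_dispersions(counts, x, pd.Series(1.0, index=counts.columns))
        assert (disp.shrunken >= 1e-4).all()
        assert disp.shrunken.median() <= 0.01

    def test_all_zero_gene_assigned_trend(self, rng):
        mu = rng.lognormal(5, 1, size=50)
        y = _nb_counts(rng, mu[:, None], 0.1, (50, 8)).astype(float)
        y[0] = 0.0
        counts = pd.DataFrame(y, index=[f"g{i}" for i in range(50)],
                              columns=[f"s{j}" for j in range(8)])
        x = np.ones((8, 1))
        disp = dea.estimate_dispersions(counts, x, pd.Series(1.0, index=counts.columns))
        assert np.isfinite(disp.shrunken.iloc[0]) and disp.shrunken.iloc[0] > 0


class TestNbGlmLrt:
    def test_identical_groups_zero_lfc(self):
        y = np.tile([[10.0, 20.0, 30.0, 40.0]], (5, 1))
        counts = pd.DataFrame(
            np.column_stack([y, y]),
            index=[f"g{i}" for i in range(5)], columns=[f"s{j}" for j in range(8)],
        )
        x = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
        res = dea.nb_glm_lrt(
            counts, x, 1, pd.Series(1.0, index=counts.columns), np.full(5, 0.1)
        )
        np.testing.assert_allclose(res.table["log2FC"], 0.0, atol=1e-6)

    def test_null_calibration(self, null_fit):
        *_, res, _ = null_fit[:6], null_fit[6]
        res = null_fit[5]
        p = res.table["p"].dropna()
        assert kstest(p, "uniform").statistic < 0.05
        assert 0.03 <= (p < 0.05).mean() <= 0.07

    def test_planted_fourfold_power(self, null_fit):
        rng, counts, x, factors, _, _, mu = null_fit
        y2 = counts.to_numpy().copy()
        de_idx = rng.choice(2000, 200, replace=False)
        y2[np.ix_(de_idx, np.arange(4, 8))] = _nb_counts(
            rng, 4.0 * mu[de_idx, None], 0.1, (200, 4)
        )
        counts2 = pd.DataFrame(y2, index=counts.index, columns=counts.columns)
        disp2 = dea.estimate_dispersions(counts2, x, factors)
        res2 = dea.nb_glm_lrt(counts2, x, 1, factors, disp2.shrunken)
        up, down = res2.degs(0.05, 1.0)
        de_set = {f"g{i}" for i in de_idx}
        assert len((up | down) & de_set) / 200 >= 0.8

    def test_rank_deficient_design_rejected(self):
        counts = pd.DataFrame(np.ones((3, 4)), index=list("abc"),
                              columns=[f"s{j}" for j in range(4)])
        x = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError, match="full rank"):
            dea.nb_glm_lrt(counts, x, 1, pd.Series(1.0, index=counts.columns), np.full(3, 0.1))


@pytest.fixture(scope="module")
def warped_queries():
    from orgbench.simulate import GeneratorConfig, simulate_query, simulate_reference

    base = dict(module_effect_sd=0.1, flat_module_effect_sd=0.15, loading_range=(2.5, 3.5))
    _, truth = simulate_reference(GeneratorConfig(seed=21, **base))
    days = tuple((f"Day{int(d)}", float(d)) for d in np.linspace(25, 200, 6).round())
    out = {}
    for tau, seed in [(1.0, 22), (2.0, 23)]:
        qcfg = GeneratorConfig(seed=seed, stages=days, samples_per_stage=4, **base)
        out[tau], _ = simulate_query(truth, qcfg, tau)
    return out, truth


class TestStagewiseDea:
    def test_warped_plateau_shifts_earlier(self, warped_queries):
        queries, _ = warped_queries
        plateau = {}
        for tau, query in queries.items():
            _, summary = dea.stagewise_dea(query, covariates=("line",))
            total = (summary["n_up"] + summary["n_down"]).to_numpy()
            below = np.flatnonzero(total < 0.2 * total.max())
            plateau[tau] = int(below.min()) if below.size else len(total)
        assert plateau[2.0] < plateau[1.0]

    def test_identical_stages_give_no_degs(self, rng):
        mu = rng.lognormal(5, 1, size=400)
        y = _nb_counts(rng, mu[:, None], 0.05, (400, 12))
        stages = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        ds = make_dataset(y, stages=stages, lines=["l1", "l2"] * 6)
        results, summary = dea.stagewise_dea(ds, covariates=("line",), min_cpm=0.1, min_samples=1)
        total_degs = (summary["n_up"] + summary["n_down"]).sum()
        assert total_degs <= 0.01 * 400 * len(results)

    def test_monotone_modules_dominate_early_degs(self, warped_queries):
        from orgbench.overlap import fisher_overlap
        from orgbench.simulate import GeneratorConfig, simulate_query

        _, truth = warped_queries
        # flatten the non-monotonic modules so early DEGs come from the
        # monotone ones; background genes stay quiet throughout
        attenuation = {
            mod: 0.0
            for mod, template in truth.template_of_module.items()
            if template.name not in ("up", "down")
        }
        days = tuple((f"Day{int(d)}", float(d)) for d in np.linspace(25, 200, 6).round())
        qcfg = GeneratorConfig(
            seed=24, stages=days, samples_per_stage=4,
            module_effect_sd=0.1, flat_module_effect_sd=0.1, loading_range=(2.5, 3.5),
        )
        query, _ = simulate_query(truth, qcfg, 1.0, attenuation=attenuation)
        results, _ = dea.stagewise_dea(query, covariates=("line",))
        up, down = results[0].degs()
        degs = up | down
        universe = set(results[0].table.index)
        monotone = set()
        for mod, template in truth.template_of_module.items():
            if template.name in ("up", "down"):
                monotone |= set(
                    truth.module_of_gene.index[truth.module_of_gene == mod]
                )
        res = fisher_overlap(degs, monotone & universe, universe)
        assert res.odds_ratio > 3

    def test_column_order_invariance(self, rng):
        mu = rng.lognormal(5, 1, size=200)
        y = _nb_counts(rng, mu[:, None], 0.1, (200, 8))
        y[:40, 4:] *= 4
        stages = ["a"] * 4 + ["b"] * 4
        ds = make_dataset(y, stages=stages)
        results1, summary1 = dea.stagewise_dea(ds, covariates=())
        perm = rng.permutation(ds.n_samples)
        shuffled = ds.subset_samples(ds.samples[perm])
        results2, summary2 = dea.stagewise_dea(shuffled, covariates=())
        pd.testing.assert_frame_equal(summary1, summary2)
        pd.testing.assert_frame_equal(
            results1[0].table.sort_index(), results2[0].table.sort_index()
        )

    def test_single_sample_stage_skipped(self, rng):
        y = _nb_counts(rng, 100.0, 0.1, (50, 5))
        ds = make_dataset(y, stages=["a", "a", "b", "b", "c"])
        results, summary = dea.stagewise_dea(ds, covariates=(), min_cpm=0.1, min_samples=1)
        assert len(results) == 1  # c vs b dropped
        assert results[0].contrast == ("b", "a")


class TestQuadrants:
    def _result(self, genes, lfcs, fdrs):
        table = pd.DataFrame(
            {"log2FC": lfcs, "p": fdrs, "fdr": fdrs,
             "mean_cpm": 10.0, "converged": True},
            index=pd.Index(genes, name="gene"),
        )
        return DEAResult(contrast=("b", "a"), table=table)

    def test_quadrant_signs(self):
        res_a = self._result(["g1"], [2.0], [0.001])
        res_b = self._result(["g1"], [1.5], [0.001])
        out = dea.consecutive_fc_quadrants(res_a, res_b)
        assert out.loc["g1", "quadrant"] == "++"

    def test_quadrants_partition_shared_degs(self):
        genes = [f"g{i}" for i in range(8)]
        lfc_a = [2, 2, -2, -2, 2, 2, -2, -2]
        lfc_b = [2, 2, 2, 2, -2, -2, -2, -2]
        res_a = self._result(genes, lfc_a, [0.001] * 8)
        res_b = self._result(genes, lfc_b, [0.001] * 8)
        out = dea.consecutive_fc_quadrants(res_a, res_b)
        assert out["quadrant"].value_counts().to_dict() == {
            "++": 2, "+-": 2, "-+": 2, "--": 2,
        }
        assert len(out) == 8

    def test_no_shared_degs_empty(self):
        res_a = self._result(["g1"], [2.0], [0.001])
        res_b = self._result(["g1"], [2.0], [0.9])
        out = dea.consecutive_fc_quadrants(res_a, res_b)
        assert out.empty

    def test_top_k_protein_coding_by_max_abs_fc(self):
        genes = [f"g{i}" for i in range(4)]
        res_a = self._result(genes, [1.5, 3.0, 2.0, 5.0], [0.001] * 4)
        res_b = self._result(genes, [2.0, 1.1, 4.0, 1.2], [0.001] * 4)
        gene_meta = pd.DataFrame(
            {"biotype": ["protein_coding", "protein_coding", "protein_coding", "lincRNA"]},
            index=genes,
        )
        out = dea.consecutive_fc_quadrants(res_a, res_b, gene_meta=gene_meta, top_k=2)
        # ranked by max(|a|,|b|): g2=4, g1=3, g0=2; g3 excluded (not coding)
        assert set(out.index[out["top"]]) == {"g2", "g1"}


class TestTissueSpecificDegs:
    def _result(self, up, down):
        genes = sorted(up | down)
        lfc = [4.0 if g in up else -4.0 for g in genes]
        table = pd.DataFrame(
            {"log2FC": lfc, "p": 0.001, "fdr": 0.001, "mean_cpm": 1.0, "converged": True},
            index=pd.Index(genes),
        )
        return DEAResult(contrast=("x", "ipsc"), table=table)

    def test_set_subtraction(self):
        target = self._result({"A", "B", "C"}, set())
        other = self._result({"B"}, set())
        up, down = dea.tissue_specific_degs(target, [other])
        assert up == {"A", "C"} and down == set()

    def test_empty_others_identity(self):
        target = self._result({"A"}, {"Z"})
        up, down = dea.tissue_specific_degs(target, [])
        assert up == {"A"} and down == {"Z"}

    def test_union_of_overlapping_others(self):
        target = self._result({"A", "B", "C", "D"}, set())
        o1 = self._result({"A", "B"}, set())
        o2 = self._result({"B", "C"}, set())
        up, _ = dea.tissue_specific_degs(target, [o1, o2])
        assert up == {"D"}

    def test_direction_specific(self):
        target = self._result({"A"}, {"B"})
        other = self._result({"B"}, {"A"})  # same genes, opposite directions
        up, down = dea.tissue_specific_degs(target, [other])
        assert up == {"A"} and down == {"B"}
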