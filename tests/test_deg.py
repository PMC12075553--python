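"""DE engine: size factors, dispersions, NB Wald test, BH, panel selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import txclass
from txclass.containers import CountMatrix, DataError
from txclass.deg import (
    SelectionThresholds,
    bh_adjust,
    estimate_dispersions,
    estimate_size_factors,
    select_panel,
    wald_test_pair,
)


def _cm(counts: np.ndarray, labels: list[str]) -> CountMatrix:
    genes = [f"g{i}" for i in range(counts.shape[0])]
    samples = [f"s{j}" for j in range(counts.shape[1])]
    return CountMatrix(
        pd.DataFrame(counts, index=genes, columns=samples),
        pd.Series(labels, index=samples),
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([[10], [20], [5], [40]])
        cm = _cm(np.tile(col, (1, 4)), ["a", "a", "b", "b"])
        sf = estimate_size_factors(cm)
        np.testing.assert_allclose(sf.to_numpy(), 1.0)

    def test_doubled_column_doubles_factor(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 100, size=(30, 1))
        counts = np.hstack([col, 2 * col, col, col])
        cm = _cm(counts, ["a", "a", "b", "b"])
        sf = estimate_size_factors(cm)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(42)
        counts = rng.negative_binomial(5, 0.3, size=(50, 6)) + 1
        cm = _cm(counts, ["a"] * 3 + ["b"] * 3)
        sf = estimate_size_factors(cm)
        # independent re-computation straight from the definition
        geomeans = np.exp(np.log(counts).mean(axis=1))
        raw = np.array(
            [np.median(counts[:, j] / geomeans) for j in range(counts.shape[1])]
        )
        expected = raw / np.exp(np.mean(np.log(raw)))
        np.testing.assert_allclose(sf.to_numpy(), expected, rtol=1e-12)

    def test_no_universally_expressed_gene_is_an_error(self):
        counts = np.array([[0, 5, 5], [5, 0, 5], [5, 5, 0]])
        cm = _cm(counts, ["a", "a", "b"])
        with pytest.raises(DataError, match="pre-filter"):
            estimate_size_factors(cm)


class TestDispersions:
    def test_poisson_gene_hits_the_floor_region(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50.0, size=(200, 400))
        cm = _cm(counts, ["a"] * 200 + ["b"] * 200)
        sf = pd.Series(1.0, index=cm.counts.columns)
        disp = estimate_dispersions(cm, sf)
        assert np.median(disp) < 0.01

    def test_known_dispersion_recovered_within_band(self):
        rng = np.random.default_rng(0)
        alpha, mu, n = 0.2, 100.0, 200
        r = 1.0 / alpha
        counts = rng.negative_binomial(r, r / (r + mu), size=(50, 2 * n))
        cm = _cm(counts, ["a"] * n + ["b"] * n)
        sf = pd.Series(1.0, index=cm.counts.columns)
        disp = estimate_dispersions(cm, sf)
        assert 0.1 < np.median(disp) < 0.4

    def test_constant_gene_floors(self):
        counts = np.full((3, 8), 7)
        cm = _cm(counts, ["a"] * 4 + ["b"] * 4)
        sf = pd.Series(1.0, index=cm.counts.columns)
        disp = estimate_dispersions(cm, sf)
        np.testing.assert_allclose(disp.to_numpy(), 1e-8)

    def test_single_sample_group_rejected(self):
        cm = _cm(np.ones((3, 3), dtype=int), ["a", "a", "b"])
        sf = pd.Series(1.0, index=cm.counts.columns)
        with pytest.raises(DataError, match="fewer than 2"):
            estimate_dispersions(cm, sf)


class TestWald:
    def _fixture(self, lfc=3.0, alpha=0.05, n=20, n_null=30, seed=0):
        rng = np.random.default_rng(seed)
        r = 1.0 / alpha
        mu_a = np.full(n_null + 1, 100.0)
        mu_b = mu_a.copy()
        mu_b[0] *= 2.0**lfc  # first gene is the spiked one
        counts = np.hstack(
            [
                rng.negative_binomial(r, r / (r + mu_a[:, None]), size=(n_null + 1, n)),
                rng.negative_binomial(r, r / (r + mu_b[:, None]), size=(n_null + 1, n)),
            ]
        )
        cm = _cm(counts, ["a"] * n + ["b"] * n)
        sf = pd.Series(1.0, index=cm.counts.columns)
        disp = pd.Series(alpha, index=cm.counts.index)
        return cm, sf, disp

    def test_identical_groups_give_null_result(self):
        counts = np.tile(np.array([[20], [50], [80]]), (1, 8))
        cm = _cm(counts, ["a"] * 4 + ["b"] * 4)
        sf = pd.Series(1.0, index=cm.counts.columns)
        disp = pd.Series(0.05, index=cm.counts.index)
        table = wald_test_pair(cm, sf, disp, "a", "b")
        np.testing.assert_allclose(table["log2FC"], 0.0, atol=1e-10)
        np.testing.assert_allclose(table["pvalue"], 1.0, atol=1e-9)

    def test_spiked_gene_recovered(self):
        cm, sf, disp = self._fixture()
        table = wald_test_pair(cm, sf, disp, "a", "b").set_index("gene")
        assert abs(table.loc["g0", "log2FC"] - 3.0) < 0.7
        assert table.loc["g0", "padj"] < 0.05

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(1)
        alpha, n = 0.05, 30
        r = 1.0 / alpha
        counts = rng.negative_binomial(r, r / (r + 100.0), size=(2000, 2 * n))
        cm = _cm(counts, ["a"] * n + ["b"] * n)
        sf = pd.Series(1.0, index=cm.counts.columns)
        disp = estimate_dispersions(cm, sf)
        table = wald_test_pair(cm, sf, disp, "a", "b")
        frac = (table["pvalue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_group_swap_negates_lfc_and_preserves_p(self):
        cm, sf, disp = self._fixture(seed=3)
        t_ab = wald_test_pair(cm, sf, disp, "a", "b")
        t_ba = wald_test_pair(cm, sf, disp, "b", "a")
        np.testing.assert_allclose(t_ab["log2FC"], -t_ba["log2FC"], atol=1e-6)
        np.testing.assert_allclose(t_ab["pvalue"], t_ba["pvalue"], atol=1e-9)

    def test_agrees_with_statsmodels_glm(self):
        """Independent oracle: per-gene NB GLM fit by statsmodels."""
        import statsmodels.api as sm

        cm, sf, disp = self._fixture(n=15, n_null=10, seed=5)
        table = wald_test_pair(cm, sf, disp, "a", "b").set_index("gene")
        x = (cm.labels == "b").to_numpy(dtype=float)
        design = np.column_stack([np.ones_like(x), x])
        for gene in ["g0", "g1", "g2", "g3"]:
            y = cm.counts.loc[gene].to_numpy(dtype=float)
            fam = sm.families.NegativeBinomial(alpha=float(disp[gene]))
            fit = sm.GLM(y, design, family=fam, offset=np.log(sf.to_numpy())).fit()
            assert table.loc[gene, "log2FC"] == pytest.approx(
                fit.params[1] / np.log(2.0), abs=1e-4
            )
            assert table.loc[gene, "wald_stat"] == pytest.approx(
                fit.tvalues[1], rel=1e-3
            )


class TestBH:
    def test_single_value_identity(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_matches_quadratic_brute_force(self, pvals):
        q = bh_adjust(pvals)
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p, kind="stable")
        expected = np.empty(m)
        for rank_i, idx in enumerate(order):
            candidates = [
                p[order[j]] * m / (j + 1) for j in range(rank_i, m)
            ]
            expected[idx] = min(1.0, min(candidates))
        np.testing.assert_allclose(q, expected, rtol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_p(self, pvals):
        q = bh_adjust(pvals)
        p = np.asarray(pvals)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_nan_rejected(self):
        with pytest.raises(DataError):
            bh_adjust([0.1, np.nan])


class TestPanel:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "contrast", "log2FC", "padj"])

    def test_single_contrast_hit_included_with_provenance(self):
        t1 = self._table([("gX", "c1", 2.5, 0.01), ("gY", "c1", 0.5, 0.01)])
        t2 = self._table([("gX", "c2", 0.1, 0.9), ("gY", "c2", 0.2, 0.9)])
        panel = select_panel([t1, t2])
        assert panel.genes == ["gX"]
        assert panel.provenance["gX"] == ["c1"]

    def test_boundary_lfc_excluded_strictly(self):
        t = self._table([("gX", "c1", 2.0, 0.001), ("gY", "c1", -2.0001, 0.001)])
        panel = select_panel([t])
        assert panel.genes == ["gY"]

    def test_order_invariance(self):
        rows = [("gB", "c1", 3.0, 0.01), ("gA", "c1", -2.5, 0.02), ("gC", "c1", 4.0, 0.03)]
        p1 = select_panel([self._table(rows)])
        p2 = select_panel([self._table(rows[::-1])])
        assert p1.genes == p2.genes

    def test_empty_panel_is_an_error(self):
        t = self._table([("gX", "c1", 0.5, 0.5)])
        with pytest.raises(DataError, match="no gene"):
            select_panel([t])

    def test_recovery_on_spiked_cohort(self):
        spec = txclass.CohortSpec(
            n_genes=1000,
            class_sizes=(20, 20, 20),
            spike_fraction=0.05,
            spike_log2fc=3.0,
            seed=0,
        )
        cm, truth = txclass.simulate_counts(spec)
        _, panel, _, _ = txclass.run_deg(cm)
        spiked = set(truth.table.loc[truth.table["is_de"], "gene"])
        recovered = spiked & set(panel.genes)
        assert len(recovered) / len(spiked) >= 0.9

    def test_all_null_cohort_yields_tiny_panel(self):
        spec = txclass.CohortSpec(
            n_genes=2000, class_sizes=(30, 30, 30), spike_fraction=0.0, seed=0
        )
        cm, _ = txclass.simulate_counts(spec)
        try:
            _, panel, _, _ = txclass.run_deg(cm)
            n_panel = len(panel)
        except DataError:
            n_panel = 0  # empty panel: even stricter than the 1% bound
        assert n_panel <= 20


def test_thresholds_validate():
    with pytest.raises(DataError):
        SelectionThresholds(lfc_min=0.0)
    with pytest.raises(DataError):
        SelectionThresholds(alpha=1.5)
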