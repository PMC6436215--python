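import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from drugmod import correlation, synthetic
from drugmod.exceptions import ValidationError


def _table(zvalues: dict, cutoff=3.2):
    z = pd.DataFrame(zvalues).T  # drugs x genes
    n = pd.DataFrame(100, index=z.index, columns=z.columns)
    return correlation.CorrelationTable(zcor=z, n=n, cutoff=cutoff)


class TestFisherZ:
    def test_closed_form(self):
        # r=0.5, n=100 -> atanh(0.5) * sqrt(97) ~ 5.41
        assert correlation.fisher_z(0.5, 100) == pytest.approx(
            np.arctanh(0.5) * np.sqrt(97))
        assert correlation.fisher_z(0.5, 100) == pytest.approx(5.41, abs=0.01)

    def test_zero_correlation_maps_to_zero(self):
        for n in (4, 50, 1000):
            assert correlation.fisher_z(0.0, n) == 0.0

    @given(st.floats(min_value=-0.99, max_value=0.99),
           st.integers(min_value=4, max_value=500))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, r, n):
        assert correlation.fisher_z(-r, n) == pytest.approx(
            -correlation.fisher_z(r, n))

    @given(st.floats(min_value=0.01, max_value=0.95),
           st.floats(min_value=0.01, max_value=0.95),
           st.integers(min_value=4, max_value=400))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_r_and_n(self, r1, r2, n):
        lo, hi = sorted((r1, r2))
        if hi > lo:
            assert correlation.fisher_z(lo, n) < correlation.fisher_z(hi, n)
        assert correlation.fisher_z(hi, n) < correlation.fisher_z(hi, n + 10)


class TestComputeZcor:
    def test_matches_direct_computation(self, small_expression,
                                        small_response):
        tab = correlation.compute_zcor(small_expression, small_response)
        drug, gene = "d2", "G3"
        x = small_expression.loc[gene]
        y = small_response.loc[drug]
        r = np.corrcoef(x, y)[0, 1]
        expected = np.arctanh(r) * np.sqrt(len(y) - 3)
        assert tab.zcor.at[drug, gene] == pytest.approx(expected)

    def test_missing_cells_reduce_n(self, small_expression, small_response):
        tab = correlation.compute_zcor(small_expression, small_response)
        assert tab.n.at["d1", "G0"] == 4  # one NaN potency
        assert tab.n.at["d2", "G0"] == 5

    def test_too_few_cells_gives_missing(self, small_expression):
        resp = pd.DataFrame([[1.0, 2.0, np.nan, np.nan, np.nan]],
                            index=["d"], columns=small_expression.columns)
        tab = correlation.compute_zcor(small_expression, resp)
        assert tab.zcor.loc["d"].isna().all()

    def test_zero_variance_gene_missing(self, small_response):
        expr = pd.DataFrame([[7.0] * 5], index=["flat"],
                            columns=small_response.columns)
        tab = correlation.compute_zcor(expr, small_response)
        assert tab.zcor["flat"].isna().all()

    def test_back_transform_stays_below_one(self, small_expression,
                                            small_response):
        tab = correlation.compute_zcor(small_expression, small_response)
        r = tab.r().to_numpy()
        assert np.nanmax(np.abs(r)) < 1.0


class TestCallSignificant:
    def test_boundary_rules(self):
        tab = _table({"d": {"a": 3.3, "b": 3.2, "c": -5.0, "e": -3.2}})
        sig = correlation.call_significant(tab)
        assert sig.positive["d"] == {"a"}
        assert sig.negative["d"] == {"c"}

    def test_pcg_ncg_disjoint(self, rng):
        z = {f"g{i}": v for i, v in
             enumerate(rng.normal(0, 4, size=200))}
        sig = correlation.call_significant(_table({"d": z}))
        assert not sig.positive["d"] & sig.negative["d"]


class TestFcgs:
    def test_degenerate_counts_give_no_fcgs(self):
        sig = correlation.SignificantSets(
            positive={f"d{i}": {f"g{i}"} for i in range(10)}, negative={})
        fcgs = correlation.find_fcgs(sig)
        assert fcgs.positive == frozenset()

    def test_bruteforce_quantile_case(self):
        # counts [1]*9 + [20]: 95% quantile is between 1 and 20, so only
        # the count-20 gene strictly exceeds it
        positive = {}
        for d in range(20):
            positive[f"d{d:02d}"] = {"hub"} | ({f"g{d}"} if d < 9 else set())
        sig = correlation.SignificantSets(positive=positive, negative={})
        fcgs = correlation.find_fcgs(sig, tail=0.05)
        assert fcgs.positive == frozenset({"hub"})
        counts = sorted(fcgs.positive_counts[fcgs.positive_counts >= 1])
        assert counts == [1] * 9 + [20]
        assert fcgs.threshold_positive == pytest.approx(
            np.quantile(counts, 0.95))

    def test_promiscuous_genes_fully_flagged(self):
        g, truth = synthetic.generate_interactome(
            n_nodes=600, n_planted=4, module_size=20, n_low_expression=40,
            seed=21)
        panel = synthetic.generate_panel(truth, n_cells=300, noise_sd=1.0,
                                         confound_shift=0.0, seed=21)
        tab = correlation.compute_zcor(panel.expression, panel.response)
        sig = correlation.call_significant(tab)
        fcgs = correlation.find_fcgs(sig, genes=tab.genes)
        assert truth.promiscuous_positive <= fcgs.positive
        assert truth.promiscuous_negative <= fcgs.negative

    def test_removal_shrinks_by_exact_overlap(self, rng):
        sig = correlation.SignificantSets(
            positive={"d": {"a", "b", "c"}}, negative={"d": {"x", "y"}})
        fcgs = correlation.FcgSets(
            positive=frozenset({"b"}), negative=frozenset({"x"}),
            positive_counts=pd.Series(dtype=float),
            negative_counts=pd.Series(dtype=float))
        out = correlation.remove_fcgs(sig, fcgs)
        assert out.positive["d"] == {"a", "c"}
        assert out.negative["d"] == {"y"}


class TestTissueZcor:
    def test_single_tissue_equals_global(self, small_expression,
                                         small_response):
        tissues = pd.Series("T1", index=small_expression.columns)
        tables, _ = correlation.tissue_zcor(small_expression, small_response,
                                            tissues)
        global_tab = correlation.compute_zcor(small_expression,
                                              small_response, min_n=4)
        pd.testing.assert_frame_equal(tables["T1"].zcor, global_tab.zcor)

    def test_tiny_tissue_skipped(self, small_expression, small_response):
        labels = ["T1", "T1", "T1", "T1", "T2"]
        tissues = pd.Series(labels, index=small_expression.columns)
        tables, _ = correlation.tissue_zcor(small_expression, small_response,
                                            tissues)
        assert "T2" not in tables

    def test_sign_agreement_without_tissue_effects(self):
        g, truth = synthetic.generate_interactome(
            n_nodes=500, n_planted=3, module_size=20, n_low_expression=30,
            seed=13)
        panel = synthetic.generate_panel(truth, n_cells=300, noise_sd=0.5,
                                         confound_shift=0.0, tissue_sd=0.0,
                                         n_tissues=4, seed=13)
        _, report = correlation.tissue_zcor(panel.expression, panel.response,
                                            panel.tissues)
        assert report.sign_agrees.mean() >= 0.95


class TestTargetCorrelationZ:
    def test_top_gene_target_strongly_positive(self, rng):
        z = {f"g{i:03d}": v for i, v in enumerate(rng.normal(size=1000))}
        top = max(z, key=z.get)
        z[top] = 10.0
        tab = _table({"d": z})
        out = correlation.target_correlation_z(tab, {"d": {top}}, seed=0)
        assert out["d"] > 1.9

    def test_observed_at_null_mean_is_zero(self):
        tab = _table({"d": {f"g{i}": 1.0 for i in range(50)}})
        out = correlation.target_correlation_z(tab, {"d": {"g0"}}, seed=0)
        assert out["d"] == pytest.approx(0.0)

    def test_same_seed_same_result(self, rng):
        z = {f"g{i}": v for i, v in enumerate(rng.normal(size=200))}
        tab = _table({"d": z, "e": z})
        out = correlation.target_correlation_z(tab, {"d": {"g5"}, "e": {"g5"}},
                                               seed=7)
        out2 = correlation.target_correlation_z(tab, {"d": {"g5"}, "e": {"g5"}},
                                                seed=7)
        assert out["d"] == out2["d"]

    def test_absent_targets_skip_drug(self, rng):
        z = {f"g{i}": v for i, v in enumerate(rng.normal(size=20))}
        tab = _table({"d": z})
        out = correlation.target_correlation_z(tab, {"d": {"missing"}}, seed=0)
        assert "d" not in out.index
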