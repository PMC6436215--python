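import numpy as np
import pandas as pd
import pytest

from drugmod import prediction, synthetic
from drugmod.exceptions import ValidationError
from drugmod.io import DrugModule


class TestZscoreGenes:
    def test_two_cell_hand_case_population_sd(self):
        expr = pd.DataFrame([[1.0, 3.0]], index=["g"], columns=["c1", "c2"])
        z = prediction.zscore_genes(expr)
        assert list(z.loc["g"]) == [-1.0, 1.0]

    def test_rows_standardized(self, small_expression):
        z = prediction.zscore_genes(small_expression)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.to_numpy().std(axis=1, ddof=0), 1, atol=1e-12)

    def test_location_shift_invariance(self, small_expression):
        z1 = prediction.zscore_genes(small_expression)
        z2 = prediction.zscore_genes(small_expression + 5.0)
        pd.testing.assert_frame_equal(z1, z2)

    def test_zero_variance_gene_dropped(self, small_expression):
        expr = small_expression.copy()
        expr.loc["flat"] = 7.0
        z = prediction.zscore_genes(expr)
        assert "flat" not in z.index


@pytest.fixture()
def toy_panel(rng):
    genes = [f"g{i}" for i in range(40)]
    cells = [f"c{i}" for i in range(30)]
    z = pd.DataFrame(rng.standard_normal((40, 30)), index=genes,
                     columns=cells)
    pcm = DrugModule("d", "positive", 1, frozenset(genes[:8]))
    ncm = DrugModule("d", "negative", 1, frozenset(genes[8:16]))
    return z, pcm, ncm


class TestRankCells:
    def test_overexpressing_cell_ranks_first(self, toy_panel):
        z, pcm, _ = toy_panel
        z["special"] = -0.5
        z.loc[sorted(pcm.genes), "special"] = 3.0
        ranking = prediction.rank_cells_by_es(z, pcm=pcm, mode="pcm_only")
        assert ranking.index[0] == "special"

    def test_identical_modules_cancel_in_combined(self, toy_panel):
        z, pcm, _ = toy_panel
        ncm_same = DrugModule("d", "negative", 1, pcm.genes)
        ranking = prediction.rank_cells_by_es(z, pcm=pcm, ncm=ncm_same,
                                              mode="combined")
        assert np.allclose(ranking.score, 0.0, atol=1e-12)

    def test_single_module_modes_agree_with_combined(self, toy_panel):
        z, pcm, ncm = toy_panel
        only_p = prediction.rank_cells_by_es(z, pcm=pcm, mode="pcm_only")
        comb_p = prediction.rank_cells_by_es(z, pcm=pcm, mode="combined")
        pd.testing.assert_series_equal(only_p.score, comb_p.score)
        only_n = prediction.rank_cells_by_es(z, ncm=ncm, mode="ncm_only")
        comb_n = prediction.rank_cells_by_es(z, ncm=ncm, mode="combined")
        pd.testing.assert_series_equal(only_n.score, comb_n.score)

    def test_best_es_takes_maximum(self, toy_panel):
        z, pcm, ncm = toy_panel
        best = prediction.rank_cells_by_es(z, pcm=pcm, ncm=ncm,
                                           mode="best_es")
        p = prediction.rank_cells_by_es(z, pcm=pcm, mode="pcm_only")
        n = prediction.rank_cells_by_es(z, ncm=ncm, mode="ncm_only")
        expected = np.maximum(p.score.sort_index(), n.score.sort_index())
        assert np.allclose(best.score.sort_index(), expected)

    def test_requires_a_module(self, toy_panel):
        z, _, _ = toy_panel
        with pytest.raises(ValidationError):
            prediction.rank_cells_by_es(z, mode="combined")


class TestAuroc:
    def _ranking(self, scores: dict) -> pd.DataFrame:
        s = pd.Series(scores, name="score").sort_values(ascending=False)
        return s.to_frame()

    def test_perfect_concordance_is_one(self):
        cells = [f"c{i}" for i in range(20)]
        potency = pd.DataFrame([np.linspace(1, 0, 20)], index=["d"],
                               columns=cells)
        ranking = self._ranking({c: 20 - i for i, c in enumerate(cells)})
        assert prediction.evaluate_auroc(ranking, potency, "d", 5) == 1.0

    def test_reversed_ranking_is_zero(self):
        cells = [f"c{i}" for i in range(20)]
        potency = pd.DataFrame([np.linspace(1, 0, 20)], index=["d"],
                               columns=cells)
        ranking = self._ranking({c: i for i, c in enumerate(cells)})
        assert prediction.evaluate_auroc(ranking, potency, "d", 5) == 0.0

    def test_random_scores_near_half(self, rng):
        cells = [f"c{i:03d}" for i in range(200)]
        potency = pd.DataFrame([rng.standard_normal(200)], index=["d"],
                               columns=cells)
        aurocs = []
        for _ in range(100):
            ranking = self._ranking(dict(zip(cells,
                                             rng.standard_normal(200))))
            aurocs.append(prediction.evaluate_auroc(ranking, potency, "d",
                                                    25))
        assert np.mean(aurocs) == pytest.approx(0.5, abs=0.1)

    def test_auroc_invariant_under_monotone_score_transform(self, rng):
        cells = [f"c{i}" for i in range(50)]
        potency = pd.DataFrame([rng.standard_normal(50)], index=["d"],
                               columns=cells)
        raw = dict(zip(cells, rng.standard_normal(50)))
        a1 = prediction.evaluate_auroc(self._ranking(raw), potency, "d", 10)
        transformed = {c: np.exp(2 * v) for c, v in raw.items()}
        a2 = prediction.evaluate_auroc(self._ranking(transformed), potency,
                                       "d", 10)
        assert a1 == a2

    def test_too_few_measured_cells_raise(self):
        cells = ["c1", "c2", "c3"]
        potency = pd.DataFrame([[1.0, 0.5, 0.2]], index=["d"], columns=cells)
        ranking = self._ranking({c: 1.0 for c in cells})
        with pytest.raises(ValidationError):
            prediction.evaluate_auroc(ranking, potency, "d", 3)


class TestNoiselessConcordance:
    def test_balanced_noiseless_panel_gives_perfect_auroc(self):
        # in the exactly deterministic limit, the ES ranking must reproduce
        # the potency order without a single inversion
        g, truth = synthetic.generate_interactome(
            n_nodes=480, n_planted=1, module_size=30, n_promiscuous=0,
            n_low_expression=0, seed=19)
        panel = synthetic.generate_panel(
            truth, n_cells=90, noise_sd=0.0, confound_shift=0.0,
            tissue_sd=0.0, promiscuous_loading=0.0, missing_frac=0.0,
            balanced=True, seed=19)
        z = prediction.zscore_genes(panel.expression)
        drug = truth.drugs[0]
        direction = truth.module_direction[drug]
        mod = DrugModule(drug, direction, 1, truth.planted_modules[drug])
        mode = "pcm_only" if direction == "positive" else "ncm_only"
        ranking = prediction.rank_cells_by_es(
            z, pcm=mod if direction == "positive" else None,
            ncm=mod if direction == "negative" else None, mode=mode)
        for top_n in (10, 25, 50):
            assert prediction.evaluate_auroc(ranking, panel.response, drug,
                                             top_n) == 1.0
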