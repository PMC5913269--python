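"""Synthetic-panel generator: determinism, planted structure, stated errors."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riccirank.synthgen import (
    SyntheticConfig,
    make_annotations,
    make_dataset,
    make_drug_response,
    make_expression,
    make_topology,
)


class TestTopology:
    def test_two_nodes_single_edge(self):
        G = make_topology(2, attachment_m=1, seed=0)
        assert G.number_of_edges() == 1 and nx.is_connected(G)

    def test_m1_attachment_is_tree(self):
        G = make_topology(5, attachment_m=1, seed=0)
        assert G.number_of_edges() == 4 and nx.is_tree(G)

    def test_attachment_edge_count(self):
        # growth from m seed nodes adds m edges per remaining node: m * (n - m)
        G = make_topology(100, attachment_m=2, seed=1)
        assert G.number_of_edges() == 2 * 98
        assert nx.is_connected(G)

    def test_modular_blocks_connected_with_module_attrs(self):
        G = make_topology(40, "modular_blocks", n_modules=4, seed=2)
        assert nx.is_connected(G)
        mods = nx.get_node_attributes(G, "module")
        assert set(mods.values()) == {0, 1, 2, 3}

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            make_topology(5, attachment_m=5)
        with pytest.raises(ValueError):
            make_topology(1)
        with pytest.raises(ValueError):
            make_topology(5, "not_a_model")

    def test_deterministic_given_seed(self):
        a = make_topology(50, seed=9)
        b = make_topology(50, seed=9)
        assert sorted(a.edges) == sorted(b.edges)


class TestExpression:
    def test_zero_noise_same_module_perfect_correlation(self):
        G = make_topology(4, attachment_m=1, seed=0)
        expr, modules = make_expression(G, 20, n_modules=1, module_loading=1.0, noise_sd=0.0, seed=0)
        genes = list(expr.index)
        r = np.corrcoef(expr.loc[genes[0]], expr.loc[genes[1]])[0, 1]
        assert r == pytest.approx(1.0)

    def test_degenerate_constant_expression_rejected(self):
        G = make_topology(4, attachment_m=1, seed=0)
        with pytest.raises(ValueError):
            make_expression(G, 10, module_loading=0.0, noise_sd=0.0)

    def test_cross_module_correlation_small(self):
        # lambda=1, noise_sd=1, n=60: independent modules, |r| < 0.35 nearly always
        G = make_topology(8, attachment_m=1, seed=0)
        hits = 0
        n_seeds = 1000
        for seed in range(n_seeds):
            expr, modules = make_expression(G, 60, n_modules=2, seed=seed)
            by_mod = {}
            for g, m in modules.items():
                by_mod.setdefault(m, []).append(g)
            g0, g1 = by_mod[0][0], by_mod[1][0]
            r = np.corrcoef(expr.loc[g0], expr.loc[g1])[0, 1]
            hits += abs(r) < 0.35
        assert hits / n_seeds >= 0.99

    def test_within_module_correlation_near_half(self):
        # population corr = lambda^2/(lambda^2 + 1) = 0.5 at lambda = noise_sd = 1
        G = make_topology(8, attachment_m=1, seed=0)
        hits = 0
        n_seeds = 1000
        for seed in range(n_seeds):
            expr, modules = make_expression(G, 60, n_modules=2, seed=seed)
            by_mod = {}
            for g, m in modules.items():
                by_mod.setdefault(m, []).append(g)
            g0, g1 = by_mod[0][:2]
            r = np.corrcoef(expr.loc[g0], expr.loc[g1])[0, 1]
            hits += abs(r - 0.5) < 0.25
        assert hits / n_seeds >= 0.95

    def test_within_exceeds_cross_module_correlation(self):
        # one-sided paired comparison over seeds
        G = make_topology(12, attachment_m=1, seed=0)
        diffs = []
        for seed in range(100):
            expr, modules = make_expression(G, 40, n_modules=3, seed=seed)
            by_mod = {}
            for g, m in modules.items():
                by_mod.setdefault(m, []).append(g)
            within = np.corrcoef(expr.loc[by_mod[0][0]], expr.loc[by_mod[0][1]])[0, 1]
            cross = np.corrcoef(expr.loc[by_mod[0][0]], expr.loc[by_mod[1][0]])[0, 1]
            diffs.append(within - cross)
        t = stats.ttest_1samp(diffs, 0.0, alternative="greater")
        assert t.pvalue < 0.01


class TestDrugResponse:
    def make_expr(self, seed=0):
        G = make_topology(10, attachment_m=1, seed=seed)
        expr, _ = make_expression(G, 30, n_modules=2, seed=seed)
        return expr

    def test_noiseless_single_target_perfect_spearman(self):
        expr = self.make_expr()
        target = expr.index[0]
        resp, truth = make_drug_response(
            expr, effect_size=1.0, response_noise_sd=0.0, missing_rate=0.0,
            seed=0, targets={"D0": [target]},
        )
        rho = stats.spearmanr(resp.loc["D0"], expr.loc[target]).statistic
        assert rho == pytest.approx(1.0)
        assert truth["D0"] == [target]

    def test_zero_missing_rate_no_missing(self):
        expr = self.make_expr()
        resp, _ = make_drug_response(expr, n_drugs=3, missing_rate=0.0, seed=1)
        assert not resp.isna().any().any()

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            make_drug_response(self.make_expr(), missing_rate=1.0)

    def test_targets_have_stronger_association_than_nontargets(self):
        # paired comparison of mean |Spearman| over seeds
        diffs = []
        for seed in range(25):
            expr = self.make_expr(seed)
            resp, truth = make_drug_response(
                expr, n_drugs=2, targets_per_drug=2, effect_size=1.5,
                response_noise_sd=0.5, missing_rate=0.0, seed=seed,
            )
            for d in resp.index:
                targets = set(truth[d])
                t_rho = np.mean(
                    [abs(stats.spearmanr(resp.loc[d], expr.loc[g]).statistic) for g in targets]
                )
                others = [g for g in expr.index if g not in targets][:5]
                o_rho = np.mean(
                    [abs(stats.spearmanr(resp.loc[d], expr.loc[g]).statistic) for g in others]
                )
                diffs.append(t_rho - o_rho)
        assert stats.ttest_1samp(diffs, 0.0, alternative="greater").pvalue < 1e-6


class TestAnnotations:
    def test_planted_term_has_min_enrichment_p(self):
        from riccirank.enrich import hypergeom_enrich

        universe = [f"G{i:03d}" for i in range(100)]
        planted = universe[:15]
        annots, truth = make_annotations(universe, n_terms=10, term_size_range=(10, 20),
                                         planted_set=planted, seed=0)
        assert truth["enriched"]["TERM_PLANTED"]
        res = hypergeom_enrich(planted, annots, universe)
        assert res.iloc[0]["term"] == "TERM_PLANTED"

    def test_saturated_single_term_p_one(self):
        from riccirank.enrich import hypergeom_enrich

        universe = [f"G{i}" for i in range(20)]
        res = hypergeom_enrich(universe[:5], {"ALL": set(universe)}, universe)
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_determinism_and_validation(self):
        universe = [f"G{i}" for i in range(50)]
        a1, _ = make_annotations(universe, n_terms=5, term_size_range=(5, 10), seed=3)
        a2, _ = make_annotations(universe, n_terms=5, term_size_range=(5, 10), seed=3)
        assert a1 == a2
        with pytest.raises(ValueError):
            make_annotations(universe, n_terms=2, term_size_range=(5, 100))
        with pytest.raises(ValueError):
            make_annotations(universe, planted_set=["NOT_THERE"])


class TestDataset:
    def test_identical_config_identical_dataset(self):
        cfg = SyntheticConfig(n_genes=40, n_cell_lines=12, n_drugs=4, n_modules=2, seed=5)
        d1, d2 = make_dataset(cfg), make_dataset(cfg)
        pd.testing.assert_frame_equal(d1.expression, d2.expression)
        pd.testing.assert_frame_equal(d1.response, d2.response)
        assert sorted(d1.topology.edges) == sorted(d2.topology.edges)
        assert d1.truth == d2.truth

    def test_contract(self, small_dataset):
        ds = small_dataset
        assert not ds.expression.isna().any().any()
        assert nx.is_connected(ds.topology)
        assert set(ds.truth["targets"]) == set(ds.response.index)
        assert set(ds.tissue_labels) == set(ds.expression.columns)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            make_dataset(SyntheticConfig(n_genes=1))
        with pytest.raises(ValueError):
            make_dataset(SyntheticConfig(n_cell_lines=2))
        with pytest.raises(ValueError):
            make_dataset(SyntheticConfig(missing_rate=1.5))
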