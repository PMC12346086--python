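"""Knowledge-graph scoring: diffusion mechanics, evidence channels, subtype
contrast, and cross-validated edge filtering."""
import numpy as np
import pandas as pd
import pytest

from genescape import kg, synthetic
from genescape.kg import KnowledgeGraph, SubtypeSpec


def _gg_edges(pairs, conf=0.8):
    df = pd.DataFrame(pairs, columns=["source", "target"])
    df["edge_type"] = "gene-gene"
    df["confidence"] = conf
    return df


@pytest.fixture
def path_graph():
    return KnowledgeGraph(_gg_edges([("A", "B")]))


class TestDiffuse:
    def test_restart_one_returns_normalized_seeds(self):
        g = KnowledgeGraph(_gg_edges([("A", "B"), ("B", "C")]))
        x = kg.diffuse(g, {"A": 2.0, "C": 2.0}, restart=1.0)
        assert x["A"] == pytest.approx(0.5) and x["C"] == pytest.approx(0.5)

    def test_two_node_closed_form(self, path_graph):
        x = kg.diffuse(path_graph, {"A": 1.0}, restart=0.5)
        assert x["A"] == pytest.approx(2 / 3, abs=1e-9)
        assert x["B"] == pytest.approx(1 / 3, abs=1e-9)

    def test_mass_conservation_random_graphs(self):
        for seed in range(5):
            cfg = synthetic.SyntheticConfig(n_genes=80, module_size=10, seed=seed)
            edges, module = synthetic.generate_ppi(cfg)
            g = KnowledgeGraph(edges)
            x = kg.diffuse(g, {m: 1.0 for m in module if m in g.genes}, restart=0.3)
            assert x.sum() == pytest.approx(1.0, abs=1e-9)
            assert (x >= 0).all()

    def test_mass_conserved_with_dangling_nodes(self):
        # Under a strict cutoff B-C drops out, leaving C dangling.
        edges = pd.DataFrame(
            {"source": ["A", "B"], "target": ["B", "C"],
             "edge_type": "gene-gene", "confidence": [0.9, 0.1]}
        )
        g = KnowledgeGraph(edges)
        x = kg.diffuse(g, {"C": 1.0}, restart=0.4, min_confidence=0.5)
        assert x.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_seeds_rejected(self, path_graph):
        with pytest.raises(ValueError, match="zero"):
            kg.diffuse(path_graph, {}, restart=0.5)

    def test_seed_locality(self):
        g = KnowledgeGraph(_gg_edges([("A", "B"), ("B", "C"), ("C", "D")]))
        lo = kg.diffuse(g, {"A": 1.0, "C": 1.0}, restart=0.5)
        hi = kg.diffuse(g, {"A": 2.0, "C": 1.0}, restart=0.5)
        assert hi["A"] >= lo["A"]

    def test_invalid_confidence_rejected(self):
        with pytest.raises(ValueError, match="confidence"):
            KnowledgeGraph(_gg_edges([("A", "B")], conf=1.5))


class TestBaseScores:
    def test_threshold_anchor_gives_unit_score(self):
        base = kg.base_scores(["g"], {"g": kg.DEFAULT_P_REF}, None, SubtypeSpec("any"))
        assert base.loc["g", "genetic_common"] == pytest.approx(1.0)

    def test_absent_gene_scores_zero_everywhere(self):
        base = kg.base_scores(["g"], {}, None, SubtypeSpec("any"))
        assert (base.loc["g"] == 0).all()

    def test_zero_pvalue_rejected(self):
        with pytest.raises(ValueError):
            kg.base_scores(["g"], {"g": 0.0}, None, SubtypeSpec("any"))

    def test_transcriptomic_caps_at_one(self):
        de = pd.DataFrame({"gene": ["g"], "effect": [12.0], "significant": [True]})
        base = kg.base_scores(["g"], {}, de, SubtypeSpec("any"))
        assert base.loc["g", "transcriptomic"] == 1.0

    def test_aggregation_follows_subtype(self):
        # A SOD1-like gene: in the SOD1 subtype's aggregates, not the generic one.
        sod1 = SubtypeSpec("sod1", aggregation_set={"g"})
        generic = SubtypeSpec("generic")
        a = kg.base_scores(["g"], {}, None, sod1)
        b = kg.base_scores(["g"], {}, None, generic)
        assert a.loc["g", "aggregation"] == 1.0
        assert b.loc["g", "aggregation"] == 0.0


class TestScoreAll:
    def test_single_channel_biorelevance_recomputation(self):
        g = KnowledgeGraph(_gg_edges([("A", "B"), ("B", "C")]))
        base = kg.base_scores(g.genes, {}, None, SubtypeSpec("s", aggregation_set={"A"}))
        scores = kg.score_all(g, base, restart=0.5)
        diff = kg.diffuse(g, {"A": 1.0}, restart=0.5)
        diff = diff / diff.max()
        for gene in g.genes:
            expected = (base.loc[gene, "aggregation"] + diff[gene]) / 8.0
            assert scores.loc[gene, "biorelevance"] == pytest.approx(expected, abs=1e-9)

    def test_saturated_gene_reaches_upper_bound(self):
        g = KnowledgeGraph(_gg_edges([("A", "B")]))
        base = kg.base_scores(
            ["A", "B"],
            {"A": kg.DEFAULT_P_REF},
            pd.DataFrame({"gene": ["A"], "effect": [9.0], "significant": [True]}),
            SubtypeSpec("s", aggregation_set={"A"}, mutation_genes={"A"}),
        )
        scores = kg.score_all(g, base, restart=0.5)
        assert scores.loc["A", "biorelevance"] == pytest.approx(1.0)
        assert scores.index[0] == "A"

    def test_all_components_within_unit_interval(self):
        cfg = synthetic.SyntheticConfig(n_genes=60, module_size=8, seed=1)
        edges, module = synthetic.generate_ppi(cfg)
        g = KnowledgeGraph(edges)
        base = kg.base_scores(g.genes, {}, None, SubtypeSpec("s", aggregation_set=set(module)))
        scores = kg.score_all(g, base)
        numeric = scores[[c for c in scores.columns]]
        assert ((numeric >= 0) & (numeric <= 1 + 1e-12)).all().all()

    def test_subtype_toggle_touches_only_aggregation_channels(self):
        g = KnowledgeGraph(_gg_edges([("A", "B"), ("B", "C")]))
        spec_on = SubtypeSpec("on", aggregation_set={"A"}, mutation_genes={"B"})
        spec_off = SubtypeSpec("off", aggregation_set=set(), mutation_genes={"B"})
        on = kg.score_all(g, kg.base_scores(g.genes, {}, None, spec_on))
        off = kg.score_all(g, kg.base_scores(g.genes, {}, None, spec_off))
        untouched = ["genetic_common", "genetic_rare", "transcriptomic",
                     "genetic_common_diffusion", "genetic_rare_diffusion",
                     "transcriptomic_diffusion"]
        pd.testing.assert_frame_equal(on[untouched].sort_index(), off[untouched].sort_index())
        assert on.loc["A", "aggregation"] != off.loc["A", "aggregation"]


class TestCvFilter:
    def _benchmark(self, seed=0):
        cfg = synthetic.SyntheticConfig(
            n_genes=300, module_size=30, p_in=0.2, p_out=0.15,
            confidence_params=(1.0, 9.0), seed=seed,
        )
        edges, module = synthetic.generate_ppi(cfg)
        return KnowledgeGraph(edges), module

    def test_single_cutoff_returned_unchanged(self):
        g, module = self._benchmark()
        chosen, curve = kg.filter_edges_by_cv(g, module[:5], [0.4])
        assert chosen == 0.4 and len(curve) == 1

    def test_too_few_known_genes_rejected(self):
        g, module = self._benchmark()
        with pytest.raises(ValueError, match="at least 3"):
            kg.filter_edges_by_cv(g, module[:2], [0.0, 0.5])

    def test_edge_destroying_cutoff_scores_half(self):
        g, module = self._benchmark()
        with pytest.warns(UserWarning, match="removes all edges"):
            _, curve = kg.filter_edges_by_cv(g, module[:5], [2.0])
        assert curve.loc[0, "mean_auroc"] == 0.5

    def test_confidence_contrast_selects_pruning_cutoff(self):
        g, module = self._benchmark(seed=0)
        chosen, _ = kg.filter_edges_by_cv(g, module, [0.0, 0.7], restart=0.5)
        assert chosen == 0.7


def test_planted_module_recovery_small():
    cfg = synthetic.SyntheticConfig(seed=0)  # 600 genes, 30-gene module
    edges, module = synthetic.generate_ppi(cfg)
    g = KnowledgeGraph(edges)
    x = kg.diffuse(g, {m: 1.0 for m in module[:10] if m in g.genes}, restart=0.5)
    rest = [m for m in module[10:] if m in x.index]
    bg = x.drop([m for m in module if m in x.index])
    auroc = np.mean([(bg < x[m]).mean() + 0.5 * (bg == x[m]).mean() for m in rest])
    assert auroc > 0.9
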