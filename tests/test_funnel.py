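"""Evidence funnel: compilation, the color rule cascade, stage nesting,
landscape finalization, and regulator enrichment."""
import math

import numpy as np
import pandas as pd
import pytest

from genescape import funnel


def _edges(pairs, **extra):
    df = pd.DataFrame(pairs, columns=["source", "target"])
    for k, v in extra.items():
        df[k] = v
    return df


class TestCompile:
    def test_union_with_provenance(self):
        table = funnel.compile_input_genes(
            [("s1", "cnv", ["A", "B"]), ("s2", "exome", ["B", "C"])]
        )
        assert sorted(table.genes) == ["A", "B", "C"]
        assert len(table.provenance["B"]) == 2
        assert table.n_data_types()["B"] == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            funnel.compile_input_genes([])

    def test_unknown_data_type_rejected(self):
        with pytest.raises(ValueError, match="unknown data type"):
            funnel.compile_input_genes([("s", "metabolomics", ["A"])])

    def test_matches_brute_force_union(self):
        rng = np.random.default_rng(0)
        pool = [f"g{i}" for i in range(40)]
        lists = [
            (f"s{j}", ["cnv", "exome", "twas"][j % 3],
             list(rng.choice(pool, size=rng.integers(1, 15), replace=False)))
            for j in range(6)
        ]
        table = funnel.compile_input_genes(lists)
        assert set(table.genes) == set().union(*(set(g) for _, _, g in lists))


class TestColorRules:
    def test_toy_cascade_matches_manual_application(self):
        # Independent manual walk of rules 1-5 over eight archetypes.
        lists = [
            ("gwas", "gwas_gene", ["g1", "g2"]),
            ("cnv", "cnv", ["g1", "g4", "g5", "g6"]),
            ("fam", "familial_mutation", ["g3"]),
            ("twas", "twas", ["g7"]),
            ("epi", "epigenomic", ["g7"]),
        ]
        table = funnel.compile_input_genes(lists)
        colors = funnel.assign_colors(
            table,
            de_genes={"g4"},
            core_interactions={"g5": 5, "g6": 4},
            k_min=5,
            grey_genes=["g8"],
        )
        assert colors == {
            "g1": "dark_green",   # gwas + cnv
            "g2": "light_green",  # gwas only
            "g3": "light_green",  # familial mutation
            "g4": "yellow",       # cnv + differential expression
            "g5": "blue",         # cnv, 5 core partners
            "g6": "excluded",     # cnv, only 4 partners
            "g7": "dark_green",   # twas + epigenomic
            "g8": "grey",         # designated regulator
        }

    def test_empty_table_yields_empty_map(self):
        table = funnel.compile_input_genes([("s", "cnv", ["x"])])
        table.flags = table.flags.iloc[0:0]
        assert funnel.assign_colors(table, set(), {}, grey_genes=[]) == {}

    def test_grey_with_genetic_evidence_rejected(self):
        table = funnel.compile_input_genes([("s", "cnv", ["A"])])
        with pytest.raises(ValueError, match="grey"):
            funnel.assign_colors(table, set(), {}, grey_genes=["A"])


class TestStages:
    def test_toy_stage_counts(self):
        colors = {
            "g1": "dark_green", "g2": "light_green", "g3": "light_green",
            "g4": "yellow", "g7": "dark_green", "g5": "blue",
            "g6": "excluded", "g8": "grey",
        }
        cl = funnel.build_candidate_list(colors)
        assert cl.stage_sizes() == {"core": 5, "candidate": 6, "candidate_plus_grey": 7}

    def test_all_excluded_gives_empty_stages(self):
        cl = funnel.build_candidate_list({"a": "excluded", "b": "excluded"})
        assert cl.stage_sizes() == {"core": 0, "candidate": 0, "candidate_plus_grey": 0}

    def test_stage_nesting(self):
        colors = {f"g{i}": c for i, c in enumerate(
            ["dark_green", "light_green", "yellow", "blue", "grey", "excluded"])}
        cl = funnel.build_candidate_list(colors)
        assert set(cl.stage("core")) <= set(cl.stage("candidate"))
        assert set(cl.stage("candidate")) <= set(cl.stage("candidate_plus_grey"))


class TestFinalize:
    def test_fully_connected_removes_nothing(self):
        colors = {f"g{i}": "dark_green" for i in range(4)}
        cl = funnel.build_candidate_list(colors)
        pairs = [(f"g{i}", f"g{j}") for i in range(4) for j in range(i + 1, 4)]
        final = funnel.finalize_landscape(cl, _edges(pairs))
        assert final.stage("landscape") == sorted(colors)
        assert final.removed_by_color == {}

    def test_toy_hand_count(self):
        # 7 candidates, edges among the first five only, no function groups.
        colors = {f"g{i}": "yellow" for i in range(7)}
        cl = funnel.build_candidate_list(colors)
        pairs = [("g0", "g1"), ("g1", "g2"), ("g2", "g3"), ("g3", "g4")]
        final = funnel.finalize_landscape(cl, _edges(pairs))
        assert len(final.stage("landscape")) == 5
        assert final.removed_by_color == {"yellow": 2}

    def test_function_group_rescues_isolated_core_gene(self):
        colors = {"a": "dark_green", "b": "dark_green", "c": "yellow"}
        cl = funnel.build_candidate_list(colors)
        final = funnel.finalize_landscape(
            cl, _edges([("a", "b")]), function_groups={"grp": ["c"]}
        )
        assert "c" in final.stage("landscape")

    def test_grey_requires_interaction_and_is_not_rescued(self):
        colors = {"a": "dark_green", "b": "dark_green", "g": "grey"}
        cl = funnel.build_candidate_list(colors)
        final = funnel.finalize_landscape(
            cl, _edges([("a", "b")]), function_groups={"grp": ["g"]}
        )
        assert "g" not in final.stage("landscape")

    def test_removal_cascades_to_fixed_point(self):
        # b's only partner a is isolated from the rest once c drops; removal
        # must propagate so re-running removes nothing further.
        colors = {"a": "yellow", "b": "yellow", "c": "yellow"}
        cl = funnel.build_candidate_list(colors)
        final = funnel.finalize_landscape(cl, _edges([("a", "b")]))
        assert final.stage("landscape") == ["a", "b"]
        again = funnel.finalize_landscape(final, _edges([("a", "b")]))
        assert again.stage("landscape") == final.stage("landscape")


class TestEnrichment:
    def test_disjoint_targets_give_p_one(self):
        df = funnel.upstream_regulator_enrichment(
            {"a", "b"}, {"reg": {"x", "y"}}, universe_size=20
        )
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    def test_matches_exhaustive_hypergeometric_enumeration(self):
        # N=20, K=5 targets, n=5 listed, overlap 3: enumerate the mass.
        N, K, n, k = 20, 5, 5, 3
        expected = sum(
            math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1)
        ) / math.comb(N, n)
        listed = {f"t{i}" for i in range(3)} | {"u1", "u2"}
        targets = {f"t{i}" for i in range(5)}
        df = funnel.upstream_regulator_enrichment(listed, {"reg": targets}, N)
        assert df.loc[0, "overlap"] == 3
        assert df.loc[0, "p_value"] == pytest.approx(expected, rel=1e-12)

    def test_exact_match_attains_minimal_p(self):
        listed = {f"t{i}" for i in range(4)}
        df = funnel.upstream_regulator_enrichment(listed, {"reg": set(listed)}, 30)
        N, K, n = 30, 4, 4
        minimal = 1 / math.comb(N, n) * math.comb(K, K)
        assert df.loc[0, "p_value"] == pytest.approx(minimal, rel=1e-12)

    def test_universe_too_small_rejected(self):
        with pytest.raises(ValueError):
            funnel.upstream_regulator_enrichment({"a", "b", "c"}, {"r": {"x"}}, 2)
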