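"""Stage orchestration: each stage reads/writes plain-text artifacts in a
run directory and records a JSON manifest (parameters, seed, input
checksums, package version) so any two runs with the same config and seed
are byte-identical."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__, compare, fixtures, funnel, genetest, io, kg, landscape, synthetic

__all__ = [
    "run_simulate",
    "run_fixture",
    "run_funnel",
    "run_genetest",
    "run_score_landscape",
    "run_score_kg",
    "run_compare",
    "run_all",
]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest(outdir: Path, stage: str, params: dict, inputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "parameters": params,
        "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2, default=str))


def _config_from_dict(params: dict, seed: int | None) -> synthetic.SyntheticConfig:
    known = {k: v for k, v in params.items() if k in synthetic.SyntheticConfig.__dataclass_fields__}
    if "study_specs" in known:
        known["study_specs"] = [synthetic.StudySpec(**s) for s in known["study_specs"]]
    cfg = synthetic.SyntheticConfig(**known)
    if seed is not None:
        cfg.seed = seed
    return cfg


def run_simulate(outdir: Path, params: dict, seed: int | None = None) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = _config_from_dict(params, seed)
    io.write_study_lists(synthetic.generate_study_lists(cfg), outdir / "study_lists.tsv")
    synthetic.generate_de_table(cfg).to_csv(outdir / "de_table.tsv", sep="\t", index=False)
    edges, module = synthetic.generate_ppi(cfg)
    io.write_edges(edges, outdir / "ppi_edges.tsv")
    io.write_gmt({"planted_module": module}, outdir / "module.gmt")
    snps, R = synthetic.generate_snp_stats(cfg)
    snps.to_csv(outdir / "snp_stats.tsv", sep="\t", index=False)
    pd.DataFrame(R).to_csv(outdir / "ld_matrix.tsv", sep="\t", index=False, header=False)
    io.write_yaml(asdict(cfg), outdir / "config_used.yaml")
    _manifest(outdir, "simulate", {"seed": cfg.seed, **{k: v for k, v in asdict(cfg).items() if k != "study_specs"}}, [])


def run_fixture(outdir: Path) -> fixtures.ReferenceFixture:
    outdir.mkdir(parents=True, exist_ok=True)
    fx = fixtures.make_reference_fixture()
    io.write_study_lists(fx.study_lists, outdir / "study_lists.tsv")
    io.write_gmt({"de_disease_tissue": fx.de_genes, "grey_designations": fx.grey_genes},
                 outdir / "gene_sets.gmt")
    io.write_edges(fx.interaction_edges, outdir / "interactions.tsv")
    fx.scoring_annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene": g, "reason": r} for g, r in fx.exclusion_list.items()]
    ).to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
    _manifest(outdir, "fixture", {}, [outdir / "study_lists.tsv", outdir / "interactions.tsv"])
    return fx


def run_funnel(outdir: Path, k_min: int = 5) -> funnel.CandidateList:
    """Evidence funnel over the artifacts of a prior ``fixture`` (or
    compatible ``simulate``) stage in the same directory."""
    study_lists = io.read_study_lists(outdir / "study_lists.tsv")
    sets = io.read_gmt(outdir / "gene_sets.gmt")
    de = sets.get("de_disease_tissue", set())
    grey = sorted(sets.get("grey_designations", set()))
    edges = io.read_edges(outdir / "interactions.tsv")

    table = funnel.compile_input_genes(study_lists)
    core0 = funnel.provisional_core(table, de)
    counts = funnel.count_core_partners(edges, core0)
    colors = funnel.assign_colors(table, de, counts, k_min=k_min, grey_genes=grey)
    cl = funnel.build_candidate_list(colors)
    final = funnel.finalize_landscape(cl, edges, function_groups=None)

    rows = [{"gene": g, "color": colors[g]} for g in final.stage("landscape")]
    pd.DataFrame(rows).to_csv(outdir / "landscape_genes.tsv", sep="\t", index=False)
    summary = {
        "n_input_genes": len(table.genes),
        **final.stage_sizes(),
        "removed_by_color": final.removed_by_color,
    }
    (outdir / "funnel_summary.json").write_text(json.dumps(summary, indent=2))
    _manifest(outdir, "funnel", {"k_min": k_min}, [outdir / "study_lists.tsv"])
    return final


def run_genetest(outdir: Path, params: dict, seed: int | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Gene-based test over a simulated null; writes per-gene results and the
    empirical rejection rate at the nominal level."""
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = _config_from_dict(params, seed)
    snps, R = synthetic.generate_snp_stats(cfg)
    gene_z = {g: grp["z"].to_numpy() for g, grp in snps.groupby("gene", sort=True)}
    results = genetest.test_genes(gene_z, R, alpha=alpha, multiplicity="bonferroni")
    results.to_csv(outdir / "gene_test.tsv", sep="\t", index=False)
    rate = float((results["p_value"] < alpha).mean())
    (outdir / "genetest_summary.json").write_text(
        json.dumps({"n_genes": len(results), "alpha": alpha, "rejection_rate": rate}, indent=2)
    )
    _manifest(outdir, "genetest", {"seed": cfg.seed, "alpha": alpha}, [])
    return results


def run_score_landscape(outdir: Path, threshold: float = 5.0) -> list[str]:
    edges = io.read_edges(outdir / "interactions.tsv")
    annotations = pd.read_csv(outdir / "annotations.tsv", sep="\t")
    land = pd.read_csv(outdir / "landscape_genes.tsv", sep="\t")
    keep = set(land["gene"].astype(str))
    sets = io.read_gmt(outdir / "gene_sets.gmt")
    de = sets.get("de_disease_tissue", set())
    excl_df = pd.read_csv(outdir / "exclusions.tsv", sep="\t")
    exclusions = dict(zip(excl_df["gene"].astype(str), excl_df["reason"].astype(str)))

    sub_edges = edges[edges["source"].isin(keep) & edges["target"].isin(keep)]
    graph = landscape.build_landscape_graph(sub_edges, annotations[annotations["gene"].isin(keep)])
    cards = landscape.score_landscape(graph, de_genes=de)
    landscape.cards_to_frame(cards).to_csv(outdir / "scorecards.tsv", sep="\t", index=False)
    top = landscape.select_top_targets(cards, threshold=threshold, exclusion_list=exclusions)
    pd.DataFrame({"gene": top}).to_csv(outdir / "top_targets.tsv", sep="\t", index=False)
    _manifest(outdir, "score_landscape", {"threshold": threshold}, [outdir / "landscape_genes.tsv"])
    return top


def run_score_kg(
    outdir: Path,
    params: dict,
    seed: int | None = None,
    restart: float = 0.5,
    cutoffs: tuple[float, ...] = (0.0, 0.3, 0.5, 0.7),
) -> pd.DataFrame:
    """Knowledge-graph scoring on the synthetic planted-module benchmark:
    the module's first genes act as known disease genes for CV edge
    filtering, module membership drives the aggregation channel."""
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = _config_from_dict(params, seed)
    edges, module = synthetic.generate_ppi(cfg)
    graph = kg.KnowledgeGraph(edges)
    known = module[: max(3, len(module) // 3)]
    chosen, curve = kg.filter_edges_by_cv(graph, known, cutoffs, restart=restart)
    subtype = kg.SubtypeSpec("module", aggregation_set=set(module), mutation_genes=set(known))
    base = kg.base_scores(graph.genes, {}, None, subtype)
    scores = kg.score_all(graph, base, restart=restart, min_confidence=chosen)
    scores.to_csv(outdir / "kg_scores.tsv", sep="\t")
    (outdir / "kg_manifest.json").write_text(json.dumps({
        "chosen_cutoff": chosen,
        "retrieval_curve": curve.to_dict(orient="records"),
        "restart": restart,
        "seed": cfg.seed,
    }, indent=2))
    _manifest(outdir, "score_kg", {"restart": restart, "cutoffs": list(cutoffs)}, [])
    return scores


def run_compare(outdir: Path) -> compare.OverlapReport:
    """Overlap analysis on the packaged industry fixture against the funnel's
    landscape list; also merges and correlates scores when both scoring
    stages have run."""
    land = pd.read_csv(outdir / "landscape_genes.tsv", sep="\t")
    landscape_genes = sorted(land["gene"].astype(str))
    ov = fixtures.make_overlap_fixture(landscape_genes)
    report = compare.overlap_analysis(ov.landscape, ov.kg_top, ov.industry)
    out = {
        "region_sizes": report.region_sizes,
        "active_proportion": report.active_proportion,
        "fisher_odds_ratio": report.fisher_odds_ratio,
        "fisher_p": report.fisher_p,
    }
    summary: dict = {"overlap": out}

    cards_path = outdir / "scorecards.tsv"
    kg_path = outdir / "kg_scores.tsv"
    if cards_path.exists() and kg_path.exists():
        cards = pd.read_csv(cards_path, sep="\t")
        kg_scores = pd.read_csv(kg_path, sep="\t", index_col=0)
        ls = dict(zip(cards["gene"].astype(str), cards["total"]))
        ks = dict(zip(kg_scores.index.astype(str), kg_scores["biorelevance"]))
        universe = sorted(set(ls) | set(ks))
        merged = compare.merge_scores(ls, ks, universe, zero_fill=True)
        merged.to_csv(outdir / "merged_scores.tsv", sep="\t")
        try:
            r, p = compare.correlate(merged["landscape_total"], merged["biorelevance"])
            summary["correlation"] = {"pearson_r": r, "p_value": p, "n": len(merged)}
        except ValueError:
            summary["correlation"] = None
    (outdir / "comparison_summary.json").write_text(json.dumps(summary, indent=2))
    _manifest(outdir, "compare", {}, [outdir / "landscape_genes.tsv"])
    return report


def run_all(outdir: Path, params: dict, seed: int | None = None) -> dict:
    """Fixture → funnel → landscape scoring → overlap comparison."""
    run_fixture(outdir)
    final = run_funnel(outdir)
    run_score_landscape(outdir)
    report = run_compare(outdir)
    return {"stages": final.stage_sizes(), "overlap": report.region_sizes}
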