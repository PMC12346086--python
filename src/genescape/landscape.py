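"""Scoring and target selection over the curated interaction landscape.

Landscape genes are annotated with functional themes (a fixed six-theme
vocabulary), tissue/cell-type evidence, and typed interactions.  The default
additive score sums four components — theme involvement, tissue evidence
(capped), a banded connectivity score, and a differential-expression bonus —
each with configurable weight.  Top targets are the genes clearing a score
threshold (inclusive) after removing genes on an exclusion list (too generic
to pursue, or already firmly disease-linked).  A five-axis specificity
profile (regional, temporal, symptomatic, molecular, modulatory) structures
the qualitative assessment of a candidate; the molecular axis is computed
from the graph, the other four are declared annotations.
"""
from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: The six functional themes of the landscape.
THEMES: frozenset[str] = frozenset(
    {
        "organelle_transport",
        "er_ergic_golgi",
        "autophagosomal",
        "hypoxia",
        "mrnp_stress_granules",
        "microglial_regulation",
    }
)

#: Typed interaction vocabulary for landscape edges.
EDGE_TYPES: frozenset[str] = frozenset(
    {
        "binding",
        "phosphorylation",
        "activation",
        "inhibition",
        "expression_regulation",
        "ubiquitination",
        "methylation",
        "degradation",
        "transport",
        "other",
    }
)

#: Default component weights of the additive score.
DEFAULT_WEIGHTS: dict[str, float] = {
    "theme": 1.0,
    "tissue": 1.0,
    "connectivity": 1.0,
    "de": 1.0,
}

SPECIFICITY_AXES = ("regional", "temporal", "symptomatic", "molecular", "modulatory")


@dataclass(frozen=True)
class ScoreCard:
    """Per-gene component scores and their weighted total."""

    gene: str
    theme_score: float
    tissue_score: float
    connectivity_score: float
    de_score: float
    total: float
    excluded: bool = False
    exclusion_reason: str | None = None


def build_landscape_graph(
    edges: pd.DataFrame, annotations: pd.DataFrame | None = None
) -> nx.Graph:
    """Assemble the landscape graph from a typed edge list and a node table.

    ``edges`` needs ``source``/``target`` and may carry ``interaction_type``,
    ``direction`` and ``pmid`` columns (kept as edge attributes).
    ``annotations`` rows (``gene``, ``themes``, ``tissues``, ``cell_type``)
    attach node attributes; list-valued fields are ``;``-separated strings.
    """
    g = nx.Graph()
    for _, row in edges.iterrows():
        etype = str(row.get("interaction_type", "other"))
        if etype not in EDGE_TYPES:
            etype = "other"
        g.add_edge(
            str(row["source"]),
            str(row["target"]),
            interaction_type=etype,
            direction=str(row.get("direction", "undirected")),
            reference=str(row.get("pmid", "")),
        )
    if annotations is not None:
        for _, row in annotations.iterrows():
            gene = str(row["gene"])
            themes = {t for t in str(row.get("themes", "")).split(";") if t}
            tissues = {t for t in str(row.get("tissues", "")).split(";") if t}
            if gene not in g:
                g.add_node(gene)
            g.nodes[gene]["themes"] = themes
            g.nodes[gene]["tissues"] = tissues
            g.nodes[gene]["cell_type"] = str(row.get("cell_type", "motor_neuron"))
    return g


def connectivity_band(degree: int) -> float:
    """Banded connectivity component: 2 for hubs (≥10 partners), 1 for
    moderately connected genes (5–9), 0 otherwise."""
    if degree >= 10:
        return 2.0
    if degree >= 5:
        return 1.0
    return 0.0


def score_gene(
    gene: str,
    themes: Iterable[str] = (),
    tissues: Iterable[str] = (),
    de: bool = False,
    degree: int = 0,
    weights: Mapping[str, float] | None = None,
) -> ScoreCard:
    """Additive score card for one landscape gene.

    ``theme_score`` counts distinct themes (vocabulary-checked);
    ``tissue_score`` counts tissue-evidence entries capped at 3;
    ``connectivity_score`` is :func:`connectivity_band` of the landscape
    degree; ``de_score`` is 1 for differentially expressed genes.  The total
    is the weighted sum with weights defaulting to 1.
    """
    themes = set(themes)
    unknown = themes - THEMES
    if unknown:
        raise ValueError(f"unknown theme labels {sorted(unknown)}; expected one of {sorted(THEMES)}")
    if degree < 0:
        raise ValueError("degree must be nonnegative")
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    theme_score = float(len(themes))
    tissue_score = float(min(len(set(tissues)), 3))
    conn_score = connectivity_band(int(degree))
    de_score = 1.0 if de else 0.0
    total = (
        w["theme"] * theme_score
        + w["tissue"] * tissue_score
        + w["connectivity"] * conn_score
        + w["de"] * de_score
    )
    return ScoreCard(gene, theme_score, tissue_score, conn_score, de_score, total)


def score_landscape(
    graph: nx.Graph,
    de_genes: Iterable[str] = (),
    weights: Mapping[str, float] | None = None,
) -> list[ScoreCard]:
    """Score every node of an annotated landscape graph."""
    de = set(map(str, de_genes))
    return [
        score_gene(
            n,
            themes=graph.nodes[n].get("themes", set()),
            tissues=graph.nodes[n].get("tissues", set()),
            de=n in de,
            degree=graph.degree(n),
            weights=weights,
        )
        for n in sorted(graph.nodes)
    ]


def select_top_targets(
    cards: Iterable[ScoreCard],
    threshold: float = 5.0,
    exclusion_list: Mapping[str, str] | None = None,
) -> list[str]:
    """Genes with total ≥ ``threshold`` (inclusive) after exclusions.

    Exclusions are applied before thresholding and logged with their reason
    (``generic`` or ``established``), so an excluded gene never appears in
    the output regardless of its score.
    """
    exclusions = dict(exclusion_list or {})
    selected = []
    for card in cards:
        if card.gene in exclusions:
            logger.info("excluded %s (reason: %s, score %.1f)",
                        card.gene, exclusions[card.gene], card.total)
            continue
        if card.total >= threshold:
            selected.append(card.gene)
    return sorted(selected)


def specificity_profile(
    gene: str,
    declared: Mapping[str, bool],
    graph: nx.Graph,
    min_themes: int = 2,
    min_degree: int = 3,
) -> tuple[dict[str, bool], int]:
    """Five-axis target-specificity profile.

    Regional, temporal, symptomatic and modulatory specificity are read from
    the declared annotations; molecular specificity is computed from the
    landscape as involvement in at least ``min_themes`` themes combined with
    at least ``min_degree`` interactions.  Returns the profile and the count
    of satisfied axes.
    """
    if gene not in graph:
        raise ValueError(f"gene {gene} not in the landscape graph")
    themes = graph.nodes[gene].get("themes", set())
    profile = {
        axis: bool(declared.get(axis, False))
        for axis in SPECIFICITY_AXES
        if axis != "molecular"
    }
    profile["molecular"] = len(themes) >= min_themes and graph.degree(gene) >= min_degree
    profile = {axis: profile[axis] for axis in SPECIFICITY_AXES}
    return profile, sum(profile.values())


def cards_to_frame(cards: Iterable[ScoreCard]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in cards])
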