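"""Deterministic fixtures reproducing the published funnel and overlap counts.

The ALS evidence-funnel study this package models reports only aggregate
stage sizes (753 input genes narrowing to 244 core, 326 candidate, 340 with
grey additions and 293 landscape genes; per-category compositions
57/110/77/82/14; per-color isolated-gene removals 11/24/12) and the
industry-target overlap structure (217 industry targets, 27 shared with the
landscape, 15 with the knowledge-graph top list, 10 in the triple
intersection).  The fixtures here are synthetic stand-ins built to match
those printed cardinalities exactly: gene identities are artificial
(``G0001`` …) and carry no biological meaning; only the set arithmetic is
faithful.  Construction uses no randomness, so repeated calls are
byte-identical.
"""
from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field
from functools import cached_property

import pandas as pd

from .funnel import EvidenceTable, compile_input_genes

__all__ = ["ReferenceFixture", "OverlapFixture", "make_reference_fixture", "make_overlap_fixture"]


def _g(i: int) -> str:
    return f"G{i:04d}"


def _grange(lo: int, hi: int) -> list[str]:
    """Genes G<lo> … G<hi> inclusive."""
    return [_g(i) for i in range(lo, hi + 1)]


# Category layout (all ranges inclusive):
#   dark green   G0001-G0057   gene-based GWAS + CNV           (57)
#   light green  G0058-G0150   gene-based GWAS only            (93)
#                G0151-G0167   familial mutation only          (17)
#   yellow       G0168-G0244   CNV only, differentially expr.  (77)
#   blue         G0245-G0326   CNV only, 5 core partners       (82)
#   excluded     G0327-G0753   CNV only, isolated              (427)
#   grey         G0754-G0767   designated, no genetic evidence (14)
_DARK = _grange(1, 57)
_LIGHT_GWAS = _grange(58, 150)
_LIGHT_FAM = _grange(151, 167)
_YELLOW = _grange(168, 244)
_BLUE = _grange(245, 326)
_EXCL = _grange(327, 753)
_GREY = _grange(754, 767)

# Genes dropped at the landscape step (no interactions): the tail of each
# core color — 11 dark green, 24 light green, 12 yellow.
_ISOLATED = set(_grange(47, 57) + _grange(144, 167) + _grange(233, 244))

_SIX_THEMES = (
    "organelle_transport",
    "er_ergic_golgi",
    "autophagosomal",
    "hypoxia",
    "mrnp_stress_granules",
    "microglial_regulation",
)


@dataclass
class ReferenceFixture:
    """All inputs needed to run the funnel and scoring stages end to end."""

    study_lists: list[tuple[str, str, list[str]]]
    de_genes: set[str]
    grey_genes: list[str]
    interaction_edges: pd.DataFrame
    function_groups: dict[str, list[str]] = field(default_factory=dict)
    scoring_annotations: pd.DataFrame | None = None
    exclusion_list: dict[str, str] = field(default_factory=dict)
    isolated_by_color: dict[str, int] = field(default_factory=dict)

    @cached_property
    def evidence_table(self) -> EvidenceTable:
        return compile_input_genes(self.study_lists)


@dataclass
class OverlapFixture:
    """Industry-target list plus the two model top lists, with the published
    intersection cardinalities."""

    landscape: list[str]
    kg_top: list[str]
    industry: pd.DataFrame  # columns: gene, status, phase


def make_reference_fixture() -> ReferenceFixture:
    """Build the deterministic funnel fixture.

    Running the funnel on it yields stage sizes 753 → 244 → 326 → 340 → 293,
    with category compositions 57 dark green, 110 light green, 77 yellow,
    82 blue and 14 grey, and isolated-gene removals of 11/24/12 per core
    color.  Scoring annotations are laid out so that exactly 49 landscape
    genes reach a default score of at least five, two of which sit on the
    exclusion list, leaving 47 top targets.
    """
    study_lists = [
        ("magma", "gwas_gene", _DARK + _LIGHT_GWAS),
        ("cnv_meta", "cnv", _DARK + _YELLOW + _BLUE + _EXCL),
        ("familial", "familial_mutation", list(_LIGHT_FAM)),
    ]
    de_genes = set(_YELLOW)

    retained_core = [
        g for g in _DARK + _LIGHT_GWAS + _LIGHT_FAM + _YELLOW if g not in _ISOLATED
    ]
    rows: list[tuple[str, str, str, str, str]] = []
    # Chain the retained core so every member has a qualifying interaction.
    for a, b in zip(retained_core, retained_core[1:]):
        rows.append((a, b, "binding", "undirected", "synthetic"))
    # Blue genes: exactly five distinct core partners each (the hub genes).
    hubs = _DARK[:5]
    for g in _BLUE:
        for h in hubs:
            rows.append((h, g, "binding", "undirected", "synthetic"))
    # Grey additions each regulate the first hub.
    for g in _GREY:
        rows.append((g, _DARK[0], "expression_regulation", "directed", "synthetic"))
    edges = pd.DataFrame(
        rows, columns=["source", "target", "interaction_type", "direction", "pmid"]
    )

    # Annotation layout for landscape scoring: 49 richly annotated genes
    # (three themes, two tissue lines of evidence) versus a sparse rest.
    rich = set(_grange(1, 46) + _grange(58, 60))
    ann_rows = []
    landscape_universe = retained_core + _BLUE + _GREY
    for g in landscape_universe:
        if g in rich:
            themes = list(_SIX_THEMES[:3])
            tissues = ["motor_cortex", "spinal_cord"]
        else:
            themes = [_SIX_THEMES[4]]
            tissues = []
        cell = "microglia" if g in _GREY else "motor_neuron"
        ann_rows.append(
            {
                "gene": g,
                "themes": ";".join(themes),
                "tissues": ";".join(tissues),
                "cell_type": cell,
            }
        )
    annotations = pd.DataFrame(ann_rows)

    return ReferenceFixture(
        study_lists=study_lists,
        de_genes=de_genes,
        grey_genes=list(_GREY),
        interaction_edges=edges,
        function_groups={},
        scoring_annotations=annotations,
        # Analogues of a hub too generic to pursue and one already firmly
        # disease-linked; both would otherwise clear the score threshold.
        exclusion_list={_g(1): "established", _g(2): "generic"},
        isolated_by_color={"dark_green": 11, "light_green": 24, "yellow": 12},
    )


def make_overlap_fixture(landscape: Sequence[str] | None = None) -> OverlapFixture:
    """Three-way overlap fixture with the published region cardinalities.

    Regions over (industry 217, landscape 293, knowledge-graph top 293):
    triple intersection 10; landscape∩industry 27; industry∩kg-top 15 (so 5
    industry targets are on the kg list but absent from the landscape).  The
    landscape∩kg-only region (90 genes) and all remaining set sizes are
    arbitrary deterministic choices consistent with the three list sizes.

    ``landscape`` defaults to the 293 landscape genes implied by
    :func:`make_reference_fixture`; supply the list produced by an actual
    funnel run to keep everything internally consistent.
    """
    if landscape is None:
        landscape = sorted(
            g
            for g in _DARK + _LIGHT_GWAS + _LIGHT_FAM + _YELLOW + _BLUE + _GREY
            if g not in _ISOLATED
        )
    landscape = list(landscape)
    if len(landscape) != 293:
        raise ValueError(f"expected a 293-gene landscape list, got {len(landscape)}")

    triple = landscape[:10]
    land_ind_only = landscape[10:27]
    land_kg_only = landscape[27:117]  # 90 genes
    ind_kg_only = [f"X{i:04d}" for i in range(1, 6)]
    kg_only = [f"K{i:04d}" for i in range(1, 189)]
    ind_only = [f"T{i:04d}" for i in range(1, 186)]

    kg_top = triple + land_kg_only + ind_kg_only + kg_only  # 293
    industry_genes = triple + land_ind_only + ind_kg_only + ind_only  # 217

    # Development status: active-drug proportion declines from the triple
    # intersection outwards (8/10, 10/17, 3/5, 55/185).
    n_active = {"triple": 8, "land": 10, "kg": 3, "only": 55}
    phases = ["preclinical", "phase1", "phase2", "phase3", "approved"]
    rows = []
    for region, genes in (
        ("triple", triple),
        ("land", land_ind_only),
        ("kg", ind_kg_only),
        ("only", ind_only),
    ):
        for i, g in enumerate(genes):
            rows.append(
                {
                    "gene": g,
                    "status": "active" if i < n_active[region] else "inactive",
                    "phase": phases[i % len(phases)],
                }
            )
    industry = pd.DataFrame(rows)
    assert len(industry) == 217
    return OverlapFixture(landscape=landscape, kg_top=kg_top, industry=industry)
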