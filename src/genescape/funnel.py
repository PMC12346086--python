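"""Multi-omics evidence funnel for candidate-gene prioritization.

The funnel compiles gene lists from heterogeneous omics studies (gene-based
GWAS, familial mutations, exome sequencing, CNV, epigenomics, TWAS) into a
single evidence table, assigns each gene a color-coded category by an ordered
rule cascade, and narrows the input list in stages:

* ``core`` — genes with multiple evidence types (dark green), association- or
  mutation-only genes (light green), and single-evidence genes that are also
  differentially expressed in disease tissue (yellow);
* ``candidate`` — core plus genes rescued by dense interaction with the core
  set (blue);
* ``candidate_plus_grey`` — candidate plus designated non-genetic additions
  such as enriched upstream regulators (grey);
* ``landscape`` — the interacting subset after removing genes with no
  qualifying interaction and no shared-function group membership.

A generic hypergeometric upstream-regulator enrichment is included so the
regulator-designation step can be driven by any regulator→targets network.
"""
from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Recognized genomic/epigenomic evidence types. ``gwas_gene`` stands for
#: gene-based GWAS association (MAGMA/FUMA-style); the rest are literal.
DATA_TYPES: tuple[str, ...] = (
    "gwas_gene",
    "familial_mutation",
    "exome",
    "cnv",
    "epigenomic",
    "twas",
)

#: Funnel category labels, in rule-precedence order.
COLORS: tuple[str, ...] = ("dark_green", "light_green", "yellow", "blue", "grey", "excluded")

#: Colors making up the core stage (rules 1-3).
CORE_COLORS = ("dark_green", "light_green", "yellow")


@dataclass
class EvidenceTable:
    """Gene × data-type evidence matrix with per-study provenance.

    ``flags`` is a boolean DataFrame indexed by gene with one column per
    entry of :data:`DATA_TYPES`; ``provenance`` maps each gene to the
    ``(study_id, data_type)`` pairs that flagged it.  A flag is true iff at
    least one provenance entry carries that data type.
    """

    flags: pd.DataFrame
    provenance: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.flags.index)

    def n_data_types(self) -> pd.Series:
        """Number of distinct evidence types per gene."""
        return self.flags.sum(axis=1)

    def validate(self) -> None:
        if self.flags.index.has_duplicates:
            raise ValueError("duplicate genes in evidence table")
        for gene in self.flags.index:
            if not self.provenance.get(gene):
                raise ValueError(f"gene {gene} flagged without provenance")


@dataclass
class CandidateList:
    """Nested funnel stages with per-gene colors.

    Stage sets satisfy ``core ⊆ candidate ⊆ candidate_plus_grey`` and
    ``landscape ⊆ candidate_plus_grey``.
    """

    colors: dict[str, str]
    stages: dict[str, list[str]]
    removed_by_color: dict[str, int] = field(default_factory=dict)

    def stage(self, name: str) -> list[str]:
        return self.stages[name]

    def stage_sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.stages.items()}


def compile_input_genes(
    study_lists: Sequence[tuple[str, str, Iterable[str]]],
) -> EvidenceTable:
    """Union per-study gene lists into an :class:`EvidenceTable`.

    Parameters
    ----------
    study_lists
        Tuples ``(study_id, data_type, genes)``; ``data_type`` must be one of
        :data:`DATA_TYPES`.

    Raises
    ------
    ValueError
        On empty input, unknown data types, or empty gene symbols.
    """
    if not study_lists:
        raise ValueError("no study lists supplied")
    provenance: dict[str, list[tuple[str, str]]] = {}
    for study_id, data_type, genes in study_lists:
        if data_type not in DATA_TYPES:
            raise ValueError(f"unknown data type {data_type!r} (study {study_id})")
        for gene in genes:
            if not gene or not str(gene).strip():
                raise ValueError(f"empty gene symbol in study {study_id}")
            provenance.setdefault(str(gene), []).append((study_id, data_type))

    genes = sorted(provenance)
    flags = pd.DataFrame(False, index=pd.Index(genes, name="gene"), columns=list(DATA_TYPES))
    for gene, prov in provenance.items():
        for _, dtype in prov:
            flags.loc[gene, dtype] = True
    table = EvidenceTable(flags=flags, provenance=provenance)
    n_multi = int((table.n_data_types() >= 2).sum())
    logger.info("compiled %d unique genes (%d with >=2 evidence types)", len(genes), n_multi)
    return table


def count_core_partners(
    edges: pd.DataFrame, core_genes: Iterable[str]
) -> dict[str, int]:
    """Count, for every gene, its distinct interaction partners in the core set.

    Partner counting (not edge counting): parallel edges between the same
    pair contribute once.
    """
    core = set(core_genes)
    partners: dict[str, set[str]] = {}
    for s, t in zip(edges["source"].astype(str), edges["target"].astype(str)):
        if s == t:
            continue
        if t in core:
            partners.setdefault(s, set()).add(t)
        if s in core:
            partners.setdefault(t, set()).add(s)
    return {g: len(p) for g, p in partners.items()}


def provisional_core(table: EvidenceTable, de_genes: Iterable[str]) -> set[str]:
    """Genes selected by rules (1)-(3) alone — the core set against which
    interaction-based rescue (rule 4) is counted."""
    de = set(de_genes)
    ntypes = table.n_data_types()
    core: set[str] = set(ntypes.index[ntypes >= 2])
    single = ntypes.index[ntypes == 1]
    for gene in single:
        if gene in core:
            continue
        dtype = table.flags.columns[table.flags.loc[gene]].tolist()[0]
        if dtype in ("gwas_gene", "familial_mutation") or gene in de:
            core.add(gene)
    return core


def assign_colors(
    table: EvidenceTable,
    de_genes: Iterable[str],
    core_interactions: Mapping[str, int],
    k_min: int = 5,
    grey_genes: Iterable[str] = (),
) -> dict[str, str]:
    """Assign each gene exactly one funnel color by the ordered rule cascade.

    Rules, applied in order (a gene takes the earliest matching color):

    1. evidence from ≥2 distinct data types → ``dark_green``
    2. gene-based GWAS association only, or a familial mutation → ``light_green``
    3. remaining single-evidence genes that are differentially expressed in
       disease tissue → ``yellow``
    4. remaining genes with ≥ ``k_min`` distinct interaction partners in the
       core set → ``blue``
    5. designated non-genetic additions → ``grey``

    everything else → ``excluded``.

    Parameters
    ----------
    core_interactions
        Map gene → number of distinct core-set partners, e.g. from
        :func:`count_core_partners` over :func:`provisional_core`.
    grey_genes
        Designated additions without genetic evidence.  A grey designee that
        carries genetic evidence in ``table`` is an error, because grey is
        defined as "not genetically associated".
    """
    de = set(map(str, de_genes))
    grey = set(map(str, grey_genes))
    genetic = set(table.genes)
    bad = grey & genetic
    if bad:
        raise ValueError(
            f"grey-designated genes carry genetic evidence: {sorted(bad)[:5]}"
        )

    ntypes = table.n_data_types()
    colors: dict[str, str] = {}
    for gene in table.genes:
        n = int(ntypes[gene])
        if n >= 2:
            colors[gene] = "dark_green"
            continue
        dtype = table.flags.columns[table.flags.loc[gene]].tolist()[0]
        if dtype in ("gwas_gene", "familial_mutation"):
            colors[gene] = "light_green"
        elif gene in de:
            colors[gene] = "yellow"
        elif core_interactions.get(gene, 0) >= k_min:
            colors[gene] = "blue"
        else:
            colors[gene] = "excluded"
    for gene in grey:
        colors[gene] = "grey"
    return colors


def build_candidate_list(colors: Mapping[str, str]) -> CandidateList:
    """Assemble nested funnel stages from a color assignment.

    ``core`` = dark green ∪ light green ∪ yellow; ``candidate`` adds blue;
    ``candidate_plus_grey`` adds grey.  Gene order within a stage is sorted.
    """
    by_color: dict[str, list[str]] = {c: [] for c in COLORS}
    for gene in sorted(colors):
        by_color[colors[gene]].append(gene)
    core = sorted(by_color["dark_green"] + by_color["light_green"] + by_color["yellow"])
    candidate = sorted(core + by_color["blue"])
    with_grey = sorted(candidate + by_color["grey"])
    stages = {"core": core, "candidate": candidate, "candidate_plus_grey": with_grey}
    cl = CandidateList(colors=dict(colors), stages=stages)
    logger.info("funnel stages: %s", cl.stage_sizes())
    return cl


def finalize_landscape(
    candidates: CandidateList,
    interactions: pd.DataFrame,
    function_groups: Mapping[str, Iterable[str]] | None = None,
) -> CandidateList:
    """Restrict the candidate list to genes that interact in the landscape.

    Dark green, light green and yellow genes are dropped when they have no
    interaction with another retained green/yellow/blue/grey member and belong
    to no shared-function group; grey additions likewise require at least one
    interaction.  Blue genes are retained by construction (they entered via
    interaction counting).  Removal iterates to a fixed point so the result is
    idempotent: a gene whose only partners were themselves removed is removed
    too.

    Returns a new :class:`CandidateList` whose ``stages`` gains a
    ``landscape`` entry and whose ``removed_by_color`` tallies removals.
    """
    colors = candidates.colors
    # Operate on the most reduced stage available so re-running on a
    # finalized list is a no-op (idempotence).
    universe = set(candidates.stages.get("landscape", candidates.stages["candidate_plus_grey"]))
    rescued = set()
    for genes in (function_groups or {}).values():
        rescued.update(map(str, genes))

    adjacency: dict[str, set[str]] = {}
    for s, t in zip(interactions["source"].astype(str), interactions["target"].astype(str)):
        if s == t:
            continue
        if s in universe and t in universe:
            adjacency.setdefault(s, set()).add(t)
            adjacency.setdefault(t, set()).add(s)

    retained = set(universe)
    removed: dict[str, int] = {}
    changed = True
    while changed:
        changed = False
        for gene in sorted(retained):
            color = colors.get(gene, "excluded")
            if color == "blue":
                continue
            has_partner = any(p in retained for p in adjacency.get(gene, ()))
            if has_partner:
                continue
            if color in CORE_COLORS and gene in rescued:
                continue  # shared-function group keeps it
            retained.discard(gene)
            removed[color] = removed.get(color, 0) + 1
            changed = True

    stages = dict(candidates.stages)
    stages["landscape"] = sorted(retained)
    out = CandidateList(colors=dict(colors), stages=stages, removed_by_color=removed)
    logger.info("landscape: kept %d, removed %s", len(retained), removed)
    return out


def upstream_regulator_enrichment(
    gene_list: Iterable[str],
    regulator_network: Mapping[str, Iterable[str]],
    universe_size: int,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each regulator's targets in a list.

    For a regulator with ``K`` targets in a universe of ``N`` genes and an
    input list of size ``n`` overlapping ``k`` targets, the upper-tail p-value
    is ``P(X ≥ k)`` for ``X ~ Hypergeom(N, K, n)``.  P-values are
    Benjamini–Hochberg adjusted and the table is sorted ascending by p.
    """
    listed = set(map(str, gene_list))
    n = len(listed)
    if universe_size < n:
        raise ValueError("universe smaller than the input gene list")
    rows = []
    for reg, targets in regulator_network.items():
        tset = set(map(str, targets))
        if universe_size < len(tset):
            raise ValueError(f"universe smaller than target set of {reg}")
        k = len(tset & listed)
        p = float(hypergeom.sf(k - 1, universe_size, len(tset), n))
        rows.append({"regulator": reg, "n_targets": len(tset), "overlap": k, "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.sort_values("p_value", kind="mergesort", ignore_index=True)
    return df
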