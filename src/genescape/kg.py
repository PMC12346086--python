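"""Knowledge-graph target scoring with network diffusion.

A heterogeneous knowledge graph (genes, diseases, drugs; typed edges with
confidences) supplies an undirected, confidence-weighted gene–gene layer
over which evidence scores are diffused by random walk with restart (RWR).
For each gene and disease subtype the scorer computes four direct evidence
channels —

* ``genetic_common``  — scaled −log10 gene-based GWAS p-value, capped at 1
  at the genome-wide threshold;
* ``genetic_rare``    — presence of a familial mutation relevant to the
  subtype;
* ``transcriptomic``  — capped standardized differential-expression effect
  (patient tissue only);
* ``aggregation``     — reported presence in the subtype's protein
  aggregates —

plus their four diffusion counterparts (each max-normalized to [0, 1]), and
aggregates the eight into a *biorelevance* score, their arithmetic mean.
The rationale is the disease-module principle: genes near many
disease-relevant genes in the interaction network are more likely relevant
themselves, even without direct evidence.

Edge-confidence filtering is chosen by cross-validation: for each candidate
cutoff, leave-one-out retrieval of known disease genes is scored by the
held-out gene's AUROC against the background, and the cutoff with the best
mean AUROC wins (ties favor the stricter cutoff).
"""
from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "KnowledgeGraph",
    "SubtypeSpec",
    "base_scores",
    "diffuse",
    "filter_edges_by_cv",
    "score_all",
]

CHANNELS = ("genetic_common", "genetic_rare", "transcriptomic", "aggregation")

#: Default genome-wide gene-based significance threshold used to anchor the
#: genetic_common channel (0.05 over the protein-coding gene count).
DEFAULT_P_REF = 0.05 / 19427


@dataclass
class KnowledgeGraph:
    """Typed edge list plus the gene universe of its diffusion layer.

    ``edges`` columns: ``source, target, edge_type, confidence``.  Gene–gene
    and rna–protein edges form the undirected diffusion layer (self-loops
    dropped, rna–protein weights scaled by ``rna_weight``); other edge types
    (gene–disease, drug–target) ride along as annotations.
    """

    edges: pd.DataFrame
    rna_weight: float = 1.0
    _diffusion_types: tuple[str, ...] = ("gene-gene", "rna-protein")

    def __post_init__(self) -> None:
        conf = self.edges.get("confidence")
        if conf is not None:
            mask = self.edges["edge_type"].isin(self._diffusion_types)
            c = pd.to_numeric(conf[mask], errors="raise")
            if ((c <= 0) | (c > 1)).any():
                raise ValueError("edge confidences must lie in (0, 1]")

    @property
    def genes(self) -> list[str]:
        mask = self.edges["edge_type"].isin(self._diffusion_types)
        sub = self.edges[mask]
        return sorted(set(sub["source"].astype(str)) | set(sub["target"].astype(str)))

    def diffusion_layer(self, min_confidence: float = 0.0) -> tuple[sparse.csr_matrix, list[str]]:
        """Symmetric weighted adjacency of the diffusion layer.

        Edges below ``min_confidence`` are dropped; node order is the sorted
        gene universe of the *unfiltered* layer so score vectors stay
        comparable across cutoffs.
        """
        genes = self.genes
        index = {g: i for i, g in enumerate(genes)}
        mask = self.edges["edge_type"].isin(self._diffusion_types)
        sub = self.edges[mask]
        conf = sub["confidence"].to_numpy(dtype=float)
        w = np.where(sub["edge_type"].to_numpy() == "rna-protein", self.rna_weight, 1.0) * conf
        keep = conf >= min_confidence
        src = sub["source"].astype(str).map(index).to_numpy()[keep]
        tgt = sub["target"].astype(str).map(index).to_numpy()[keep]
        w = w[keep]
        loop = src == tgt
        src, tgt, w = src[~loop], tgt[~loop], w[~loop]
        n = len(genes)
        A = sparse.coo_matrix((w, (src, tgt)), shape=(n, n))
        A = A + A.T
        return A.tocsr(), genes


@dataclass
class SubtypeSpec:
    """A disease subtype: which aggregation set and mutation annotations
    apply (e.g. a generic TDP-43 form versus a SOD1-driven form)."""

    name: str
    aggregation_set: set[str] = field(default_factory=set)
    mutation_genes: set[str] = field(default_factory=set)
    channels: tuple[str, ...] = CHANNELS


def base_scores(
    genes: Sequence[str],
    gene_p: Mapping[str, float],
    de_table: pd.DataFrame | None,
    subtype: SubtypeSpec,
    p_ref: float = DEFAULT_P_REF,
    effect_cap: float = 5.0,
) -> pd.DataFrame:
    """Direct (pre-diffusion) evidence channels, each in [0, 1].

    ``genetic_common = min(1, −log10 p / −log10 p_ref)``; a gene exactly at
    the genome-wide threshold scores 1.  ``transcriptomic`` is
    ``min(1, |effect| / effect_cap)`` for significant rows of ``de_table``
    (columns ``gene, effect, significant``) and 0 otherwise.  Genes absent
    from all evidence score 0 on every channel.
    """
    rows = []
    de_sig: dict[str, float] = {}
    if de_table is not None:
        for _, r in de_table.iterrows():
            if bool(r["significant"]):
                de_sig[str(r["gene"])] = float(r["effect"])
    log_ref = -np.log10(p_ref)
    for g in genes:
        p = gene_p.get(g)
        if p is not None:
            if p <= 0 or p > 1:
                raise ValueError(f"p-value for {g} outside (0, 1]")
            gc = min(1.0, -np.log10(p) / log_ref)
        else:
            gc = 0.0
        rows.append(
            {
                "gene": g,
                "genetic_common": gc,
                "genetic_rare": 1.0 if g in subtype.mutation_genes else 0.0,
                "transcriptomic": min(1.0, abs(de_sig.get(g, 0.0)) / effect_cap)
                if g in de_sig
                else 0.0,
                "aggregation": 1.0 if g in subtype.aggregation_set else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def diffuse(
    graph: KnowledgeGraph | tuple[sparse.csr_matrix, list[str]],
    seeds: Mapping[str, float] | pd.Series,
    restart: float = 0.5,
    min_confidence: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> pd.Series:
    """Random walk with restart over the confidence-weighted gene layer.

    Iterates ``x ← restart·s̃ + (1−restart)·Wᵀx`` with ``W`` the
    column-normalized adjacency and ``s̃`` the seed vector normalized to sum
    1, until the L1 change drops below ``tol``.  Walkers leaving a dangling
    (degree-zero under the cutoff) node teleport back to the seeds, so the
    output always sums to 1.
    """
    if not (0 < restart <= 1):
        raise ValueError("restart must lie in (0, 1]")
    A, genes = graph.diffusion_layer(min_confidence) if isinstance(graph, KnowledgeGraph) else graph
    s = np.array([float(seeds.get(g, 0.0)) for g in genes])
    if (s < 0).any():
        raise ValueError("seed values must be nonnegative")
    total = s.sum()
    if total <= 0:
        raise ValueError("seeds are all zero")
    s = s / total
    if restart == 1.0:
        return pd.Series(s, index=genes)

    colsum = np.asarray(A.sum(axis=0)).ravel()
    dangling = colsum <= 0
    inv = np.zeros_like(colsum)
    inv[~dangling] = 1.0 / colsum[~dangling]
    W = A @ sparse.diags(inv)  # column-normalized

    x = s.copy()
    for _ in range(max_iter):
        leaked = x[dangling].sum()  # mass on dangling nodes teleports home
        x_new = restart * s + (1.0 - restart) * (W @ x + leaked * s)
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            break
        x = x_new
    return pd.Series(x, index=genes)


def filter_edges_by_cv(
    graph: KnowledgeGraph,
    known_genes: Iterable[str],
    thresholds: Sequence[float],
    restart: float = 0.5,
) -> tuple[float, pd.DataFrame]:
    """Choose the edge-confidence cutoff by leave-one-out retrieval.

    For each cutoff, each known disease gene is held out in turn: the
    remaining known genes seed a diffusion and the held-out gene's AUROC is
    the fraction of non-seed background genes it outranks (ties count half).
    The cutoff with the highest mean AUROC wins; ties go to the larger
    (stricter) cutoff.  A cutoff that removes every edge scores 0.5 with a
    warning.  Returns the chosen cutoff and the full retrieval curve.
    """
    known = sorted(set(map(str, known_genes)))
    if len(known) < 3:
        raise ValueError("cross-validation needs at least 3 known genes")
    if not thresholds:
        raise ValueError("no candidate thresholds supplied")
    rows = []
    for cutoff in thresholds:
        A, genes = graph.diffusion_layer(min_confidence=cutoff)
        if A.nnz == 0:
            warnings.warn(f"cutoff {cutoff} removes all edges; scored as AUROC 0.5")
            rows.append({"cutoff": float(cutoff), "mean_auroc": 0.5})
            continue
        aurocs = []
        gene_index = {g: i for i, g in enumerate(genes)}
        for held in known:
            if held not in gene_index:
                continue
            seeds = {g: 1.0 for g in known if g != held and g in gene_index}
            if not seeds:
                continue
            x = diffuse((A, genes), seeds, restart=restart).to_numpy()
            bg = np.array([i for g, i in gene_index.items() if g not in seeds and g != held])
            held_score = x[gene_index[held]]
            below = np.sum(x[bg] < held_score) + 0.5 * np.sum(x[bg] == held_score)
            aurocs.append(below / len(bg))
        rows.append({"cutoff": float(cutoff), "mean_auroc": float(np.mean(aurocs)) if aurocs else 0.5})
    curve = pd.DataFrame(rows)
    best = curve["mean_auroc"].max()
    chosen = float(curve.loc[curve["mean_auroc"] >= best - 1e-12, "cutoff"].max())
    logger.info("cv edge filter: chose cutoff %.3g (mean AUROC %.3f)", chosen, best)
    return chosen, curve


def score_all(
    graph: KnowledgeGraph,
    base: pd.DataFrame,
    restart: float = 0.5,
    min_confidence: float = 0.0,
) -> pd.DataFrame:
    """Eight-channel score table plus the biorelevance mean, ranked.

    ``base`` is the output of :func:`base_scores`.  Each channel is diffused
    separately (an all-zero channel yields an all-zero diffusion), the
    diffusion vector is max-normalized to [0, 1], and biorelevance is the
    arithmetic mean of the four direct and four diffusion channels.
    """
    layer = graph.diffusion_layer(min_confidence)
    genes = layer[1]
    out = base.reindex(genes).fillna(0.0)
    for ch in CHANNELS:
        seeds = out[ch]
        if seeds.sum() <= 0:
            out[f"{ch}_diffusion"] = 0.0
            continue
        x = diffuse(layer, seeds, restart=restart)
        out[f"{ch}_diffusion"] = (x / x.max()).to_numpy()
    cols = list(CHANNELS) + [f"{c}_diffusion" for c in CHANNELS]
    out["biorelevance"] = out[cols].mean(axis=1)
    return out.sort_values("biorelevance", ascending=False, kind="mergesort")


def top_k(scores: pd.DataFrame, k: int = 293) -> list[str]:
    """The ``k`` genes with the highest biorelevance (table order breaks ties)."""
    return list(scores.index[:k])
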