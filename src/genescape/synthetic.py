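"""Synthetic benchmark data with known ground truth.

Every input the pipeline consumes can be generated here: per-study gene
lists with controlled overlap, SNP Z-statistics under block-exchangeable
linkage disequilibrium with optional non-centrality, stochastic-block-model
interaction networks with a planted disease module and confidence-weighted
edges, and per-gene differential-expression tables.  All draws flow from a
single seed in :class:`SyntheticConfig`, so identical configurations yield
byte-identical outputs.

Design notes
------------
* LD within a block is exchangeable (single correlation ``ld_rho``) rather
  than autoregressive: the block correlation matrix
  ``R = (1-ρ)I + ρJ`` has closed-form eigenvalues ``1+(m-1)ρ`` and ``1-ρ``,
  which makes the gene-based test's null analytically checkable.
* Edge confidences follow a Beta law; edges inside the planted module swap
  the two shape parameters so module edges have stochastically higher
  confidence, mirroring database confidence semantics and giving the
  cross-validated confidence filter a recoverable signal.
"""
from __future__ import annotations

import math
import zlib
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .funnel import DATA_TYPES, EvidenceTable, compile_input_genes

__all__ = [
    "StudySpec",
    "SyntheticConfig",
    "gene_names",
    "generate_study_lists",
    "generate_evidence_tables",
    "generate_snp_stats",
    "block_ld_matrix",
    "generate_ppi",
    "generate_de_table",
]


@dataclass(frozen=True)
class StudySpec:
    """One omics study: its label, evidence type, size, and the fraction of
    its genes drawn from genes already flagged by earlier studies."""

    study_id: str
    data_type: str
    n_genes: int
    overlap_fraction: float = 0.0


def _default_studies(n_genes: int) -> list[StudySpec]:
    # A small multi-omics panel: one gene-based GWAS study plus four
    # follow-up data types re-sampling part of the GWAS hits.  Sizes scale
    # with the gene universe (fractions chosen to echo a GWAS-dominant mix).
    def sz(frac: float) -> int:
        return max(1, round(frac * n_genes))

    return [
        StudySpec("gwas1", "gwas_gene", sz(0.20), 0.0),
        StudySpec("exome1", "exome", sz(0.10), 0.2),
        StudySpec("cnv1", "cnv", sz(0.13), 0.2),
        StudySpec("epi1", "epigenomic", sz(0.17), 0.2),
        StudySpec("twas1", "twas", sz(0.10), 0.2),
    ]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic benchmark.

    Defaults match the planted-module benchmark used throughout the test
    suite: 600 genes, a 30-gene disease module with within-module edge
    probability 0.3 against a 0.01 background, 20 SNPs per gene in LD blocks
    of 10 with within-block correlation 0.5, and Beta(2, 8) background edge
    confidences (module edges use the swapped shapes, Beta(8, 2)).
    """

    n_genes: int = 600
    study_specs: list[StudySpec] | None = None
    ld_block_size: int = 10
    ld_rho: float = 0.5
    snps_per_gene: int = 20
    module_size: int | None = None
    p_in: float = 0.3
    p_out: float = 0.01
    confidence_params: tuple[float, float] = (2.0, 8.0)
    de_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.study_specs is None:
            self.study_specs = _default_studies(self.n_genes)
        if self.module_size is None:
            # 30 genes at the default 600-gene universe, scaled down for
            # smaller universes.
            self.module_size = min(30, max(1, self.n_genes // 20))

    def validate(self) -> None:
        if self.n_genes <= 0 or self.ld_block_size <= 0 or self.snps_per_gene <= 0:
            raise ValueError("n_genes, ld_block_size and snps_per_gene must be positive")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.module_size > self.n_genes:
            raise ValueError("module_size exceeds n_genes")
        for p, name in ((self.p_in, "p_in"), (self.p_out, "p_out"), (self.de_fraction, "de_fraction")):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.module_size > 1 and self.p_in < self.p_out:
            raise ValueError("planted-module benchmarks require p_in >= p_out")
        if min(self.confidence_params) <= 0:
            raise ValueError("confidence_params must be positive Beta shapes")
        for s in self.study_specs:
            if s.data_type not in DATA_TYPES:
                raise ValueError(f"unknown data type {s.data_type!r} in study {s.study_id}")
            if s.n_genes > self.n_genes:
                raise ValueError(f"study {s.study_id} larger than the gene universe")
            if not (0.0 <= s.overlap_fraction <= 1.0):
                raise ValueError("overlap_fraction must lie in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream so each generator draws independently of the rest.

        Uses a CRC of the stream name (stable across processes, unlike
        ``hash``) to key the substream off the root seed.
        """
        key = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


def gene_names(n: int, prefix: str = "G") -> list[str]:
    """Synthetic gene symbols ``G0001 … Gnnnn`` (no real identifiers)."""
    return [f"{prefix}{i + 1:04d}" for i in range(n)]


def generate_study_lists(config: SyntheticConfig) -> list[tuple[str, str, list[str]]]:
    """Draw per-study gene lists with the configured between-study overlap.

    For each study, ``round(overlap_fraction * n)`` genes are sampled from the
    union of genes flagged by earlier studies (when available) and the rest
    from previously unflagged genes, so ``overlap_fraction=1`` for two
    equal-size consecutive studies yields identical sets.
    """
    config.validate()
    rng = config.rng("studies")
    universe = gene_names(config.n_genes)
    seen: list[str] = []
    seen_set: set[str] = set()
    out: list[tuple[str, str, list[str]]] = []
    for spec in config.study_specs:
        n_overlap = min(round(spec.overlap_fraction * spec.n_genes), len(seen))
        fresh_pool = [g for g in universe if g not in seen_set]
        n_fresh = spec.n_genes - n_overlap
        if n_fresh > len(fresh_pool):  # fall back to more overlap than asked
            n_fresh = len(fresh_pool)
            n_overlap = spec.n_genes - n_fresh
        chosen = list(rng.choice(seen, size=n_overlap, replace=False)) if n_overlap else []
        chosen += list(rng.choice(fresh_pool, size=n_fresh, replace=False)) if n_fresh else []
        out.append((spec.study_id, spec.data_type, sorted(chosen)))
        for g in chosen:
            if g not in seen_set:
                seen_set.add(g)
                seen.append(g)
    return out


def generate_evidence_tables(config: SyntheticConfig) -> EvidenceTable:
    """Generate study lists and compile them into an evidence table."""
    return compile_input_genes(generate_study_lists(config))


def block_ld_matrix(n_snps: int, block_size: int, rho: float) -> np.ndarray:
    """Block-diagonal exchangeable correlation: ``(1-ρ)I + ρJ`` per block."""
    R = np.eye(n_snps)
    for start in range(0, n_snps, block_size):
        stop = min(start + block_size, n_snps)
        R[start:stop, start:stop] = rho
    np.fill_diagonal(R, 1.0)
    return R


def generate_snp_stats(
    config: SyntheticConfig,
    noncentrality: float | Mapping[str, float] = 0.0,
    genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate per-gene SNP Z-statistics under block-exchangeable LD.

    Each gene carries ``snps_per_gene`` SNPs whose Z-vector is multivariate
    normal with correlation :func:`block_ld_matrix`; a per-gene
    non-centrality ``ncp`` shifts every SNP mean by ``sqrt(ncp / n_snps)`` so
    the expected gene statistic exceeds its null mean by exactly ``ncp``.
    Under ``noncentrality=0`` every Z is marginally standard normal.

    Returns
    -------
    (snps, R)
        ``snps`` — DataFrame with columns ``snp_id, chrom, pos, gene, z``;
        positions tile genes along one chromosome, 100 bp apart.
        ``R`` — the (shared) per-gene LD matrix.
    """
    config.validate()
    rng = config.rng("snps")
    if genes is None:
        genes = gene_names(config.n_genes)
    n = config.snps_per_gene
    rho = config.ld_rho
    R = block_ld_matrix(n, config.ld_block_size, rho)

    n_genes = len(genes)
    # Exchangeable blocks sample as sqrt(rho)*shared + sqrt(1-rho)*idio.
    n_blocks = math.ceil(n / config.ld_block_size)
    block_index = np.minimum(np.arange(n) // config.ld_block_size, n_blocks - 1)
    shared = rng.standard_normal((n_genes, n_blocks))
    idio = rng.standard_normal((n_genes, n))
    z = math.sqrt(rho) * shared[:, block_index] + math.sqrt(1.0 - rho) * idio

    if isinstance(noncentrality, Mapping):
        ncp = np.array([float(noncentrality.get(g, 0.0)) for g in genes])
    else:
        ncp = np.full(n_genes, float(noncentrality))
    if (ncp < 0).any():
        raise ValueError("noncentrality must be nonnegative")
    z = z + np.sqrt(ncp / n)[:, None]

    gene_idx = np.repeat(np.arange(n_genes), n)
    snp_idx = np.tile(np.arange(n), n_genes)
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{g * n + s + 1}" for g, s in zip(gene_idx, snp_idx)],
            "chrom": "1",
            "pos": gene_idx * (n * 100 + 10_000) + snp_idx * 100 + 1,
            "gene": np.asarray(genes, dtype=object)[gene_idx],
            "z": z.ravel(),
        }
    )
    return snps, R


def generate_ppi(config: SyntheticConfig) -> tuple[pd.DataFrame, list[str]]:
    """Stochastic-block-model interaction network with a planted module.

    Within-module pairs connect with probability ``p_in``, all other pairs
    with ``p_out``.  Confidences are Beta-distributed: background edges use
    shapes ``(a, b) = confidence_params`` ordered low-mean, module-module
    edges the swapped (high-mean) shapes.

    Returns the edge list (``source, target, edge_type, confidence``) and the
    ground-truth module membership (the first ``module_size`` genes).
    """
    config.validate()
    rng = config.rng("ppi")
    genes = gene_names(config.n_genes)
    module = genes[: config.module_size]
    in_module = np.zeros(config.n_genes, dtype=bool)
    in_module[: config.module_size] = True

    iu, ju = np.triu_indices(config.n_genes, k=1)
    pair_in = in_module[iu] & in_module[ju]
    p = np.where(pair_in, config.p_in, config.p_out)
    keep = rng.random(p.size) < p
    iu, ju, pair_in = iu[keep], ju[keep], pair_in[keep]

    a, b = config.confidence_params
    lo, hi = min(a, b), max(a, b)
    conf = np.where(
        pair_in,
        rng.beta(hi, lo, size=iu.size),  # module edges: high-mean
        rng.beta(lo, hi, size=iu.size),
    )
    conf = np.clip(conf, 1e-9, 1.0)
    names = np.asarray(genes, dtype=object)
    edges = pd.DataFrame(
        {
            "source": names[iu],
            "target": names[ju],
            "edge_type": "gene-gene",
            "confidence": conf,
        }
    )
    return edges, module


def generate_de_table(config: SyntheticConfig) -> pd.DataFrame:
    """Differential-expression table: a ``de_fraction`` of genes significant,
    with standard-normal effects inflated (|effect|+1) for significant genes."""
    config.validate()
    rng = config.rng("de")
    genes = gene_names(config.n_genes)
    sig = rng.random(config.n_genes) < config.de_fraction
    effect = rng.standard_normal(config.n_genes)
    effect[sig] = np.sign(effect[sig]) * (np.abs(effect[sig]) + 1.0)
    return pd.DataFrame({"gene": genes, "effect": effect, "significant": sig})
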