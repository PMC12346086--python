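"""Cross-model comparison of landscape and knowledge-graph scores.

Merges the two scoring systems over a common gene universe, computes the
Pearson correlation between them (and the full score-correlation matrix),
runs rank-based group comparisons (Mann–Whitney U, exact by permutation
enumeration for small groups, normal approximation with tie correction
otherwise, Benjamini–Hochberg across contrasts), and performs the
three-way overlap analysis between the landscape list, the knowledge-graph
top list, and an externally curated industry-target list with
development-status labels.
"""
from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "merge_scores",
    "correlate",
    "correlation_matrix",
    "mannwhitney",
    "compare_groups",
    "star_code",
    "overlap_analysis",
    "OverlapReport",
]

#: Significance-star thresholds, strictest first.
STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))

_EXACT_MAX_MIN_N = 8
_EXACT_MAX_COMBOS = 200_000


def merge_scores(
    landscape_scores: Mapping[str, float],
    kg_scores: Mapping[str, float],
    universe: Iterable[str],
    zero_fill: bool = True,
    flags: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Outer-join both models' scores over a declared gene universe.

    With ``zero_fill`` (the default policy), genes lacking a landscape score
    enter with 0 — the interpretation under which a genome-scale correlation
    between the two models is defined.  Without it, genes missing either
    score carry NaN and are dropped by downstream correlation.  Optional
    ``flags`` adds boolean membership columns (e.g. landscape / kg_top /
    industry_target).
    """
    universe = list(dict.fromkeys(map(str, universe)))
    if len(universe) != len(set(universe)):
        raise ValueError("duplicate genes in universe")
    missing = (set(landscape_scores) | set(kg_scores)) - set(universe)
    if missing:
        raise ValueError(f"scores outside the declared universe: {sorted(missing)[:5]}")
    df = pd.DataFrame(index=pd.Index(universe, name="gene"))
    df["landscape_total"] = pd.Series(landscape_scores, dtype=float).reindex(universe)
    df["biorelevance"] = pd.Series(kg_scores, dtype=float).reindex(universe)
    if zero_fill:
        df = df.fillna(0.0)
    for name, members in (flags or {}).items():
        df[name] = df.index.isin(set(map(str, members)))
    return df


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with its two-sided p-value (t transform, n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input to correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation over all numeric score columns."""
    numeric = scores.select_dtypes(include=[np.number])
    mat = numeric.corr(method="pearson")
    np.fill_diagonal(mat.values, 1.0)
    return mat


def star_code(p: float) -> str:
    for cutoff, stars in STAR_LEVELS:
        if p < cutoff:
            return stars
    return "ns"


def _exact_mw_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann–Whitney p by full enumeration of group assignments.

    Enumerates every ``C(n+m, n)`` split of the pooled midranks and counts
    splits whose U is at least as far from the null mean ``nm/2`` as the
    observed one.  Valid under ties because the permutation distribution is
    computed from the observed pooled sample itself.
    """
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nm_half = n * m / 2.0
    obs_u = ranks[:n].sum() - n * (n + 1) / 2.0
    obs_dev = abs(obs_u - nm_half)
    total = math.comb(n + m, n)
    hits = 0
    idx = np.arange(n + m)
    for combo in combinations(idx, n):
        u = ranks[list(combo)].sum() - n * (n + 1) / 2.0
        if abs(u - nm_half) >= obs_dev - 1e-9:
            hits += 1
    return hits / total


def mannwhitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, str]:
    """Two-sided Mann–Whitney U test.

    Exact permutation enumeration when the smaller group has ≤ 8
    observations and the enumeration stays below 200k splits; otherwise the
    normal approximation with tie correction and continuity correction.
    Returns ``(U, p, mode)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    u = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic)
    n, m = len(x), len(y)
    if min(n, m) <= _EXACT_MAX_MIN_N and math.comb(n + m, min(n, m)) <= _EXACT_MAX_COMBOS:
        return u, _exact_mw_pvalue(x, y), "exact"
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)
    return u, p, "asymptotic"


def compare_groups(values: Sequence[float], labels: Sequence[str]) -> pd.DataFrame:
    """All pairwise Mann–Whitney contrasts between labeled groups.

    P-values are Benjamini–Hochberg adjusted across contrasts and annotated
    with star codes (*, **, ***, **** at 0.05/0.01/0.001/0.0001).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    groups = list(dict.fromkeys(labels.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    by_group = {g: values[labels == g] for g in groups}
    for g, v in by_group.items():
        if len(v) == 0:
            raise ValueError(f"group {g} is empty")
    rows = []
    for a, b in combinations(groups, 2):
        u, p, mode = mannwhitney(by_group[a], by_group[b])
        rows.append({"group_a": a, "group_b": b, "n_a": len(by_group[a]),
                     "n_b": len(by_group[b]), "U": u, "p_value": p, "mode": mode})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["stars"] = df["p_adjusted"].map(star_code)
    return df


@dataclass
class OverlapReport:
    """Three-way overlap: region cardinalities, memberships, active-status
    proportions per region, and an enrichment test for active development in
    the triple intersection versus the industry-only region."""

    regions: dict[str, set[str]]
    region_sizes: dict[str, int] = field(init=False)
    active_proportion: dict[str, float] = field(default_factory=dict)
    fisher_odds_ratio: float = float("nan")
    fisher_p: float = float("nan")

    def __post_init__(self) -> None:
        self.region_sizes = {k: len(v) for k, v in self.regions.items()}


def overlap_analysis(
    landscape: Iterable[str],
    kg_top: Iterable[str],
    industry: pd.DataFrame,
) -> OverlapReport:
    """Venn decomposition of landscape / kg-top / industry target sets.

    ``industry`` needs columns ``gene`` and ``status`` (``active`` /
    ``inactive``); an optional ``phase`` column is carried through untouched.
    The seven region keys are dotted membership labels
    (``landscape.kg.industry`` for the triple intersection, etc.).  The
    Fisher exact test contrasts active-status counts in the triple
    intersection against the industry-only region.
    """
    land = set(map(str, landscape))
    kg = set(map(str, kg_top))
    ind = set(industry["gene"].astype(str))
    regions = {
        "landscape.kg.industry": land & kg & ind,
        "landscape.kg": (land & kg) - ind,
        "landscape.industry": (land & ind) - kg,
        "kg.industry": (kg & ind) - land,
        "landscape": land - kg - ind,
        "kg": kg - land - ind,
        "industry": ind - land - kg,
    }
    report = OverlapReport(regions=regions)

    status = dict(zip(industry["gene"].astype(str), industry["status"].astype(str)))
    counts: dict[str, tuple[int, int]] = {}
    for key, members in regions.items():
        with_status = [g for g in members if g in status]
        if not with_status:
            continue
        active = sum(status[g] == "active" for g in with_status)
        counts[key] = (active, len(with_status) - active)
        report.active_proportion[key] = active / len(with_status)

    triple = counts.get("landscape.kg.industry")
    only = counts.get("industry")
    if triple and only:
        odds, p = stats.fisher_exact([list(triple), list(only)], alternative="two-sided")
        report.fisher_odds_ratio, report.fisher_p = float(odds), float(p)
    logger.info("overlap regions: %s", report.region_sizes)
    return report
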