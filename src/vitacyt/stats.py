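"""Cohort-level statistics: rank correlation with BH-FDR, correlation
networks, median stratification, two-group rank tests, Shannon diversity, and
partial-Mayo activity classification.

Spearman's rho and its t-approximation p-value come from scipy; BH adjustment
from statsmodels. The Mann-Whitney U test uses exact enumeration of the
permutation distribution (tie-safe) for small samples (m + n <= 12) and the
tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_MW_LIMIT = 12


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its two-sided
    t-approximation p-value, on pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("need >= 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class CorrelationNetwork:
    """Significant pairwise associations among cohort variables.

    ``edges`` has columns var_a, var_b, rho, p, q (q < alpha only);
    ``graph`` is the corresponding networkx Graph with rho/q edge attributes.
    """

    nodes: tuple[str, ...]
    edges: pd.DataFrame
    graph: nx.Graph
    alpha: float


def correlation_network(
    table: pd.DataFrame,
    variables: list[str],
    alpha: float = 0.05,
) -> CorrelationNetwork:
    """All pairwise Spearman correlations with one BH family over the pairs;
    edges where q < alpha. Missing values are handled pairwise-complete."""
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"variable absent from table: {missing[0]}")
    if len(variables) < 2:
        raise ValueError("need >= 2 variables")
    pairs = list(itertools.combinations(variables, 2))
    rows = []
    for a, b in pairs:
        rho, p = spearman_rho(table[a], table[b])
        rows.append((a, b, rho, p))
    result = pd.DataFrame(rows, columns=["var_a", "var_b", "rho", "p"])
    result["q"] = bh_adjust(result["p"].to_numpy())
    edges = result[result["q"] < alpha].reset_index(drop=True)
    g = nx.Graph()
    g.add_nodes_from(variables)
    for row in edges.itertuples(index=False):
        g.add_edge(row.var_a, row.var_b, rho=row.rho, q=row.q)
    return CorrelationNetwork(nodes=tuple(variables), edges=edges, graph=g,
                              alpha=alpha)


def median_split(values) -> tuple[float, np.ndarray, np.ndarray]:
    """Split at the sample median; values below go low, values at or above go
    high (the boundary is assigned to the high group)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    threshold = float(np.median(v))
    return threshold, v[v < threshold], v[v >= threshold]


def _exact_mw_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating all group assignments (tie-safe).

    Uses the distance of U from its mean m*n/2 as the two-sided criterion.
    """
    pooled = np.concatenate([x, y])
    m, n = len(x), len(y)
    ranks = sps.rankdata(pooled)
    mu = m * n / 2.0
    d_obs = abs(u_obs - mu)
    count = total = 0
    for idx in itertools.combinations(range(m + n), m):
        u = ranks[list(idx)].sum() - m * (m + 1) / 2.0
        total += 1
        if abs(u - mu) >= d_obs - 1e-12:
            count += 1
    return count / total


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U (x vs y) with a two-sided p-value.

    Exact enumeration for m + n <= 12; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    u, _ = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    if x.size + y.size <= EXACT_MW_LIMIT:
        p = _exact_mw_p(x, y, u)
    else:
        _, p = sps.mannwhitneyu(x, y, alternative="two-sided",
                                method="asymptotic")
    return float(u), float(min(p, 1.0))


def shannon_diversity(abundances) -> float:
    """Shannon index in bits: -sum p_i log2 p_i over normalised nonzero
    abundances."""
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be >= 0")
    total = a.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = a[a > 0] / total
    return float(-(p * np.log2(p)).sum())


def classify_uc_activity(partial_mayo: int, max_subscore: int) -> str:
    """Partial-Mayo activity: 'active' for score >= 3; 'inactive' for score
    < 2 with no subscore > 1; 'intermediate' otherwise (the score-2 gap)."""
    if partial_mayo < 0 or max_subscore < 0:
        raise ValueError("scores must be >= 0")
    if partial_mayo >= 3:
        return "active"
    if partial_mayo < 2 and max_subscore <= 1:
        return "inactive"
    return "intermediate"


def kruskal_dunn(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Kruskal-Wallis across groups followed by pairwise Mann-Whitney with BH
    adjustment (Dunn-style screen, delegated to scipy). Returns the pairwise
    table with the omnibus p attached; used for multi-group load comparisons."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    h, p_omni = sps.kruskal(*[np.asarray(groups[g], dtype=float) for g in names])
    rows = []
    for a, b in itertools.combinations(names, 2):
        u, p = mann_whitney(groups[a], groups[b])
        rows.append((a, b, u, p))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "U", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    out.attrs["kruskal_H"] = float(h)
    out.attrs["kruskal_p"] = float(p_omni)
    return out
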