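"""PPI link-count enrichment between a query and a target gene set.

The observed statistic is the total number of distinct edges from query
genes to target-set genes in a confidence-filtered interactome. Its null
distribution comes from K equal-size gene sets drawn uniformly without
replacement from the network universe; the permutation p-value uses the
add-one rule p = (#{null >= observed} + 1) / (K + 1).  For K >= 30 a
normal-approximation z-test against the null mean/sd is reported as well.
"""

from __future__ import annotations

from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .containers import Interactome

__all__ = [
    "load_interactome",
    "link_counts",
    "random_set_null",
    "empirical_p",
    "normal_approx_p",
    "rank_links",
    "LinkEnrichmentResult",
    "link_enrichment",
]


def load_interactome(edge_file, score_cutoff: float = 0.7) -> Interactome:
    """Read a 3-column (gene_a, gene_b, score) edge list into a filtered graph.

    STRING-dialect integer scores on the 0-1000 scale are detected (any
    score > 1) and divided by 1000.  Edges with score >= ``score_cutoff``
    (inclusive) are kept; pairs are canonicalized, self-loops dropped, and
    duplicate pairs keep their highest score.
    """
    rows = []
    with open(edge_file) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{edge_file}:{lineno}: expected 3 tab-separated columns")
            try:
                score = float(parts[2])
            except ValueError as exc:
                if lineno == 1:  # header line
                    continue
                raise ValueError(f"{edge_file}:{lineno}: bad score {parts[2]!r}") from exc
            rows.append((parts[0], parts[1], score))
    scores = np.array([s for _, _, s in rows], dtype=float)
    if scores.size and scores.max() > 1:
        scores = scores / 1000.0
    g = nx.Graph()
    for (a, b, _), s in zip(rows, scores):
        if a == b or s < score_cutoff:
            continue
        u, v = (a, b) if a <= b else (b, a)
        if g.has_edge(u, v):
            g[u][v]["score"] = max(g[u][v]["score"], float(s))
        else:
            g.add_edge(u, v, score=float(s))
    return Interactome(graph=g, score_cutoff=score_cutoff)


def link_counts(net: Interactome, query_set, target_set) -> tuple[pd.Series, int]:
    """Distinct target-set neighbors per query gene, and their total.

    A query gene that is itself in the target set counts its target
    neighbors excluding itself (no self-links).
    """
    query = sorted(set(query_set) & set(net.graph.nodes))
    if not query:
        raise ValueError("query set has no genes in the network")
    target = set(target_set)
    counts = {}
    for gene in query:
        counts[gene] = len((set(net.graph.neighbors(gene)) & target) - {gene})
    series = pd.Series(counts, name="link_count").sort_index()
    return series, int(series.sum())


def random_set_null(
    net: Interactome,
    set_size: int,
    target_set,
    K: int = 999,
    seed: int = 0,
    universe=None,
) -> np.ndarray:
    """Null link totals from K uniform random query sets of ``set_size``.

    The sampling universe defaults to all network nodes outside the target
    set (query and target disjoint by construction).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    target = set(target_set)
    if universe is None:
        universe = [n for n in net.graph.nodes if n not in target]
    universe = sorted(universe)
    if len(universe) < set_size:
        raise ValueError("universe smaller than the requested set size")
    rng = np.random.default_rng(seed)
    neighbors = {n: set(net.graph.neighbors(n)) for n in universe}
    totals = np.empty(K, dtype=int)
    arr = np.array(universe, dtype=object)
    for k in range(K):
        pick = rng.choice(arr, size=set_size, replace=False)
        totals[k] = sum(len((neighbors[g] & target) - {g}) for g in pick)
    return totals


def empirical_p(observed_total: int, null_totals) -> float:
    """Add-one permutation p-value, P(null >= observed)."""
    null_totals = np.asarray(null_totals)
    if null_totals.size == 0:
        raise ValueError("null distribution is empty")
    k = null_totals.size
    return (int((null_totals >= observed_total).sum()) + 1) / (k + 1)


def normal_approx_p(observed_total: int, null_totals) -> float:
    """One-sided z-test p against the null mean/sd (for K >= 30)."""
    from scipy.stats import norm

    null_totals = np.asarray(null_totals, dtype=float)
    if null_totals.size < 30:
        raise ValueError("normal approximation needs at least 30 null draws")
    sd = null_totals.std(ddof=1)
    if sd == 0:
        return 1.0 if observed_total <= null_totals.mean() else 0.0
    z = (observed_total - null_totals.mean()) / sd
    return float(norm.sf(z))


def rank_links(per_gene_counts: pd.Series, top_n: int = 30) -> pd.DataFrame:
    """Hub ranking: top genes by link count, ties broken lexicographically."""
    df = per_gene_counts.rename("link_count").rename_axis("gene").reset_index()
    df = df.sort_values(["link_count", "gene"], ascending=[False, True])
    return df.head(top_n).reset_index(drop=True)


class LinkEnrichmentResult(NamedTuple):
    per_gene: pd.Series
    observed_total: int
    null_totals: np.ndarray
    empirical_p: float
    K: int


def link_enrichment(
    net: Interactome,
    query_set,
    target_set,
    K: int = 999,
    seed: int = 0,
    universe=None,
) -> LinkEnrichmentResult:
    """Observed link total plus its random-set null and permutation p."""
    per_gene, observed = link_counts(net, query_set, target_set)
    nulls = random_set_null(net, len(per_gene), target_set, K=K, seed=seed, universe=universe)
    return LinkEnrichmentResult(per_gene, observed, nulls, empirical_p(observed, nulls), K)
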