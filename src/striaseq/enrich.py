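"""Preranked gene-set enrichment, pathway-overlap networks, and the
sex-interaction score.

The enrichment score is the extremum of the weighted Kolmogorov-Smirnov
running sum over the ranking (hit steps proportional to |statistic|,
miss steps 1/(N - n)); significance comes from gene-label permutations,
the normalized score divides by the mean |permuted ES| of the same sign,
and q-values use the covariate-aware FDR with set size as the covariate.
Significant pathways are linked into a network by the overlap
coefficient of their leading-edge genes and clustered by greedy
modularity. The sex-interaction score contrasts female and male
case-control effects per gene:
``sign(log2FC_F) * (-log10 p_F) - sign(log2FC_M) * (-log10 p_M)``.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .fdr import qvalue_covariate

__all__ = [
    "enrichment_score",
    "preranked_gsea",
    "interaction_score",
    "cluster_pathways",
    "map_orthologs",
]


def enrichment_score(
    stats_sorted: np.ndarray, hit_positions: np.ndarray
) -> tuple[float, int]:
    """ES of one set given |statistics| sorted in ranking order.

    ``hit_positions`` are 0-based positions of set members in the ranking.
    Returns ``(ES, extremum position)``; the running sum takes a weighted
    step up at hits and a constant step down at misses, and ES is the
    extremum with the larger magnitude.
    """
    N = len(stats_sorted)
    k = len(hit_positions)
    if k == 0 or k >= N:
        raise ValueError("set must be a proper non-empty subset of the ranking")
    pos = np.sort(np.asarray(hit_positions))
    w = np.abs(stats_sorted[pos])
    total = w.sum()
    if total == 0:
        w = np.ones(k)
        total = float(k)
    miss = 1.0 / (N - k)
    cum_hit = np.cumsum(w) / total
    # value at each hit, and the low point just before each hit
    at_hit = cum_hit - (pos + 1 - np.arange(1, k + 1)) * miss
    before_hit = np.concatenate([[0.0], cum_hit[:-1]]) - (pos - np.arange(k)) * miss
    # the walk starts and ends at 0, peaks only at hit steps, and bottoms
    # only just before a hit (or at the endpoints)
    hi = max(float(at_hit.max()), 0.0)
    lo = min(float(before_hit.min()), 0.0)
    if hi >= -lo:
        j = int(np.argmax(at_hit))
        return float(hi), int(pos[j])
    j = int(np.argmin(before_hit))
    return float(lo), int(pos[j]) - 1


def _es_batch(absw: np.ndarray, N: int, pos_matrix: np.ndarray) -> np.ndarray:
    """Vectorized ES for many same-size sets; ``pos_matrix`` is B x k."""
    B, k = pos_matrix.shape
    pos = np.sort(pos_matrix, axis=1)
    w = absw[pos]
    total = w.sum(axis=1, keepdims=True)
    total = np.where(total == 0, 1.0, total)
    miss = 1.0 / (N - k)
    cum_hit = np.cumsum(w, axis=1) / total
    j = np.arange(1, k + 1)
    at_hit = cum_hit - (pos + 1 - j[None, :]) * miss
    before = np.concatenate([np.zeros((B, 1)), cum_hit[:, :-1]], axis=1) - (
        pos - (j - 1)[None, :]
    ) * miss
    hi = np.maximum(at_hit.max(axis=1), 0.0)
    lo = np.minimum(before.min(axis=1), 0.0)
    return np.where(hi >= -lo, hi, lo)


def preranked_gsea(
    ranking: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 10_000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked GSEA by gene-label permutation.

    ``ranking`` maps genes to a signed statistic (no NaN). Sets are
    filtered to the configured size range after intersection with the
    ranking; sets with fewer than 2 ranked members are skipped. Returns a
    table with ES, NES, permutation p, covariate-aware q, and the
    leading-edge genes.
    """
    if ranking.isna().any():
        raise ValueError("ranking contains NaN statistics")
    order = np.argsort(-ranking.to_numpy(), kind="mergesort")
    genes = ranking.index.to_numpy()[order]
    stats_sorted = ranking.to_numpy()[order]
    absw = np.abs(stats_sorted)
    gene_pos = {g: i for i, g in enumerate(genes)}
    N = len(genes)
    rng = np.random.default_rng(seed)
    perm_cache: dict[int, np.ndarray] = {}

    rows = []
    for name, members in sets.items():
        pos = np.array(sorted(gene_pos[g] for g in members if g in gene_pos))
        k = len(pos)
        if k < 2:
            warnings.warn(f"gene set {name!r} has <2 ranked members; skipped")
            continue
        if not (min_size <= k <= max_size):
            continue
        es, extremum = enrichment_score(stats_sorted, pos)
        if k not in perm_cache:
            perm_cache[k] = np.array(
                [rng.choice(N, size=k, replace=False) for _ in range(n_perm)]
            )
        es_perm = _es_batch(absw, N, perm_cache[k])
        same_sign = es_perm * np.sign(es) > 0
        n_same = same_sign.sum()
        p = (1.0 + np.sum(np.abs(es_perm[same_sign]) >= abs(es))) / (1.0 + n_same)
        denom = np.abs(es_perm[same_sign]).mean() if n_same else np.abs(es_perm).mean()
        nes = es / denom if denom > 0 else 0.0
        if es >= 0:
            leading = [g for g in genes[: extremum + 1] if g in set(members)]
        else:
            leading = [g for g in genes[extremum + 1 :] if g in set(members)]
        rows.append((name, k, es, nes, p, leading))
    out = pd.DataFrame(rows, columns=["pathway", "size", "ES", "NES", "p", "leading_edge"])
    if len(out):
        out["q"] = qvalue_covariate(out["p"].to_numpy(), out["size"].to_numpy())
    else:
        out["q"] = []
    return out


def interaction_score(de_f: pd.DataFrame, de_m: pd.DataFrame) -> pd.Series:
    """Per-gene sex-interaction score from within-sex DE tables.

    Both tables need ``gene``, ``logFC`` and ``P.Value`` columns; genes
    missing from either table are omitted (count reported in a warning).
    ``sign(0)`` is 0; p-values are floored at 1e-300 before the log.
    """
    f = de_f.set_index("gene") if "gene" in de_f.columns else de_f
    m = de_m.set_index("gene") if "gene" in de_m.columns else de_m
    shared = f.index.intersection(m.index)
    dropped = len(f.index.union(m.index)) - len(shared)
    if dropped:
        warnings.warn(f"{dropped} genes missing from one sex table; omitted")
    pf = np.clip(f.loc[shared, "P.Value"].to_numpy(dtype=float), 1e-300, None)
    pm = np.clip(m.loc[shared, "P.Value"].to_numpy(dtype=float), 1e-300, None)
    sf = np.sign(f.loc[shared, "logFC"].to_numpy(dtype=float))
    sm = np.sign(m.loc[shared, "logFC"].to_numpy(dtype=float))
    score = sf * (-np.log10(pf)) - sm * (-np.log10(pm))
    return pd.Series(score, index=shared, name="interaction_score")


def cluster_pathways(
    results: pd.DataFrame,
    min_overlap: float = 0.5,
    q_threshold: float = 0.05,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Overlap network and greedy-modularity clusters of significant pathways.

    Nodes are pathways with ``q < q_threshold``; the edge weight between
    two pathways is ``|A & B| / min(|A|, |B|)`` over leading-edge genes,
    kept when at least ``min_overlap``. Returns the graph and a node table
    with cluster ids (singletons keep their own cluster, flagged).
    """
    sig = results[results["q"] < q_threshold] if "q" in results.columns else results
    graph = nx.Graph()
    edge_sets = {}
    for _, row in sig.iterrows():
        genes = set(row["leading_edge"])
        if not genes:
            continue
        graph.add_node(row["pathway"])
        edge_sets[row["pathway"]] = genes
    names = sorted(edge_sets)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = len(edge_sets[a] & edge_sets[b])
            denom = min(len(edge_sets[a]), len(edge_sets[b]))
            w = inter / denom if denom else 0.0
            if w >= min_overlap:
                graph.add_edge(a, b, weight=w)
    communities = nx.algorithms.community.greedy_modularity_communities(graph)
    rows = []
    for cid, comm in enumerate(sorted(communities, key=lambda c: sorted(c)[0])):
        for node in sorted(comm):
            rows.append((node, cid, len(comm) == 1))
    table = pd.DataFrame(rows, columns=["pathway", "cluster", "singleton"])
    return graph, table


def map_orthologs(genes, mapping: pd.DataFrame, name: str = "gene set") -> list[str]:
    """Map a gene set through a source->target ortholog table.

    One-to-many mappings expand; unmapped members are dropped (count in a
    warning); the result is deduplicated preserving order. An empty result
    is an error naming the set.
    """
    src_col, tgt_col = mapping.columns[:2]
    lut: dict[str, list[str]] = {}
    for s, t in zip(mapping[src_col], mapping[tgt_col]):
        lut.setdefault(s, []).append(t)
    out: list[str] = []
    n_unmapped = 0
    for g in genes:
        if g in lut:
            out.extend(lut[g])
        else:
            n_unmapped += 1
    if n_unmapped:
        warnings.warn(f"{n_unmapped} members of {name} had no ortholog; dropped")
    out = list(dict.fromkeys(out))
    if not out:
        raise ValueError(f"ortholog mapping left {name!r} empty")
    return out
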