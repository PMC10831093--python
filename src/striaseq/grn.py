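"""Consensus TF-gene regulatory network inference.

Per individual, a seeded randomized tree-ensemble regresses every target
gene on the expression of all transcription factors; a TF's importance
for a target is its share of the ensemble's total split gain. Edges are
kept per target up to a cumulative importance mass, then filtered by two
reproducibility tiers: presence in at least 80% of repeated stochastic
runs within an individual, and detection in at least 80% of individuals.
Surviving edges can be pruned against a TF->target allowlist (standing
in for motif-based promoter filtering) and grouped into regulons.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "downsample_majority",
    "score_tf_importance",
    "aggregate_runs",
    "aggregate_individuals",
    "prune_edges",
    "run_grn",
]


def downsample_majority(cell_index, labels, seed: int = 0) -> np.ndarray:
    """Subsample the most prevalent type down to the second most prevalent.

    Returns the retained subset of ``cell_index``. With a tie for most
    prevalent, or a single type, the input is returned unchanged.
    """
    cell_index = np.asarray(cell_index)
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        warnings.warn("single cell type; nothing to downsample")
        return cell_index
    top, second = counts.iloc[0], counts.iloc[1]
    if top == second:
        return cell_index
    rng = np.random.default_rng(seed)
    top_type = counts.index[0]
    top_cells = cell_index[labels == top_type]
    keep_top = rng.choice(top_cells, size=second, replace=False)
    keep = np.concatenate([cell_index[labels != top_type], keep_top])
    return np.sort(keep)


def _log_cpm(X: np.ndarray) -> np.ndarray:
    lib = X.sum(axis=1, keepdims=True)
    lib = np.where(lib > 0, lib, 1)
    return np.log1p(X / lib * 1e4)


def _stump_importance(
    F: np.ndarray,
    Y: np.ndarray,
    rng: np.random.Generator,
    n_trees: int,
    subsample: float,
    n_thresholds: int,
) -> np.ndarray:
    """Split-gain importance (TFs x targets) from a randomized stump forest.

    Each tree draws a row subsample and a random sqrt-sized TF subset,
    proposes random split thresholds, and credits the variance reduction
    of the best split to its TF — evaluated for every target at once.
    """
    n, q = F.shape
    G = Y.shape[1]
    imp = np.zeros((q, G))
    mtry = max(2, int(np.ceil(np.sqrt(q))))
    m = max(10, int(subsample * n))
    for _ in range(n_trees):
        rows = rng.choice(n, size=m, replace=False)
        feats = rng.choice(q, size=min(mtry, q), replace=False)
        Ysub = Y[rows]
        cand_feat, cand_gain = [], []
        for f in feats:
            x = F[rows, f]
            for thr in rng.uniform(np.min(x), np.max(x), size=n_thresholds):
                mask = x > thr
                n1 = int(mask.sum())
                if n1 == 0 or n1 == m:
                    continue
                d = mask @ Ysub / n1 - (~mask) @ Ysub / (m - n1)
                cand_feat.append(f)
                cand_gain.append(n1 * (m - n1) / m * d**2)
        if not cand_gain:
            continue
        gains = np.vstack(cand_gain)  # candidates x targets
        winner = np.argmax(gains, axis=0)
        best = gains[winner, np.arange(G)]
        np.add.at(imp, (np.asarray(cand_feat)[winner], np.arange(G)), best)
    return imp


def score_tf_importance(
    expr,
    tf_list,
    gene_names,
    seed: int = 0,
    n_trees: int = 50,
    subsample: float = 0.5,
    n_thresholds: int = 2,
    mass_cutoff: float = 0.95,
    min_cells: int = 50,
) -> pd.DataFrame:
    """TF->target importances for one individual, one stochastic run.

    ``expr`` is cells x genes raw counts (log-CPM is taken internally so
    library size does not masquerade as co-regulation). Every non-TF gene
    is regressed on all TFs by the randomized stump forest; importances
    are normalized to sum to 1 per target and edges are kept in
    decreasing order until ``mass_cutoff`` of the total split gain is
    covered. Constant targets yield no edges.
    """
    X = expr.toarray() if sp.issparse(expr) else np.asarray(expr, dtype=float)
    gene_names = np.asarray(gene_names)
    if X.shape[0] < min_cells:
        raise ValueError(f"need >= {min_cells} cells, got {X.shape[0]}")
    name_pos = {g: i for i, g in enumerate(gene_names)}
    missing = [t for t in tf_list if t not in name_pos]
    if missing:
        raise ValueError(f"TFs absent from gene namespace: {missing[:5]}")
    tf_idx = np.array([name_pos[t] for t in tf_list])
    tf_set = set(tf_idx.tolist())
    logx = _log_cpm(X)
    F = logx[:, tf_idx]
    target_idx = np.array(
        [i for i in range(len(gene_names)) if i not in tf_set and logx[:, i].std() > 0]
    )
    if len(target_idx) == 0:
        return pd.DataFrame(columns=["tf", "target", "importance"])
    Y = logx[:, target_idx]
    rng = np.random.default_rng(seed)
    imp = _stump_importance(F, Y, rng, n_trees, subsample, n_thresholds)
    total = imp.sum(axis=0)
    tf_names = np.asarray(tf_list)
    rows = []
    for j, gi in enumerate(target_idx):
        if total[j] <= 0:
            continue
        share = imp[:, j] / total[j]
        order = np.argsort(-share)
        cum = np.cumsum(share[order])
        n_keep = int(np.searchsorted(cum, mass_cutoff) + 1)
        g = gene_names[gi]
        for t in order[:n_keep]:
            if share[t] <= 0 or tf_names[t] == g:
                continue
            rows.append((tf_names[t], g, float(share[t])))
    return pd.DataFrame(rows, columns=["tf", "target", "importance"])


def aggregate_runs(
    run_edges: list[pd.DataFrame],
    run_threshold: float = 0.8,
    strict: bool = False,
) -> pd.DataFrame:
    """Keep edges reproducible across repeated stochastic runs.

    An edge survives when present in at least ``ceil(run_threshold * R)``
    of R runs (with ``strict=True``, strictly more than ``run_threshold *
    R``); its importance is the mean over the runs where it appeared.
    """
    R = len(run_edges)
    if R < 2:
        raise ValueError("need at least 2 runs to aggregate")
    allr = pd.concat(run_edges, ignore_index=True)
    g = allr.groupby(["tf", "target"], sort=True)["importance"].agg(["size", "mean"])
    if strict:
        keep = g["size"] > run_threshold * R
    else:
        keep = g["size"] >= int(np.ceil(run_threshold * R - 1e-9))
    out = g[keep].reset_index()
    out["run_support"] = out.pop("size") / R
    out = out.rename(columns={"mean": "importance"})
    return out[["tf", "target", "importance", "run_support"]]


def aggregate_individuals(
    indiv_edges: list[pd.DataFrame],
    indiv_threshold: float = 0.8,
    strict: bool = False,
) -> pd.DataFrame:
    """Consensus edges detected in at least 80% of individuals.

    Importance is the mean of per-individual importances over individuals
    where the edge was detected; the individual-support fraction (and the
    mean run-support where available) is recorded.
    """
    N = len(indiv_edges)
    if N < 2:
        raise ValueError("need at least 2 individuals to aggregate")
    allr = pd.concat(indiv_edges, ignore_index=True)
    agg = {"size": ("importance", "size"), "importance": ("importance", "mean")}
    if "run_support" in allr.columns:
        agg["run_support"] = ("run_support", "mean")
    g = allr.groupby(["tf", "target"], sort=True).agg(**agg)
    if strict:
        keep = g["size"] > indiv_threshold * N
    else:
        keep = g["size"] >= int(np.ceil(indiv_threshold * N - 1e-9))
    out = g[keep].reset_index()
    out["individual_support"] = out.pop("size") / N
    cols = ["tf", "target", "importance", "individual_support"]
    if "run_support" in out.columns:
        cols.append("run_support")
    return out[cols]


def prune_edges(
    edges: pd.DataFrame,
    allowlist: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Group edges into regulons, optionally pruned by a TF->target allowlist.

    The allowlist (columns tf, target) stands in for motif-based promoter
    filtering: an edge survives only when its target is permitted for its
    TF. TFs left without targets are omitted (logged via warning).
    """
    work = edges
    if allowlist is not None:
        permitted = set(zip(allowlist.iloc[:, 0], allowlist.iloc[:, 1]))
        mask = [(t, g) in permitted for t, g in zip(work["tf"], work["target"])]
        work = work[np.asarray(mask, dtype=bool)] if len(work) else work
    regulons: dict[str, pd.DataFrame] = {}
    dropped = []
    for tf in sorted(edges["tf"].unique()):
        sub = work[work["tf"] == tf]
        if len(sub) == 0:
            dropped.append(tf)
            continue
        regulons[tf] = sub.reset_index(drop=True)
    if dropped:
        warnings.warn(f"TFs with no surviving targets omitted: {dropped}")
    return regulons


def run_grn(
    adata,
    tf_list,
    n_runs: int = 4,
    run_threshold: float = 0.8,
    indiv_threshold: float = 0.8,
    allowlist: pd.DataFrame | None = None,
    seed: int = 0,
    **score_kwargs,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-individual inference with two-tier reproducibility aggregation.

    The most prevalent cell type is downsampled per individual before
    inference (to the second most prevalent type's count). Returns the
    consensus edge table and the regulons after optional pruning.
    """
    ss = np.random.SeedSequence(seed)
    indivs = sorted(adata.obs["individual"].unique())
    per_indiv = []
    for ind, child in zip(indivs, ss.spawn(len(indivs))):
        mask = (adata.obs["individual"] == ind).to_numpy()
        idx = np.flatnonzero(mask)
        labels = adata.obs["cell_type"].to_numpy()[idx]
        rng_keys = child.spawn(n_runs + 1)
        keep = downsample_majority(
            idx, labels, seed=int(np.random.default_rng(rng_keys[0]).integers(2**31 - 1))
        )
        expr = adata.X[keep]
        runs = []
        for r in range(n_runs):
            run_seed = int(np.random.default_rng(rng_keys[r + 1]).integers(2**31 - 1))
            runs.append(
                score_tf_importance(
                    expr, tf_list, adata.var_names, seed=run_seed, **score_kwargs
                )
            )
        per_indiv.append(aggregate_runs(runs, run_threshold=run_threshold))
    consensus = aggregate_individuals(per_indiv, indiv_threshold=indiv_threshold)
    regulons = prune_edges(consensus, allowlist=allowlist)
    return consensus, regulons
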