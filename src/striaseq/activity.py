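"""AUCell-style gene-set activity scoring and activity regressions.

Within each cell, genes are ranked by decreasing count (ties broken by a
seeded random permutation) and a gene set's activity is the area under
its recovery curve within the top fraction of the ranking, normalized so
a set occupying the very top ranks scores 1. Scores are averaged into
pseudobulk by (individual, region, cell type) and compared between
groups with ordinary least squares models matching the human
(diagnosis + Age/PMI/RIN/Sex covariates, or the cell-type interaction
form) and paired macaque (treatment + pair) designs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.formula.api as smf

from .fdr import bh_adjust, qvalue_covariate

__all__ = [
    "rank_cells",
    "aucell_score",
    "score_cells",
    "pseudobulk_activity",
    "test_activity",
]


def rank_cells(counts, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell gene rankings by decreasing count with seeded tie-breaks.

    Returns ``(ranks, all_zero)``: ``ranks[i, g]`` is the 1-based rank of
    gene g in cell i (rank 1 = highest count); all-zero cells are flagged
    for exclusion from scoring.
    """
    X = counts.toarray() if sp.issparse(counts) else np.asarray(counts)
    rng = np.random.default_rng(seed)
    jitter = rng.random(X.shape) * 0.5  # < 1 so only integer ties reorder
    order = np.argsort(-(X + jitter), axis=1, kind="stable")
    ranks = np.empty_like(order)
    n = X.shape[1]
    rows = np.arange(X.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, n + 1)[None, :]
    all_zero = X.sum(axis=1) == 0
    return ranks, all_zero


def aucell_score(
    ranks: np.ndarray,
    set_positions: np.ndarray,
    top_frac: float = 0.05,
) -> np.ndarray:
    """Recovery-curve AUC of one gene set for each ranked cell.

    With threshold ``k = max(1, floor(top_frac * n_genes))``, the recovery
    curve R(j) counts set genes at rank <= j for j = 1..k; the score is
    sum_j R(j) divided by its maximum (all set genes at the very top), so
    it is 1 iff the set occupies the top ranks and 0 when no member is in
    the top k.
    """
    n_genes = ranks.shape[1]
    if len(set_positions) == 0:
        raise ValueError("gene set has no members in the namespace")
    k = max(1, int(np.floor(top_frac * n_genes)))
    r = ranks[:, set_positions]  # cells x set
    within = np.clip(k - r + 1, 0, None)  # each member at rank r contributes k-r+1
    total = within.sum(axis=1)
    m = min(len(set_positions), k)
    # maximum attainable: members at ranks 1..m contribute sum_{r<=m}(k-r+1)
    max_total = m * k - m * (m - 1) // 2
    return total / max_total


def score_cells(
    adata,
    gene_sets: dict[str, list[str]],
    top_frac: float = 0.05,
    seed: int = 0,
    chunk: int = 2048,
) -> pd.DataFrame:
    """AUCell scores (cells x gene sets); all-zero cells get NaN."""
    name_pos = {g: i for i, g in enumerate(adata.var_names)}
    positions = {}
    for name, members in gene_sets.items():
        pos = np.array([name_pos[g] for g in members if g in name_pos])
        if len(pos) == 0:
            raise ValueError(f"gene set {name!r} shares no genes with the data")
        positions[name] = pos
    out = np.empty((adata.n_obs, len(gene_sets)))
    ss = np.random.SeedSequence(seed)
    for ci, lo in enumerate(range(0, adata.n_obs, chunk)):
        hi = min(lo + chunk, adata.n_obs)
        ranks, zero = rank_cells(
            adata.X[lo:hi], seed=int(np.random.default_rng(ss.spawn(1)[0]).integers(2**31 - 1))
        )
        for j, (name, pos) in enumerate(positions.items()):
            out[lo:hi, j] = aucell_score(ranks, pos, top_frac=top_frac)
        out[lo:hi][zero] = np.nan
    return pd.DataFrame(out, index=adata.obs_names, columns=list(gene_sets))


def pseudobulk_activity(
    scores: pd.DataFrame,
    cell_meta: pd.DataFrame,
    keys: tuple[str, ...] = ("individual", "region", "cell_type"),
    min_cells: int = 20,
) -> pd.DataFrame:
    """Mean per-cell score per (individual, region, cell type) group.

    Groups with fewer than ``min_cells`` scored cells are dropped (count
    reported via warning). NaN-scored cells are excluded from the means.
    """
    for k in keys:
        if k not in cell_meta.columns:
            raise ValueError(f"missing grouping key {k!r}")
    joined = scores.join(cell_meta[list(keys)])
    grouped = joined.groupby(list(keys), observed=True, dropna=True)
    means = grouped[scores.columns.tolist()].mean()
    n = grouped[scores.columns[0]].count().rename("n_cells")
    out = means.join(n).reset_index()
    small = out["n_cells"] < min_cells
    if small.any():
        warnings.warn(f"{int(small.sum())} pseudobulk activity groups below {min_cells} cells dropped")
    return out[~small].reset_index(drop=True)


_MODES = ("human_sample", "human_celltype", "macaque_sample", "macaque_celltype")


def test_activity(
    pb_scores: pd.DataFrame,
    covariates: pd.DataFrame,
    gene_sets: list[str],
    mode: str = "human_celltype",
) -> pd.DataFrame:
    """Group-effect regressions on pseudobulk activity scores.

    Modes and their OLS formulas:

    * ``human_sample``:     score ~ Dx + Age + PMI + RIN + Sex
    * ``human_celltype``:   score ~ Dx:Celltype + Celltype + Age + PMI + RIN
      (+ log cell count), extracting the per-cell-type interaction terms
    * ``macaque_sample``:   score ~ Tx + Pair
    * ``macaque_celltype``: score ~ Celltype:Tx + Celltype + Pair

    Returns estimates, two-sided p, and FDR across all gene set x cell
    type tests jointly (covariate-aware when the family is large enough,
    plain BH otherwise).
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {_MODES}")
    df = pb_scores.merge(covariates, on="individual", how="left")
    group = "Dx" if mode.startswith("human") else "Tx"
    if mode == "human_sample":
        rhs = f"C({group}) + Age + PMI + RIN + C(Sex)"
    elif mode == "human_celltype":
        rhs = f"C({group}):C(cell_type) + C(cell_type) + Age + PMI + RIN"
        if "n_cells" in df.columns:
            df["log_n_cells"] = np.log(df["n_cells"].astype(float))
            rhs += " + log_n_cells"
    elif mode == "macaque_sample":
        rhs = f"C({group}) + C(Pair)"
    else:
        rhs = f"C(cell_type):C({group}) + C(cell_type) + C(Pair)"

    rows = []
    for gs in gene_sets:
        work = df.rename(columns={gs: "score"})
        model = smf.ols(f"score ~ {rhs}", data=work)
        mat = model.exog
        if np.linalg.matrix_rank(mat) < mat.shape[1]:
            u, s, vt = np.linalg.svd(mat)
            aliased = [
                model.exog_names[j]
                for j in np.flatnonzero(np.abs(vt[-1]) > 1e-6)
            ]
            raise ValueError(f"rank-deficient activity design; aliased terms: {aliased}")
        fit = model.fit()
        for name in fit.params.index:
            if f"C({group})" not in name:
                continue
            ct = None
            if "cell_type" in name:
                ct = name.split("C(cell_type)[")[1].split("]")[0]
                ct = ct.removeprefix("T.")
            term = f"{group}:Celltype" if ct else group
            # orient the estimate as case minus control regardless of which
            # level patsy picked as the dummy
            level = name.split(f"C({group})[")[1].split("]")[0].removeprefix("T.")
            sign = -1.0 if level in ("UC", "Control") else 1.0
            rows.append(
                (gs, ct, term, sign * float(fit.params[name]), float(fit.pvalues[name]))
            )
    out = pd.DataFrame(rows, columns=["gene_set", "cell_type", "term", "estimate", "p"])
    if len(out) >= 50:
        sizes = out.groupby("gene_set")["p"].transform("size").to_numpy(dtype=float)
        out["FDR"] = qvalue_covariate(out["p"].to_numpy(), sizes)
    elif len(out):
        out["FDR"] = bh_adjust(out["p"].to_numpy())
    else:
        out["FDR"] = []
    return out
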