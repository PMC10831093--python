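"""Reference-based label transfer, reproducible markers, abundance testing.

Label transfer is centroid-based: each query cell's log-normalized profile
is Spearman-correlated with every reference type centroid over shared
highly variable genes, correlations are converted to prediction scores by
a softmax, and cells whose best score falls below 0.5 stay "unassigned".
A second pass at higher resolution re-labels cells of a designated parent
class (medium spiny neurons in the striatal setting) against a subtype
reference. Marker genes are called one-vs-rest within each biological
replicate and kept only when reproducible across replicates; cell-type
abundance differences are tested on logit proportions with a mixed model.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = ["transfer_labels", "find_markers", "test_abundance"]


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def _log_norm(X: np.ndarray) -> np.ndarray:
    lib = X.sum(axis=1, keepdims=True)
    lib = np.where(lib > 0, lib, 1)
    return np.log1p(X / lib * 1e4)


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(X, axis=1)


def _spearman_to_centroids(cells: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Spearman correlation of each cell row with each centroid row."""
    rc = _rank_rows(cells)
    rr = _rank_rows(centroids)
    rc = rc - rc.mean(axis=1, keepdims=True)
    rr = rr - rr.mean(axis=1, keepdims=True)
    rc_n = np.linalg.norm(rc, axis=1, keepdims=True)
    rr_n = np.linalg.norm(rr, axis=1, keepdims=True)
    rc = np.divide(rc, rc_n, out=np.zeros_like(rc), where=rc_n > 0)
    rr = np.divide(rr, rr_n, out=np.zeros_like(rr), where=rr_n > 0)
    return rc @ rr.T


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _select_hvg(logx: np.ndarray, n_hvg: int) -> np.ndarray:
    v = logx.var(axis=0)
    if len(v) <= n_hvg:
        return np.arange(len(v))
    return np.sort(np.argsort(-v)[:n_hvg])


def _score_pass(
    query: np.ndarray,
    gene_names: np.ndarray,
    reference: pd.DataFrame,
    n_hvg: int,
    softmax_scale: float,
) -> tuple[np.ndarray, pd.DataFrame]:
    shared = reference.index.intersection(pd.Index(gene_names))
    if len(shared) < 50:
        raise ValueError(f"only {len(shared)} shared genes between query and reference")
    if (reference.loc[shared].sum(axis=0) == 0).any():
        raise ValueError("reference contains an all-zero type profile on shared genes")
    pos = pd.Index(gene_names).get_indexer(shared)
    logq = _log_norm(query[:, pos])
    logr = np.log1p(reference.loc[shared].T.to_numpy() * 1e4)  # types x genes
    hvg = _select_hvg(logq, n_hvg)
    corr = _spearman_to_centroids(logq[:, hvg], logr[:, hvg])
    scores = _softmax(softmax_scale * corr)
    return scores, pd.DataFrame(scores, columns=reference.columns)


def transfer_labels(
    query,
    reference: pd.DataFrame,
    min_score: float = 0.5,
    subtype_reference: pd.DataFrame | None = None,
    parent_class: str = "MSN",
    subtype_parents: dict[str, str] | None = None,
    n_hvg: int = 1000,
    softmax_scale: float = 30.0,
) -> pd.DataFrame:
    """Two-stage label transfer with prediction-score filtering.

    ``query`` is an AnnData or (counts, gene names) pair; ``reference`` a
    genes x types profile table. Cells whose maximum class score is below
    ``min_score`` are labeled ``"unassigned"``. When ``subtype_reference``
    is given, cells whose class label equals ``parent_class`` (or maps to
    it through ``subtype_parents``) are re-scored against the subtype
    reference, with the same cutoff.
    """
    if hasattr(query, "X"):
        X = _dense(query.X)
        gene_names = np.asarray(query.var_names)
        index = query.obs_names
    else:
        X, gene_names = query
        X = _dense(X)
        gene_names = np.asarray(gene_names)
        index = pd.RangeIndex(X.shape[0])
    if reference.shape[1] < 2:
        raise ValueError("reference must contain at least 2 types")

    _, score_df = _score_pass(X, gene_names, reference, n_hvg, softmax_scale)
    best = score_df.to_numpy().argmax(axis=1)
    max_score = score_df.to_numpy().max(axis=1)
    labels = score_df.columns.to_numpy()[best].astype(object)
    labels[max_score < min_score] = "unassigned"

    out = pd.DataFrame(
        {
            "class_label": labels,
            "class_score": max_score,
            "subtype_label": pd.array([None] * len(labels), dtype=object),
            "subtype_score": np.full(len(labels), np.nan),
        },
        index=index,
    )
    if subtype_reference is not None:
        parents = subtype_parents or {}
        is_parent = np.array(
            [lab == parent_class or parents.get(lab) == parent_class for lab in labels]
        )
        if is_parent.any():
            _, sub_df = _score_pass(
                X[is_parent], gene_names, subtype_reference, n_hvg, softmax_scale
            )
            sbest = sub_df.to_numpy().argmax(axis=1)
            smax = sub_df.to_numpy().max(axis=1)
            slab = sub_df.columns.to_numpy()[sbest].astype(object)
            slab[smax < min_score] = "unassigned"
            out.loc[is_parent, "subtype_label"] = slab
            out.loc[is_parent, "subtype_score"] = smax
    out["scores"] = list(score_df.to_numpy())
    return out


def find_markers(
    counts,
    labels,
    replicates,
    min_replicate_frac: float = 0.8,
    min_log2fc: float = 1.0,
    min_detect_diff: float = 0.2,
    alpha: float = 0.05,
    gene_names=None,
) -> pd.DataFrame:
    """Cell-type markers reproducible across biological replicates.

    Within each replicate a gene is a candidate marker of type T when its
    one-vs-rest log2 fold-change is >= ``min_log2fc``, its detection-rate
    difference is >= ``min_detect_diff``, and a rank-sum test rejects at
    ``alpha``. A gene is reported as a marker when it passes in at least
    ``min_replicate_frac`` of the replicates containing T.
    """
    X = _dense(counts)
    labels = np.asarray(labels)
    replicates = np.asarray(replicates)
    if gene_names is None:
        gene_names = np.array([f"g{i}" for i in range(X.shape[1])])
    gene_names = np.asarray(gene_names)
    types = np.unique(labels)
    rep_ids = np.unique(replicates)
    records = []
    for t in types:
        reps_with_t = [r for r in rep_ids if ((replicates == r) & (labels == t)).sum() >= 3]
        if len(reps_with_t) < 2:
            warnings.warn(f"cell type {t!r} present in <2 replicates; skipped")
            continue
        passes = np.zeros(X.shape[1], dtype=int)
        for r in reps_with_t:
            in_rep = replicates == r
            logx = _log_norm(X[in_rep])
            is_t = labels[in_rep] == t
            if (~is_t).sum() < 3:
                continue
            mean_in = logx[is_t].mean(axis=0)
            mean_out = logx[~is_t].mean(axis=0)
            lfc = (mean_in - mean_out) / np.log(2)  # log1p-CPM difference on log2 scale
            det_diff = (X[in_rep][is_t] > 0).mean(axis=0) - (X[in_rep][~is_t] > 0).mean(axis=0)
            stat = scipy.stats.mannwhitneyu(
                logx[is_t], logx[~is_t], axis=0, alternative="greater"
            )
            ok = (lfc >= min_log2fc) & (det_diff >= min_detect_diff) & (stat.pvalue < alpha)
            passes += ok.astype(int)
        frac = passes / len(reps_with_t)
        hit = frac >= min_replicate_frac
        for gi in np.flatnonzero(hit):
            records.append((t, gene_names[gi], frac[gi]))
    return pd.DataFrame(records, columns=["cell_type", "gene", "replicate_frac"])


def test_abundance(
    cell_counts: pd.DataFrame,
    covariates: pd.DataFrame,
    group_col: str = "Dx",
    min_samples: int = 3,
) -> pd.DataFrame:
    """Differential cell-type abundance on logit proportions.

    ``cell_counts`` has one row per sample with columns ``individual``,
    ``region`` and one count column per cell type. Proportions (with a
    Haldane 0.5 offset) are logit-transformed and regressed on the group
    factor plus sex and region with a random intercept per individual;
    when the mixed fit is singular the model falls back to OLS with
    individual-clustered standard errors. P-values are BH-adjusted across
    cell types.
    """
    meta_cols = [c for c in ("individual", "region") if c in cell_counts.columns]
    type_cols = [c for c in cell_counts.columns if c not in meta_cols]
    counts = cell_counts[type_cols].to_numpy(dtype=float)
    total = counts.sum(axis=1, keepdims=True)
    prop = (counts + 0.5) / (total + 0.5 * counts.shape[1])
    logit = np.log(prop / (1.0 - prop))

    df = cell_counts[meta_cols].copy()
    df = df.merge(covariates, on="individual", how="left")
    results = []
    for j, t in enumerate(type_cols):
        observed = counts[:, j] > 0
        if observed.sum() < min_samples:
            warnings.warn(f"cell type {t!r} observed in <{min_samples} samples; excluded")
            continue
        work = df.copy()
        work["y"] = logit[:, j]
        if np.ptp(logit[:, j]) < 1e-12:
            # identical proportions everywhere: exactly null
            results.append((t, 0.0, 1.0))
            continue
        terms = [f"C({group_col})"]
        if "Sex" in work.columns and work["Sex"].nunique() > 1:
            terms.append("C(Sex)")
        if "region" in work.columns and work["region"].nunique() > 1:
            terms.append("C(region)")
        formula = "y ~ " + " + ".join(terms)
        coef_name = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm(formula, work, groups=work["individual"])
                fit = md.fit(reml=True, method="lbfgs")
            if not np.isfinite(fit.bse.iloc[1]) or fit.cov_re.iloc[0, 0] < 1e-10:
                raise np.linalg.LinAlgError("singular random effect")
            coef_name = [c for c in fit.params.index if c.startswith(f"C({group_col})")][0]
            coef = fit.params[coef_name]
            # between-within t df: the group factor varies at the
            # individual level, so the normal-based Wald p is too liberal
            df_bw = max(work["individual"].nunique() - len(terms) - 1, 3)
            p = 2.0 * scipy.stats.t.sf(abs(coef / fit.bse[coef_name]), df_bw)
        except Exception:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.ols(formula, work).fit(
                    cov_type="cluster", cov_kwds={"groups": work["individual"]}
                )
            coef_name = [c for c in fit.params.index if c.startswith(f"C({group_col})")][0]
            coef = fit.params[coef_name]
            df_bw = max(work["individual"].nunique() - len(terms) - 1, 3)
            p = 2.0 * scipy.stats.t.sf(abs(coef / fit.bse[coef_name]), df_bw)
        results.append((t, float(coef), float(p)))
    out = pd.DataFrame(results, columns=["cell_type", "coefficient", "p"])
    if len(out):
        out["FDR"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["FDR"] = []
    return out
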