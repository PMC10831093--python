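"""Droplet-level QC flags and the cluster-level removal rule.

Three per-cell flaggers mirror the standard snRNA-seq triage:

* empty droplets from a two-component split of the nuclear (intronic UMI)
  fraction with the conventional rescue clauses (``nf_rescue=0.50``,
  ``umi_rescue=1000``),
* doublets from a two-part hybrid score (marker co-expression + simulated
  doublet proximity), each part normalized to [0, 1] and summed, with the
  fixed call threshold of 1.0,
* damaged nuclei from a two-component EM mixture of regressions of
  mitochondrial fraction on detected genes, called at posterior > 0.75.

A cluster is then removed outright when more than 10% of its cells carry
any flag; flagged cells inside retained clusters are removed individually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "flag_empty_droplets",
    "score_doublets",
    "flag_damaged",
    "drop_flagged_clusters",
    "run_qc",
    "MixtureRegressionFit",
]


def flag_empty_droplets(
    nuclear_fraction: np.ndarray,
    umi_total: np.ndarray,
    nf_rescue: float = 0.50,
    umi_rescue: int = 1000,
    random_state: int = 0,
) -> np.ndarray:
    """Flag cells in the low nuclear-fraction component as empty droplets.

    The boundary between ambient-dominated droplets and true nuclei is
    found by a two-component 1-D Gaussian mixture on the nuclear fraction.
    A cell escapes the flag when ``nuclear_fraction > nf_rescue`` or
    ``umi_total >= umi_rescue``.
    """
    nf = np.asarray(nuclear_fraction, dtype=float)
    umi = np.asarray(umi_total)
    if nf.shape != umi.shape:
        raise ValueError("nuclear_fraction and umi_total differ in length")
    if np.ptp(nf) < 1e-12:
        warnings.warn("all nuclear fractions identical; no empty-droplet boundary")
        return np.zeros(nf.shape, dtype=bool)
    gm = GaussianMixture(n_components=2, random_state=random_state, n_init=3)
    labels = gm.fit_predict(nf[:, None])
    means = gm.means_.ravel()
    if abs(means[0] - means[1]) < 0.02:
        warnings.warn("nuclear fraction appears unimodal; no empty-droplet boundary")
        return np.zeros(nf.shape, dtype=bool)
    low = int(np.argmin(means))
    flagged = labels == low
    flagged &= ~(nf > nf_rescue)
    flagged &= ~(umi >= umi_rescue)
    return flagged


def _log_cpm(counts: np.ndarray) -> np.ndarray:
    lib = counts.sum(axis=1, keepdims=True)
    lib = np.where(lib > 0, lib, 1)
    return np.log1p(counts / lib * 1e4)


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-12:
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def _marker_panel(logx: np.ndarray, clusters: np.ndarray, n_markers: int) -> dict:
    """Top cluster-exclusive genes by mean difference from best other cluster."""
    uniq = np.unique(clusters)
    means = np.vstack([logx[clusters == c].mean(axis=0) for c in uniq])
    panel = {}
    for i, c in enumerate(uniq):
        others = np.delete(means, i, axis=0)
        spec = means[i] - others.max(axis=0)
        panel[c] = np.argsort(-spec)[:n_markers]
    return panel


def score_doublets(
    counts,
    cluster_labels,
    seed: int = 0,
    n_markers: int = 25,
    n_components: int = 30,
    n_neighbors: int = 20,
    threshold: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Hybrid doublet score in [0, 2]; cells above ``threshold`` are flagged.

    Component (a): for each cell, detection of the marker panel of its
    second-best cluster — high only when markers of two mutually exclusive
    clusters are co-detected. Component (b): the fraction of simulated
    doublets (sums of random cell pairs) among the cell's nearest
    neighbors in PCA space. Each component is min-max normalized to [0, 1].
    With a single cluster, component (a) is undefined and (b) alone is
    scaled to [0, 2].
    """
    X = counts.toarray() if sp.issparse(counts) else np.asarray(counts)
    clusters = np.asarray(cluster_labels)
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty count matrix")
    rng = np.random.default_rng(seed)
    logx = _log_cpm(X)

    # (b) simulated-doublet proximity; heterotypic pairs only, so that
    # depth-doubled cells of the majority type do not pollute the simulation
    n_sim = n
    ii = rng.integers(0, n, size=n_sim)
    jj = rng.integers(0, n, size=n_sim)
    for _ in range(10):
        same = clusters[ii] == clusters[jj]
        if not same.any() or len(np.unique(clusters)) < 2:
            break
        jj[same] = rng.integers(0, n, size=int(same.sum()))
    sim = X[ii] + X[jj]
    log_all = np.vstack([logx, _log_cpm(sim)])
    n_comp = min(n_components, log_all.shape[1], log_all.shape[0] - 1)
    pca = PCA(n_components=n_comp, random_state=seed)
    emb = pca.fit_transform(log_all)
    k = min(n_neighbors, n + n_sim - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n])
    idx = idx[:, 1:]  # drop self
    prox = (idx >= n).mean(axis=1)

    uniq = np.unique(clusters)
    if len(uniq) < 2:
        warnings.warn("single cluster: doublet score from proximity component only")
        score = 2.0 * _minmax(prox)
        return score, score > threshold

    # (a) co-expression of mutually exclusive cluster markers
    panel = _marker_panel(logx, clusters, n_markers)
    detect = np.vstack([(X[:, panel[c]] > 0).mean(axis=1) for c in uniq]).T  # n x T
    order = np.argsort(-detect, axis=1)
    second = detect[np.arange(n), order[:, 1]]
    if np.ptp(second) < 1e-12 and np.ptp(prox) < 1e-12:
        return np.zeros(n), np.zeros(n, dtype=bool)

    score = _minmax(second) + _minmax(prox)
    return score, score > threshold


@dataclass
class MixtureRegressionFit:
    """EM fit of a 2-component mixture of linear regressions."""

    coef_intact: np.ndarray
    coef_damaged: np.ndarray
    sigma: np.ndarray
    weight_damaged: float
    converged: bool
    n_iter: int


def _wls(X, y, w):
    sw = np.sqrt(np.clip(w, 1e-12, None))
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return beta


def flag_damaged(
    mito_fraction: np.ndarray,
    n_genes: np.ndarray,
    posterior_cutoff: float = 0.75,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, MixtureRegressionFit]:
    """Posterior damaged-cell probabilities from an EM mixture of regressions.

    Fits two linear regressions of mitochondrial fraction on the number of
    detected genes: an intact component (flat, low) and a damaged component
    (elevated). Initialization splits cells at the 10th/90th mitochondrial
    fraction quantiles; EM runs at most ``max_iter`` iterations to a
    log-likelihood tolerance of ``tol``. Cells with posterior membership in
    the damaged component strictly above ``posterior_cutoff`` are flagged.
    """
    y = np.asarray(mito_fraction, dtype=float)
    x = np.asarray(n_genes, dtype=float)
    n = len(y)
    if n < 10 or np.ptp(y) < 1e-9:
        return np.zeros(n), np.zeros(n, dtype=bool), MixtureRegressionFit(
            np.zeros(2), np.zeros(2), np.zeros(2), 0.0, True, 0
        )
    xs = (x - x.mean()) / (x.std() + 1e-12)
    X = np.column_stack([np.ones(n), xs])
    q10, q90 = np.quantile(y, [0.10, 0.90])
    resp = np.clip((y - q10) / max(q90 - q10, 1e-9), 0.0, 1.0)  # damaged resp.

    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w_dam = resp
        w_int = 1.0 - resp
        b_int = _wls(X, y, w_int)
        b_dam = _wls(X, y, w_dam)
        r_int = y - X @ b_int
        r_dam = y - X @ b_dam
        s_int = np.sqrt(np.sum(w_int * r_int**2) / max(w_int.sum(), 1e-9)) + 1e-6
        s_dam = np.sqrt(np.sum(w_dam * r_dam**2) / max(w_dam.sum(), 1e-9)) + 1e-6
        pi_dam = np.clip(resp.mean(), 1e-6, 1 - 1e-6)
        log_int = np.log(1 - pi_dam) - np.log(s_int) - 0.5 * (r_int / s_int) ** 2
        log_dam = np.log(pi_dam) - np.log(s_dam) - 0.5 * (r_dam / s_dam) ** 2
        mx = np.maximum(log_int, log_dam)
        ll = float(np.sum(mx + np.log(np.exp(log_int - mx) + np.exp(log_dam - mx))))
        resp = 1.0 / (1.0 + np.exp(log_int - log_dam))
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll
    if not converged:
        warnings.warn(f"damaged-cell EM did not converge in {max_iter} iterations")

    # orient: damaged = the component with the higher mean fitted level
    if (X @ b_dam).mean() < (X @ b_int).mean():
        resp = 1.0 - resp
        b_int, b_dam = b_dam, b_int
        s_int, s_dam = s_dam, s_int
    # degenerate single-component data: components indistinguishable
    if abs((X @ b_dam).mean() - (X @ b_int).mean()) < 3e-3:
        resp = np.zeros(n)
    fit = MixtureRegressionFit(
        coef_intact=b_int,
        coef_damaged=b_dam,
        sigma=np.array([s_int, s_dam]),
        weight_damaged=float(resp.mean()),
        converged=converged,
        n_iter=it,
    )
    return resp, resp > posterior_cutoff, fit


def drop_flagged_clusters(
    cluster_labels,
    flagged,
    max_flagged_frac: float = 0.10,
) -> pd.Series:
    """Boolean retained mask after the cluster-level removal rule.

    A cluster is removed iff strictly more than ``max_flagged_frac`` of its
    cells carry at least one flag; all its cells are excluded. Flagged cells
    inside retained clusters are also excluded individually.
    """
    clusters = pd.Series(np.asarray(cluster_labels, dtype=object))
    flags = pd.Series(np.asarray(flagged, dtype=bool))
    if clusters.isna().any():
        raise ValueError("unlabeled cells: every cell needs a cluster label")
    frac = flags.groupby(clusters).mean()
    bad_clusters = set(frac.index[frac > max_flagged_frac])
    retained = ~clusters.isin(bad_clusters) & ~flags
    retained.index = clusters.index
    return retained


def run_qc(
    adata,
    nf_rescue: float = 0.50,
    umi_rescue: int = 1000,
    doublet_threshold: float = 1.0,
    miqc_posterior: float = 0.75,
    max_flagged_frac: float = 0.10,
    seed: int = 0,
    sample_key: str | None = None,
) -> pd.DataFrame:
    """Run all three flaggers (per sample) plus the cluster rule on a cohort.

    Returns a per-cell table with the metrics, the three boolean flags, and
    the final ``retained`` decision. Requires ``obs`` columns
    ``nuclear_fraction``, ``umi_total``, ``n_genes``, ``mito_fraction``,
    ``cluster``, and (when ``sample_key`` is given) the sample grouping.
    """
    obs = adata.obs
    n = adata.n_obs
    empty = np.zeros(n, dtype=bool)
    doublet_score = np.zeros(n)
    doublet = np.zeros(n, dtype=bool)
    damaged_post = np.zeros(n)
    damaged = np.zeros(n, dtype=bool)
    if sample_key is None:
        groups = {None: np.arange(n)}
    else:
        groups = {
            k: np.asarray(v)
            for k, v in obs.groupby(sample_key, sort=False, observed=True).indices.items()
        }
    for gi, idx in enumerate(groups.values()):
        sub = obs.iloc[idx]
        empty[idx] = flag_empty_droplets(
            sub["nuclear_fraction"].to_numpy(),
            sub["umi_total"].to_numpy(),
            nf_rescue=nf_rescue,
            umi_rescue=umi_rescue,
            random_state=seed,
        )
        doublet_score[idx], doublet[idx] = score_doublets(
            adata.X[idx],
            sub["cluster"].to_numpy(),
            seed=seed + gi,
            threshold=doublet_threshold,
        )
        damaged_post[idx], damaged[idx], _ = flag_damaged(
            sub["mito_fraction"].to_numpy(),
            sub["n_genes"].to_numpy(),
            posterior_cutoff=miqc_posterior,
        )
    any_flag = empty | doublet | damaged
    retained = drop_flagged_clusters(
        obs["cluster"].to_numpy(), any_flag, max_flagged_frac=max_flagged_frac
    ).to_numpy()
    return pd.DataFrame(
        {
            "barcode": obs.index,
            "umi_total": obs["umi_total"].to_numpy(),
            "n_genes": obs["n_genes"].to_numpy(),
            "mito_fraction": obs["mito_fraction"].to_numpy(),
            "nuclear_fraction": obs["nuclear_fraction"].to_numpy(),
            "doublet_score": doublet_score,
            "damaged_posterior": damaged_post,
            "flag_empty": empty,
            "flag_doublet": doublet,
            "flag_damaged": damaged,
            "retained": retained,
        }
    ).set_index("barcode")
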