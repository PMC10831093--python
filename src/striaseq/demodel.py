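"""Precision-weighted nested-factor linear modeling for pseudobulk DE.

The model follows the precision-weighted linear-model tradition for
pseudobulk RNA-seq: log2-CPM responses, a mean-variance trend converted
into observation weights plus per-sample quality weights, a consensus
intra-individual correlation used as a known correlation in generalized
least squares, surrogate variables from the residual matrix, and
empirical-Bayes moderation of the residual variances. Diagnosis effects
are encoded through a single nested factor (cell type x diagnosis x sex
x region, or cell type x treatment for the paired-treatment design) so
that every contrast family — overall case-control, within one sex, and
the sex-by-diagnosis interaction — is a linear contrast over its levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess
from scipy.stats import t as t_dist

from . import pseudobulk
from .fdr import bh_adjust, qvalue_covariate

__all__ = [
    "build_design",
    "estimate_precision_weights",
    "estimate_duplicate_correlation",
    "estimate_surrogate_variables",
    "fit_nested_model",
    "ebayes",
    "contrast_stats",
    "build_contrasts",
    "run_de",
    "NestedFit",
]

NESTED_SEP = "_"


# --------------------------------------------------------------------------
# design
# --------------------------------------------------------------------------

def nested_level(row, species: str = "human") -> str:
    if species == "human":
        return NESTED_SEP.join([str(row["cell_type"]), str(row["Dx"]), str(row["Sex"]), str(row["region"])])
    return NESTED_SEP.join([str(row["cell_type"]), str(row["Tx"])])


def build_design(
    meta: pd.DataFrame,
    covariates: pd.DataFrame,
    species: str = "human",
) -> pd.DataFrame:
    """Design matrix: intercept-free nested factor plus scaled covariates.

    Human mode adds Age, PMI, RIN, and GDR; the paired macaque mode adds
    GDR and the matched-pair blocking dummies instead.
    """
    work = meta.merge(covariates, on="individual", how="left")
    work.index = meta.index
    levels = work.apply(nested_level, axis=1, species=species)
    dummies = pd.get_dummies(levels, dtype=float)
    design = dummies
    if species == "human":
        for c in ("Age", "PMI", "RIN"):
            v = work[c].astype(float)
            design[c] = (v - v.mean()) / (v.std() if v.std() > 0 else 1.0)
    else:
        pair = pd.get_dummies(work["Pair"], prefix="Pair", drop_first=True, dtype=float)
        design = pd.concat([design, pair], axis=1)
    if "GDR" in work.columns:
        v = work["GDR"].astype(float)
        design["GDR"] = (v - v.mean()) / (v.std() if v.std() > 0 else 1.0)
    design.index = meta.index
    return design


def _check_full_rank(X: np.ndarray, columns) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        aliased = [str(columns[j]) for j in piv[rank:]] if len(diag) else []
        raise ValueError(f"design is rank deficient; aliased columns: {aliased}")


# --------------------------------------------------------------------------
# precision weights (voom-style) and sample quality weights
# --------------------------------------------------------------------------

def estimate_precision_weights(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    span: float = 0.5,
    quality_weights: bool = True,
    n_quality_iter: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Observation weights from the mean-variance trend, times per-sample
    quality weights.

    ``counts`` is profiles x genes (raw sums). Returns ``(weights,
    sample_weights)`` with ``weights`` of shape (n_profiles, n_genes).
    With fewer than 10 genes there is no trend to fit and constant
    weights are returned with a warning.
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    G = counts.shape[1]
    lib = counts.sum(axis=1).to_numpy(dtype=float)
    y = pseudobulk.normalize_cpm(counts).to_numpy()  # n x G
    if G < 10:
        warnings.warn("fewer than 10 genes; constant precision weights")
        return np.ones((n, G)), np.ones(n)
    pinv = np.linalg.pinv(X)
    beta = pinv @ y
    fitted = X @ beta
    resid = y - fitted
    df = n - np.linalg.matrix_rank(X)
    sigma = np.sqrt((resid**2).sum(axis=0) / max(df, 1))
    # mean log2-count scale for the trend
    sx = y.mean(axis=0) + np.log2(np.exp(np.mean(np.log(lib + 1.0)))) - np.log2(1e6)
    sy = np.sqrt(sigma)
    lo = lowess(sy, sx, frac=span, return_sorted=True)
    lx, ly = lo[:, 0], np.clip(lo[:, 1], 1e-6, None)
    fitted_count = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[:, None]
    pred = np.interp(fitted_count, lx, ly)
    w = pred**-4.0

    sample_w = np.ones(n)
    if quality_weights:
        # per-sample variance factor from trend-standardized residuals;
        # the leverage correction n/df keeps the factors unbiased
        h = np.clip(np.einsum("ij,ji->i", X, pinv), 0.0, 0.95)
        r2 = (resid * np.sqrt(w)) ** 2
        s2 = r2.sum(axis=0) / max(df, 1)
        ratio = r2 / np.clip(s2, 1e-12, None)[None, :]
        v = ratio.mean(axis=1) / np.clip(1.0 - h, 0.05, None)
        sample_w = 1.0 / np.clip(v, 1e-3, None)
        sample_w /= np.exp(np.mean(np.log(sample_w)))
    return w * sample_w[:, None], sample_w


# --------------------------------------------------------------------------
# duplicate correlation
# --------------------------------------------------------------------------

def estimate_duplicate_correlation(
    log_cpm: pd.DataFrame,
    design: pd.DataFrame,
    blocks,
    weights: np.ndarray | None = None,
) -> float:
    """Consensus intra-block correlation of model residuals.

    Per gene, a one-way random-effects decomposition of the residuals over
    blocks gives an intraclass correlation; the consensus is
    ``tanh(mean(atanh(rho_g)))`` over genes with finite estimates.
    """
    X = design.to_numpy(dtype=float)
    y = log_cpm.to_numpy()
    blocks = np.asarray(blocks)
    uniq, block_idx = np.unique(blocks, return_inverse=True)
    sizes = np.bincount(block_idx)
    if (sizes < 2).all():
        warnings.warn("no repeated blocks; duplicate correlation set to 0")
        return 0.0
    # weights are accepted for interface compatibility but the consensus
    # correlation is estimated on unweighted residuals; it is a single
    # robust summary and insensitive to the precision weighting
    del weights
    pinv = np.linalg.pinv(X)
    resid = y - X @ (pinv @ y)
    n = len(blocks)
    B = len(uniq)
    ind = np.zeros((B, n))
    ind[block_idx, np.arange(n)] = 1.0
    group_sum = ind @ resid  # B x G
    group_mean = group_sum / sizes[:, None]
    grand = resid.mean(axis=0)
    ssb = (sizes[:, None] * (group_mean - grand[None, :]) ** 2).sum(axis=0)
    ssw = ((resid - group_mean[block_idx]) ** 2).sum(axis=0)
    dfb = B - 1
    dfw = n - B
    if dfb <= 0 or dfw <= 0:
        warnings.warn("degenerate block structure; duplicate correlation set to 0")
        return 0.0
    msb = ssb / dfb
    msw = ssw / dfw
    n0 = (n - (sizes**2).sum() / n) / dfb
    icc = (msb - msw) / (msb + (n0 - 1) * msw)
    icc = np.clip(icc, -0.99, 0.99)
    z = np.arctanh(icc)
    z = z[np.isfinite(z)]
    if len(z) == 0:
        warnings.warn("no finite intra-block correlations; consensus set to 0")
        return 0.0
    return float(np.tanh(z.mean()))


# --------------------------------------------------------------------------
# surrogate variables
# --------------------------------------------------------------------------

def estimate_surrogate_variables(
    log_cpm: pd.DataFrame,
    design: pd.DataFrame,
    n_sv: int | str = "auto",
    n_perm: int = 20,
    quantile: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Surrogate variables from the residual matrix after the known design.

    The residual matrix (profiles x genes) is decomposed by SVD; the
    sample-space singular vectors are the SV candidates. In ``auto`` mode
    a permutation parallel analysis keeps the leading components whose
    singular value exceeds the ``quantile`` of ``n_perm`` within-gene
    permuted decompositions. Returned SVs are orthogonalized against the
    design (and each other).
    """
    X = design.to_numpy(dtype=float)
    y = log_cpm.to_numpy()
    n, G = y.shape
    pinv = np.linalg.pinv(X)
    resid = y - X @ (pinv @ y)
    max_rank = n - np.linalg.matrix_rank(X)
    if isinstance(n_sv, (int, np.integer)) and n_sv >= max_rank:
        raise ValueError(f"requested n_sv={n_sv} >= residual rank {max_rank}")
    U, S, _ = np.linalg.svd(resid, full_matrices=False)
    if n_sv == "auto":
        # keyed substream so the permutation draws never share a stream
        # with whatever generated the data under the same integer seed
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x53F]))
        k_check = min(10, len(S))
        perm_s = np.empty((n_perm, k_check))
        for b in range(n_perm):
            # permute the data within each gene, then re-residualize, so the
            # permuted decompositions live in the same rank-reduced space as
            # the observed residuals
            shuffled = np.take_along_axis(
                y, np.argsort(rng.random(y.shape), axis=0), axis=0
            )
            shuffled = shuffled - X @ (pinv @ shuffled)
            perm_s[b] = np.linalg.svd(shuffled, compute_uv=False)[:k_check]
        thresh = np.quantile(perm_s, quantile, axis=0)
        k = 0
        for i in range(k_check):
            if S[i] > thresh[i]:
                k += 1
            else:
                break
        k = min(k, max_rank - 1)
    else:
        k = int(n_sv)
    if k <= 0:
        return np.zeros((n, 0))
    sv = U[:, :k] * S[:k]
    sv = sv - X @ (pinv @ sv)  # enforce orthogonality to the design
    q, _ = np.linalg.qr(sv)
    return q[:, :k]


# --------------------------------------------------------------------------
# nested GLS fit with eBayes moderation
# --------------------------------------------------------------------------

@dataclass
class NestedFit:
    coef: np.ndarray          # G x p
    cov_unscaled: np.ndarray  # G x p x p
    sigma2: np.ndarray        # G
    df_resid: float
    design_columns: list[str]
    genes: pd.Index
    amean: np.ndarray = field(default=None)  # average log-CPM per gene


def _block_correlation(blocks, rho: float) -> np.ndarray:
    blocks = np.asarray(blocks)
    n = len(blocks)
    C = np.eye(n)
    if rho != 0.0:
        same = blocks[:, None] == blocks[None, :]
        C = np.where(same, rho, 0.0)
        np.fill_diagonal(C, 1.0)
    return C


def fit_nested_model(
    log_cpm: pd.DataFrame,
    design: pd.DataFrame,
    weights: np.ndarray | None = None,
    rho: float = 0.0,
    blocks=None,
) -> NestedFit:
    """Gene-wise weighted GLS fit with a known intra-block correlation.

    The per-gene covariance is ``diag(1/sqrt(w)) C diag(1/sqrt(w))`` with
    ``C`` compound-symmetric within blocks at correlation ``rho``. Raises
    on rank-deficient designs, naming the aliased columns.
    """
    X = design.to_numpy(dtype=float)
    y = log_cpm.to_numpy()
    n, p = X.shape
    G = y.shape[1]
    _check_full_rank(X, design.columns)
    if weights is None:
        weights = np.ones((n, G))
    if rho != 0.0 and blocks is None:
        raise ValueError("rho != 0 requires block labels")
    whiten = None
    if rho != 0.0:
        C = _block_correlation(blocks, rho)
        L = np.linalg.cholesky(C)
        whiten = L

    coef = np.empty((G, p))
    cov = np.empty((G, p, p))
    sigma2 = np.empty(G)
    df = n - p
    sw = np.sqrt(np.clip(weights, 1e-12, None))
    chunk = max(1, int(2**25 / max(n * p, 1)))  # ~256 MB peak in float64
    for lo in range(0, G, chunk):
        hi = min(lo + chunk, G)
        swc = sw[:, lo:hi]  # n x g
        A = X[None, :, :] * swc.T[:, :, None]  # g x n x p
        b_vec = (y[:, lo:hi] * swc).T[:, :, None]  # g x n x 1
        if whiten is not None:
            gsz = hi - lo
            A2 = np.concatenate([A, b_vec], axis=2).transpose(1, 0, 2).reshape(n, -1)
            A2 = scipy.linalg.solve_triangular(whiten, A2, lower=True)
            A2 = A2.reshape(n, gsz, p + 1).transpose(1, 0, 2)
            A, b_vec = A2[:, :, :p], A2[:, :, p:]
        XtX = np.matmul(A.transpose(0, 2, 1), A)
        Xty = np.matmul(A.transpose(0, 2, 1), b_vec)
        ci = np.linalg.inv(XtX)
        bet = np.matmul(ci, Xty)
        r = b_vec - np.matmul(A, bet)
        coef[lo:hi] = bet[:, :, 0]
        cov[lo:hi] = ci
        sigma2[lo:hi] = (r[:, :, 0] ** 2).sum(axis=1) / df
    return NestedFit(
        coef=coef,
        cov_unscaled=cov,
        sigma2=sigma2,
        df_resid=float(df),
        design_columns=list(design.columns),
        genes=log_cpm.columns,
        amean=y.mean(axis=0),
    )


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if np.max(-dif / y) < 1e-8:
            break
    return y


def ebayes(fit: NestedFit, prior_df: float | None = None) -> dict:
    """Empirical-Bayes variance moderation by moment matching on log s^2.

    Fits a scaled inverse-chi-square prior to the gene-wise residual
    variances; ``prior_df=0`` disables shrinkage (ordinary t-statistics).
    Returns prior df, prior variance, and posterior variances.
    """
    s2 = np.clip(fit.sigma2, 1e-12, None)
    d = fit.df_resid
    z = np.log(s2)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    if prior_df is None:
        evar = np.var(e, ddof=1) - polygamma(1, d / 2.0)
        if evar > 0:
            df_prior = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
        else:
            df_prior = np.inf
    else:
        df_prior = float(prior_df)
    if np.isfinite(df_prior) and df_prior > 0:
        s2_prior = float(np.exp(np.mean(e) + digamma(df_prior / 2.0) - np.log(df_prior / 2.0)))
        s2_post = (df_prior * s2_prior + d * s2) / (df_prior + d)
    elif df_prior == 0:
        s2_prior = float(np.exp(np.mean(e)))
        s2_post = s2.copy()
    else:
        s2_prior = float(np.exp(np.mean(e)))
        s2_post = np.full_like(s2, s2_prior)
    return {"df_prior": df_prior, "s2_prior": s2_prior, "s2_post": s2_post}


def contrast_stats(
    fit: NestedFit,
    contrasts: pd.DataFrame,
    moderation: dict | None = None,
) -> pd.DataFrame:
    """Per-gene log2FC, (moderated) t, and two-sided p for each contrast.

    ``contrasts`` is indexed by design columns (missing rows are treated
    as zero) with one column per contrast.
    """
    if moderation is None:
        moderation = ebayes(fit)
    Lmat = contrasts.reindex(fit.design_columns).fillna(0.0).to_numpy()  # p x K
    est = fit.coef @ Lmat  # G x K
    var_unscaled = np.einsum("pk,gpq,qk->gk", Lmat, fit.cov_unscaled, Lmat)
    s2_post = moderation["s2_post"]
    df_total = fit.df_resid + (
        moderation["df_prior"] if np.isfinite(moderation["df_prior"]) else 0.0
    )
    if not np.isfinite(moderation["df_prior"]):
        df_total = 1e6
    se = np.sqrt(var_unscaled * s2_post[:, None])
    tstat = est / se
    pval = 2.0 * t_dist.sf(np.abs(tstat), df_total)
    frames = []
    for k, name in enumerate(contrasts.columns):
        frames.append(
            pd.DataFrame(
                {
                    "gene": fit.genes,
                    "contrast": name,
                    "logFC": est[:, k],
                    "t": tstat[:, k],
                    "P.Value": pval[:, k],
                    "AveExpr": fit.amean,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# contrasts over nested levels
# --------------------------------------------------------------------------

def _level_parts(level: str) -> list[str]:
    return level.split(NESTED_SEP)


def _diff_vector(levels, scope_types, case, control, sex=None) -> pd.Series:
    vec = pd.Series(0.0, index=pd.Index(levels))
    case_lv, ctrl_lv = [], []
    for lv in levels:
        parts = _level_parts(lv)
        if parts[0] not in scope_types:
            continue
        if sex is not None and len(parts) > 2 and parts[2] != sex:
            continue
        if parts[1] == case:
            case_lv.append(lv)
        elif parts[1] == control:
            ctrl_lv.append(lv)
    if not case_lv or not ctrl_lv:
        raise ValueError(
            f"no {case}/{control} levels for scope {sorted(scope_types)} (sex={sex})"
        )
    vec[case_lv] = 1.0 / len(case_lv)
    vec[ctrl_lv] = -1.0 / len(ctrl_lv)
    return vec


def build_contrasts(
    levels,
    family: str,
    scope_types,
    case: str = "OUD",
    control: str = "UC",
) -> pd.Series:
    """Contrast vector over observed nested levels for one family/scope.

    Families: ``overall`` (case - control averaged over sex and region),
    ``within_F`` / ``within_M`` (restricted to one sex),
    ``sex_interaction`` (the female difference minus the male difference),
    and ``treatment`` for the paired design (case - control per type).
    """
    scope_types = set(scope_types)
    present = {p for lv in levels for p in [_level_parts(lv)[0]]}
    if not scope_types & present:
        raise ValueError(f"scope {sorted(scope_types)} has no levels in the design")
    if family == "overall" or family == "treatment":
        return _diff_vector(levels, scope_types, case, control)
    if family == "within_F":
        return _diff_vector(levels, scope_types, case, control, sex="F")
    if family == "within_M":
        return _diff_vector(levels, scope_types, case, control, sex="M")
    if family == "sex_interaction":
        return _diff_vector(levels, scope_types, case, control, sex="F") - _diff_vector(
            levels, scope_types, case, control, sex="M"
        )
    raise ValueError(f"unknown contrast family {family!r}")


# --------------------------------------------------------------------------
# end-to-end driver
# --------------------------------------------------------------------------

HUMAN_FAMILIES = ("overall", "within_F", "within_M", "sex_interaction")


def run_de(
    adata,
    covariates: pd.DataFrame,
    species: str = "human",
    families=None,
    type_classes: dict[str, str] | None = None,
    min_cells: int = 20,
    min_mean_umi: float = 5.0,
    n_sv: int | str = "auto",
    seed: int = 0,
) -> pd.DataFrame:
    """Full pseudobulk DE: aggregate, filter, weight, fit, contrast, adjust.

    Returns a tidy table with one row per gene x cell-type scope x contrast
    family, carrying log2FC, moderated t, p, and the two covariate-adjusted
    FDR columns (within each cell type, and pooled across cell types).
    ``type_classes`` maps cell types to "Neuron"/"Glia" to enable the
    pooled scopes alongside the per-type ones.
    """
    profiles, meta = pseudobulk.aggregate_pseudobulk(adata, min_cells=min_cells)
    genes = pseudobulk.filter_genes(profiles, adata.var, min_mean_umi=min_mean_umi)
    profiles = profiles[genes]
    log_cpm = pseudobulk.normalize_cpm(profiles)
    design = build_design(meta, covariates, species=species)
    sv = estimate_surrogate_variables(log_cpm, design, n_sv=n_sv, seed=seed)
    for j in range(sv.shape[1]):
        design[f"SV{j + 1}"] = sv[:, j]
    weights, _ = estimate_precision_weights(profiles, design)
    blocks = meta["individual"].to_numpy()
    rho = estimate_duplicate_correlation(log_cpm, design, blocks, weights=weights)
    fit = fit_nested_model(log_cpm, design, weights=weights, rho=rho, blocks=blocks)
    mod = ebayes(fit)

    if families is None:
        families = HUMAN_FAMILIES if species == "human" else ("treatment",)
    case, control = ("OUD", "UC") if species == "human" else ("Morphine", "Control")
    levels = [c for c in design.columns if NESTED_SEP in c and not c.startswith("SV")]
    cell_types = sorted(meta["cell_type"].unique())
    scopes: dict[str, list[str]] = {ct: [ct] for ct in cell_types}
    if type_classes:
        for cls in ("Neuron", "Glia"):
            members = [ct for ct in cell_types if type_classes.get(ct) == cls]
            if members:
                scopes[cls] = members
        scopes["All"] = cell_types

    frames = []
    for family in families:
        cols = {}
        for scope_name, members in scopes.items():
            try:
                cols[scope_name] = build_contrasts(
                    levels, family, members, case=case, control=control
                )
            except ValueError:
                continue
        if not cols:
            continue
        cmat = pd.DataFrame(cols)
        stats = contrast_stats(fit, cmat, moderation=mod)
        stats = stats.rename(columns={"contrast": "cell_type"})
        stats["family"] = family
        frames.append(stats)
    out = pd.concat(frames, ignore_index=True)

    out["adj.P.Val.Within"] = np.nan
    out["adj.P.Val.Between"] = np.nan
    for family, fidx in out.groupby("family").indices.items():
        fidx = np.asarray(fidx)
        sub = out.iloc[fidx]
        for _, cidx in sub.groupby("cell_type").indices.items():
            rows = fidx[np.asarray(cidx)]
            out.iloc[rows, out.columns.get_loc("adj.P.Val.Within")] = qvalue_covariate(
                out["P.Value"].iloc[rows].to_numpy(), out["AveExpr"].iloc[rows].to_numpy()
            )
        out.iloc[fidx, out.columns.get_loc("adj.P.Val.Between")] = qvalue_covariate(
            out["P.Value"].iloc[fidx].to_numpy(), out["AveExpr"].iloc[fidx].to_numpy()
        )
    return out
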