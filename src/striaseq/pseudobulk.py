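"""Pseudobulk aggregation, gene filtering, and log-CPM normalization.

Raw UMI counts are summed over all cells sharing (individual, region,
cell type); profiles built from fewer than 20 cells are dropped, as are
mitochondrial, ribosomal, and low-expressed genes (mean UMI < 5 across
retained profiles). Each profile carries its cell count and gene
detection rate (GDR), both later used as model covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["aggregate_pseudobulk", "filter_genes", "normalize_cpm"]


def aggregate_pseudobulk(
    adata,
    keys: tuple[str, ...] = ("individual", "region", "cell_type"),
    min_cells: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum UMI counts per group of cells sharing ``keys``.

    Returns ``(profiles, meta)``: ``profiles`` is groups x genes integer
    sums, ``meta`` carries the key columns, ``n_cells``, and ``GDR`` (the
    fraction of genes detected in the profile). Groups with fewer than
    ``min_cells`` cells are dropped.
    """
    for k in keys:
        if k not in adata.obs.columns:
            raise ValueError(f"missing grouping key {k!r} in cell records")
    groups = adata.obs.groupby(list(keys), sort=True, observed=True).indices
    if not groups:
        raise ValueError("empty grouping: no cells to aggregate")
    X = adata.X.tocsr() if sp.issparse(adata.X) else np.asarray(adata.X)
    rows, meta_rows, names = [], [], []
    for key, idx in groups.items():
        if len(idx) < min_cells:
            continue
        block = X[np.asarray(idx)]
        total = np.asarray(block.sum(axis=0)).ravel().astype(np.int64)
        rows.append(total)
        key = key if isinstance(key, tuple) else (key,)
        names.append(":".join(str(k) for k in key))
        meta_rows.append((*key, len(idx), float((total > 0).mean())))
    if not rows:
        raise ValueError(f"no group reached min_cells={min_cells}")
    profiles = pd.DataFrame(np.vstack(rows), index=names, columns=adata.var_names)
    meta = pd.DataFrame(meta_rows, columns=[*keys, "n_cells", "GDR"], index=names)
    return profiles, meta


def filter_genes(
    profiles: pd.DataFrame,
    var: pd.DataFrame | None = None,
    min_mean_umi: float = 5.0,
) -> pd.Index:
    """Retained genes: not mito/ribo-flagged, mean count >= ``min_mean_umi``."""
    keep = pd.Series(True, index=profiles.columns)
    if var is not None:
        for flag in ("mito", "ribo"):
            if flag in var.columns:
                keep &= ~var[flag].reindex(profiles.columns).fillna(False).astype(bool)
    keep &= profiles.mean(axis=0) >= min_mean_umi
    retained = profiles.columns[keep]
    if len(retained) == 0:
        raise ValueError("no genes retained after filtering")
    return retained


def normalize_cpm(profiles: pd.DataFrame, prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a library-scaled prior count (voom-style).

    ``log2((count + 0.5) / (libsize + 1) * 1e6)`` — strictly increasing in
    the count at fixed library size and invariant to count doubling up to
    the prior.
    """
    lib = profiles.sum(axis=1).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("zero library size in pseudobulk profiles")
    cpm = (profiles.to_numpy(dtype=float) + prior_count) / (lib[:, None] + 1.0) * 1e6
    return pd.DataFrame(np.log2(cpm), index=profiles.index, columns=profiles.columns)
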