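"""Readers and writers for the plain-text formats used across the pipeline.

Counts travel as a MatrixMarket triplet directory (``matrix.mtx`` with
genes x cells orientation, plus ``features.tsv`` and ``barcodes.tsv``,
optionally gzipped), gene sets as GMT, and everything tabular as TSV.
In memory, counts live in an :class:`anndata.AnnData` with cells as
observations and genes as variables.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_table",
    "write_table",
]


def _find(dirpath: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dirpath / name
        if p.exists():
            return p
    raise FileNotFoundError(f"missing {stem}[.gz] in {dirpath}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def dedup_names(names) -> list[str]:
    """Disambiguate duplicate identifiers with deterministic .1, .2 suffixes."""
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}.{seen[n]}")
        else:
            seen[n] = 0
            out.append(n)
    return out


def read_counts(path) -> ad.AnnData:
    """Read a 10x-style MTX triplet directory into an AnnData (cells x genes).

    Raises ``ValueError`` on dimension mismatches between the matrix and the
    feature/barcode files, and on non-integer stored values.
    """
    dirpath = Path(path)
    mtx = _find(dirpath, "matrix.mtx")
    with _open_text(mtx) as fh:
        mat = scipy.io.mmread(fh).tocsc()
    features = pd.read_csv(
        _find(dirpath, "features.tsv"), sep="\t", header=None, dtype=str
    )
    barcodes = pd.read_csv(
        _find(dirpath, "barcodes.tsv"), sep="\t", header=None, dtype=str
    )
    if mat.shape[0] != len(features):
        raise ValueError(
            f"matrix has {mat.shape[0]} rows but features.tsv has {len(features)}"
        )
    if mat.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix has {mat.shape[1]} columns but barcodes.tsv has {len(barcodes)}"
        )
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise ValueError("count matrix contains non-integer values")
    var = pd.DataFrame(index=dedup_names(features[0].tolist()))
    for j, col in enumerate(("gene_id", "mito", "ribo")):
        if features.shape[1] > j + 1:
            var[col] = features[j + 1].values
    for flag in ("mito", "ribo"):
        if flag in var.columns:
            var[flag] = var[flag].map({"True": True, "False": False, "1": True, "0": False}).fillna(False).astype(bool)
    obs = pd.DataFrame(index=dedup_names(barcodes[0].tolist()))
    X = sp.csr_matrix(mat.T.astype(np.int64))
    return ad.AnnData(X=X, obs=obs, var=var)


def write_counts(adata: ad.AnnData, path) -> None:
    """Write an AnnData to a genes x cells MTX triplet directory."""
    dirpath = Path(path)
    dirpath.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X.T)
    scipy.io.mmwrite(str(dirpath / "matrix.mtx"), X, field="integer")
    feat = pd.DataFrame({"name": adata.var_names})
    feat["gene_id"] = adata.var["gene_id"] if "gene_id" in adata.var else adata.var_names
    for flag in ("mito", "ribo"):
        if flag in adata.var:
            feat[flag] = adata.var[flag].astype(bool).values
    feat.to_csv(dirpath / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        dirpath / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file into an ordered ``{set name: member list}`` mapping.

    Members are deduplicated preserving first occurrence; blank lines are
    skipped; a line with fewer than 3 tab-separated fields is an error
    reported with its line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name = fields[0]
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def write_table(df: pd.DataFrame, path, header_meta: dict | None = None, index=False) -> None:
    """Write a TSV with optional ``# key=value`` provenance comment lines."""
    with open(path, "w") as fh:
        if header_meta:
            for k, v in header_meta.items():
                fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
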