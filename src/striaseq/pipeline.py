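"""Pipeline driver: run the stages in dependency order from one config.

Stages: simulate -> qc -> annotate -> de -> gsea / grn / activity. Every
output TSV is stamped with the config hash, the seed, and the package
version so reruns are attributable; deterministic stages are
bit-reproducible for a fixed config.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, activity, annotate, demodel, enrich, grn, io, qc, synthio

DEFAULTS = {
    "seed": 0,
    "species": "human",
    "stages": ["simulate", "qc", "annotate", "de", "gsea", "grn", "activity"],
    "nf_rescue": 0.50,
    "umi_rescue": 1000,
    "doublet_threshold": 1.0,
    "miqc_posterior": 0.75,
    "max_flagged_frac": 0.10,
    "min_score": 0.5,
    "min_cells": 20,
    "min_mean_umi": 5.0,
    "n_sv": "auto",
    "n_perm": 1000,
    "grn_runs": 4,
    "run_threshold": 0.8,
    "indiv_threshold": 0.8,
    "top_frac": 0.05,
    "activity_mode": "human_celltype",
    "paths": {},
}

_RANGES = {
    "nf_rescue": (0.0, 1.0),
    "doublet_threshold": (0.0, 2.0),
    "miqc_posterior": (0.0, 1.0),
    "max_flagged_frac": (0.0, 1.0),
    "min_score": (0.0, 1.0),
    "top_frac": (0.0, 1.0),
    "run_threshold": (0.0, 1.0),
    "indiv_threshold": (0.0, 1.0),
}


def load_config(path_or_dict) -> dict:
    """Load and validate a pipeline config; unknown keys are rejected."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    unknown = set(user) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**DEFAULTS, **user}
    for key, (lo, hi) in _RANGES.items():
        if not lo <= float(cfg[key]) <= hi:
            raise ValueError(f"config {key}={cfg[key]} outside [{lo}, {hi}]")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stamp(cfg: dict) -> dict:
    return {"config_sha256": config_hash(cfg), "seed": cfg["seed"], "striaseq": __version__}


def run_pipeline(cfg: dict, out_dir) -> Path:
    """Run the configured stages; partial output from a failed stage is
    kept under ``failed/`` and the failing stage is named in the error."""
    cfg = load_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = _stamp(cfg)
    seed = int(cfg["seed"])
    stages = cfg["stages"]
    state: dict = {}
    for stage in stages:
        try:
            _run_stage(stage, cfg, state, out, stamp, seed)
        except Exception as exc:  # mark partial output, name the stage
            (out / "failed").mkdir(exist_ok=True)
            (out / "failed" / f"{stage}.txt").write_text(f"{type(exc).__name__}: {exc}\n")
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    with open(out / "run_info.json", "w") as fh:
        json.dump({**stamp, "stages": stages}, fh, indent=2)
    return out


def _run_stage(stage, cfg, state, out, stamp, seed):
    if stage == "simulate":
        config = synthio.default_config(seed=seed)
        adata, covars, truth = synthio.generate_cohort(config)
        state.update(adata=adata, covars=covars, truth=truth)
        io.write_counts(adata, out / "counts")
        io.write_table(covars, out / "covariates.tsv", stamp)
        io.write_table(adata.obs.reset_index(), out / "cells.tsv", stamp)
        synthio.write_truth(truth, out / "truth")
        with open(out / "cohort_config.yaml", "w") as fh:
            yaml.safe_dump({"seed": seed, "n_genes": config.n_genes}, fh)
    elif stage == "qc":
        table = qc.run_qc(
            state["adata"],
            nf_rescue=cfg["nf_rescue"],
            umi_rescue=cfg["umi_rescue"],
            doublet_threshold=cfg["doublet_threshold"],
            miqc_posterior=cfg["miqc_posterior"],
            max_flagged_frac=cfg["max_flagged_frac"],
            seed=seed,
            sample_key="individual",
        )
        state["qc"] = table
        state["retained"] = state["adata"][table["retained"].to_numpy()]
        io.write_table(table.reset_index(), out / "qc_flags.tsv", stamp)
    elif stage == "annotate":
        ref = synthio.generate_reference(synthio.default_config(seed=seed))
        labels = annotate.transfer_labels(state["retained"], ref, min_score=cfg["min_score"])
        state["labels"] = labels
        io.write_table(
            labels.drop(columns="scores").reset_index(), out / "labels.tsv", stamp
        )
    elif stage == "de":
        de = demodel.run_de(
            state["retained"],
            state["covars"],
            species=cfg["species"],
            min_cells=cfg["min_cells"],
            min_mean_umi=cfg["min_mean_umi"],
            n_sv=cfg["n_sv"],
            seed=seed,
        )
        state["de"] = de
        for family, sub in de.groupby("family"):
            io.write_table(sub, out / f"de_{family}.tsv", stamp)
    elif stage == "gsea":
        de = state["de"]
        overall = de[(de["family"] == "overall")]
        frames = []
        truth = state["truth"]
        sets = {"planted_activity": truth.activity_truth["genes"].iloc[0].split(";")} if len(
            truth.activity_truth
        ) else {}
        for ct, sub in overall.groupby("cell_type"):
            if not sets:
                continue
            ranking = pd.Series(sub["t"].to_numpy(), index=sub["gene"].to_numpy())
            res = enrich.preranked_gsea(ranking, sets, n_perm=cfg["n_perm"], seed=seed)
            res["cell_type"] = ct
            frames.append(res)
        if frames:
            gsea = pd.concat(frames, ignore_index=True)
            gsea["leading_edge"] = gsea["leading_edge"].map(lambda g: ";".join(g))
            state["gsea"] = gsea
            io.write_table(gsea, out / "gsea.tsv", stamp)
    elif stage == "grn":
        truth = state["truth"]
        tfs = sorted(truth.regulon_truth["tf"].unique()) if len(truth.regulon_truth) else []
        if tfs:
            sub = state["retained"][:, :]
            consensus, regulons = grn.run_grn(
                sub,
                tfs,
                n_runs=cfg["grn_runs"],
                run_threshold=cfg["run_threshold"],
                indiv_threshold=cfg["indiv_threshold"],
                seed=seed,
            )
            state["grn"] = consensus
            io.write_table(consensus, out / "grn_edges.tsv", stamp)
            io.write_gmt(
                {tf: reg["target"].tolist() for tf, reg in regulons.items()},
                out / "regulons.gmt",
            )
    elif stage == "activity":
        truth = state["truth"]
        if len(truth.activity_truth):
            sets = {
                row["gene_set"]: row["genes"].split(";")
                for _, row in truth.activity_truth.iterrows()
            }
            scores = activity.score_cells(
                state["retained"], sets, top_frac=cfg["top_frac"], seed=seed
            )
            pb = activity.pseudobulk_activity(
                scores, state["retained"].obs, min_cells=cfg["min_cells"]
            )
            res = activity.test_activity(
                pb, state["covars"], list(sets), mode=cfg["activity_mode"]
            )
            state["activity"] = res
            io.write_table(pb, out / "activity_pseudobulk.tsv", stamp)
            io.write_table(res, out / "activity_regression.tsv", stamp)
    else:
        raise ValueError(f"unknown stage {stage!r}")
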