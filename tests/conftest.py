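"""Shared fixtures: one default synthetic cohort (with QC) per session."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pytest

from striaseq import qc, synthio


@pytest.fixture(scope="session")
def cohort():
    """Default cohort with planted DE, regulons, activity, and artifacts."""
    cfg = synthio.default_config(seed=1)
    adata, covars, truth = synthio.generate_cohort(cfg)
    return cfg, adata, covars, truth


@pytest.fixture(scope="session")
def qc_table(cohort):
    _, adata, _, _ = cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return qc.run_qc(adata, sample_key="individual", seed=0)


@pytest.fixture(scope="session")
def retained(cohort, qc_table):
    _, adata, _, _ = cohort
    return adata[qc_table["retained"].to_numpy()]


def make_grn_cohort(seed: int = 1, coupling: float = 0.6):
    """Regulon-recovery cohort: 200 genes, homogeneous baseline profiles,
    5 planted regulons of 15 targets each, 15 decoy TFs."""
    base = synthio.CohortConfig(
        n_genes=200,
        cell_types=("A", "B", "C", "D", "E"),
        proportions=(0.4, 0.2, 0.15, 0.15, 0.1),
        n_markers_per_type=0,
        cells_per_sample=100,
        doublet_frac=0,
        ambient_frac=0,
        damaged_frac=0,
        empty_frac=0,
        seed=seed,
    )
    genes = np.array(base.gene_names()[base.n_mito + base.n_ribo :])
    rng = np.random.default_rng(seed + 77)
    picks = rng.choice(genes, size=100, replace=False)
    regs, k = [], 0
    for _ in range(5):
        regs.append(synthio.PlantedRegulon(picks[k], tuple(picks[k + 1 : k + 16]), coupling))
        k += 16
    decoys = picks[k : k + 15]
    cfg = dataclasses.replace(base, planted_regulons=tuple(regs))
    tfs = sorted(r.tf for r in regs) + sorted(decoys.tolist())
    return cfg, tfs


@pytest.fixture(scope="session")
def grn_cohort():
    cfg, tfs = make_grn_cohort(seed=1)
    adata, covars, truth = synthio.generate_cohort(cfg)
    return adata, tfs, truth


def null_cohort_config(seed: int, **overrides) -> synthio.CohortConfig:
    """Fully null cohort at the calibration-study size: 12 individuals,
    2 regions, 6 cell types, 2000 genes, no planted effects, no artifacts."""
    kw = dict(
        cell_types=("A", "B", "C", "D", "E", "F"),
        proportions=(0.30, 0.20, 0.14, 0.13, 0.12, 0.11),
        cells_per_sample=150,
        doublet_frac=0,
        ambient_frac=0,
        damaged_frac=0,
        empty_frac=0,
        seed=seed,
    )
    kw.update(overrides)
    return synthio.CohortConfig(**kw)
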