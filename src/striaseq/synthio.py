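"""Seeded synthetic snRNA-seq cohort generator with known ground truth.

The generator emulates a balanced postmortem case-control design: a dozen
individuals, two striatal regions sampled per individual, sexes balanced
within diagnosis, and roughly ten transcriptionally distinct cell types
with exclusive marker genes. UMI counts are negative binomial with
gene-wise dispersion and log-normal library sizes. Ground-truth effects
are planted multiplicatively on the NB means:

* differential expression in case cells of one type (optionally one sex),
* TF->target co-expression modules through a shared per-cell latent factor,
* gene-set activity up-shifts in case cells of one type,

and droplet artifacts are planted afterwards: doublets (count sums of two
cells of different types), damaged nuclei (inflated mitochondrial load,
thinned nuclear transcriptome), empty droplets (shallow draws from the
ambient profile, low intronic fraction), and ambient contamination (a
fraction of every cell's UMIs redrawn from the cohort-average profile).

All randomness flows from one master seed through named substreams so a
given config is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "PlantedDE",
    "PlantedRegulon",
    "PlantedActivity",
    "CohortConfig",
    "TruthTables",
    "generate_cohort",
    "generate_reference",
    "write_truth",
    "read_truth",
    "default_config",
]

_STREAMS = ("profiles", "individuals", "cells", "counts", "artifacts", "noise")

DEFAULT_CELL_TYPES = (
    "Oligos",
    "Astrocytes",
    "Microglia",
    "OPCs",
    "Endothelial",
    "D1-Matrix",
    "D2-Matrix",
    "D1-Striosome",
    "D2-Striosome",
    "Interneurons",
)
# oligodendrocytes stay the most prevalent type, but the abundance range is
# compressed relative to real tissue so every type clears the 20-cell
# pseudobulk floor at desk-scale cell counts
DEFAULT_PROPORTIONS = (0.23, 0.10, 0.09, 0.08, 0.08, 0.09, 0.09, 0.08, 0.08, 0.08)

NEURONAL_TYPES = frozenset(
    {"D1-Matrix", "D2-Matrix", "D1-Striosome", "D2-Striosome", "D1/D2-Hybrid", "Interneurons"}
)


@dataclass(frozen=True)
class PlantedDE:
    gene: str
    cell_type: str
    log2fc: float
    scope: str = "both"  # both | F_only | M_only


@dataclass(frozen=True)
class PlantedRegulon:
    tf: str
    targets: tuple[str, ...]
    coupling: float = 0.5


@dataclass(frozen=True)
class PlantedActivity:
    name: str
    genes: tuple[str, ...]
    cell_type: str
    shift: float  # fold-change multiplier on set-gene means in case cells


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_individuals: int = 12
    regions: tuple[str, ...] = ("Caudate", "Putamen")
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    n_genes: int = 2000
    cells_per_sample: int = 400
    nb_dispersion: float = 0.3
    libsize_mu: float = float(np.log(2500.0))
    libsize_sigma: float = 0.35
    n_markers_per_type: int = 40
    marker_boost: float = 8.0
    marker_suppress: float = 0.05
    indiv_effect_sd: float = 0.10  # per individual x gene, log2 scale
    n_mito: int = 13
    n_ribo: int = 30
    planted_de: tuple[PlantedDE, ...] = ()
    planted_regulons: tuple[PlantedRegulon, ...] = ()
    planted_activity: tuple[PlantedActivity, ...] = ()
    doublet_frac: float = 0.05
    ambient_frac: float = 0.05
    damaged_frac: float = 0.05
    empty_frac: float = 0.05
    nf_nuclei: tuple[float, float] = (20.0, 2.0)  # Beta for true nuclei
    nf_empty: tuple[float, float] = (2.0, 20.0)  # Beta for empty droplets
    empty_libsize_mu: float = float(np.log(300.0))
    empty_libsize_sigma: float = 0.5
    species: str = "human"  # human (Dx=OUD/UC) | macaque (Tx=Morphine/Control)
    seed: int = 0

    def gene_names(self) -> list[str]:
        names = [f"MT-{i + 1}" for i in range(self.n_mito)]
        names += [f"RP{'LS'[i % 2]}{i + 1}" for i in range(self.n_ribo)]
        names += [f"G{i + 1:05d}" for i in range(self.n_genes - self.n_mito - self.n_ribo)]
        return names

    def validate(self) -> None:
        for name in ("doublet_frac", "ambient_frac", "damaged_frac", "empty_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.doublet_frac + self.damaged_frac + self.empty_frac > 1.0:
            raise ValueError("artifact fractions sum above 1")
        if len(self.cell_types) != len(self.proportions):
            raise ValueError("cell_types and proportions differ in length")
        if len(self.cell_types) < 1:
            raise ValueError("need at least one cell type")
        if abs(sum(self.proportions) - 1.0) > 1e-6:
            raise ValueError("proportions must sum to 1")
        if min(self.proportions) < 0:
            raise ValueError("proportions must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_individuals % 2:
            raise ValueError("n_individuals must be even (matched pairs)")
        if self.species not in ("human", "macaque"):
            raise ValueError(f"unknown species {self.species!r}")
        genes = set(self.gene_names())
        for p in self.planted_de:
            if p.gene not in genes:
                raise ValueError(f"planted DE gene {p.gene!r} not in namespace")
            if p.cell_type not in self.cell_types:
                raise ValueError(f"planted DE cell type {p.cell_type!r} unknown")
            if p.scope not in ("both", "F_only", "M_only"):
                raise ValueError(f"planted DE scope {p.scope!r} unknown")
        for r in self.planted_regulons:
            for g in (r.tf, *r.targets):
                if g not in genes:
                    raise ValueError(f"planted regulon gene {g!r} not in namespace")
        for a in self.planted_activity:
            if a.cell_type not in self.cell_types:
                raise ValueError(f"planted activity cell type {a.cell_type!r} unknown")
            for g in a.genes:
                if g not in genes:
                    raise ValueError(f"planted activity gene {g!r} not in namespace")


@dataclass
class TruthTables:
    """Ground truth written alongside a generated cohort."""

    de_truth: pd.DataFrame
    regulon_truth: pd.DataFrame
    activity_truth: pd.DataFrame
    cell_artifacts: pd.DataFrame


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _build_profiles(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-type expression profiles (genes x types, columns sum to 1)."""
    genes = config.gene_names()
    G, T = config.n_genes, len(config.cell_types)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=G)
    mito = np.arange(config.n_mito)
    ribo = np.arange(config.n_mito, config.n_mito + config.n_ribo)
    # pin housekeeping mass: ~2% mitochondrial, ~5% ribosomal in intact nuclei
    base[mito] = 0.02 * base.sum() / max(config.n_mito, 1)
    base[ribo] = 0.05 * base.sum() / max(config.n_ribo, 1)
    profiles = np.tile(base[:, None], (1, T))
    pool = np.arange(config.n_mito + config.n_ribo, G)
    pool = rng.permutation(pool)
    k = config.n_markers_per_type
    if k * T > len(pool):
        raise ValueError("not enough genes for the requested marker structure")
    for t in range(T):
        markers = pool[t * k : (t + 1) * k]
        profiles[markers, :] *= config.marker_suppress
        profiles[markers, t] = base[markers] * config.marker_boost
    profiles /= profiles.sum(axis=0, keepdims=True)
    return pd.DataFrame(profiles, index=genes, columns=list(config.cell_types))


def _allocate(n: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n cells to types (deterministic)."""
    raw = n * proportions
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def _individual_table(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_individuals
    ids = [f"I{i + 1:02d}" for i in range(n)]
    pair = np.repeat(np.arange(n // 2), 2)
    if config.species == "human":
        group = np.tile(["OUD", "UC"], n // 2)
        gcol = "Dx"
    else:
        group = np.tile(["Morphine", "Control"], n // 2)
        gcol = "Tx"
    sex = np.repeat(np.tile(["F", "M"], (n // 2 + 1) // 2)[: n // 2], 2)
    age_pair = rng.normal(45.0, 8.0, size=n // 2)
    tab = pd.DataFrame(
        {
            "individual": ids,
            gcol: group,
            "Sex": sex,
            "Pair": [f"P{p + 1:02d}" for p in pair],
            "Age": np.round(age_pair[pair] + rng.normal(0, 2.0, size=n), 1),
            "PMI": np.round(np.clip(rng.normal(14.0, 5.0, size=n), 3.0, None), 1),
            "RIN": np.round(np.clip(rng.normal(8.0, 0.6, size=n), 5.0, 10.0), 2),
        }
    )
    return tab


def generate_cohort(config: CohortConfig) -> tuple[ad.AnnData, pd.DataFrame, TruthTables]:
    """Generate one cohort.

    Returns ``(adata, covariates, truth)`` where ``adata`` is cells x genes
    with per-cell records in ``.obs`` (individual, region, sex, diagnosis or
    treatment, true cell type, cluster label, QC metrics, artifact label) and
    gene flags in ``.var``; ``covariates`` is the individual-level table; and
    ``truth`` carries the planted ground truth.
    """
    config.validate()
    rngs = _rngs(config.seed)
    profiles = _build_profiles(config, rngs["profiles"])
    genes = profiles.index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    G = config.n_genes
    T = len(config.cell_types)
    gcol = "Dx" if config.species == "human" else "Tx"
    case_label = "OUD" if config.species == "human" else "Morphine"

    indiv = _individual_table(config, rngs["individuals"])
    type_counts = _allocate(config.cells_per_sample, np.asarray(config.proportions))

    # per individual x gene multiplicative effect (biological replicate noise)
    noise_rng = rngs["noise"]
    indiv_eff = 2.0 ** (
        config.indiv_effect_sd * noise_rng.standard_normal((config.n_individuals, G))
    )

    # planted DE multipliers resolved to (type, sex-scope) -> gene multiplier
    de_mult: dict[tuple[str, str], np.ndarray] = {}
    for p in config.planted_de:
        key = (p.cell_type, p.scope)
        de_mult.setdefault(key, np.ones(G))[gene_pos[p.gene]] *= 2.0 ** p.log2fc
    act_mult: dict[str, np.ndarray] = {}
    for a in config.planted_activity:
        m = act_mult.setdefault(a.cell_type, np.ones(G))
        for g in a.genes:
            m[gene_pos[g]] *= a.shift

    reg_genes = [
        (np.array([gene_pos[g] for g in (r.tf, *r.targets)]), r.coupling)
        for r in config.planted_regulons
    ]

    cells_rng = rngs["cells"]
    counts_rng = rngs["counts"]
    disp = config.nb_dispersion * np.exp(
        0.3 * rngs["profiles"].standard_normal(G)
    )  # gene-wise dispersion around the base value
    r_shape = 1.0 / disp

    blocks: list[sp.csr_matrix] = []
    obs_rows: list[pd.DataFrame] = []
    for i, row in indiv.iterrows():
        for region in config.regions:
            type_labels = np.repeat(np.arange(T), type_counts)
            n = len(type_labels)
            libsize = cells_rng.lognormal(config.libsize_mu, config.libsize_sigma, size=n)
            mean = profiles.values.T[type_labels] * libsize[:, None]  # n x G
            mean *= indiv_eff[i][None, :]
            is_case = row[gcol] == case_label
            for (ct, scope), mult in de_mult.items():
                if not is_case:
                    continue
                if scope == "F_only" and row["Sex"] != "F":
                    continue
                if scope == "M_only" and row["Sex"] != "M":
                    continue
                sel = type_labels == config.cell_types.index(ct)
                mean[sel] *= mult[None, :]
            if is_case:
                for ct, mult in act_mult.items():
                    sel = type_labels == config.cell_types.index(ct)
                    mean[sel] *= mult[None, :]
            for idx, coupling in reg_genes:
                z = cells_rng.standard_normal(n)
                mean[:, idx] *= np.exp(coupling * z - 0.5 * coupling**2)[:, None]
            lam = counts_rng.gamma(shape=r_shape[None, :], scale=mean / r_shape[None, :])
            counts = counts_rng.poisson(lam).astype(np.int64)
            blocks.append(counts)
            obs_rows.append(
                pd.DataFrame(
                    {
                        "individual": row["individual"],
                        "region": region,
                        "Sex": row["Sex"],
                        gcol: row[gcol],
                        "cell_type": np.asarray(config.cell_types)[type_labels],
                    }
                )
            )

    counts = np.vstack(blocks)
    obs = pd.concat(obs_rows, ignore_index=True)
    n_cells = len(obs)

    # ---- artifacts --------------------------------------------------------
    art_rng = rngs["artifacts"]
    artifact = np.full(n_cells, "clean", dtype=object)
    sample_key = obs["individual"].astype(str) + ":" + obs["region"].astype(str)
    ambient_profile = counts.sum(axis=0).astype(float)
    ambient_profile /= ambient_profile.sum()

    for _, idx in obs.groupby(sample_key, sort=False).indices.items():
        idx = np.asarray(idx)
        m = len(idx)
        n_doub = int(round(config.doublet_frac * m))
        n_dam = int(round(config.damaged_frac * m))
        n_emp = int(round(config.empty_frac * m))
        chosen = art_rng.choice(idx, size=n_doub + n_dam + n_emp, replace=False)
        doub, dam, emp = np.split(chosen, [n_doub, n_doub + n_dam])
        clean_local = np.setdiff1d(idx, chosen)
        types = obs["cell_type"].to_numpy()
        for c in doub:
            other = clean_local[types[clean_local] != types[c]]
            partner = art_rng.choice(other if len(other) else clean_local)
            counts[c] += counts[partner]
        artifact[doub] = "doublet"
        # damaged: thin the nuclear transcriptome, inflate mitochondrial load
        if n_dam:
            kept = art_rng.binomial(counts[dam], 0.6)
            counts[dam] = kept
            tot = kept.sum(axis=1)
            target_mf = art_rng.uniform(0.25, 0.55, size=n_dam)
            extra = np.round(tot * target_mf / (1.0 - target_mf)).astype(np.int64)
            mito_idx = np.arange(config.n_mito)
            mito_p = ambient_profile[mito_idx]
            mito_p = mito_p / mito_p.sum() if mito_p.sum() > 0 else np.full(len(mito_idx), 1 / len(mito_idx))
            for j, c in enumerate(dam):
                counts[c, mito_idx] += art_rng.multinomial(extra[j], mito_p)
            artifact[dam] = "damaged"
        if n_emp:
            lib = art_rng.lognormal(config.empty_libsize_mu, config.empty_libsize_sigma, size=n_emp)
            counts[emp] = art_rng.poisson(lib[:, None] * ambient_profile[None, :])
            artifact[emp] = "empty"

    if config.ambient_frac > 0:
        keep = art_rng.binomial(counts, 1.0 - config.ambient_frac)
        swapped = counts.sum(axis=1) - keep.sum(axis=1)
        counts = keep + art_rng.poisson(swapped[:, None] * ambient_profile[None, :])

    # ---- per-cell metrics -------------------------------------------------
    umi_total = counts.sum(axis=1)
    nf = np.where(
        artifact == "empty",
        art_rng.beta(*config.nf_empty, size=n_cells),
        art_rng.beta(*config.nf_nuclei, size=n_cells),
    )
    obs["barcode"] = [
        f"{s}_{i:05d}" for s, i in zip(sample_key, obs.groupby(sample_key).cumcount())
    ]
    obs.index = pd.Index(obs.pop("barcode"), name="barcode")
    obs["artifact"] = artifact
    # over-clustering puts ambient/empty and high-mito droplets in their own
    # clusters, as graph clustering does on real data; doublets co-cluster
    # with their dominant type
    obs["cluster"] = np.where(
        artifact == "empty", "Empty", np.where(artifact == "damaged", "Damaged", obs["cell_type"])
    )
    obs["umi_total"] = umi_total
    obs["n_genes"] = (counts > 0).sum(axis=1)
    mito_counts = counts[:, : config.n_mito].sum(axis=1)
    obs["mito_fraction"] = np.divide(
        mito_counts, umi_total, out=np.zeros(n_cells), where=umi_total > 0
    )
    obs["nuclear_fraction"] = nf

    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["mito"] = [g.startswith("MT-") for g in genes]
    var["ribo"] = [g.startswith(("RPL", "RPS")) for g in genes]

    # at desk scale the count matrix is not sparse enough to benefit from
    # CSR storage; keep it dense unless genuinely sparse
    density = float((counts > 0).mean())
    X = sp.csr_matrix(counts) if density < 0.35 else counts
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["profiles"] = profiles
    adata.uns["seed"] = config.seed

    truth = TruthTables(
        de_truth=pd.DataFrame(
            [(p.gene, p.cell_type, p.scope, p.log2fc) for p in config.planted_de],
            columns=["gene", "cell_type", "scope", "log2fc"],
        ),
        regulon_truth=pd.DataFrame(
            [(r.tf, t) for r in config.planted_regulons for t in r.targets],
            columns=["tf", "target"],
        ),
        activity_truth=pd.DataFrame(
            [(a.name, a.cell_type, a.shift, ";".join(a.genes)) for a in config.planted_activity],
            columns=["gene_set", "cell_type", "shift", "genes"],
        ),
        cell_artifacts=pd.DataFrame({"barcode": obs.index, "label": artifact}).reset_index(
            drop=True
        ),
    )
    return adata, indiv, truth


def generate_reference(
    config: CohortConfig, noise: float = 0.0, seed: int | None = None
) -> pd.DataFrame:
    """Reference expression profiles (genes x types, columns sum to 1).

    ``noise`` perturbs profiles multiplicatively (log-normal sigma) to mimic
    a reference assembled from an independent cohort; 0 reproduces the
    generating profiles exactly.
    """
    if len(config.cell_types) == 0:
        raise ValueError("empty cell type list")
    rngs = _rngs(config.seed)
    profiles = _build_profiles(config, rngs["profiles"])
    if noise > 0:
        rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
        profiles = profiles * np.exp(noise * rng.standard_normal(profiles.shape))
        profiles /= profiles.sum(axis=0)
    return profiles


_TRUTH_FILES = {
    "de_truth": "de_truth.tsv",
    "regulon_truth": "regulon_truth.tsv",
    "activity_truth": "activity_truth.tsv",
    "cell_artifacts": "cell_artifacts.tsv",
}


def write_truth(truth: TruthTables, path) -> None:
    """Write the truth tables as TSVs (headers always present)."""
    dirpath = Path(path)
    dirpath.mkdir(parents=True, exist_ok=True)
    for attr, fname in _TRUTH_FILES.items():
        getattr(truth, attr).to_csv(dirpath / fname, sep="\t", index=False)


def read_truth(path) -> TruthTables:
    dirpath = Path(path)
    kwargs = {}
    for attr, fname in _TRUTH_FILES.items():
        kwargs[attr] = pd.read_csv(dirpath / fname, sep="\t")
        if kwargs[attr].empty:
            kwargs[attr] = kwargs[attr].astype(object)
    return TruthTables(**kwargs)


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The standard test cohort: planted DE, regulons, and activity shifts.

    Planted genes are drawn from the mid-to-high-abundance, non-marker part
    of the namespace so they survive the expression filter downstream.
    """
    base = CohortConfig(seed=seed)
    profiles = _build_profiles(base, _rngs(seed)["profiles"])
    mean_profile = profiles.mean(axis=1)
    body = mean_profile.iloc[base.n_mito + base.n_ribo :]
    eligible = body[body > body.quantile(0.60)].index.to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDE]))
    picks = rng.choice(eligible, size=200, replace=False)
    de_types = ("Oligos", "Astrocytes", "Microglia", "D1-Matrix", "D2-Matrix", "Interneurons")
    planted_de = []
    k = 0
    for ct in de_types:
        for _ in range(8):
            planted_de.append(PlantedDE(picks[k], ct, 1.0 if k % 2 == 0 else -1.0, "both"))
            k += 1
        for _ in range(6):
            planted_de.append(PlantedDE(picks[k], ct, 1.0, "F_only"))
            k += 1
    regulons = []
    for r in range(5):
        tf, targets = picks[k], tuple(picks[k + 1 : k + 16])
        regulons.append(PlantedRegulon(tf, targets, coupling=0.6))
        k += 16
    act_genes = tuple(picks[k : k + 25])
    activity = (PlantedActivity("dna_damage_like", act_genes, "Interneurons", 2.0),)
    cfg = dataclasses.replace(
        base,
        planted_de=tuple(planted_de),
        planted_regulons=tuple(regulons),
        planted_activity=activity,
        seed=seed,
        **overrides,
    )
    return cfg
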