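"""Synthetic multi-dataset single-cell count collections with planted ground truth.

The generator emulates the study design this package targets: several
independent single-cell RNA-seq "datasets" (a mix of shallow UMI-style and
deep full-length-style depth regimes) each containing the same handful of
cell types. Every cell type carries

* one *hormone* gene with bimodal (two-component lognormal) expression —
  high in its own type, near-absent elsewhere;
* a block of planted *marker* genes upregulated in that type, each with a
  cross-dataset *reproducibility* ``r``: the marker's effect is switched on
  in a given dataset by an independent Bernoulli(``r``) draw, fixed by the
  master seed;
* shared *background* genes, a small set of *mitochondrial* genes, spiked
  *doublets* (column sums of two real cells) and *bihormonal* hybrid cells
  that only ever gain expression relative to their mono-hormonal parents.

Counts are negative-binomial with per-gene base means, per-cell size
factors, and a per-dataset depth multiplier. Everything is deterministic
given ``SimulationConfig.seed``.

Gene naming is deterministic so truth joins are string based:
``MARKER_<type>_<i>``, ``HORMONE_<type>``, ``MT-<i>``, ``BG_<i>``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "SimulationConfig",
    "SyntheticCollection",
    "generate_collection",
    "generate_dataset",
    "spike_doublets",
    "plant_bihormonal",
]

_DEFAULT_TYPES = ("alpha", "beta", "gamma", "delta")


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child RNG: SeedSequence(seed) extended by an integer key path."""
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic collection.

    Defaults describe the design the pipeline is exercised on end-to-end:
    seven datasets (two shallow "umi", five deep "fulllength"), four cell
    types with 100 cells each per dataset, and 80 markers per type in three
    reproducibility tiers (30 at 1.0, 30 at 0.6, 20 at 0.3).
    """

    n_datasets: int = 7
    cell_types: tuple[str, ...] = _DEFAULT_TYPES
    cells_per_type: int | Mapping[str, int] = 100
    n_markers_per_type: int = 80
    marker_log_fold_change: float = 1.0  # natural-log units
    #: per-marker cross-dataset reproducibility; scalar broadcasts to all markers
    marker_reproducibility: float | tuple[float, ...] = (1.0,) * 30 + (0.6,) * 30 + (0.3,) * 20
    n_background_genes: int = 800
    baseline_mean: float = 0.5
    marker_baseline_mean: float = 1.0
    gene_mean_log_sd: float = 0.5
    marker_mean_log_sd: float = 0.3
    nb_dispersion: float = 0.4
    # hormone two-component lognormal mixture (log-count scale)
    hormone_high_log_mean: float = math.log(40.0)
    hormone_low_log_mean: float = math.log(0.25)
    hormone_log_sd: float = 0.35
    doublet_rate: float = 0.05
    bihormonal_fraction: float = 0.02
    bihormonal_pair: tuple[str, str] = ("alpha", "beta")  # (donor, acceptor)
    n_acceptor_markers: int = 10
    mito_gene_count: int = 10
    mito_rate: float = 0.05
    depth_per_dataset: tuple[float, ...] | None = None
    protocols: tuple[str, ...] | None = None
    cell_size_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if len(set(self.cell_types)) != len(self.cell_types) or not self.cell_types:
            raise ValueError("cell_types must be non-empty and unique")
        for t, n in self.cells_map.items():
            if n < 2:
                raise ValueError(f"cells_per_type must be >= 2 per dataset (got {n} for {t!r})")
        reps = self.reproducibilities
        if len(reps) != self.n_markers_per_type:
            raise ValueError(
                f"marker_reproducibility length {len(reps)} != n_markers_per_type "
                f"{self.n_markers_per_type}"
            )
        if any(not (0.0 < r <= 1.0) for r in reps):
            raise ValueError("marker reproducibilities must lie in (0, 1]")
        if not (0.0 <= self.doublet_rate <= 0.2):
            raise ValueError("doublet_rate must lie in [0, 0.2]")
        for name in ("bihormonal_fraction", "mito_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.bihormonal_fraction > 0:
            donor, acceptor = self.bihormonal_pair
            if donor not in self.cell_types or acceptor not in self.cell_types or donor == acceptor:
                raise ValueError("bihormonal_pair must name two distinct configured cell types")
        if self.depth_per_dataset is not None and len(self.depth_per_dataset) != self.n_datasets:
            raise ValueError("depth_per_dataset length must equal n_datasets")
        if self.protocols is not None and len(self.protocols) != self.n_datasets:
            raise ValueError("protocols length must equal n_datasets")
        names = self.gene_names()
        if len(set(names)) != len(names):
            raise ValueError("gene roles are not disjoint: duplicate generated gene ids")

    # -- derived views -------------------------------------------------------

    @property
    def cells_map(self) -> dict[str, int]:
        if isinstance(self.cells_per_type, Mapping):
            missing = set(self.cell_types) - set(self.cells_per_type)
            if missing:
                raise ValueError(f"cells_per_type missing entries for {sorted(missing)}")
            return {t: int(self.cells_per_type[t]) for t in self.cell_types}
        return {t: int(self.cells_per_type) for t in self.cell_types}

    @property
    def reproducibilities(self) -> tuple[float, ...]:
        if isinstance(self.marker_reproducibility, (int, float)):
            return (float(self.marker_reproducibility),) * self.n_markers_per_type
        return tuple(float(r) for r in self.marker_reproducibility)

    @property
    def depths(self) -> tuple[float, ...]:
        if self.depth_per_dataset is not None:
            return tuple(float(d) for d in self.depth_per_dataset)
        return tuple(1.0 if p == "umi" else 6.0 for p in self.protocol_list)

    @property
    def protocol_list(self) -> tuple[str, ...]:
        if self.protocols is not None:
            return self.protocols
        n_umi = min(2, self.n_datasets)
        return ("umi",) * n_umi + ("fulllength",) * (self.n_datasets - n_umi)

    def hormone_gene(self, cell_type: str) -> str:
        return f"HORMONE_{cell_type}"

    def marker_genes(self, cell_type: str) -> list[str]:
        return [f"MARKER_{cell_type}_{i}" for i in range(self.n_markers_per_type)]

    def gene_names(self) -> list[str]:
        names: list[str] = []
        for t in self.cell_types:
            names.extend(self.marker_genes(t))
        names.extend(self.hormone_gene(t) for t in self.cell_types)
        names.extend(f"MT-{i}" for i in range(self.mito_gene_count))
        names.extend(f"BG_{i}" for i in range(self.n_background_genes))
        return names

    def gene_table(self) -> pd.DataFrame:
        """Per-gene truth: role, marker-of type, reproducibility tier."""
        rows: list[tuple[str, str, str, float]] = []
        reps = self.reproducibilities
        for t in self.cell_types:
            for i, g in enumerate(self.marker_genes(t)):
                rows.append((g, "marker", t, reps[i]))
        for t in self.cell_types:
            rows.append((self.hormone_gene(t), "hormone", t, 1.0))
        for i in range(self.mito_gene_count):
            rows.append((f"MT-{i}", "mito", "", np.nan))
        for i in range(self.n_background_genes):
            rows.append((f"BG_{i}", "background", "", np.nan))
        df = pd.DataFrame(rows, columns=["gene", "role", "marker_of", "reproducibility"])
        return df.set_index("gene")


@dataclass
class SyntheticCollection:
    """A list of per-dataset AnnData objects plus joined truth tables.

    Each AnnData is cells x genes with raw counts in ``X``; ``obs`` carries
    ``dataset``, ``donor``, ``true_type``, ``is_doublet``, ``is_bihormonal``
    and ``var`` carries ``role``, ``marker_of``, ``reproducibility``,
    ``is_mito``, ``is_hormone``, ``hormone_of``.
    """

    datasets: list[ad.AnnData]
    config: SimulationConfig
    marker_activity: pd.DataFrame = field(repr=False)  # markers x datasets, bool

    @property
    def cell_truth(self) -> pd.DataFrame:
        cols = ["dataset", "donor", "true_type", "is_doublet", "is_bihormonal"]
        return pd.concat([d.obs[cols] for d in self.datasets])

    @property
    def gene_truth(self) -> pd.DataFrame:
        return self.datasets[0].var.copy()

    def write(self, outdir) -> None:
        from . import io as _io

        _io.write_collection(self, outdir)


def _gene_base_means(config: SimulationConfig) -> pd.Series:
    """Per-gene base (off-type, depth-1) NB means, fixed by the master seed."""
    rng = _child_rng(config.seed, 1)
    table = config.gene_table()
    base = np.empty(len(table))
    is_marker = (table["role"] == "marker").to_numpy()
    is_bg = (table["role"] == "background").to_numpy()
    base[is_marker] = config.marker_baseline_mean * np.exp(
        rng.normal(0.0, config.marker_mean_log_sd, is_marker.sum())
    )
    base[is_bg] = config.baseline_mean * np.exp(
        rng.normal(0.0, config.gene_mean_log_sd, is_bg.sum())
    )
    # hormone and mito means are handled separately per cell; placeholder zeros
    base[(table["role"] == "hormone").to_numpy()] = 0.0
    base[(table["role"] == "mito").to_numpy()] = 0.0
    return pd.Series(base, index=table.index, name="base_mean")


def marker_activity_matrix(config: SimulationConfig) -> pd.DataFrame:
    """Bernoulli(reproducibility) activity of every marker in every dataset.

    Fixed by the master seed, independent of all other draws.
    """
    rng = _child_rng(config.seed, 2)
    genes: list[str] = []
    reps: list[float] = []
    for t in config.cell_types:
        genes.extend(config.marker_genes(t))
        reps.extend(config.reproducibilities)
    r = np.asarray(reps)[:, None]
    active = rng.random((len(genes), config.n_datasets)) < r
    return pd.DataFrame(
        active, index=genes, columns=[f"ds{d}" for d in range(config.n_datasets)]
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean=mu, var=mu + dispersion*mu^2) counts; mu may contain zeros."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_dataset(
    config: SimulationConfig,
    dataset_index: int,
    *,
    activity: pd.DataFrame | None = None,
    base_means: pd.Series | None = None,
    seed_offset: int = 0,
) -> ad.AnnData:
    """Generate one dataset of the collection (without doublets/bihormonals).

    ``seed_offset`` shifts the per-dataset child seed path so that extra
    evaluation datasets can be drawn from the same gene-level truth without
    reusing the randomness of the primary datasets.
    """
    if activity is None:
        activity = marker_activity_matrix(config)
    if base_means is None:
        base_means = _gene_base_means(config)
    rng = _child_rng(config.seed, 3, dataset_index + seed_offset)
    genes = config.gene_names()
    gene_idx = {g: i for i, g in enumerate(genes)}
    depth = config.depths[dataset_index % config.n_datasets]
    cells_map = config.cells_map
    types_of_cells = np.concatenate(
        [np.repeat(t, cells_map[t]) for t in config.cell_types]
    )
    n_cells = types_of_cells.size
    order = rng.permutation(n_cells)
    types_of_cells = types_of_cells[order]
    size_factors = np.exp(rng.normal(0.0, config.cell_size_log_sd, n_cells))

    mu = np.tile(base_means.to_numpy()[:, None], (1, n_cells))
    # marker boosts where the marker is active in this dataset
    boost = math.exp(config.marker_log_fold_change)
    ds_col = activity.columns[dataset_index % len(activity.columns)]
    for t in config.cell_types:
        cols = types_of_cells == t
        for g in config.marker_genes(t):
            if activity.loc[g, ds_col]:
                mu[gene_idx[g], cols] *= boost
    # hormone genes: per-cell lognormal means (high for own type, low otherwise)
    for t in config.cell_types:
        gi = gene_idx[config.hormone_gene(t)]
        own = types_of_cells == t
        logm = np.where(own, config.hormone_high_log_mean, config.hormone_low_log_mean)
        mu[gi, :] = np.exp(rng.normal(logm, config.hormone_log_sd))
    mu *= depth * size_factors[None, :]
    # mitochondrial genes: fixed fraction of each cell's non-mito expectation
    if config.mito_gene_count > 0:
        mito_rows = np.array([gene_idx[f"MT-{i}"] for i in range(config.mito_gene_count)])
        nonmito_total = mu.sum(axis=0)  # mito rows still zero here
        per_gene = (
            config.mito_rate
            / max(1e-12, 1.0 - config.mito_rate)
            * nonmito_total
            / config.mito_gene_count
        )
        mu[mito_rows, :] = per_gene[None, :]

    counts = _nb_draw(rng, mu, config.nb_dispersion)

    name = f"ds{dataset_index}" if seed_offset == 0 else f"eval{dataset_index}"
    obs = pd.DataFrame(
        {
            "dataset": name,
            "donor": [f"{name}_don{j}" for j in rng.integers(0, 2, n_cells)],
            "true_type": types_of_cells,
            "is_doublet": False,
            "is_bihormonal": False,
        },
        index=[f"{name}_c{i}" for i in range(n_cells)],
    )
    gene_tab = config.gene_table()
    var = gene_tab.copy()
    var["is_mito"] = var["role"] == "mito"
    var["is_hormone"] = var["role"] == "hormone"
    var["hormone_of"] = np.where(var["is_hormone"], var["marker_of"], "")
    adata = ad.AnnData(
        X=sparse.csr_matrix(counts.T.astype(np.int64)), obs=obs, var=var
    )
    adata.uns["protocol"] = config.protocol_list[dataset_index % config.n_datasets]
    adata.uns["depth"] = depth
    return adata


def plant_bihormonal(
    adata: ad.AnnData,
    fraction: float,
    donor_type: str,
    acceptor_type: str,
    *,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> ad.AnnData:
    """Convert a fraction of donor-type cells into hybrid bihormonal cells.

    Hybrids *gain* the acceptor hormone and a small block of acceptor markers
    by adding freshly drawn counts; no gene's expected count ever decreases.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0:
        return adata
    for t in (donor_type, acceptor_type):
        if not (adata.obs["true_type"] == t).any():
            raise ValueError(f"cell type {t!r} not present in matrix")
    donors = np.flatnonzero(
        (adata.obs["true_type"] == donor_type).to_numpy()
        & ~adata.obs["is_doublet"].to_numpy()
    )
    n_pick = int(round(fraction * donors.size))
    if n_pick > donors.size:
        raise ValueError("bihormonal fraction too large for donor population")
    if n_pick == 0:
        return adata
    picked = rng.choice(donors, size=n_pick, replace=False)
    depth = float(adata.uns.get("depth", 1.0))
    X = adata.X.tolil() if sparse.issparse(adata.X) else adata.X
    gene_idx = {g: i for i, g in enumerate(adata.var_names)}
    add_genes = [config.hormone_gene(acceptor_type)] + config.marker_genes(acceptor_type)[
        : config.n_acceptor_markers
    ]
    boost_extra = math.exp(config.marker_log_fold_change) - 1.0
    base = _gene_base_means(config)
    for g in add_genes:
        gi = gene_idx[g]
        if g.startswith("HORMONE_"):
            mu = np.exp(rng.normal(config.hormone_high_log_mean, config.hormone_log_sd, n_pick))
        else:
            mu = np.full(n_pick, boost_extra * base[g])
        extra = _nb_draw(rng, mu * depth, config.nb_dispersion)
        for c, e in zip(picked, extra):
            if e:
                X[c, gi] = X[c, gi] + int(e)
    out = adata.copy()
    out.X = sparse.csr_matrix(X) if sparse.issparse(adata.X) else X
    is_bi = out.obs["is_bihormonal"].to_numpy().copy()
    is_bi[picked] = True
    out.obs["is_bihormonal"] = is_bi
    return out


def spike_doublets(adata: ad.AnnData, rate: float, seed: int | np.random.Generator) -> ad.AnnData:
    """Append ``round(rate * n_cells)`` doublets, each the sum of two distinct cells."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("doublet rate must lie in [0, 1)")
    if adata.n_obs < 2:
        raise ValueError("need at least 2 cells to form doublets")
    if rate == 0:
        return adata
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = adata.n_obs
    n_dbl = int(round(rate * n))
    if n_dbl == 0:
        return adata
    pairs = np.empty((n_dbl, 2), dtype=int)
    for i in range(n_dbl):
        pairs[i] = rng.choice(n, size=2, replace=False)
    X = adata.X.tocsr() if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    dbl_X = X[pairs[:, 0]] + X[pairs[:, 1]]
    ds = str(adata.obs["dataset"].iloc[0])
    obs = pd.DataFrame(
        {
            "dataset": ds,
            "donor": adata.obs["donor"].iloc[pairs[:, 0]].to_numpy(),
            "true_type": [
                "+".join(
                    sorted(
                        {
                            str(adata.obs["true_type"].iloc[a]),
                            str(adata.obs["true_type"].iloc[b]),
                        }
                    )
                )
                for a, b in pairs
            ],
            "is_doublet": True,
            "is_bihormonal": False,
        },
        index=[f"{ds}_dbl{i}" for i in range(n_dbl)],
    )
    dbl = ad.AnnData(X=dbl_X, obs=obs, var=adata.var.copy())
    out = ad.concat([adata, dbl], join="outer", merge="first")
    out.var = adata.var.copy()
    out.uns.update(adata.uns)
    out.obs["is_doublet"] = out.obs["is_doublet"].astype(bool)
    out.obs["is_bihormonal"] = out.obs["is_bihormonal"].astype(bool)
    return out


def generate_collection(config: SimulationConfig) -> SyntheticCollection:
    """Generate the full multi-dataset collection described by ``config``."""
    activity = marker_activity_matrix(config)
    base = _gene_base_means(config)
    datasets: list[ad.AnnData] = []
    for d in range(config.n_datasets):
        adata = generate_dataset(config, d, activity=activity, base_means=base)
        if config.bihormonal_fraction > 0:
            donor_t, acceptor_t = config.bihormonal_pair
            adata = plant_bihormonal(
                adata,
                config.bihormonal_fraction,
                donor_t,
                acceptor_t,
                config=config,
                rng=_child_rng(config.seed, 4, d),
            )
        adata = spike_doublets(adata, config.doublet_rate, _child_rng(config.seed, 5, d))
        datasets.append(adata)
    return SyntheticCollection(datasets=datasets, config=config, marker_activity=activity)


def generate_evaluation_datasets(
    config: SimulationConfig, n_eval: int = 3, *, clean: bool = False
) -> list[ad.AnnData]:
    """Extra held-out datasets from the same truth, for geneset evaluation.

    Drawn with a disjoint seed path. ``clean=True`` skips doublet and
    bihormonal spiking (evaluation ranks are built from typed singlets).
    Marker activity in evaluation datasets is re-drawn per marker with the
    same reproducibility tiers (column cycling over the activity matrix is
    avoided by sampling fresh Bernoulli draws).
    """
    rng = _child_rng(config.seed, 6)
    genes: list[str] = []
    for t in config.cell_types:
        genes.extend(config.marker_genes(t))
    reps = np.tile(np.asarray(config.reproducibilities), len(config.cell_types))
    activity = pd.DataFrame(
        rng.random((len(genes), max(n_eval, 1))) < reps[:, None],
        index=genes,
        columns=[f"ds{d}" for d in range(max(n_eval, 1))],
    )
    base = _gene_base_means(config)
    out = []
    for d in range(n_eval):
        adata = generate_dataset(
            config, d, activity=activity, base_means=base, seed_offset=1000
        )
        if not clean:
            if config.bihormonal_fraction > 0:
                donor_t, acceptor_t = config.bihormonal_pair
                adata = plant_bihormonal(
                    adata,
                    config.bihormonal_fraction,
                    donor_t,
                    acceptor_t,
                    config=config,
                    rng=_child_rng(config.seed, 7, d),
                )
            adata = spike_doublets(adata, config.doublet_rate, _child_rng(config.seed, 8, d))
        out.append(adata)
    return out
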