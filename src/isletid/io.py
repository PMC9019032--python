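"""Plain-text exchange formats: sparse MTX datasets, truth/identity tables, configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import anndata as ad
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simulate import SimulationConfig, SyntheticCollection

__all__ = [
    "write_dataset_mtx",
    "read_dataset_mtx",
    "write_collection",
    "read_collection_dir",
    "config_to_dict",
    "config_from_dict",
    "write_identity_table",
    "read_identity_table",
]


def write_dataset_mtx(adata: ad.AnnData, outdir) -> None:
    """Write one dataset as genes x cells MTX plus genes.tsv / barcodes.tsv / obs.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X.tocsr() if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    spio.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo())
    adata.var.reset_index(names="gene").to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.Series(adata.obs_names, name="barcode").to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    adata.obs.reset_index(names="barcode").to_csv(outdir / "obs.tsv", sep="\t", index=False)
    meta = {k: v for k, v in adata.uns.items() if isinstance(v, (str, int, float))}
    (outdir / "uns.json").write_text(json.dumps(meta))


def read_dataset_mtx(path) -> ad.AnnData:
    """Read a dataset written by :func:`write_dataset_mtx` (or bare MTX + TSVs)."""
    path = Path(path)
    X = spio.mmread(str(path / "matrix.mtx")).tocsr().T.tocsr()
    genes = pd.read_csv(path / "genes.tsv", sep="\t")
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    var = genes.set_index("gene") if "gene" in genes else genes.set_index(genes.columns[0])
    obs_path = path / "obs.tsv"
    if obs_path.exists():
        obs = pd.read_csv(obs_path, sep="\t").set_index("barcode")
        obs.index = obs.index.astype(str)
    else:
        obs = pd.DataFrame(index=barcodes)
    adata = ad.AnnData(X=X, obs=obs, var=var)
    uns_path = path / "uns.json"
    if uns_path.exists():
        adata.uns.update(json.loads(uns_path.read_text()))
    for col in ("is_doublet", "is_bihormonal"):
        if col in adata.obs:
            adata.obs[col] = adata.obs[col].astype(bool)
    return adata


def write_collection(collection: SyntheticCollection, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, adata in enumerate(collection.datasets):
        write_dataset_mtx(adata, outdir / f"ds{i}")
    collection.cell_truth.reset_index(names="cell_id").to_csv(
        outdir / "cell_truth.tsv", sep="\t", index=False
    )
    collection.gene_truth.reset_index(names="gene").to_csv(
        outdir / "gene_truth.tsv", sep="\t", index=False
    )
    collection.marker_activity.reset_index(names="gene").to_csv(
        outdir / "marker_activity.tsv", sep="\t", index=False
    )
    (outdir / "config.json").write_text(json.dumps(config_to_dict(collection.config), indent=1))


def read_collection_dir(path) -> SyntheticCollection:
    path = Path(path)
    config = config_from_dict(json.loads((path / "config.json").read_text()))
    datasets = [read_dataset_mtx(path / f"ds{i}") for i in range(config.n_datasets)]
    activity = pd.read_csv(path / "marker_activity.tsv", sep="\t").set_index("gene")
    return SyntheticCollection(datasets=datasets, config=config, marker_activity=activity)


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    if isinstance(d.get("cells_per_type"), dict):
        d["cells_per_type"] = dict(d["cells_per_type"])
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    for key in (
        "cell_types", "marker_reproducibility", "depth_per_dataset",
        "protocols", "bihormonal_pair",
    ):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SimulationConfig(**d)


def write_identity_table(identities: pd.DataFrame, path) -> None:
    """Per-cell identity TSV: cell_id, cluster, hormones, final_type, doublet_flag."""
    identities.to_csv(path, sep="\t", index=False)


def read_identity_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["hormones"] = df["hormones"].fillna("")
    df["doublet_flag"] = df["doublet_flag"].astype(bool)
    return df
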