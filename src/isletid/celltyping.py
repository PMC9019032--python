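"""Per-dataset QC, normalization, doublet flagging, hormone thresholding and
final cell type allocation.

The allocation logic mirrors standard islet single-cell practice: cells are
clustered, each cluster is called to a type, per-cell hormone expression is
thresholded on the bimodal log-normalized distribution, and the final label
is the cluster's type unless the hormone profile overrides it (a single
mismatching hormone re-assigns the cell; two or more hormones make it
*bihormonal*; no hormone in a non-endocrine cluster makes it *other*).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.signal import find_peaks
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "QCThresholds",
    "HormoneThreshold",
    "CellIdentity",
    "qc_filter",
    "normalize_log",
    "umi_collision_correct",
    "doublet_score",
    "flag_doublets",
    "hormone_threshold",
    "classify_hormones",
    "cluster_cells",
    "call_cluster_types",
    "allocate_cell_types",
]


@dataclass(frozen=True)
class QCThresholds:
    """Minimum counts / detected genes and maximum mitochondrial fraction per cell."""

    min_counts: int = 0
    min_genes: int = 0
    max_mito_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.min_counts < 0 or self.min_genes < 0:
            raise ValueError("QC minima must be non-negative")
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class HormoneThreshold:
    """A per-hormone cutoff on the log-normalized scale and how it was found."""

    value: float
    method: str  # "kde_minimum" | "otsu_fallback"


@dataclass(frozen=True)
class CellIdentity:
    cluster: str
    hormones: frozenset[str]
    cell_type: str


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


def qc_filter(adata: ad.AnnData, thresholds: QCThresholds) -> tuple[ad.AnnData, dict]:
    """Keep cells with total >= min_counts, detected genes >= min_genes and
    mito fraction strictly below max_mito_fraction.

    Returns the filtered matrix and a report of removals per criterion
    (criteria overlap, so the per-criterion numbers need not sum to the total).
    """
    X = adata.X
    totals = np.ravel(X.sum(axis=1)).astype(float)
    n_genes = np.ravel((X > 0).sum(axis=1)).astype(int)
    if thresholds.max_mito_fraction < 1.0:
        if "is_mito" not in adata.var:
            raise ValueError("mito flags required in .var['is_mito'] for a mito cutoff")
        mito_mask = adata.var["is_mito"].to_numpy().astype(bool)
        mito_counts = np.ravel(X[:, mito_mask].sum(axis=1)).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1e-12), 1.0)
        pass_mito = mito_frac < thresholds.max_mito_fraction
    else:
        mito_frac = np.zeros(adata.n_obs)
        pass_mito = np.ones(adata.n_obs, dtype=bool)
    pass_counts = totals >= thresholds.min_counts
    pass_genes = n_genes >= thresholds.min_genes
    keep = pass_counts & pass_genes & pass_mito
    report = {
        "n_input": int(adata.n_obs),
        "n_kept": int(keep.sum()),
        "removed_low_counts": int((~pass_counts).sum()),
        "removed_low_genes": int((~pass_genes).sum()),
        "removed_high_mito": int((~pass_mito).sum()),
    }
    if report["n_kept"] == 0:
        warnings.warn("qc_filter removed every cell", stacklevel=2)
    return adata[keep].copy(), report


def normalize_log(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Library-size normalize and natural-log transform:
    ``value = log(1 + scale_factor * count / cell_total)``.

    Raw counts are preserved in ``.layers['counts']``.
    """
    totals = np.ravel(adata.X.sum(axis=1)).astype(float)
    if (totals == 0).any():
        bad = adata.obs_names[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"cell {bad!r} has zero total counts; run qc_filter first")
    out = adata.copy()
    out.layers["counts"] = adata.X.copy()
    if sparse.issparse(adata.X):
        X = adata.X.tocsr().astype(float)
        scale = scale_factor / totals
        X = sparse.diags(scale) @ X
        X.data = np.log1p(X.data)
        out.X = X
    else:
        X = np.asarray(adata.X, dtype=float) * (scale_factor / totals)[:, None]
        out.X = np.log1p(X)
    out.uns["normalization"] = {"scale_factor": scale_factor, "log": "natural"}
    return out


def umi_collision_correct(b, umi_length: int):
    """Correct observed UMI counts for barcode collisions.

    ``m = -n * ln(1 - (b - 1) / n)`` with ``n = 4**umi_length`` the barcode
    space size and ``b`` the observed number of distinct UMIs. ``m >= b - 1``
    with equality only at ``b = 1``, and ``m`` is strictly increasing in ``b``.
    """
    b_arr = np.asarray(b, dtype=float)
    if (b_arr < 1).any():
        raise ValueError("observed UMI count b must be >= 1")
    n = 4.0 ** int(umi_length)
    if ((b_arr - 1) >= n).any():
        raise ValueError(f"b - 1 must be < 4^l = {n:g} (collision saturation)")
    m = -n * np.log1p(-(b_arr - 1.0) / n)
    return float(m) if np.isscalar(b) else m


def _pca_embed(lognorm: np.ndarray, n_pcs: int, seed: int) -> np.ndarray:
    n_pcs = int(min(n_pcs, lognorm.shape[0] - 1, lognorm.shape[1]))
    if n_pcs < 1:
        return np.zeros((lognorm.shape[0], 1))
    pca = PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed)
    return pca.fit_transform(lognorm - lognorm.mean(axis=0, keepdims=True))


def doublet_score(
    adata: ad.AnnData,
    k_neighbors: int = 10,
    synthetic_fraction: float = 0.25,
    *,
    n_pcs: int = 20,
    scale_factor: float = 1e4,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic-doublet k-nearest-neighbour doublet score per cell, in [0, 1].

    Synthetic doublets (count sums of two random distinct cells) are spiked so
    they make up ``synthetic_fraction`` of the augmented pool, everything is
    log-normalized and embedded by PCA, and each real cell's score is its
    fraction of synthetic neighbours among the ``k_neighbors`` nearest,
    rescaled into a calibrated probability by the synthetic pool fraction:
    a cell whose neighbourhood matches the pool composition scores 0.5.
    """
    n = adata.n_obs
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    if n < 2 * k_neighbors:
        raise ValueError("need at least 2 * k_neighbors cells")
    if not (0.0 < synthetic_fraction < 1.0):
        raise ValueError("synthetic_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    X = adata.X.tocsr() if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    n_syn = max(1, int(round(synthetic_fraction / (1 - synthetic_fraction) * n)))
    left = rng.integers(0, n, n_syn)
    shift = rng.integers(1, n, n_syn)
    right = (left + shift) % n  # distinct partner
    syn = X[left] + X[right]
    pool = sparse.vstack([X, syn]).tocsr()
    totals = np.ravel(pool.sum(axis=1)).astype(float)
    totals[totals == 0] = 1.0
    norm = sparse.diags(scale_factor / totals) @ pool.astype(float)
    norm.data = np.log1p(norm.data)
    emb = _pca_embed(np.asarray(norm.todense()), n_pcs, seed)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n])
    neigh = idx[:, 1:]  # drop self
    rho = (neigh >= n).mean(axis=1)
    f = n_syn / (n + n_syn)
    num = rho * (1 - f)
    den = num + (1 - rho) * f
    return num / np.maximum(den, 1e-12)


def flag_doublets(
    scores_a: np.ndarray, scores_b: np.ndarray, expected_rate: float
) -> np.ndarray:
    """Union doublet flag: each detector flags its top ``expected_rate`` fraction."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must have identical length")
    if not (0.0 <= expected_rate <= 1.0):
        raise ValueError("expected_rate must lie in [0, 1]")
    n = a.size
    n_flag = int(round(expected_rate * n))
    flags = np.zeros(n, dtype=bool)
    for s in (a, b):
        if n_flag > 0:
            top = np.argsort(-s, kind="stable")[:n_flag]
            flags[top] = True
    return flags


def hormone_threshold(
    values: np.ndarray,
    *,
    n_grid: int = 512,
    prominence_fraction: float = 0.05,
) -> HormoneThreshold:
    """Bimodal cutoff for one hormone gene on log-normalized expression.

    A Gaussian KDE (Silverman bandwidth) is evaluated on a 512-point grid;
    the threshold is the density minimum strictly between the two highest
    prominence-filtered modes. When fewer than two modes survive the filter,
    an Otsu-style variance-minimizing split is used and tagged
    ``otsu_fallback``.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 50:
        raise ValueError("need at least 50 values to estimate a hormone threshold")
    if np.ptp(v) == 0:
        raise ValueError("constant expression: no hormone threshold definable")
    kde = stats.gaussian_kde(v, bw_method="silverman")
    grid = np.linspace(v.min(), v.max(), n_grid)
    dens = kde(grid)
    padded = np.concatenate([[-1.0], dens, [-1.0]])
    peaks, _ = find_peaks(padded, prominence=prominence_fraction * dens.max())
    peaks = peaks - 1
    if peaks.size >= 2:
        top2 = peaks[np.argsort(dens[peaks])][-2:]
        lo, hi = int(top2.min()), int(top2.max())
        if hi - lo > 1:
            inner = slice(lo + 1, hi)
            t_idx = lo + 1 + int(np.argmin(dens[inner]))
            return HormoneThreshold(value=float(grid[t_idx]), method="kde_minimum")
    return HormoneThreshold(value=_otsu_split(v), method="otsu_fallback")


def _otsu_split(v: np.ndarray) -> float:
    """Between-class-variance-maximizing split of a 1-d sample."""
    x = np.sort(v)
    n = x.size
    cum = np.cumsum(x)
    total = cum[-1]
    k = np.arange(1, n)  # split after k values
    m0 = cum[:-1] / k
    m1 = (total - cum[:-1]) / (n - k)
    w0 = k / n
    between = w0 * (1 - w0) * (m0 - m1) ** 2
    valid = x[1:] > x[:-1]  # only cut between distinct values
    between = np.where(valid, between, -np.inf)
    i = int(np.argmax(between))
    return float(0.5 * (x[i] + x[i + 1]))


def classify_hormones(
    adata: ad.AnnData, thresholds: Mapping[str, HormoneThreshold | float]
) -> pd.DataFrame:
    """Boolean cells x hormones table: expression >= threshold counts as expressed."""
    missing = [g for g in thresholds if g not in adata.var_names]
    if missing:
        raise KeyError(f"hormone genes missing from matrix: {missing}")
    out = {}
    for gene, thr in thresholds.items():
        cut = thr.value if isinstance(thr, HormoneThreshold) else float(thr)
        vals = np.ravel(_dense(adata[:, gene].X))
        out[gene] = vals >= cut
    return pd.DataFrame(out, index=adata.obs_names)


def cluster_cells(
    adata: ad.AnnData, n_pcs: int = 20, n_clusters: int = 4, *, seed: int = 0
) -> np.ndarray:
    """K-means cluster labels on the top principal components of log-normalized data.

    Deliberately pluggable: any externally produced label vector can be used
    in its place throughout the rest of the pipeline.
    """
    if n_clusters > adata.n_obs:
        raise ValueError("n_clusters cannot exceed the number of cells")
    if n_clusters == adata.n_obs:
        return np.array([f"c{i}" for i in range(adata.n_obs)])
    emb = _pca_embed(_dense(adata.X), n_pcs, seed)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(emb)
    return np.array([f"c{l}" for l in labels])


def call_cluster_types(
    clusters: Sequence[str],
    hormone_flags: pd.DataFrame,
    hormone_to_type: Mapping[str, str],
    *,
    min_mono_fraction: float = 0.2,
) -> dict[str, str]:
    """Call each cluster to the majority type of its mono-hormonal cells.

    Clusters where fewer than ``min_mono_fraction`` of cells are mono-hormonal
    are called ``"other"`` (non-endocrine).
    """
    clusters = np.asarray(clusters)
    n_h = hormone_flags.to_numpy().sum(axis=1)
    calls: dict[str, str] = {}
    for c in np.unique(clusters):
        in_c = clusters == c
        mono = in_c & (n_h == 1)
        if mono.sum() < min_mono_fraction * in_c.sum():
            calls[str(c)] = "other"
            continue
        sub = hormone_flags.loc[mono]
        counts = sub.sum(axis=0)
        winner_gene = counts.idxmax()
        calls[str(c)] = hormone_to_type[winner_gene]
    return calls


def allocate_cell_types(
    clusters: Sequence[str],
    cluster_type_calls: Mapping[str, str],
    hormone_flags: pd.DataFrame,
    hormone_to_type: Mapping[str, str],
) -> list[CellIdentity]:
    """Final per-cell identity from cluster calls corrected by hormone profiles.

    Default is the cluster's type. A single hormone that contradicts the
    cluster re-assigns the cell to that hormone's type; two or more hormones
    make the cell *bihormonal*; no hormone in an ``"other"`` cluster leaves
    it *other*.
    """
    clusters = [str(c) for c in clusters]
    unmapped = sorted(set(clusters) - set(cluster_type_calls))
    if unmapped:
        raise KeyError(f"clusters without a type call: {unmapped}")
    flags = hormone_flags.to_numpy().astype(bool)
    genes = list(hormone_flags.columns)
    out: list[CellIdentity] = []
    for i, c in enumerate(clusters):
        profile = frozenset(g for g, f in zip(genes, flags[i]) if f)
        ct = cluster_type_calls[c]
        if len(profile) >= 2:
            final = "bihormonal"
        elif len(profile) == 1:
            h_type = hormone_to_type[next(iter(profile))]
            final = h_type if h_type != ct else ct
        else:
            final = ct  # "other" stays other; typed cluster keeps its type
        out.append(CellIdentity(cluster=c, hormones=profile, cell_type=final))
    return out
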