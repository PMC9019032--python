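"""Pairwise per-dataset differential expression between cell types.

Two test families are provided, matching common single-cell practice for the
two depth regimes:

* ``nb_lrt`` — per-gene negative-binomial regression on raw counts with a
  group indicator and nuisance covariates (log library size, detected-gene
  count), likelihood-ratio test of the group term. Dispersion is estimated
  per gene by method of moments from a Poisson fit. Intended for UMI data.
* ``hurdle_lrt`` — a two-part hurdle model on log-normalized values:
  logistic regression for detection plus Gaussian regression for positive
  values, combined into a 2-df likelihood-ratio test. Intended for deep
  full-length data.

Both are implemented as IRLS solvers *batched across genes* (all genes share
the design matrix, so the per-gene normal equations are solved in one
stacked ``np.linalg.solve``), which keeps thousands of fits per comparison
tractable. Log fold changes are computed uniformly as the natural log of
pseudocounted library-size-normalized group means, so the same effect-size
scale applies regardless of the test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.special import gammaln

__all__ = [
    "DETestConfig",
    "DETABLE_COLUMNS",
    "adjust_pvalues",
    "nb_lrt_test",
    "hurdle_lrt_test",
    "wilcoxon_rank_sum_test",
    "de_test_table",
    "filter_de_table",
    "flip_de_table",
    "de_pairwise",
]

DETABLE_COLUMNS = [
    "gene", "logfc", "p", "padj", "pct_a", "pct_b", "dataset", "type_a", "type_b",
]

_SCALE = 1e4
_ETA_CLIP = 30.0


@dataclass(frozen=True)
class DETestConfig:
    """Test choice, filters and correction for one pairwise DE analysis.

    ``direction="positive_only"`` with ``min_abs_logfc=0.5`` and
    ``max_padj=0.05`` is the derivation setting; rank files for evaluation
    use ``direction="both"`` with ``min_abs_logfc=0.1``.
    """

    test: str = "nb_lrt"  # "nb_lrt" | "hurdle_lrt" | "wilcoxon"
    min_abs_logfc: float = 0.5
    max_padj: float = 0.05
    direction: str = "positive_only"  # "positive_only" | "both"
    correction: str = "bonferroni"  # "bonferroni" | "bh"
    min_expr_fraction: float = 0.1
    use_donor: bool = False

    def __post_init__(self) -> None:
        if self.test not in ("nb_lrt", "hurdle_lrt", "wilcoxon"):
            raise ValueError(f"unknown test {self.test!r}")
        if not (0.0 < self.max_padj <= 1.0):
            raise ValueError("max_padj must lie in (0, 1]")
        if self.min_abs_logfc < 0:
            raise ValueError("min_abs_logfc must be >= 0")
        if self.direction not in ("positive_only", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.correction not in ("bonferroni", "bh"):
            raise ValueError(f"unknown correction {self.correction!r}")


def adjust_pvalues(p, method: str, n_tests: int | None = None) -> np.ndarray:
    """Multiple-testing adjustment over an explicit correction universe.

    ``bonferroni``: min(1, p * n). ``bh``: Benjamini-Hochberg step-up with
    universe size ``n_tests`` (defaults to ``len(p)``).
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p) if n_tests is None else int(n_tests)
    if method == "bonferroni":
        return np.minimum(1.0, p * n)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * n / np.arange(1, len(p) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(1.0, adj)
        return out
    raise ValueError(f"unknown correction method {method!r}")


# ---------------------------------------------------------------------------
# batched solvers
# ---------------------------------------------------------------------------


def _batch_solve(X: np.ndarray, W: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Solve per-gene weighted least squares (X' W_g X) b_g = X' W_g z_g.

    ``W``/``Z`` are cells x genes; returns betas genes x p.
    """
    A = np.einsum("ng,np,nq->gpq", W, X, X, optimize=True)
    b = np.einsum("ng,np->gp", W * Z, X, optimize=True)
    A = A + 1e-8 * np.eye(X.shape[1])[None, :, :]
    return np.linalg.solve(A, b[..., None])[..., 0]


def _irls_glm(
    Y: np.ndarray, X: np.ndarray, alpha: np.ndarray | None, *, max_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched IRLS for log-link Poisson (alpha None) or NB (fixed per-gene alpha).

    Returns (betas genes x p, mu cells x genes).
    """
    n, G = Y.shape
    p = X.shape[1]
    beta = np.zeros((G, p))
    beta[:, 0] = np.log(Y.mean(axis=0) + 1e-8)
    for _ in range(max_iter):
        eta = np.clip(X @ beta.T, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        if alpha is None:
            W = mu
        else:
            W = mu / (1.0 + alpha[None, :] * mu)
        Z = eta + (Y - mu) / np.maximum(mu, 1e-12)
        new = _batch_solve(X, np.maximum(W, 1e-12), Z)
        delta = np.max(np.abs(new - beta))
        beta = new
        if delta < tol:
            break
    eta = np.clip(X @ beta.T, -_ETA_CLIP, _ETA_CLIP)
    return beta, np.exp(eta)


def _nb_loglik(Y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood (cells summed out)."""
    a = np.maximum(alpha[None, :], 1e-10)
    r = 1.0 / a
    mu = np.maximum(mu, 1e-12)
    ll = (
        gammaln(Y + r) - gammaln(r) - gammaln(Y + 1.0)
        + Y * np.log(a * mu / (1.0 + a * mu))
        - r * np.log1p(a * mu)
    )
    return ll.sum(axis=0)


def _default_covariates(counts_all: np.ndarray) -> np.ndarray:
    """Standardized log library size and detected-gene count per cell."""
    totals = counts_all.sum(axis=1).astype(float)
    ngenes = (counts_all > 0).sum(axis=1).astype(float)
    cov = np.column_stack([np.log(np.maximum(totals, 1.0)), ngenes])
    sd = cov.std(axis=0)
    sd[sd == 0] = 1.0
    return (cov - cov.mean(axis=0)) / sd


def _design(n_a: int, n_b: int, covariates: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Full and null design matrices: [1, group(A=1), covariates...]."""
    n = n_a + n_b
    group = np.concatenate([np.ones(n_a), np.zeros(n_b)])
    cols = [np.ones(n), group]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError("covariates must have one row per cell (A then B)")
        cols.append(cov)
    X = np.column_stack(cols)
    X0 = np.delete(X, 1, axis=1)
    return X, X0


def _normalized_means(counts: np.ndarray, scale: float = _SCALE) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    return (counts / totals * scale).mean(axis=0)


def group_logfc(
    counts_a: np.ndarray, counts_b: np.ndarray, pseudocount: float = 1.0
) -> np.ndarray:
    """Natural-log fold change of pseudocounted library-size-normalized group means."""
    ma = _normalized_means(counts_a)
    mb = _normalized_means(counts_b)
    return np.log((ma + pseudocount) / (mb + pseudocount))


def nb_lrt_test(
    counts_a, counts_b, covariates: np.ndarray | None = None, *, gene_names=None
) -> pd.DataFrame:
    """Negative-binomial LRT of group membership, batched across genes.

    ``counts_a`` / ``counts_b`` are raw cells x genes count matrices of the
    two groups (same gene order). Default covariates are standardized log
    library size and detected-gene count. Returns a DataFrame with columns
    ``gene, logfc, p, untestable``.
    """
    A = _as_dense(counts_a)
    B = _as_dense(counts_b)
    if A.shape[0] < 3 or B.shape[0] < 3:
        raise ValueError("need at least 3 cells per group")
    if A.shape[1] != B.shape[1]:
        raise ValueError("gene dimensions differ between groups")
    Y = np.vstack([A, B]).astype(float)
    if covariates is None:
        covariates = _default_covariates(Y)
    X, X0 = _design(A.shape[0], B.shape[0], covariates)
    untestable = Y.sum(axis=0) == 0
    # dispersion per gene by moments from a Poisson full-model fit
    _, mu_pois = _irls_glm(Y, X, None, max_iter=25)
    resid = (Y - mu_pois) ** 2 - mu_pois
    denom = (mu_pois**2).sum(axis=0)
    alpha = np.clip(resid.sum(axis=0) / np.maximum(denom, 1e-12), 1e-8, 10.0)
    _, mu_full = _irls_glm(Y, X, alpha)
    _, mu_null = _irls_glm(Y, X0, alpha)
    lrt = 2.0 * (_nb_loglik(Y, mu_full, alpha) - _nb_loglik(Y, mu_null, alpha))
    p = stats.chi2.sf(np.maximum(lrt, 0.0), df=1)
    logfc = group_logfc(A, B)
    p[untestable] = 1.0
    logfc[untestable] = 0.0
    return _result_frame(gene_names, A.shape[1], logfc, p, untestable)


def hurdle_lrt_test(
    lognorm_a, lognorm_b, covariates: np.ndarray | None = None, *, gene_names=None
) -> pd.DataFrame:
    """Two-part hurdle LRT on log-normalized values, batched across genes.

    Detection is modelled by logistic regression and positive values by
    Gaussian regression; the group term is tested by a combined 2-df LRT.
    """
    A = _as_dense(lognorm_a)
    B = _as_dense(lognorm_b)
    if A.shape[0] < 3 or B.shape[0] < 3:
        raise ValueError("need at least 3 cells per group")
    if A.shape[1] != B.shape[1]:
        raise ValueError("gene dimensions differ between groups")
    V = np.vstack([A, B]).astype(float)
    n, G = V.shape
    detected = (V > 0).astype(float)
    if covariates is None:
        covariates = _default_covariates(np.expm1(V))
    X, X0 = _design(A.shape[0], B.shape[0], covariates)
    untestable = detected.sum(axis=0) == 0

    lrt_bin = _logistic_lrt(detected, X, X0)
    lrt_cont = _gaussian_lrt(V, detected, X, X0)
    p = stats.chi2.sf(np.maximum(lrt_bin + lrt_cont, 0.0), df=2)
    logfc = group_logfc(np.expm1(A), np.expm1(B), pseudocount=1.0)
    # expm1 of log-normalized values recovers normalized counts, whose
    # column sums are ~constant, so group_logfc's internal re-normalization
    # is a harmless rescale of the same quantity.
    p[untestable] = 1.0
    logfc[untestable] = 0.0
    return _result_frame(gene_names, G, logfc, p, untestable)


def _logistic_lrt(Y01: np.ndarray, X: np.ndarray, X0: np.ndarray) -> np.ndarray:
    degenerate = (Y01.sum(axis=0) == 0) | (Y01.sum(axis=0) == Y01.shape[0])

    def fit(Xd: np.ndarray) -> np.ndarray:
        G = Y01.shape[1]
        beta = np.zeros((G, Xd.shape[1]))
        pbar = np.clip(Y01.mean(axis=0), 1e-4, 1 - 1e-4)
        beta[:, 0] = np.log(pbar / (1 - pbar))
        for _ in range(30):
            eta = np.clip(Xd @ beta.T, -12.0, 12.0)
            mu = 1.0 / (1.0 + np.exp(-eta))
            W = np.maximum(mu * (1 - mu), 1e-6)
            Z = eta + (Y01 - mu) / W
            new = _batch_solve(Xd, W, Z)
            if np.max(np.abs(new - beta)) < 1e-6:
                beta = new
                break
            beta = new
        eta = np.clip(Xd @ beta.T, -12.0, 12.0)
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-10, 1 - 1e-10)
        return (Y01 * np.log(mu) + (1 - Y01) * np.log(1 - mu)).sum(axis=0)

    lrt = 2.0 * (fit(X) - fit(X0))
    lrt[degenerate] = 0.0
    return np.maximum(lrt, 0.0)


def _gaussian_lrt(V: np.ndarray, M: np.ndarray, X: np.ndarray, X0: np.ndarray) -> np.ndarray:
    """Gaussian LRT on detected cells only, via 0/1-weighted least squares."""
    n_pos = M.sum(axis=0)

    def rss(Xd: np.ndarray) -> np.ndarray:
        beta = _batch_solve(Xd, M, V)
        fit = Xd @ beta.T
        return (M * (V - fit) ** 2).sum(axis=0)

    testable = n_pos > X.shape[1] + 1
    out = np.zeros(V.shape[1])
    if testable.any():
        r1 = np.maximum(rss(X), 1e-12)
        r0 = np.maximum(rss(X0), 1e-12)
        out = np.where(testable, n_pos * np.log(np.maximum(r0 / r1, 1.0)), 0.0)
    return out


def wilcoxon_rank_sum_test(
    values_a, values_b, covariates=None, *, gene_names=None
) -> pd.DataFrame:
    """Two-sided Mann-Whitney rank-sum test per gene (covariates ignored)."""
    A = _as_dense(values_a)
    B = _as_dense(values_b)
    res = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float)
    untestable = (A.sum(axis=0) + B.sum(axis=0)) == 0
    logfc = group_logfc(np.expm1(A), np.expm1(B))
    p[untestable] = 1.0
    logfc[untestable] = 0.0
    return _result_frame(gene_names, A.shape[1], logfc, p, untestable)


def _as_dense(x) -> np.ndarray:
    if sparse.issparse(x):
        return np.asarray(x.todense())
    return np.asarray(x)


def _result_frame(gene_names, G, logfc, p, untestable) -> pd.DataFrame:
    genes = list(gene_names) if gene_names is not None else [f"g{i}" for i in range(G)]
    return pd.DataFrame(
        {"gene": genes, "logfc": logfc, "p": np.clip(p, 0.0, 1.0), "untestable": untestable}
    )


# ---------------------------------------------------------------------------
# pairwise comparison driver
# ---------------------------------------------------------------------------


def de_test_table(
    adata: ad.AnnData,
    identities: Sequence[str],
    type_a: str,
    type_b: str,
    config: DETestConfig,
    *,
    dataset: str | None = None,
) -> pd.DataFrame:
    """Unfiltered pairwise test results (type_a vs type_b) for one dataset.

    Genes expressed in at least ``config.min_expr_fraction`` of either group
    are tested; the multiple-testing correction runs over tested genes only.
    Use :func:`filter_de_table` to apply direction/effect/significance
    filters, or :func:`de_pairwise` for both steps at once.
    """
    ids = np.asarray([str(t) for t in identities])
    if ids.shape[0] != adata.n_obs:
        raise ValueError("identities must align with cells")
    for t in (type_a, type_b):
        if (ids == t).sum() < 3:
            raise ValueError(f"cell type {t!r} absent or has fewer than 3 cells")
    counts = adata.layers["counts"] if "counts" in adata.layers else adata.X
    counts = _as_dense(counts)
    mask_a = ids == type_a
    mask_b = ids == type_b
    Ca, Cb = counts[mask_a], counts[mask_b]
    pct_a = (Ca > 0).mean(axis=0)
    pct_b = (Cb > 0).mean(axis=0)
    tested = np.maximum(pct_a, pct_b) >= config.min_expr_fraction
    genes = np.asarray(adata.var_names)

    cov = _pairwise_covariates(adata, mask_a, mask_b, counts, config)
    if config.test == "nb_lrt":
        res = nb_lrt_test(Ca[:, tested], Cb[:, tested], cov, gene_names=genes[tested])
    else:
        totals = counts.sum(axis=1, keepdims=True).astype(float)
        totals[totals == 0] = 1.0
        lognorm = np.log1p(counts / totals * _SCALE)
        La, Lb = lognorm[mask_a][:, tested], lognorm[mask_b][:, tested]
        fn = hurdle_lrt_test if config.test == "hurdle_lrt" else wilcoxon_rank_sum_test
        res = fn(La, Lb, cov, gene_names=genes[tested])

    res = res[~res["untestable"]].copy()
    res["padj"] = adjust_pvalues(res["p"].to_numpy(), config.correction)
    res["pct_a"] = res["gene"].map(dict(zip(genes, pct_a)))
    res["pct_b"] = res["gene"].map(dict(zip(genes, pct_b)))
    res["dataset"] = dataset if dataset is not None else str(adata.obs["dataset"].iloc[0])
    res["type_a"] = type_a
    res["type_b"] = type_b
    return res[DETABLE_COLUMNS].reset_index(drop=True)


def filter_de_table(table: pd.DataFrame, config: DETestConfig) -> pd.DataFrame:
    """Apply direction / min \\|logFC\\| / max padj filters and the canonical ordering."""
    res = table.copy()
    if config.direction == "positive_only":
        keep = res["logfc"] >= config.min_abs_logfc
    else:
        keep = res["logfc"].abs() >= config.min_abs_logfc
    keep &= res["padj"] <= config.max_padj
    res = res[keep].copy()
    res["_abs_lfc"] = res["logfc"].abs()
    res = res.sort_values(
        ["padj", "_abs_lfc", "gene"], ascending=[True, False, True], kind="stable"
    )
    return res.drop(columns="_abs_lfc").reset_index(drop=True)


def flip_de_table(table: pd.DataFrame) -> pd.DataFrame:
    """The same test results viewed from the other group (logFC negated, groups swapped)."""
    out = table.copy()
    out["logfc"] = -out["logfc"]
    out[["type_a", "type_b"]] = out[["type_b", "type_a"]].to_numpy()
    out[["pct_a", "pct_b"]] = out[["pct_b", "pct_a"]].to_numpy()
    return out


def de_pairwise(
    adata: ad.AnnData,
    identities: Sequence[str],
    type_a: str,
    type_b: str,
    config: DETestConfig,
    *,
    dataset: str | None = None,
) -> pd.DataFrame:
    """One filtered pairwise DE table (type_a vs type_b) for one dataset.

    Rows are filtered by direction, ``min_abs_logfc`` and ``max_padj`` and
    ordered by (padj asc, \\|logfc\\| desc, gene asc).
    """
    full = de_test_table(adata, identities, type_a, type_b, config, dataset=dataset)
    return filter_de_table(full, config)


def _pairwise_covariates(adata, mask_a, mask_b, counts, config) -> np.ndarray:
    sub = np.vstack([counts[mask_a], counts[mask_b]])
    cov = _default_covariates(sub)
    if config.use_donor and "donor" in adata.obs:
        donors = pd.concat(
            [adata.obs.loc[mask_a, "donor"], adata.obs.loc[mask_b, "donor"]]
        )
        if donors.nunique() > 1:
            dummies = pd.get_dummies(donors, drop_first=True).to_numpy(dtype=float)
            cov = np.column_stack([cov, dummies])
    return cov
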