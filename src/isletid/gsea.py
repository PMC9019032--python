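"""Self-contained pre-ranked gene set enrichment analysis.

The enrichment score (ES) is the classic weighted Kolmogorov-Smirnov
running-sum statistic: walking down the ranked list, geneset hits increment
the running sum by ``|score|^weight`` normalized over all matched hits, and
misses decrement it by ``1/(N - n_matched)``; the ES is the maximum signed
deviation (the extremum of larger magnitude; an exact tie prefers the
positive peak). Significance comes from gene-label permutations: membership
is reassigned uniformly at the same size, the normalized enrichment score
(NES) divides the observed ES by the mean of same-sign null ES values, and
the nominal p is the fraction of same-sign null values at least as extreme
(with the conventional +1 smoothing).

Scores are ``-log10(padj)`` (floored at 1e-300), signed by the fold-change
direction when requested, so depleted genesets score negatively.

Failure semantics follow the geneset-matching gate: a geneset matching
fewer than ``min_matched`` (default 15) or more than ``max_matched``
(default 500) genes of the ranked list is not scored and carries an
explicit failure status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genesets import GeneSet

__all__ = [
    "RankedList",
    "GseaParams",
    "EnrichmentInfo",
    "PermutationResult",
    "GseaResult",
    "build_ranked_list",
    "enrichment_score",
    "permutation_nes",
    "gene_retrieval_rate",
    "leading_edge",
    "run_gsea",
]

PADJ_FLOOR = 1e-300


@dataclass(frozen=True)
class RankedList:
    """A gene ranking: unique genes with finite scores, sorted descending.

    Ties keep input order (stable sort), which makes every downstream
    statistic deterministic.
    """

    genes: tuple[str, ...]
    scores: tuple[float, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must align")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        s = np.asarray(self.scores, dtype=float)
        if not np.isfinite(s).all():
            raise ValueError("scores must be finite")
        order = np.argsort(-s, kind="stable")
        if not np.array_equal(order, np.arange(len(s))):
            object.__setattr__(self, "genes", tuple(np.asarray(self.genes)[order]))
            object.__setattr__(self, "scores", tuple(s[order]))
        else:
            object.__setattr__(self, "scores", tuple(s))

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def score_array(self) -> np.ndarray:
        return np.asarray(self.scores, dtype=float)

    @classmethod
    def from_rnk(cls, path, provenance: str | None = None) -> "RankedList":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["gene", "score"])
        return cls(
            genes=tuple(df["gene"].astype(str)),
            scores=tuple(df["score"].astype(float)),
            provenance=provenance or str(path),
        )

    def to_rnk(self, path) -> None:
        with open(path, "w") as fh:
            for g, s in zip(self.genes, self.scores):
                fh.write(f"{g}\t{s:.10g}\n")


def build_ranked_list(
    de_table: pd.DataFrame, floor: float = PADJ_FLOOR, signed: bool = True
) -> RankedList:
    """Rank genes by -log10(padj), optionally signed by fold-change direction."""
    genes = de_table["gene"].astype(str)
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ValueError(f"duplicate gene {dup!r} in DE table")
    padj = np.maximum(de_table["padj"].to_numpy(dtype=float), floor)
    score = -np.log10(padj)
    if signed:
        score = score * np.sign(de_table["logfc"].to_numpy(dtype=float))
    prov = ""
    if {"dataset", "type_a", "type_b"} <= set(de_table.columns) and len(de_table):
        r = de_table.iloc[0]
        prov = f"{r['dataset']}:{r['type_a']}_vs_{r['type_b']}"
    return RankedList(genes=tuple(genes), scores=tuple(score), provenance=prov)


@dataclass(frozen=True)
class GseaParams:
    weight: float = 1.0
    n_perm: int = 1000
    seed: int = 0
    min_matched: int = 15
    max_matched: int = 500


@dataclass
class EnrichmentInfo:
    es: float
    running_sum: np.ndarray
    hit_positions: np.ndarray  # 0-based positions of matched genes in the ranked list
    peak_index: int


@dataclass
class PermutationResult:
    es: float
    nes: float
    p: float
    null_es: np.ndarray = field(repr=False)
    unstable: bool = False


@dataclass
class GseaResult:
    name: str
    status: str  # "ok" | "failed_too_few" | "failed_too_many"
    n_matched: int
    grr: float
    es: float | None = None
    nes: float | None = None
    p: float | None = None
    q: float | None = None
    leading_edge: tuple[str, ...] = ()
    unstable: bool = False


def _hit_mask(ranked: RankedList, geneset: GeneSet) -> np.ndarray:
    members = set(geneset.genes)
    return np.fromiter((g in members for g in ranked.genes), dtype=bool, count=len(ranked))


def _running_sum(scores: np.ndarray, hits: np.ndarray, weight: float) -> np.ndarray:
    n = scores.size
    m = int(hits.sum())
    w = np.abs(scores) ** weight
    hit_w = np.where(hits, w, 0.0)
    total = hit_w.sum()
    if total > 0:
        inc = hit_w / total
    else:  # all matched scores exactly zero: fall back to equal hit mass
        inc = hits / m
    dec = np.where(hits, 0.0, 1.0 / (n - m))
    return np.cumsum(inc - dec)


def _es_from_running(running: np.ndarray) -> tuple[float, int]:
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        return float(running[i_max]), i_max
    return float(running[i_min]), i_min


def enrichment_score(
    ranked: RankedList, geneset: GeneSet, weight: float = 1.0
) -> EnrichmentInfo:
    """Weighted running-sum enrichment score of a geneset against a ranking."""
    hits = _hit_mask(ranked, geneset)
    m = int(hits.sum())
    if m == 0:
        raise ValueError("geneset matches no gene in the ranked list")
    if m == len(ranked):
        raise ValueError("geneset covers the entire ranked list (no misses possible)")
    running = _running_sum(ranked.score_array, hits, weight)
    es, peak = _es_from_running(running)
    return EnrichmentInfo(
        es=es, running_sum=running, hit_positions=np.flatnonzero(hits), peak_index=peak
    )


def leading_edge(
    ranked: RankedList, geneset: GeneSet, es_info: EnrichmentInfo
) -> list[str]:
    """Matched genes driving the enrichment signal.

    For positive ES: matched genes at or before the running-sum peak; for
    negative ES: matched genes at or after the trough. Returned in rank order.
    """
    hits = es_info.hit_positions
    if es_info.es >= 0:
        keep = hits[hits <= es_info.peak_index]
    else:
        keep = hits[hits >= es_info.peak_index]
    return [ranked.genes[i] for i in keep]


def gene_retrieval_rate(ranked: RankedList, geneset: GeneSet) -> float:
    """Fraction of the geneset's genes present in the ranked list."""
    if len(geneset) == 0:
        raise ValueError("empty geneset")
    present = set(ranked.genes)
    return sum(g in present for g in geneset.genes) / len(geneset)


def _null_es(
    scores: np.ndarray, m: int, n_perm: int, weight: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized gene-label permutation null: membership reassigned at size m."""
    n = scores.size
    w = np.abs(scores) ** weight
    # random membership per permutation via partial argsort of uniforms
    u = rng.random((n_perm, n))
    pick = np.argpartition(u, m - 1, axis=1)[:, :m]
    H = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(H, pick, True, axis=1)
    hit_w = np.where(H, w[None, :], 0.0)
    totals = hit_w.sum(axis=1, keepdims=True)
    inc = np.divide(hit_w, totals, out=np.where(H, 1.0 / m, 0.0), where=totals > 0)
    dec = np.where(H, 0.0, 1.0 / (n - m))
    running = np.cumsum(inc - dec, axis=1)
    rmax = running.max(axis=1)
    rmin = running.min(axis=1)
    return np.where(rmax >= -rmin, rmax, rmin)


def permutation_nes(
    ranked: RankedList,
    geneset: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    weight: float = 1.0,
) -> PermutationResult:
    """Permutation-normalized enrichment score and nominal p for one geneset."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    info = enrichment_score(ranked, geneset, weight)
    m = info.hit_positions.size
    rng = np.random.default_rng(seed)
    null = _null_es(ranked.score_array, m, n_perm, weight, rng)
    same_sign = null >= 0 if info.es >= 0 else null < 0
    n_ss = int(same_sign.sum())
    if n_ss == 0:
        return PermutationResult(
            es=info.es, nes=np.nan, p=1.0 / n_perm, null_es=null, unstable=True
        )
    mean_ss = float(np.abs(null[same_sign]).mean())
    nes = info.es / mean_ss if mean_ss > 0 else np.nan
    extreme = int((np.abs(null[same_sign]) >= abs(info.es)).sum())
    p = (1.0 + extreme) / (1.0 + n_ss)
    return PermutationResult(
        es=info.es, nes=float(nes), p=float(p), null_es=null, unstable=not np.isfinite(nes)
    )


def run_gsea(
    ranked: RankedList, genesets: Sequence[GeneSet], params: GseaParams = GseaParams()
) -> list[GseaResult]:
    """Score a collection of genesets against one ranked list.

    Genesets matching fewer than ``params.min_matched`` or more than
    ``params.max_matched`` genes fail with an explicit status and carry no
    scores. FDR q-values are computed across the scored genesets by the
    standard pooled-null NES normalization.
    """
    if len(ranked) == 0:
        raise ValueError("empty ranked list")
    results: list[GseaResult] = []
    pooled_null_nes: list[np.ndarray] = []
    for i, gs in enumerate(genesets):
        n_matched = int(_hit_mask(ranked, gs).sum())
        grr = gene_retrieval_rate(ranked, gs)
        if n_matched < params.min_matched:
            results.append(GseaResult(gs.name, "failed_too_few", n_matched, grr))
            continue
        if n_matched > params.max_matched:
            results.append(GseaResult(gs.name, "failed_too_many", n_matched, grr))
            continue
        perm = permutation_nes(
            ranked, gs, n_perm=params.n_perm,
            seed=params.seed + 1000 * i, weight=params.weight,
        )
        info = enrichment_score(ranked, gs, params.weight)
        le = tuple(leading_edge(ranked, gs, info))
        results.append(
            GseaResult(
                gs.name, "ok", n_matched, grr,
                es=perm.es, nes=perm.nes, p=perm.p,
                leading_edge=le, unstable=perm.unstable,
            )
        )
        null = perm.null_es
        pos = null[null >= 0]
        neg = null[null < 0]
        norm = np.empty_like(null)
        norm[null >= 0] = pos / pos.mean() if pos.size else np.nan
        norm[null < 0] = -neg / neg.mean() if neg.size else np.nan
        pooled_null_nes.append(norm[np.isfinite(norm)])
    _attach_fdr(results, pooled_null_nes)
    return results


def _attach_fdr(results: list[GseaResult], pooled: list[np.ndarray]) -> None:
    scored = [r for r in results if r.status == "ok" and r.nes is not None and np.isfinite(r.nes)]
    if not scored or not pooled:
        return
    null = np.concatenate(pooled)
    obs = np.array([r.nes for r in scored])
    for r in scored:
        if r.nes >= 0:
            num = (null >= r.nes).mean()
            den = (obs >= r.nes).mean()
        else:
            num = (null <= r.nes).mean()
            den = (obs <= r.nes).mean()
        r.q = float(min(1.0, num / den)) if den > 0 else 1.0


def results_frame(results: Sequence[GseaResult]) -> pd.DataFrame:
    """Tabular view of GSEA results (one row per geneset)."""
    return pd.DataFrame(
        [
            {
                "name": r.name, "status": r.status, "n_matched": r.n_matched,
                "grr": r.grr, "es": r.es, "nes": r.nes, "p": r.p, "q": r.q,
                "leading_edge_size": len(r.leading_edge),
            }
            for r in results
        ]
    )
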