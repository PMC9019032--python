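"""Geneset evaluation metric, optimal intersect-level selection, and
collection benchmarking.

A geneset is evaluated over a grid of ranked lists (in the reference design,
3 held-out datasets x 3 opposing cell types = 9 evaluations). Sensitivity is
proxied by the mean normalized enrichment score (NES) over the grid,
specificity by the mean gene retrieval rate (GRR: the fraction of geneset
genes present in each ranked list). The evaluation metric is their product,

    EM = mean(NES) * mean(GRR),

and it is zeroed outright when any evaluation fails the GSEA matching gate —
a geneset that cannot be scored everywhere is not admissible. Per cell type,
the eligible geneset with the highest EM is selected; EM ties break toward
the higher (more specific) intersect level.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneSet
from .gsea import GseaParams, RankedList, run_gsea

__all__ = [
    "EvaluationScore",
    "BenchmarkReport",
    "evaluate_geneset",
    "select_optimal_level",
    "benchmark_genesets",
    "wilcoxon_signed_rank",
]


@dataclass
class EvaluationScore:
    """Per-grid NES/GRR values and the combined EM for one geneset."""

    name: str
    cell_type: str
    level: int
    size: int
    nes_values: tuple[float, ...]  # NaN where the evaluation failed
    grr_values: tuple[float, ...]
    n_failed: int
    mean_nes: float
    mean_grr: float
    em: float


def evaluate_geneset(
    geneset: GeneSet,
    ranked_lists: Sequence[RankedList],
    gsea_params: GseaParams = GseaParams(),
) -> EvaluationScore:
    """Run GSEA against every ranked list and combine into an EM score.

    Means are taken over successful evaluations; any failure zeroes the EM
    while the per-evaluation breakdown is still reported.
    """
    if not ranked_lists:
        raise ValueError("need at least one ranked list")
    nes, grr = [], []
    n_failed = 0
    for ranked in ranked_lists:
        res = run_gsea(ranked, [geneset], gsea_params)[0]
        grr.append(res.grr)
        if res.status != "ok" or res.nes is None or not np.isfinite(res.nes):
            nes.append(np.nan)
            n_failed += 1
        else:
            nes.append(res.nes)
    nes_arr = np.asarray(nes)
    ok = np.isfinite(nes_arr)
    mean_nes = float(nes_arr[ok].mean()) if ok.any() else np.nan
    mean_grr = float(np.asarray(grr)[ok].mean()) if ok.any() else float(np.mean(grr))
    em = 0.0 if n_failed > 0 or not ok.any() else mean_nes * mean_grr
    return EvaluationScore(
        name=geneset.name,
        cell_type=geneset.cell_type,
        level=geneset.level,
        size=len(geneset),
        nes_values=tuple(nes),
        grr_values=tuple(grr),
        n_failed=n_failed,
        mean_nes=mean_nes,
        mean_grr=mean_grr,
        em=em,
    )


def select_optimal_level(
    eligible_genesets: Sequence[GeneSet],
    ranked_lists: Sequence[RankedList],
    gsea_params: GseaParams = GseaParams(),
) -> tuple[GeneSet | None, pd.DataFrame]:
    """Pick the eligible geneset with the highest EM (ties -> higher level).

    Returns the winner (None when every EM is zero — no admissible geneset)
    and the full score table for reporting.
    """
    if not eligible_genesets:
        raise ValueError("no eligible genesets supplied")
    scores = [evaluate_geneset(gs, ranked_lists, gsea_params) for gs in eligible_genesets]
    table = pd.DataFrame(
        {
            "name": [s.name for s in scores],
            "cell_type": [s.cell_type for s in scores],
            "level": [s.level for s in scores],
            "size": [s.size for s in scores],
            "mean_nes": [s.mean_nes for s in scores],
            "mean_grr": [s.mean_grr for s in scores],
            "n_failed": [s.n_failed for s in scores],
            "em": [s.em for s in scores],
        }
    )
    if (table["em"] <= 0).all():
        return None, table
    best_em = table["em"].max()
    tied = table[table["em"] == best_em]
    winner_level = int(tied["level"].max())
    winner = next(
        gs for gs in eligible_genesets
        if gs.level == winner_level and table.loc[table["name"] == gs.name, "em"].iloc[0] == best_em
    )
    return winner, table


def wilcoxon_signed_rank(
    differences, alternative: str = "two-sided"
) -> float:
    """Wilcoxon signed-rank p-value for paired differences.

    Zeros are dropped (all-zero input gives p = 1). For n <= 12 nonzero
    differences the null is enumerated exactly over all 2^n sign
    assignments (average ranks for ties); larger samples use the normal
    approximation with tie correction and continuity correction.
    """
    d = np.asarray(differences, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= 12:
        # exact enumeration of W+ over all sign assignments
        totals = np.zeros(1)
        for r in ranks:
            totals = np.concatenate([totals, totals + r])
        if alternative == "greater":
            p = float((totals >= w_pos - 1e-9).mean())
        elif alternative == "less":
            p = float((totals <= w_pos + 1e-9).mean())
        else:
            mu = ranks.sum() / 2.0
            dev = abs(w_pos - mu)
            p = float((np.abs(totals - mu) >= dev - 1e-9).mean())
        return min(1.0, p)
    mu = n * (n + 1) / 4.0
    ties = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (ties**3 - ties).sum() / 48.0
    if var <= 0:
        return 1.0
    if alternative == "greater":
        z = (w_pos - mu - 0.5) / sqrt(var)
        return float(stats.norm.sf(z))
    if alternative == "less":
        z = (w_pos - mu + 0.5) / sqrt(var)
        return float(stats.norm.cdf(z))
    z = (abs(w_pos - mu) - 0.5) / sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


@dataclass
class BenchmarkReport:
    """Grid scores per collection plus paired tests against a reference."""

    scores: pd.DataFrame  # columns: collection, cell_type, eval_index, nes, grr, em
    tests: pd.DataFrame  # columns: collection, metric, p, n_pairs
    reference: str


def benchmark_genesets(
    collections: Mapping[str, Sequence[GeneSet]],
    ranked_lists: Mapping[str, Sequence[RankedList]],
    reference_name: str,
    gsea_params: GseaParams = GseaParams(),
) -> BenchmarkReport:
    """Score every collection on the shared evaluation grid and compare to a reference.

    ``ranked_lists`` maps cell type -> the grid of ranked lists for genesets
    of that type, so all collections face the same evaluations. Failed
    evaluations enter the table as NaN NES/GRR (EM 0) and are dropped from
    the paired Wilcoxon signed-rank tests.
    """
    if reference_name not in collections:
        raise KeyError(f"reference collection {reference_name!r} not supplied")
    rows = []
    for cname, genesets in collections.items():
        for gs in genesets:
            grid = ranked_lists.get(gs.cell_type)
            if not grid:
                raise ValueError(f"no ranked lists supplied for cell type {gs.cell_type!r}")
            score = evaluate_geneset(gs, grid, gsea_params)
            for i, (nes, grr) in enumerate(zip(score.nes_values, score.grr_values)):
                failed = not np.isfinite(nes)
                rows.append(
                    {
                        "collection": cname,
                        "cell_type": gs.cell_type,
                        "eval_index": i,
                        "nes": np.nan if failed else nes,
                        "grr": np.nan if failed else grr,
                        "em": 0.0 if score.n_failed > 0 else score.em,
                    }
                )
    scores = pd.DataFrame(rows)
    ref = scores[scores["collection"] == reference_name].set_index(
        ["cell_type", "eval_index"]
    )
    tests = []
    for cname in collections:
        if cname == reference_name:
            continue
        other = scores[scores["collection"] == cname].set_index(["cell_type", "eval_index"])
        joined = other.join(ref, lsuffix="_c", rsuffix="_ref")
        for metric in ("nes", "grr"):
            pair = joined[[f"{metric}_c", f"{metric}_ref"]].dropna()
            diffs = (pair[f"{metric}_c"] - pair[f"{metric}_ref"]).to_numpy()
            p = wilcoxon_signed_rank(diffs) if len(diffs) else np.nan
            tests.append(
                {"collection": cname, "metric": metric, "p": p, "n_pairs": len(diffs)}
            )
    return BenchmarkReport(
        scores=scores, tests=pd.DataFrame(tests), reference=reference_name
    )
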