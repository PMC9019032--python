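"""Independent brute-force oracles used to validate the implementation.

Deliberately naive, loop-based re-implementations that share no code with
the package internals.
"""

from __future__ import annotations

import numpy as np


def naive_enrichment(genes, scores, members, weight=1.0):
    """Step-by-step running-sum enrichment: returns (es, running, peak, sorted_genes, hits)."""
    n = len(genes)
    # stable descending sort: ties keep input order
    order = sorted(range(n), key=lambda i: (-scores[i], i))
    g = [genes[i] for i in order]
    s = [scores[i] for i in order]
    member_set = set(members)
    hits = [x in member_set for x in g]
    m = sum(hits)
    assert 0 < m < n
    denom = sum(abs(s[i]) ** weight for i in range(n) if hits[i])
    running = []
    cum = 0.0
    for i in range(n):
        if hits[i]:
            cum += abs(s[i]) ** weight / denom if denom > 0 else 1.0 / m
        else:
            cum -= 1.0 / (n - m)
        running.append(cum)
    # extremum of larger magnitude; exact tie prefers the positive peak
    i_max = running.index(max(running))
    i_min = running.index(min(running))
    if running[i_max] >= -running[i_min]:
        best, peak = running[i_max], i_max
    else:
        best, peak = running[i_min], i_min
    return best, running, peak, g, hits


def naive_leading_edge(genes, scores, members, weight=1.0):
    es, running, peak, g, hits = naive_enrichment(genes, scores, members, weight)
    if es >= 0:
        return [g[i] for i in range(len(g)) if hits[i] and i <= peak]
    return [g[i] for i in range(len(g)) if hits[i] and i >= peak]


def naive_signed_rank_p(diffs, alternative="two-sided"):
    """Full 2^n enumeration of the Wilcoxon signed-rank null."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    if n == 0:
        return 1.0
    absd = [abs(x) for x in d]
    # average ranks with ties
    order = sorted(range(n), key=lambda i: absd[i])
    ranks = [0.0] * n
    i = 0
    r = 1
    while i < n:
        j = i
        while j + 1 < n and absd[order[j + 1]] == absd[order[i]]:
            j += 1
        avg = (r + r + (j - i)) / 2.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        r += j - i + 1
        i = j + 1
    w_obs = sum(ranks[i] for i in range(n) if d[i] > 0)
    total = sum(ranks)
    count = 0
    n_assign = 2**n
    mu = total / 2.0
    for mask in range(n_assign):
        w = sum(ranks[i] for i in range(n) if (mask >> i) & 1)
        if alternative == "greater":
            count += w >= w_obs - 1e-9
        elif alternative == "less":
            count += w <= w_obs + 1e-9
        else:
            count += abs(w - mu) >= abs(w_obs - mu) - 1e-9
    return count / n_assign


def naive_integration(rows, padj_floor=1e-300):
    """Dictionary-based aggregation + sort oracle for cross-dataset integration.

    ``rows`` is a list of (gene, logfc, padj) tuples pooled over analyses.
    Returns gene ids in the canonical order.
    """
    per_gene: dict[str, list[tuple[float, float]]] = {}
    for gene, logfc, padj in rows:
        per_gene.setdefault(gene, []).append((logfc, max(padj, padj_floor)))
    stats = {}
    for gene, vals in per_gene.items():
        n = len(vals)
        avg_lfc = sum(v[0] for v in vals) / n
        avg_neglog = sum(-np.log10(v[1]) for v in vals) / n
        avg_padj = 10.0 ** (-avg_neglog)
        score = -np.log10(avg_padj) * avg_lfc
        stats[gene] = (n, score)
    return sorted(stats, key=lambda g: (-stats[g][0], -stats[g][1], g))
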