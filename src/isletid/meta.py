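"""Cross-dataset integration of pairwise DE tables into per-gene evidence records.

A gene's evidence for a target cell type is aggregated over every pairwise
analysis (dataset x opposing type) in which it passed the DE filters:

* ``n_analyses`` — the number of contributing analyses (missing is missing,
  never zero);
* ``avg_logfc`` — arithmetic mean log fold change over contributing analyses;
* ``avg_padj`` — ``10 ** -mean(-log10(padj))``, i.e. the geometric mean of
  the adjusted p-values (floored at 1e-300 before taking logs);
* ``rank_score`` — ``-log10(avg_padj) * avg_logfc``.

Records are ordered by ``n_analyses`` (desc), then ``rank_score`` (desc),
then gene id — the same total order used to build intersect-level genesets.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PADJ_FLOOR",
    "aggregate_avg_padj",
    "rank_score",
    "integrate_de",
    "annotate_genes",
    "read_flag_table",
]

PADJ_FLOOR = 1e-300


def aggregate_avg_padj(padj_values: Iterable[float]) -> float:
    """Geometric-mean aggregation of adjusted p-values: 10^(-mean(-log10 p))."""
    p = np.asarray(list(padj_values), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]; floor zeros upstream")
    return float(10.0 ** (-np.mean(-np.log10(p))))


def rank_score(avg_padj: float, avg_logfc: float) -> float:
    """Combined evidence score: -log10(avg_padj) * avg_logfc."""
    if not (0.0 < avg_padj <= 1.0):
        raise ValueError("avg_padj must lie in (0, 1]")
    return float(-np.log10(avg_padj) * avg_logfc)


def integrate_de(
    tables: Sequence[pd.DataFrame], target_type: str, *, padj_floor: float = PADJ_FLOOR
) -> pd.DataFrame:
    """Aggregate filtered pairwise DE tables for one target cell type.

    Every table must have the target as ``type_a`` (positive log fold change
    = enriched in the target). Returns one row per gene with overall and
    per-opponent aggregates, in the canonical ordering.
    """
    if not tables:
        raise ValueError("no DE tables supplied")
    for t in tables:
        bad = set(t["type_a"].unique()) - {target_type}
        if bad:
            raise ValueError(
                f"table with type_a {sorted(bad)} passed while integrating {target_type!r}"
            )
    cat = pd.concat(tables, ignore_index=True)
    dup = cat.duplicated(subset=["gene", "dataset", "type_b"])
    if dup.any():
        first = cat[dup].iloc[0]
        raise ValueError(
            f"duplicate analysis row for gene {first['gene']!r} "
            f"({first['dataset']}, vs {first['type_b']})"
        )
    cat = cat.assign(
        _padj=np.maximum(cat["padj"].to_numpy(dtype=float), padj_floor)
    )
    cat["_neglog"] = -np.log10(cat["_padj"])

    def _agg(df: pd.DataFrame) -> pd.DataFrame:
        g = df.groupby("gene", sort=True)
        out = pd.DataFrame(
            {
                "n_analyses": g.size(),
                "avg_logfc": g["logfc"].mean(),
                "avg_padj": 10.0 ** (-g["_neglog"].mean()),
            }
        )
        out["rank_score"] = -np.log10(out["avg_padj"]) * out["avg_logfc"]
        return out

    overall = _agg(cat)
    overall.insert(0, "cell_type", target_type)
    for opp in sorted(cat["type_b"].unique()):
        sub = _agg(cat[cat["type_b"] == opp])
        sub.columns = [f"{c}_vs_{opp}" for c in sub.columns]
        overall = overall.join(sub.drop(columns=[f"cell_type_vs_{opp}"], errors="ignore"))
    overall["n_analyses"] = overall["n_analyses"].astype(int)
    overall = overall.reset_index()
    overall = overall.sort_values(
        ["n_analyses", "rank_score", "gene"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    return overall


def read_flag_table(path) -> pd.DataFrame:
    """Read a (gene -> flag/category) TSV, reporting the offending line on error."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 1 or not fields[0]:
                raise ValueError(f"{path}: malformed annotation line {lineno}: {line!r}")
            rows.append((fields[0], fields[1] if len(fields) > 1 else "true"))
    return pd.DataFrame(rows, columns=["gene", "category"]).drop_duplicates("gene")


def annotate_genes(
    records: pd.DataFrame,
    tf_table: pd.DataFrame | None = None,
    surface_table: pd.DataFrame | None = None,
    localization_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Left-join annotation flags onto aggregated records.

    Unmatched genes get ``False`` flags / empty localization; tables are
    (gene, category) frames as produced by :func:`read_flag_table`.
    """
    out = records.copy()
    out["is_tf"] = _flag(out["gene"], tf_table)
    out["is_surface"] = _flag(out["gene"], surface_table)
    if localization_table is not None:
        loc = dict(zip(localization_table["gene"], localization_table["category"]))
        out["localization"] = out["gene"].map(loc).fillna("")
    else:
        out["localization"] = ""
    return out


def _flag(genes: pd.Series, table: pd.DataFrame | None) -> np.ndarray:
    if table is None or len(table) == 0:
        return np.zeros(len(genes), dtype=bool)
    members = set(table["gene"])
    return genes.isin(members).to_numpy()
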