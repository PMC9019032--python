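"""End-to-end orchestration: simulate -> cell typing -> pairwise DE ->
cross-dataset integration -> intersect-level genesets -> evaluation ranks ->
NES x GRR optimization -> benchmarking.

Each ``run_*`` function is an importable pipeline stage operating on
in-memory objects; the ``cmd_*`` functions are their file-based counterparts
used by the command-line interface, communicating through plain-text
artifacts (MTX, TSV, GMT, RNK, JSON) in a working directory. All randomness
flows from explicit seeds and every stage is idempotent for identical
inputs; ``run_full`` records a manifest with the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from . import io as _io
from .celltyping import (
    QCThresholds,
    allocate_cell_types,
    call_cluster_types,
    classify_hormones,
    cluster_cells,
    doublet_score,
    flag_doublets,
    hormone_threshold,
    normalize_log,
    qc_filter,
)
from .de import DETestConfig, de_test_table, filter_de_table, flip_de_table
from .genesets import (
    GeneSet,
    build_intersect_genesets,
    overlap_partition,
    read_gmt,
    size_filter,
    write_gmt,
)
from .gsea import GseaParams, RankedList, build_ranked_list, results_frame, run_gsea
from .meta import integrate_de
from .optimize import benchmark_genesets, select_optimal_level
from .simulate import (
    SimulationConfig,
    SyntheticCollection,
    generate_collection,
    generate_evaluation_datasets,
)

__all__ = [
    "PipelineParams",
    "PipelineResult",
    "run_celltype_stage",
    "run_derivation_de",
    "run_integration",
    "run_geneset_building",
    "run_evaluation_ranks",
    "run_optimization",
    "run_full",
    "cmd_simulate",
    "cmd_celltype",
    "cmd_de",
    "cmd_integrate",
    "cmd_buildsets",
    "cmd_gsea",
    "cmd_optimize",
    "cmd_benchmark",
]


@dataclass(frozen=True)
class PipelineParams:
    """All knobs of the end-to-end analysis, with the reference study design
    as defaults: positive-only DE at logFC >= 0.5 / padj <= 0.05 for geneset
    derivation, two-sided DE at logFC >= 0.1 for evaluation ranks, geneset
    size bounds [40, 500], GSEA matching gate [15, 500]."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCThresholds = field(
        default_factory=lambda: QCThresholds(min_counts=100, min_genes=50, max_mito_fraction=0.5)
    )
    derivation: DETestConfig = field(default_factory=DETestConfig)
    evaluation: DETestConfig = field(
        default_factory=lambda: DETestConfig(direction="both", min_abs_logfc=0.1)
    )
    gsea: GseaParams = field(default_factory=GseaParams)
    n_eval_datasets: int = 3
    min_geneset_size: int = 40
    max_geneset_size: int = 500
    expected_doublet_rate: float = 0.05
    doublet_k: tuple[int, int] = (10, 30)
    synthetic_doublet_fraction: float = 0.25
    n_pcs: int = 20
    n_clusters: int | None = None  # default: one per hormone gene

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = _io.config_to_dict(self.sim)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineParams":
        d = dict(d)
        kwargs = {}
        if "sim" in d:
            kwargs["sim"] = _io.config_from_dict(d.pop("sim"))
        for key, typ in (
            ("qc", QCThresholds),
            ("derivation", DETestConfig),
            ("evaluation", DETestConfig),
            ("gsea", GseaParams),
        ):
            if key in d:
                kwargs[key] = typ(**d.pop(key))
        if "doublet_k" in d:
            d["doublet_k"] = tuple(d["doublet_k"])
        kwargs.update(d)
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    params: PipelineParams
    collection: SyntheticCollection
    typed: list[ad.AnnData]
    identity_tables: dict[str, pd.DataFrame]
    celltype_reports: dict[str, dict]
    de_tables: dict[str, list[pd.DataFrame]]
    records: dict[str, pd.DataFrame]
    genesets_all: dict[str, list[GeneSet]]
    genesets_eligible: dict[str, list[GeneSet]]
    ranked_lists: dict[str, list[RankedList]]
    winners: dict[str, GeneSet | None]
    score_tables: dict[str, pd.DataFrame]
    partition: object
    manifest: dict


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def run_celltype_stage(
    adata: ad.AnnData, params: PipelineParams, *, seed: int = 0
) -> tuple[ad.AnnData, pd.DataFrame, dict]:
    """QC, doublet removal, clustering, hormone thresholding and allocation
    for one dataset.

    Returns the typed log-normalized matrix (doublet-flagged cells removed),
    the per-cell identity table covering every post-QC cell, and a report
    with QC numbers, hormone thresholds and doublet flags.
    """
    filtered, qc_report = qc_filter(adata, params.qc)
    k1, k2 = params.doublet_k
    s1 = doublet_score(
        filtered, k1, params.synthetic_doublet_fraction, n_pcs=params.n_pcs, seed=seed
    )
    s2 = doublet_score(
        filtered, k2, params.synthetic_doublet_fraction, n_pcs=params.n_pcs, seed=seed + 1
    )
    dbl = flag_doublets(s1, s2, params.expected_doublet_rate)
    singlets = filtered[~dbl].copy()
    lognorm = normalize_log(singlets)

    hormones = [g for g in lognorm.var_names[lognorm.var["is_hormone"].astype(bool)]]
    hormone_to_type = dict(
        zip(hormones, lognorm.var.loc[hormones, "hormone_of"].astype(str))
    )
    thresholds = {}
    for g in hormones:
        vals = np.ravel(np.asarray(lognorm[:, g].X.todense()))
        thresholds[g] = hormone_threshold(vals)
    flags = classify_hormones(lognorm, thresholds)

    n_clusters = params.n_clusters or len(hormones)
    clusters = cluster_cells(lognorm, n_pcs=params.n_pcs, n_clusters=n_clusters, seed=seed)
    calls = call_cluster_types(clusters, flags, hormone_to_type)
    identities = allocate_cell_types(clusters, calls, flags, hormone_to_type)

    lognorm.obs["cluster"] = [c.cluster for c in identities]
    lognorm.obs["hormones"] = [";".join(sorted(c.hormones)) for c in identities]
    lognorm.obs["cell_type"] = [c.cell_type for c in identities]

    table = pd.DataFrame(
        {
            "cell_id": filtered.obs_names,
            "cluster": "",
            "hormones": "",
            "final_type": "removed_doublet",
            "doublet_flag": dbl,
        }
    )
    table = table.set_index("cell_id")
    table.loc[lognorm.obs_names, "cluster"] = lognorm.obs["cluster"].to_numpy()
    table.loc[lognorm.obs_names, "hormones"] = lognorm.obs["hormones"].to_numpy()
    table.loc[lognorm.obs_names, "final_type"] = lognorm.obs["cell_type"].to_numpy()
    table = table.reset_index()

    report = {
        "qc": qc_report,
        "n_flagged_doublets": int(dbl.sum()),
        "hormone_thresholds": {
            g: {"value": t.value, "method": t.method} for g, t in thresholds.items()
        },
        "cluster_calls": calls,
    }
    return lognorm, table, report


def _test_config_for(adata: ad.AnnData, base: DETestConfig) -> DETestConfig:
    """NB test for UMI-style datasets, hurdle test otherwise."""
    protocol = str(adata.uns.get("protocol", "umi"))
    return replace(base, test="nb_lrt" if protocol == "umi" else "hurdle_lrt")


def _pairwise_tables(
    typed: ad.AnnData, cell_types: Sequence[str], config: DETestConfig
) -> dict[tuple[str, str], pd.DataFrame]:
    """Filtered tables for every ordered type pair, testing each unordered pair once."""
    ids = typed.obs["cell_type"].to_numpy()
    present = [t for t in cell_types if (ids == t).sum() >= 3]
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for i, a in enumerate(present):
        for b in present[i + 1 :]:
            full = de_test_table(typed, ids, a, b, config)
            out[(a, b)] = filter_de_table(full, config)
            out[(b, a)] = filter_de_table(flip_de_table(full), config)
    return out


def run_derivation_de(
    typed_datasets: Sequence[ad.AnnData], params: PipelineParams
) -> dict[str, list[pd.DataFrame]]:
    """Positive-only pairwise DE per dataset, grouped by target cell type."""
    targets: dict[str, list[pd.DataFrame]] = {t: [] for t in params.sim.cell_types}
    for typed in typed_datasets:
        cfg = _test_config_for(typed, params.derivation)
        tables = _pairwise_tables(typed, params.sim.cell_types, cfg)
        for (a, _b), tab in tables.items():
            targets[a].append(tab)
    return targets


def run_integration(
    de_tables: Mapping[str, Sequence[pd.DataFrame]], params: PipelineParams
) -> dict[str, pd.DataFrame]:
    return {
        t: integrate_de(list(tabs), t)
        for t, tabs in de_tables.items()
        if any(len(x) for x in tabs)
    }


def run_geneset_building(
    records: Mapping[str, pd.DataFrame], params: PipelineParams
) -> tuple[dict[str, list[GeneSet]], dict[str, list[GeneSet]]]:
    max_level = params.sim.n_datasets * (len(params.sim.cell_types) - 1)
    all_sets = {
        t: build_intersect_genesets(rec, t, max_level=max_level)
        for t, rec in records.items()
    }
    eligible = {
        t: size_filter(sets, params.min_geneset_size, params.max_geneset_size)
        for t, sets in all_sets.items()
    }
    return all_sets, eligible


def run_evaluation_ranks(
    params: PipelineParams, *, seed: int = 0
) -> dict[str, list[RankedList]]:
    """Held-out evaluation datasets -> signed -log10(padj) ranked lists.

    Each target cell type gets n_eval_datasets x (n_types - 1) ranked lists
    (one per dataset x opposing type), built from two-sided DE at the
    evaluation thresholds on the datasets' own allocated cell types.
    """
    evals = generate_evaluation_datasets(params.sim, params.n_eval_datasets)
    ranks: dict[str, list[RankedList]] = {t: [] for t in params.sim.cell_types}
    for i, adata in enumerate(evals):
        typed, _, _ = run_celltype_stage(adata, params, seed=seed + 100 + i)
        cfg = _test_config_for(typed, params.evaluation)
        tables = _pairwise_tables(typed, params.sim.cell_types, cfg)
        for (a, b), tab in tables.items():
            if len(tab):
                ranks[a].append(build_ranked_list(tab, signed=True))
    return ranks


def run_optimization(
    eligible: Mapping[str, Sequence[GeneSet]],
    ranked_lists: Mapping[str, Sequence[RankedList]],
    params: PipelineParams,
) -> tuple[dict[str, GeneSet | None], dict[str, pd.DataFrame]]:
    winners: dict[str, GeneSet | None] = {}
    tables: dict[str, pd.DataFrame] = {}
    for t, sets in eligible.items():
        if not sets or not ranked_lists.get(t):
            winners[t] = None
            tables[t] = pd.DataFrame()
            continue
        winner, table = select_optimal_level(list(sets), list(ranked_lists[t]), params.gsea)
        winners[t] = winner
        tables[t] = table
    return winners, tables


def run_full(params: PipelineParams | None = None, *, seed: int | None = None) -> PipelineResult:
    """The whole chain on the configured synthetic collection."""
    params = params or PipelineParams()
    if seed is not None:
        params = replace(
            params,
            sim=replace(params.sim, seed=seed),
            gsea=replace(params.gsea, seed=seed),
        )
    base_seed = params.sim.seed
    collection = generate_collection(params.sim)
    typed_list: list[ad.AnnData] = []
    identity_tables: dict[str, pd.DataFrame] = {}
    celltype_reports: dict[str, dict] = {}
    for i, adata in enumerate(collection.datasets):
        typed, table, report = run_celltype_stage(adata, params, seed=base_seed + i)
        typed_list.append(typed)
        name = str(adata.obs["dataset"].iloc[0])
        identity_tables[name] = table
        celltype_reports[name] = report
    de_tables = run_derivation_de(typed_list, params)
    records = run_integration(de_tables, params)
    all_sets, eligible = run_geneset_building(records, params)
    ranks = run_evaluation_ranks(params, seed=base_seed)
    winners, score_tables = run_optimization(eligible, ranks, params)
    final = [w for w in winners.values() if w is not None]
    partition = overlap_partition(final) if final else None
    manifest = {
        "config_hash": params.config_hash(),
        "seed": base_seed,
        "stages": [
            "simulate", "celltype", "de", "integrate", "buildsets",
            "evalranks", "optimize",
        ],
        "selected_levels": {t: (w.level if w else None) for t, w in winners.items()},
    }
    return PipelineResult(
        params=params,
        collection=collection,
        typed=typed_list,
        identity_tables=identity_tables,
        celltype_reports=celltype_reports,
        de_tables=de_tables,
        records=records,
        genesets_all=all_sets,
        genesets_eligible=eligible,
        ranked_lists=ranks,
        winners=winners,
        score_tables=score_tables,
        partition=partition,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# file-based commands (CLI backends)
# ---------------------------------------------------------------------------


def _workdir(out) -> Path:
    p = Path(out)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(path: Path, hint: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing upstream artifact {path} — run `{hint}` first")
    return path


def _write_manifest(out: Path, stage: str, params: PipelineParams) -> None:
    manifest = {
        "stage": stage,
        "config_hash": params.config_hash(),
        "seed": params.sim.seed,
    }
    (out / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=1))


def cmd_simulate(params: PipelineParams, out) -> Path:
    outdir = _workdir(out)
    collection = generate_collection(params.sim)
    collection.write(outdir / "datasets")
    _write_manifest(outdir, "simulate", params)
    return outdir


def cmd_celltype(params: PipelineParams, out) -> Path:
    outdir = _workdir(out)
    ds_dir = _require(outdir / "datasets", "isletid simulate")
    id_dir = outdir / "identities"
    id_dir.mkdir(exist_ok=True)
    reports = {}
    for i in range(params.sim.n_datasets):
        adata = _io.read_dataset_mtx(ds_dir / f"ds{i}")
        _, table, report = run_celltype_stage(adata, params, seed=params.sim.seed + i)
        _io.write_identity_table(table, id_dir / f"ds{i}.tsv")
        reports[f"ds{i}"] = report
    (outdir / "qc_report.json").write_text(json.dumps(reports, indent=1, default=str))
    _write_manifest(outdir, "celltype", params)
    return outdir


def _typed_from_files(params: PipelineParams, outdir: Path) -> list[ad.AnnData]:
    ds_dir = _require(outdir / "datasets", "isletid simulate")
    id_dir = _require(outdir / "identities", "isletid celltype")
    typed = []
    for i in range(params.sim.n_datasets):
        adata = _io.read_dataset_mtx(ds_dir / f"ds{i}")
        ids = _io.read_identity_table(id_dir / f"ds{i}.tsv").set_index("cell_id")
        keep = ids[~ids["doublet_flag"]].index
        sub = adata[adata.obs_names.isin(keep)].copy()
        sub = normalize_log(sub)
        sub.obs["cell_type"] = ids.loc[sub.obs_names, "final_type"].to_numpy()
        typed.append(sub)
    return typed


def cmd_de(params: PipelineParams, out) -> Path:
    outdir = _workdir(out)
    typed = _typed_from_files(params, outdir)
    tables = run_derivation_de(typed, params)
    cat = pd.concat(
        [t for tabs in tables.values() for t in tabs if len(t)], ignore_index=True
    )
    cat.to_csv(outdir / "de_tables.tsv", sep="\t", index=False)
    _write_manifest(outdir, "de", params)
    return outdir


def cmd_integrate(params: PipelineParams, out) -> Path:
    outdir = _workdir(out)
    cat = pd.read_csv(_require(outdir / "de_tables.tsv", "isletid de"), sep="\t")
    for t in params.sim.cell_types:
        sub = cat[cat["type_a"] == t]
        if not len(sub):
            continue
        groups = [g for _, g in sub.groupby(["dataset", "type_b"], sort=True)]
        rec = integrate_de(groups, t)
        rec.to_csv(outdir / f"records_{t}.tsv", sep="\t", index=False)
    _write_manifest(outdir, "integrate", params)
    return outdir


def cmd_buildsets(params: PipelineParams, out) -> Path:
    outdir = _workdir(out)
    all_sets: list[GeneSet] = []
    eligible: list[GeneSet] = []
    max_level = params.sim.n_datasets * (len(params.sim.cell_types) - 1)
    for t in params.sim.cell_types:
        path = outdir / f"records_{t}.tsv"
        if not path.exists():
            continue
        rec = pd.read_csv(path, sep="\t")
        sets = build_intersect_genesets(rec, t, max_level=max_level)
        all_sets.extend(sets)
        eligible.extend(size_filter(sets, params.min_geneset_size, params.max_geneset_size))
    if not all_sets:
        raise FileNotFoundError(
            f"no records_<type>.tsv files in {outdir} — run `isletid integrate` first"
        )
    write_gmt(all_sets, outdir / "genesets_all.gmt")
    write_gmt(eligible, outdir / "genesets_eligible.gmt")
    _write_manifest(outdir, "buildsets", params)
    return outdir


def cmd_gsea(rnk_path, gmt_path, out_path, gsea_params: GseaParams = GseaParams()) -> pd.DataFrame:
    """Score the genesets of a GMT file against one RNK ranking; write a TSV."""
    ranked = RankedList.from_rnk(rnk_path)
    genesets = read_gmt(gmt_path)
    results = run_gsea(ranked, genesets, gsea_params)
    frame = results_frame(results)
    frame.to_csv(out_path, sep="\t", index=False)
    return frame


def cmd_optimize(params: PipelineParams, out) -> Path:
    outdir = _workdir(out)
    eligible_sets = read_gmt(_require(outdir / "genesets_eligible.gmt", "isletid buildsets"))
    eligible: dict[str, list[GeneSet]] = {}
    for gs in eligible_sets:
        eligible.setdefault(gs.cell_type, []).append(gs)
    ranks = run_evaluation_ranks(params, seed=params.sim.seed)
    winners, tables = run_optimization(eligible, ranks, params)
    final = [w for w in winners.values() if w is not None]
    if final:
        write_gmt(final, outdir / "genesets_final.gmt")
        part = overlap_partition(final)
        rows = [
            {"signature": "+".join(sorted(sig)), "n_genes": len(genes)}
            for sig, genes in sorted(
                part.signatures.items(), key=lambda kv: "+".join(sorted(kv[0]))
            )
        ]
        pd.DataFrame(rows).to_csv(outdir / "partition.tsv", sep="\t", index=False)
    score = pd.concat([t for t in tables.values() if len(t)], ignore_index=True)
    score.to_csv(outdir / "selection.tsv", sep="\t", index=False)
    _write_manifest(outdir, "optimize", params)
    return outdir


def cmd_benchmark(
    params: PipelineParams, out, against_gmt, against_name: str = "published"
) -> Path:
    outdir = _workdir(out)
    ours = read_gmt(_require(outdir / "genesets_final.gmt", "isletid optimize"))
    other = read_gmt(Path(against_gmt))
    ranks = run_evaluation_ranks(params, seed=params.sim.seed)
    report = benchmark_genesets(
        {"ours": ours, against_name: other}, ranks, "ours", params.gsea
    )
    report.scores.to_csv(outdir / "benchmark_scores.tsv", sep="\t", index=False)
    report.tests.to_csv(outdir / "benchmark_tests.tsv", sep="\t", index=False)
    _write_manifest(outdir, "benchmark", params)
    return outdir
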