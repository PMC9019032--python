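"""Intersect-level geneset construction, size filtering, overlap partitioning,
ortholog mapping, and GMT exchange.

A geneset at intersect level *k* contains every gene found differentially
expressed in at least *k* of the integrated pairwise analyses — so the
levels are nested (``set(k+1) is a subset of set(k)``) and sizes are
monotone non-increasing in *k*. With 7 datasets and 3 opposing types the
design yields 21 levels per cell type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GeneSet",
    "OverlapPartition",
    "build_intersect_genesets",
    "size_filter",
    "overlap_partition",
    "map_orthologs",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class GeneSet:
    """A named, sorted, duplicate-free gene list at one intersect level."""

    name: str
    cell_type: str
    level: int
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("intersect level must be >= 0")
        ordered = tuple(sorted(set(self.genes)))
        if ordered != self.genes:
            object.__setattr__(self, "genes", ordered)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


def build_intersect_genesets(
    records: pd.DataFrame, cell_type: str, max_level: int = 21
) -> list[GeneSet]:
    """One geneset per intersect level k=1..max_level: genes with n_analyses >= k."""
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    if "n_analyses" not in records:
        raise ValueError("records must carry an 'n_analyses' column")
    n = records.set_index("gene")["n_analyses"]
    out = []
    for k in range(1, max_level + 1):
        genes = tuple(sorted(n.index[n >= k]))
        out.append(GeneSet(name=f"{cell_type}_L{k:02d}", cell_type=cell_type, level=k, genes=genes))
    return out


def size_filter(
    genesets: Iterable[GeneSet], min_size: int = 40, max_size: int = 500
) -> list[GeneSet]:
    """Keep genesets with min_size <= |genes| <= max_size (bounds inclusive)."""
    return [gs for gs in genesets if min_size <= len(gs) <= max_size]


@dataclass
class OverlapPartition:
    """Membership-signature partition of one geneset per cell type.

    ``signatures`` maps each observed membership signature (a frozenset of
    cell types) to its gene list; exclusive and pairwise counts are derived
    views. Conservation holds exactly: summing signature-class sizes over
    the signatures containing a type reproduces that type's geneset size.
    """

    cell_types: tuple[str, ...]
    signatures: dict[frozenset, tuple[str, ...]] = field(default_factory=dict)

    @property
    def exclusive_counts(self) -> dict[str, int]:
        return {
            t: len(self.signatures.get(frozenset([t]), ())) for t in self.cell_types
        }

    @property
    def pairwise_counts(self) -> dict[frozenset, int]:
        """Genes shared by *exactly* one unordered pair of types."""
        out = {}
        for i, a in enumerate(self.cell_types):
            for b in self.cell_types[i + 1 :]:
                key = frozenset([a, b])
                out[key] = len(self.signatures.get(key, ()))
        return out

    def total_for(self, cell_type: str) -> int:
        return sum(
            len(genes) for sig, genes in self.signatures.items() if cell_type in sig
        )


def overlap_partition(collection: Sequence[GeneSet]) -> OverlapPartition:
    """Partition the genes of one geneset per cell type by full membership signature."""
    types = [gs.cell_type for gs in collection]
    if len(set(types)) != len(types):
        raise ValueError("duplicate cell type in collection")
    membership: dict[str, set[str]] = {}
    for gs in collection:
        for g in gs.genes:
            membership.setdefault(g, set()).add(gs.cell_type)
    sigs: dict[frozenset, list[str]] = {}
    for g, who in membership.items():
        sigs.setdefault(frozenset(who), []).append(g)
    return OverlapPartition(
        cell_types=tuple(types),
        signatures={sig: tuple(sorted(genes)) for sig, genes in sigs.items()},
    )


def map_orthologs(geneset: GeneSet, ortholog_table: pd.DataFrame) -> GeneSet:
    """Convert a geneset through a (source_gene, target_gene) ortholog table.

    One-to-many rows expand (e.g. INS -> Ins1 + Ins2); genes without any
    table row are dropped; the output is de-duplicated and sorted.
    """
    cols = set(ortholog_table.columns)
    if not {"source_gene", "target_gene"} <= cols:
        raise ValueError(
            "ortholog table must have 'source_gene' and 'target_gene' columns"
        )
    lookup: dict[str, list[str]] = {}
    for src, tgt in zip(ortholog_table["source_gene"], ortholog_table["target_gene"]):
        if not isinstance(src, str) or not isinstance(tgt, str) or not src or not tgt:
            raise ValueError(f"malformed ortholog row: {src!r} -> {tgt!r}")
        lookup.setdefault(src, []).append(tgt)
    mapped: set[str] = set()
    for g in geneset.genes:
        mapped.update(lookup.get(g, ()))
    return GeneSet(
        name=f"{geneset.name}_ortholog",
        cell_type=geneset.cell_type,
        level=geneset.level,
        genes=tuple(sorted(mapped)),
    )


def write_gmt(collection: Sequence[GeneSet], path) -> None:
    """Write genesets in GMT dialect: name TAB description TAB gene TAB gene..."""
    with open(path, "w") as fh:
        for gs in collection:
            desc = f"cell_type={gs.cell_type};level={gs.level}"
            fh.write("\t".join([gs.name, desc, *gs.genes]) + "\n")


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file; the description field restores cell type and level if present."""
    out: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line {lineno} has fewer than 3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if len(set(genes)) != len(genes):
                warnings.warn(
                    f"{path}: duplicate genes within GMT line {lineno} collapsed",
                    stacklevel=2,
                )
            cell_type, level = name, 0
            for part in desc.split(";"):
                if part.startswith("cell_type="):
                    cell_type = part.split("=", 1)[1]
                elif part.startswith("level="):
                    try:
                        level = int(part.split("=", 1)[1])
                    except ValueError:
                        pass
            out.append(
                GeneSet(name=name, cell_type=cell_type, level=level, genes=tuple(sorted(set(genes))))
            )
    return out
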