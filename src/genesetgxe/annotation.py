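"""Variant-to-gene mapping by transcription boundaries and gene-sets.

Coordinates are 1-based with both transcription boundaries inclusive (the
NCBI convention): a variant belongs to a gene iff it lies on the same
chromosome and within ``[tss - flank, tes + flank]``.  Strand never
affects membership.  A variant may belong to several overlapping genes
(e.g. adjacent receptor/kinase loci); the distinct-variant total counts
each variant once while per-gene counts may overlap.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import GenotypeDataset

_AUTOSOMES = set(range(1, 23))


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    """Autosomal gene with orientation-normalized boundaries (tss < tes)."""

    name: str
    chromosome: int
    tss: int
    tes: int
    strand: str = "+"
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.chromosome not in _AUTOSOMES:
            raise ValueError(
                f"{self.name}: chromosome must be an autosome 1..22, got {self.chromosome}"
            )
        if self.tss > self.tes:
            low, high = self.tes, self.tss
            object.__setattr__(self, "tss", low)
            object.__setattr__(self, "tes", high)
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.name}: strand must be '+' or '-'")

    def matches(self, name: str) -> bool:
        name = name.casefold()
        return name == self.name.casefold() or any(
            name == a.casefold() for a in self.aliases
        )


def genes_from_table(table: pd.DataFrame) -> list[GeneRecord]:
    """Build gene records from an annotation table.

    Expects columns ``gene`` (or ``name``), ``chrom``, ``tss``, ``tes``,
    ``strand``; an optional comma-separated ``alias`` column is honoured.
    """
    name_col = "gene" if "gene" in table.columns else "name"
    records = []
    for row in table.itertuples():
        aliases: tuple[str, ...] = ()
        if "alias" in table.columns:
            raw = getattr(row, "alias")
            if isinstance(raw, str) and raw:
                aliases = tuple(a.strip() for a in raw.split(",") if a.strip())
        records.append(
            GeneRecord(
                name=str(getattr(row, name_col)),
                chromosome=int(row.chrom),
                tss=int(row.tss),
                tes=int(row.tes),
                strand=str(row.strand),
                aliases=aliases,
            )
        )
    return records


@dataclasses.dataclass
class GeneSet:
    """A named, ordered collection of genes with variant membership."""

    name: str
    genes: list[str]
    membership: dict[str, list[str]]

    def __post_init__(self) -> None:
        for gene, ids in self.membership.items():
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate variant within gene {gene!r}")

    def variants(self) -> list[str]:
        """Distinct variant ids across the set, in first-seen order."""
        seen: dict[str, None] = {}
        for gene in self.genes:
            for vid in self.membership.get(gene, []):
                seen.setdefault(vid, None)
        return list(seen)

    def genes_with_variants(self) -> list[str]:
        return [g for g in self.genes if self.membership.get(g)]

    def subset(self, genes: Sequence[str], name: str | None = None) -> "GeneSet":
        genes = list(genes)
        unknown = [g for g in genes if g not in self.membership]
        if unknown:
            raise KeyError(f"genes not in set: {unknown}")
        return GeneSet(
            name or self.name,
            genes,
            {g: list(self.membership[g]) for g in genes},
        )


def resolve_gene(genes: Iterable[GeneRecord], name: str) -> GeneRecord:
    """Exact case-insensitive lookup against gene names and aliases."""
    for gene in genes:
        if gene.matches(name):
            return gene
    raise KeyError(f"unknown gene: {name!r}")


def map_snps_to_genes(
    variants: pd.DataFrame,
    genes: Sequence[GeneRecord],
    flank_bp: int = 0,
    set_name: str = "gene-set",
) -> GeneSet:
    """Assign variants to genes by inclusive transcription boundaries.

    ``variants`` needs columns ``variant_id``, ``chrom``, ``pos``.
    Membership is invariant to variant input order (output is sorted by
    position within each gene).
    """
    chrom = variants["chrom"].to_numpy()
    try:
        chrom = chrom.astype(int)
    except (TypeError, ValueError) as err:
        bad = sorted({c for c in chrom if not str(c).isdigit()})
        raise ValueError(f"unknown chromosome labels: {bad}") from err
    unknown = sorted(set(chrom) - _AUTOSOMES)
    if unknown:
        raise ValueError(f"unknown chromosome labels: {unknown}")
    pos = variants["pos"].to_numpy().astype(int)
    ids = variants["variant_id"].to_numpy()

    membership: dict[str, list[str]] = {}
    for gene in genes:
        mask = (
            (chrom == gene.chromosome)
            & (pos >= gene.tss - flank_bp)
            & (pos <= gene.tes + flank_bp)
        )
        hit_order = np.lexsort((ids[mask], pos[mask]))  # position, then id
        membership[gene.name] = list(ids[mask][hit_order])
    return GeneSet(set_name, [g.name for g in genes], membership)


def add_manual_variant(
    dataset: GenotypeDataset,
    geneset: GeneSet,
    gene: str,
    variant_id: str,
    values,
    chrom: int | None = None,
    pos: int | None = None,
) -> tuple[GenotypeDataset, GeneSet]:
    """Append a manually genotyped variant to the data and a gene's membership.

    Models polymorphisms absent from the array (e.g. a VNTR coded
    additively): values must be in {0, 1, 2} or missing.  Returns the
    extended dataset and gene-set; the inputs are not mutated.
    """
    if gene not in geneset.membership:
        raise KeyError(f"gene not in set: {gene!r}")
    if variant_id in set(dataset.variants["variant_id"]):
        raise ValueError(f"variant id already present: {variant_id!r}")
    new_dataset = dataset.add_variant(
        variant_id,
        values,
        chrom=chrom if chrom is not None else 0,
        pos=pos if pos is not None else 0,
        a1="M",
        a2="m",
    )
    membership = {g: list(v) for g, v in geneset.membership.items()}
    membership[gene] = membership[gene] + [variant_id]
    return new_dataset, GeneSet(geneset.name, list(geneset.genes), membership)


def remove_manual_variant(
    dataset: GenotypeDataset, geneset: GeneSet, gene: str, variant_id: str
) -> tuple[GenotypeDataset, GeneSet]:
    """Inverse of :func:`add_manual_variant`."""
    membership = {g: list(v) for g, v in geneset.membership.items()}
    if variant_id not in membership.get(gene, []):
        raise KeyError(f"variant {variant_id!r} not in gene {gene!r}")
    membership[gene] = [v for v in membership[gene] if v != variant_id]
    return (
        dataset.drop_variant(variant_id),
        GeneSet(geneset.name, list(geneset.genes), membership),
    )


def geneset_summary(geneset: GeneSet) -> tuple[int, int]:
    """(number of genes with >= 1 variant, distinct variants in the set)."""
    return len(geneset.genes_with_variants()), len(geneset.variants())
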