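"""Interval mapping statistics: unions, coverage ratios and hit counts.

Given a genome model, a set of miRNA gene loci and a set of de novo CNVs,
this module computes per (chromosome, CNV type):

* ``L1`` — summed length of the miRNA genes on the chromosome, and
  ``R1 = L1 / G`` where ``G`` is the chromosome length;
* ``L2`` — length of the union of the CNV intervals (overlapping CNV
  regions counted once), and ``R2 = L2 / G``;
* ``hits`` — the total number of CNV-gene overlap incidences, where a gene
  overlapped by two distinct CNVs contributes two hits;
* ``unique`` — the number of distinct genes overlapped at least once.

All intervals are closed (1-based inclusive); two intervals overlap iff
they share at least one base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from mircnv.io import CNV_TYPES, ChromosomeModel, CnvRecord, MirnaGene

OVERLAP_MODES = ("any", "containment")


def gene_length(gene: MirnaGene) -> int:
    """Length in bp of a gene locus: ``end - start + 1``."""
    return gene.end - gene.start + 1


def union_length(cnvs: Sequence[CnvRecord]) -> int:
    """Total number of bases covered by at least one CNV (sort-and-sweep merge).

    All records must share one chromosome and one CNV type; overlapping
    regions are counted once.
    """
    if not cnvs:
        return 0
    chroms = {c.chrom for c in cnvs}
    types = {c.cnv_type for c in cnvs}
    if len(chroms) > 1 or len(types) > 1:
        raise ValueError(
            f"union_length expects one chromosome and one CNV type, got {sorted(chroms)} / {sorted(types)}"
        )
    total = 0
    cur_start = cur_end = None
    for start, end in sorted((c.start, c.end) for c in cnvs):
        if cur_end is None:
            cur_start, cur_end = start, end
        elif start <= cur_end + 1:  # adjacent closed intervals merge without a gap
            cur_end = max(cur_end, end)
        else:
            total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
    total += cur_end - cur_start + 1
    return total


def overlaps(cnv: CnvRecord, gene: MirnaGene, mode: str = "any") -> bool:
    """Whether a CNV and a gene intersect (``any``) or the CNV contains the gene.

    Closed-interval test, strand-agnostic; adjacency is not overlap.
    """
    if cnv.chrom != gene.chrom:
        raise ValueError(f"CNV on {cnv.chrom!r} vs gene on {gene.chrom!r}: different chromosomes")
    if mode == "any":
        return cnv.start <= gene.end and cnv.end >= gene.start
    if mode == "containment":
        return cnv.start <= gene.start and cnv.end >= gene.end
    raise ValueError(f"unknown overlap mode {mode!r}")


def count_hits(
    cnvs: Sequence[CnvRecord], genes: Sequence[MirnaGene], mode: str = "any"
) -> tuple[int, int]:
    """Count overlap incidences between CNVs and genes.

    Returns ``(hits, unique)``: hits sums, over CNVs, the number of genes
    each overlaps (a gene under two CNVs counts twice); unique is the number
    of distinct genes overlapped.  Empty inputs give ``(0, 0)``.
    """
    hits = 0
    seen: set[str] = set()
    for cnv in cnvs:
        for gene in genes:
            if overlaps(cnv, gene, mode):
                hits += 1
                seen.add(gene.gene_id)
    return hits, len(seen)


@dataclass(frozen=True)
class ChromTypeSummary:
    """Mapping statistics for one (chromosome, CNV type) cell.

    When the dataset has no CNVs of the given type on the chromosome, the
    CNV-dependent fields (``L2``, ``R2``, ``hits``, ``unique``) are ``None``
    and the row is reported as N/A.
    """

    chrom: str
    cnv_type: str
    chrom_length: int
    n_genes: int
    n_cnvs: int
    L1: int
    R1: float
    L2: int | None
    R2: float | None
    hits: int | None
    unique: int | None

    @property
    def has_data(self) -> bool:
        return self.n_cnvs > 0


def summarize(
    genome: Sequence[ChromosomeModel],
    genes: Sequence[MirnaGene],
    cnvs: Sequence[CnvRecord],
    overlap_mode: str = "any",
) -> list[ChromTypeSummary]:
    """Per-(chromosome, type) mapping statistics over the whole genome model.

    Emits one row per chromosome and CNV type, in genome order with Gain
    before Loss; chromosomes lacking CNVs of a type get an N/A row.  Genes
    or CNVs on chromosomes absent from the genome model are an error.
    """
    if overlap_mode not in OVERLAP_MODES:
        raise ValueError(f"unknown overlap mode {overlap_mode!r}")
    known = {c.name for c in genome}
    bad_genes = sorted({g.chrom for g in genes if g.chrom not in known})
    if bad_genes:
        raise ValueError(f"miRNA genes on chromosomes absent from genome model: {bad_genes}")
    bad_cnvs = sorted({c.chrom for c in cnvs if c.chrom not in known})
    if bad_cnvs:
        raise ValueError(f"CNVs on chromosomes absent from genome model: {bad_cnvs}")

    genes_by_chrom: dict[str, list[MirnaGene]] = {c.name: [] for c in genome}
    for g in genes:
        genes_by_chrom[g.chrom].append(g)
    cnvs_by_cell: dict[tuple[str, str], list[CnvRecord]] = {}
    for c in cnvs:
        cnvs_by_cell.setdefault((c.chrom, c.cnv_type), []).append(c)

    out: list[ChromTypeSummary] = []
    for chrom in genome:
        chrom_genes = genes_by_chrom[chrom.name]
        L1 = sum(gene_length(g) for g in chrom_genes)
        R1 = L1 / chrom.length
        for cnv_type in CNV_TYPES:
            cell = cnvs_by_cell.get((chrom.name, cnv_type), [])
            if cell:
                L2 = union_length(cell)
                hits, unique = count_hits(cell, chrom_genes, overlap_mode)
                out.append(
                    ChromTypeSummary(
                        chrom=chrom.name,
                        cnv_type=cnv_type,
                        chrom_length=chrom.length,
                        n_genes=len(chrom_genes),
                        n_cnvs=len(cell),
                        L1=L1,
                        R1=R1,
                        L2=L2,
                        R2=L2 / chrom.length,
                        hits=hits,
                        unique=unique,
                    )
                )
            else:
                out.append(
                    ChromTypeSummary(
                        chrom=chrom.name,
                        cnv_type=cnv_type,
                        chrom_length=chrom.length,
                        n_genes=len(chrom_genes),
                        n_cnvs=0,
                        L1=L1,
                        R1=R1,
                        L2=None,
                        R2=None,
                        hits=None,
                        unique=None,
                    )
                )
    return out


def summaries_to_frame(summaries: Sequence[ChromTypeSummary]) -> pd.DataFrame:
    """Tabulate summaries (one row per chromosome/type; N/A cells become NaN)."""
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in summaries],
            "type": [s.cnv_type for s in summaries],
            "n_cnvs": [s.n_cnvs for s in summaries],
            "L1": [s.L1 for s in summaries],
            "L2": [s.L2 for s in summaries],
            "R1": [s.R1 for s in summaries],
            "R2": [s.R2 for s in summaries],
            "hits": [s.hits for s in summaries],
            "unique": [s.unique for s in summaries],
        }
    )
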