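"""Bundled reference tables from a published autism de novo CNV study.

Three small TSVs ship with the package (GRCh37 coordinates throughout):

* ``apl_chromosome_summary.tsv`` — per-chromosome mapping statistics for
  178 deduplicated de novo CNVs from 192 autism patients: chromosome
  length, miRNA gene count, the R1 gene-coverage ratio and, per CNV type,
  the R2 CNV-coverage ratio and the hit count;
* ``apl_enrichment_results.tsv`` — the published FDR-adjusted p-values of
  the randomization test on the same dataset;
* ``apl_candidate_mirna_genes.tsv`` — the 24 candidate miRNA genes from
  the enriched chromosomes, with their loci and a flag recording whether
  each also overlaps population CNVs from the Database of Genomic
  Variants.

These are inputs for the correlation analysis, for coordinate-convention
checks and for worked examples; the raw patient-level CNV coordinates are
not redistributable here, so full re-mapping from scratch needs the study's
supplementary CNV table and a matching miRBase snapshot supplied by the
user.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from mircnv.io import GAIN, LOSS, MirnaGene
from mircnv.overlap import ChromTypeSummary


def _read(name: str) -> pd.DataFrame:
    path = resources.files("mircnv.data").joinpath(name)
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#", dtype={"chrom": str}, na_values=["NA"])


def load_chromosome_summary() -> pd.DataFrame:
    """Per-chromosome mapping summary of the autism de novo CNV dataset."""
    return _read("apl_chromosome_summary.tsv")


def load_enrichment_results() -> pd.DataFrame:
    """Published FDR-adjusted p-values of the randomization test."""
    return _read("apl_enrichment_results.tsv")


def load_candidate_genes() -> pd.DataFrame:
    """The 24 candidate miRNA genes with GRCh37 loci and DGV status."""
    return _read("apl_candidate_mirna_genes.tsv")


def candidate_gene_records() -> list[MirnaGene]:
    """Candidate gene loci as :class:`MirnaGene` records."""
    df = load_candidate_genes()
    return [
        MirnaGene(
            gene_id=row.gene_id,
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
        )
        for row in df.itertuples(index=False)
    ]


def chromosome_summaries() -> list[ChromTypeSummary]:
    """The bundled per-chromosome summary as :class:`ChromTypeSummary` rows.

    Gene-level lengths (L1, L2) are reconstructed from the published
    ratios; N/A cells become rows with ``n_cnvs = 0``.  The actual CNV
    counts per cell are not part of the published summary, so ``n_cnvs``
    is recorded as 1 for cells with data (enough to mark them non-N/A).
    """
    df = load_chromosome_summary()
    out: list[ChromTypeSummary] = []
    for row in df.itertuples(index=False):
        G = int(row.length_bp)
        L1 = int(round(row.ratio1 * G))
        for cnv_type, r2_col, hits_col in (
            (GAIN, "gain_ratio2", "gain_hits"),
            (LOSS, "loss_ratio2", "loss_hits"),
        ):
            r2 = getattr(row, r2_col)
            hits = getattr(row, hits_col)
            has = pd.notna(r2)
            out.append(
                ChromTypeSummary(
                    chrom=str(row.chrom),
                    cnv_type=cnv_type,
                    chrom_length=G,
                    n_genes=int(row.n_mirna_genes),
                    n_cnvs=1 if has else 0,
                    L1=L1,
                    R1=float(row.ratio1),
                    L2=int(round(r2 * G)) if has else None,
                    R2=float(r2) if has else None,
                    hits=int(hits) if has else None,
                    unique=None if not has else int(hits),
                )
            )
    return out
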