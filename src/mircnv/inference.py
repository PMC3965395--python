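"""Significance calls, correlation analysis and the population-CNV filter.

The per-(chromosome, type) empirical p-values are corrected with the
Benjamini–Hochberg step-up procedure; the FDR family is, by default, each
CNV type separately (Gain rows adjusted together, Loss rows adjusted
together, N/A rows excluded), with a joint family available.  Chromosomes
whose adjusted p-value falls below alpha (strict inequality, default 0.05)
are called enriched; the distinct miRNA genes overlapped by observed CNVs
on those chromosome/type cells form the candidate list, which is then
split into population-shared and study-specific genes by intersection with
a population CNV set (DGV-style).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from mircnv.io import CnvRecord, MirnaGene
from mircnv.overlap import ChromTypeSummary, overlaps

FDR_FAMILIES = ("per-type", "joint")


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment call for one (chromosome, CNV type) cell."""

    chrom: str
    cnv_type: str
    observed_hits: int
    unique: int
    p_raw: float
    p_fdr: float
    significant: bool


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation and least-squares fit of hits on the R2 coverage ratio."""

    cnv_type: str
    n_points: int
    r: float
    slope: float
    intercept: float


@dataclass(frozen=True)
class CandidateMirna:
    """A miRNA gene drawn from a significantly enriched chromosome/type cell."""

    gene: MirnaGene
    chrom: str
    cnv_types: tuple[str, ...]
    n_patients: int
    in_population: bool | None = None


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min_{j >= i} (p_(j) * m / j) over the ascending order
    statistics, capped at 1.
    """
    p = list(p_values)
    for v in p:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"p-value {v} outside [0, 1]")
    if not p:
        return []
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in adjusted]


def select_significant(
    results: Sequence[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Rows with adjusted p-value strictly below alpha."""
    return [r for r in results if r.p_fdr < alpha]


def adjust_results(
    raw: Sequence[tuple[ChromTypeSummary, float]],
    alpha: float = 0.05,
    fdr_family: str = "per-type",
) -> list[EnrichmentResult]:
    """Attach BH-adjusted p-values and significance flags to raw p-values.

    ``raw`` pairs each non-N/A summary with its empirical p-value; the
    BH family is either each CNV type separately or all rows jointly.
    """
    if fdr_family not in FDR_FAMILIES:
        raise ValueError(f"unknown FDR family {fdr_family!r}")
    adjusted = [0.0] * len(raw)
    if fdr_family == "joint":
        groups = [list(range(len(raw)))]
    else:
        types = sorted({s.cnv_type for s, _ in raw})
        groups = [[i for i, (s, _) in enumerate(raw) if s.cnv_type == t] for t in types]
    for idx in groups:
        adj = bh_adjust([raw[i][1] for i in idx])
        for i, v in zip(idx, adj):
            adjusted[i] = v
    out = []
    for (summary, p), p_fdr in zip(raw, adjusted):
        out.append(
            EnrichmentResult(
                chrom=summary.chrom,
                cnv_type=summary.cnv_type,
                observed_hits=summary.hits,
                unique=summary.unique,
                p_raw=p,
                p_fdr=p_fdr,
                significant=p_fdr < alpha,
            )
        )
    return out


def correlate(summaries: Sequence[ChromTypeSummary], cnv_type: str) -> CorrelationResult:
    """Pearson correlation between CNV coverage (R2) and hit counts across chromosomes.

    N/A rows (no CNVs of the type) are excluded; at least three data points
    and non-degenerate variance in both variables are required.
    """
    pts = [(s.R2, s.hits) for s in summaries if s.cnv_type == cnv_type and s.has_data]
    if len(pts) < 3:
        raise ValueError(
            f"correlation for {cnv_type} needs >= 3 chromosomes with data, got {len(pts)}"
        )
    x = [p[0] for p in pts]
    y = [p[1] for p in pts]
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValueError(f"correlation for {cnv_type} undefined: zero variance")
    fit = stats.linregress(x, y)
    return CorrelationResult(
        cnv_type=cnv_type,
        n_points=len(pts),
        r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def candidate_genes(
    genes: Sequence[MirnaGene],
    cnvs: Sequence[CnvRecord],
    significant: Sequence[EnrichmentResult],
    overlap_mode: str = "any",
) -> list[CandidateMirna]:
    """Distinct miRNA genes overlapped by observed CNVs in significant cells.

    For each gene the contributing CNV types are pooled across significant
    cells and ``n_patients`` counts the distinct patients carrying an
    overlapping CNV.
    """
    sig_cells = {(r.chrom, r.cnv_type) for r in significant}
    per_gene: dict[str, dict] = {}
    for gene in genes:
        for cnv in cnvs:
            if cnv.chrom != gene.chrom or (cnv.chrom, cnv.cnv_type) not in sig_cells:
                continue
            if overlaps(cnv, gene, overlap_mode):
                entry = per_gene.setdefault(
                    gene.gene_id, {"gene": gene, "types": set(), "patients": set()}
                )
                entry["types"].add(cnv.cnv_type)
                entry["patients"].update(cnv.patient_ids)
    out = []
    for gene in genes:  # preserve annotation order
        entry = per_gene.get(gene.gene_id)
        if entry is None:
            continue
        out.append(
            CandidateMirna(
                gene=entry["gene"],
                chrom=entry["gene"].chrom,
                cnv_types=tuple(sorted(entry["types"])),
                n_patients=len(entry["patients"]),
            )
        )
    return out


def population_filter(
    candidates: Sequence[CandidateMirna],
    population_cnvs: Sequence[CnvRecord],
    overlap_mode: str = "any",
) -> list[CandidateMirna]:
    """Flag candidates seen in population CNVs; the rest are study-specific.

    Gains and Losses from the population set are pooled: a candidate is
    ``in_population`` iff its locus overlaps at least one population CNV
    under the same overlap predicate used for mapping.
    """
    out = []
    for cand in candidates:
        found = any(
            cnv.chrom == cand.gene.chrom and overlaps(cnv, cand.gene, overlap_mode)
            for cnv in population_cnvs
        )
        out.append(
            CandidateMirna(
                gene=cand.gene,
                chrom=cand.chrom,
                cnv_types=cand.cnv_types,
                n_patients=cand.n_patients,
                in_population=found,
            )
        )
    return out
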