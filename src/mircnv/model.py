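"""Model/Results interface tying mapping, randomization and inference together.

``CnvMirnaEnrichment`` holds a genome model, a miRNA annotation and a de
novo CNV set; ``fit()`` runs the per-(chromosome, type) null — Monte Carlo
by default, exact convolution on request — corrects the empirical
p-values for multiple testing and returns a results object carrying the
mapping summaries, the enrichment calls and the downstream analyses
(correlation of hits on CNV coverage, candidate genes, population filter).

Example
-------
>>> from mircnv import CnvMirnaEnrichment, FixtureSpec, make_dataset
>>> genome, genes, cnvs = make_dataset(FixtureSpec({"1": 10_000_000}, seed=7))
>>> res = CnvMirnaEnrichment(genome, genes, cnvs).fit(n_realizations=10_000, seed=1)
>>> frame = res.frame()  # one row per chromosome/type with p_raw, p_fdr
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mircnv.io import (
    ChromosomeModel,
    CnvRecord,
    MirnaGene,
    read_chrom_sizes,
    read_cnv_table,
    read_mirna_annotation,
)
from mircnv.exact import exact_null
from mircnv.inference import (
    CandidateMirna,
    CorrelationResult,
    EnrichmentResult,
    adjust_results,
    candidate_genes,
    correlate,
    population_filter,
    select_significant,
)
from mircnv.overlap import ChromTypeSummary, summaries_to_frame, summarize
from mircnv.randomization import (
    DEFAULT_REALIZATIONS,
    NullDistribution,
    SimulationConfig,
    empirical_pvalue,
    simulate_null,
)


class CnvMirnaEnrichment:
    """Enrichment model for miRNA genes inside de novo CNVs.

    Parameters
    ----------
    genome : chromosome name/length models
    genes : miRNA gene loci (1-based inclusive)
    cnvs : deduplicated de novo CNV records
    overlap_mode : ``any`` (>= 1 shared base, default) or ``containment``
        (gene wholly inside the CNV)
    """

    def __init__(
        self,
        genome: Sequence[ChromosomeModel],
        genes: Sequence[MirnaGene],
        cnvs: Sequence[CnvRecord],
        overlap_mode: str = "any",
    ):
        self.genome = list(genome)
        self.genes = list(genes)
        self.cnvs = list(cnvs)
        self.overlap_mode = overlap_mode
        self._summaries: list[ChromTypeSummary] | None = None

    @classmethod
    def from_files(
        cls,
        genome_path: str | Path,
        mirna_path: str | Path,
        cnv_path: str | Path,
        overlap_mode: str = "any",
        keep_duplicates: bool = False,
        mirna_dialect: str = "auto",
    ) -> "CnvMirnaEnrichment":
        """Build the model from chrom.sizes, annotation and CNV table files."""
        genome = read_chrom_sizes(genome_path)
        genes = read_mirna_annotation(mirna_path, dialect=mirna_dialect, genome=genome)
        cnvs = read_cnv_table(cnv_path, genome=genome, keep_duplicates=keep_duplicates)
        return cls(genome, genes, cnvs, overlap_mode=overlap_mode)

    @property
    def summaries(self) -> list[ChromTypeSummary]:
        """Mapping statistics per (chromosome, CNV type), computed once."""
        if self._summaries is None:
            self._summaries = summarize(
                self.genome, self.genes, self.cnvs, overlap_mode=self.overlap_mode
            )
        return self._summaries

    def fit(
        self,
        n_realizations: int = DEFAULT_REALIZATIONS,
        seed: int | None = None,
        alpha: float = 0.05,
        fdr_family: str = "per-type",
        exact: bool = False,
    ) -> "CnvMirnaEnrichmentResults":
        """Estimate per-cell null distributions and enrichment p-values.

        Each non-N/A (chromosome, type) cell gets its own null: the
        observed CNV lengths re-placed uniformly over that chromosome,
        either sampled ``n_realizations`` times (child seeds derived
        deterministically from ``seed``) or computed exactly by
        convolution when ``exact`` is set.
        """
        genes_by_chrom: dict[str, list[MirnaGene]] = {c.name: [] for c in self.genome}
        for g in self.genes:
            genes_by_chrom[g.chrom].append(g)
        lengths = {c.name: c.length for c in self.genome}

        cells = [s for s in self.summaries if s.has_data]
        seed_seq = np.random.SeedSequence(seed)
        children = seed_seq.spawn(len(cells))
        nulls: dict[tuple[str, str], NullDistribution] = {}
        raw: list[tuple[ChromTypeSummary, float]] = []
        for summary, child in zip(cells, children):
            cell_cnvs = [
                c for c in self.cnvs if c.chrom == summary.chrom and c.cnv_type == summary.cnv_type
            ]
            cnv_lengths = [c.length for c in cell_cnvs]
            chrom_genes = genes_by_chrom[summary.chrom]
            G = lengths[summary.chrom]
            if exact:
                null = exact_null(
                    chrom_genes, cnv_lengths, G, mode=self.overlap_mode,
                    chrom=summary.chrom, cnv_type=summary.cnv_type,
                )
            else:
                # per-cell integer seed derived deterministically from the run seed
                cell_seed = int(child.generate_state(1, dtype=np.uint32)[0])
                config = SimulationConfig(
                    n_realizations=n_realizations,
                    seed=cell_seed,
                    overlap_mode=self.overlap_mode,
                )
                null = simulate_null(
                    chrom_genes, cnv_lengths, G, config,
                    chrom=summary.chrom, cnv_type=summary.cnv_type,
                )
            nulls[(summary.chrom, summary.cnv_type)] = null
            raw.append((summary, empirical_pvalue(null, summary.hits)))
        results = adjust_results(raw, alpha=alpha, fdr_family=fdr_family)
        return CnvMirnaEnrichmentResults(
            model=self,
            results=results,
            null_distributions=nulls,
            alpha=alpha,
            fdr_family=fdr_family,
            n_realizations=0 if exact else n_realizations,
            seed=seed,
            exact=exact,
        )


@dataclass
class CnvMirnaEnrichmentResults:
    """Fitted enrichment results: p-values, significance calls, diagnostics."""

    model: CnvMirnaEnrichment
    results: list[EnrichmentResult]
    null_distributions: dict[tuple[str, str], NullDistribution]
    alpha: float
    fdr_family: str
    n_realizations: int
    seed: int | None
    exact: bool

    @property
    def significant(self) -> list[EnrichmentResult]:
        return select_significant(self.results, self.alpha)

    def summaries_frame(self) -> pd.DataFrame:
        """Mapping statistics table (per chromosome/type, N/A rows as NaN)."""
        return summaries_to_frame(self.model.summaries)

    def frame(self) -> pd.DataFrame:
        """Enrichment table: chrom, type, unique, hits, p_raw, p_fdr, significant."""
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.results],
                "type": [r.cnv_type for r in self.results],
                "unique": [r.unique for r in self.results],
                "hits": [r.observed_hits for r in self.results],
                "p_raw": [r.p_raw for r in self.results],
                "p_fdr": [r.p_fdr for r in self.results],
                "significant": [r.significant for r in self.results],
            }
        )

    def correlation(self, cnv_type: str) -> CorrelationResult:
        """Pearson r and least-squares fit of hits on R2 for one CNV type."""
        return correlate(self.model.summaries, cnv_type)

    def candidates(
        self, population_cnvs: Sequence[CnvRecord] | None = None
    ) -> list[CandidateMirna]:
        """miRNA genes from significant cells, optionally DGV-filtered."""
        cands = candidate_genes(
            self.model.genes, self.model.cnvs, self.significant, self.model.overlap_mode
        )
        if population_cnvs is not None:
            cands = population_filter(cands, population_cnvs, self.model.overlap_mode)
        return cands

    def summary(self) -> str:
        """Human-readable report of the fit."""
        lines = [
            "miRNA-in-CNV enrichment (Monte Carlo randomization test)"
            if not self.exact
            else "miRNA-in-CNV enrichment (exact placement null)",
            "=" * 64,
            f"chromosomes: {len(self.model.genome)}   miRNA genes: {len(self.model.genes)}   "
            f"CNVs: {len(self.model.cnvs)}",
            f"overlap mode: {self.model.overlap_mode}   realizations per cell: "
            f"{'exact' if self.exact else self.n_realizations}   seed: {self.seed}",
            f"FDR family: {self.fdr_family}   alpha: {self.alpha}",
            "-" * 64,
            f"{'chrom':>6} {'type':>5} {'unique':>6} {'hits':>5} {'p_raw':>9} {'p_fdr':>9}  sig",
        ]
        for r in sorted(self.results, key=lambda r: (r.cnv_type, _chrom_key(r.chrom))):
            lines.append(
                f"{r.chrom:>6} {r.cnv_type:>5} {r.unique:>6} {r.observed_hits:>5} "
                f"{r.p_raw:>9.5f} {r.p_fdr:>9.5f}  {'*' if r.significant else ''}"
            )
        lines.append("-" * 64)
        sig = self.significant
        lines.append(
            f"{len(sig)} chromosome/type cell(s) enriched at FDR < {self.alpha}: "
            + (", ".join(f"{r.chrom}/{r.cnv_type}" for r in sig) if sig else "none")
        )
        return "\n".join(lines)


def _chrom_key(name: str):
    return (0, int(name)) if name.isdigit() else (1, name)
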