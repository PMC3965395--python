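"""Seeded synthetic datasets: genomes, miRNA annotations and CNV sets.

The generator emulates the scale of the real problem: miRNA gene loci of
roughly 80-110 bp scattered without mutual overlap along a chromosome, and
CNVs whose lengths are log-uniform between 1 kb and 1 Mb (de novo CNVs
span three orders of magnitude).  Under the null regime (``enrichment
q = 0``) CNVs are placed uniformly, which is exactly the randomization
null, so p-values computed on such data are calibrated by construction.
With ``q > 0`` a fraction q of the CNVs is forced to cover a randomly
chosen gene, planting the enrichment signal the test is meant to detect.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from mircnv.io import (
    CNV_TYPES,
    ChromosomeModel,
    CnvRecord,
    MirnaGene,
)

_MAX_PACKING_TRIES = 1000


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``enrichment`` is the fraction q of CNVs forced to cover a gene; it may
    be a scalar (all chromosomes) or a per-chromosome mapping, with
    chromosomes absent from the mapping left at q = 0.
    """

    chrom_lengths: Mapping[str, int]
    n_genes: int = 20
    gene_length_range: tuple[int, int] = (80, 110)
    n_cnvs: int = 10
    cnv_length_range: tuple[int, int] = (1_000, 1_000_000)
    enrichment: float | Mapping[str, float] = 0.0
    seed: int | None = None

    def q_for(self, chrom: str) -> float:
        if isinstance(self.enrichment, Mapping):
            return float(self.enrichment.get(chrom, 0.0))
        return float(self.enrichment)

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length < 1:
                raise ValueError(f"chromosome {chrom!r}: non-positive length")
            q = self.q_for(chrom)
            if not (0.0 <= q <= 1.0):
                raise ValueError(f"enrichment fraction {q} outside [0, 1]")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("gene_length_range lo > hi")
        if self.cnv_length_range[0] > self.cnv_length_range[1]:
            raise ValueError("cnv_length_range lo > hi")
        if self.gene_length_range[0] < 1 or self.cnv_length_range[0] < 1:
            raise ValueError("lengths must be positive")


def _place_genes(
    chrom: str, G: int, n: int, length_range: tuple[int, int], rng: np.random.Generator
) -> list[MirnaGene]:
    """Uniform non-overlapping gene placement by rejection sampling."""
    placed: list[tuple[int, int]] = []
    genes = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if length > G:
            raise ValueError(f"gene length {length} exceeds chromosome {chrom} length {G}")
        for _ in range(_MAX_PACKING_TRIES):
            start = int(rng.integers(1, G - length + 2))
            end = start + length - 1
            if all(end < s or start > e for s, e in placed):
                placed.append((start, end))
                genes.append(
                    MirnaGene(
                        gene_id=f"syn-mir-{chrom}-{i + 1}",
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand="+" if rng.integers(2) else "-",
                    )
                )
                break
        else:
            raise ValueError(
                f"cannot pack {n} non-overlapping genes on chromosome {chrom} (length {G})"
            )
    return genes


def _log_uniform_length(lo: int, hi: int, G: int, rng: np.random.Generator) -> int:
    hi = min(hi, G)
    lo = min(lo, hi)
    length = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
    return max(lo, min(length, hi))


def _forced_start(gene: MirnaGene, L: int, G: int, rng: np.random.Generator) -> int:
    """Start for a CNV of length L whose span covers the given gene.

    Uniform over the starts at which the CNV contains the whole gene,
    clamped to chromosome bounds; if the CNV is shorter than the gene the
    placement degrades to covering the gene's start.
    """
    lo = max(1, gene.end - L + 1)
    hi = min(gene.start, G - L + 1)
    if lo > hi:  # L < gene length, or clamping collapsed the window
        return max(1, min(gene.start, G - L + 1))
    return int(rng.integers(lo, hi + 1))


def make_dataset(
    spec: FixtureSpec,
) -> tuple[list[ChromosomeModel], list[MirnaGene], list[CnvRecord]]:
    """Generate a (genome, genes, cnvs) triple; deterministic for a fixed seed.

    Per chromosome: ``n_genes`` non-overlapping gene loci placed uniformly;
    for each CNV type, ``n_cnvs`` CNVs with log-uniform lengths, of which a
    fraction q cover a uniformly chosen gene and the rest are uniform.
    """
    rng = np.random.default_rng(spec.seed)
    genome = [ChromosomeModel(name=c, length=l) for c, l in spec.chrom_lengths.items()]
    genes: list[MirnaGene] = []
    cnvs: list[CnvRecord] = []
    for chrom in genome:
        chrom_genes = _place_genes(
            chrom.name, chrom.length, spec.n_genes, spec.gene_length_range, rng
        )
        genes.extend(chrom_genes)
        q = spec.q_for(chrom.name)
        for cnv_type in CNV_TYPES:
            n_forced = int(round(q * spec.n_cnvs))
            for j in range(spec.n_cnvs):
                L = _log_uniform_length(*spec.cnv_length_range, chrom.length, rng)
                if j < n_forced and chrom_genes:
                    target = chrom_genes[int(rng.integers(len(chrom_genes)))]
                    start = _forced_start(target, L, chrom.length, rng)
                else:
                    start = int(rng.integers(1, chrom.length - L + 2))
                cnvs.append(
                    CnvRecord(
                        chrom=chrom.name,
                        start=start,
                        end=start + L - 1,
                        cnv_type=cnv_type,
                        patient_ids=(f"pt{j + 1:03d}",),
                        source="case",
                    )
                )
    return genome, genes, cnvs


def write_dataset(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[list[ChromosomeModel], list[MirnaGene], list[CnvRecord]]:
    """Materialize a dataset as chrom.sizes + GFF3 + CNV TSV files.

    Writes ``genome.chrom.sizes``, ``mirna.gff3``, ``cnvs.tsv`` and the
    spec itself as ``fixture_spec.json``; byte-identical for a fixed seed.
    """
    from mircnv.io import write_cnv_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome, genes, cnvs = make_dataset(spec)
    with open(out_dir / "genome.chrom.sizes", "w") as fh:
        for chrom in genome:
            fh.write(f"{chrom.name}\t{chrom.length}\n")
    with open(out_dir / "mirna.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};Name={g.gene_id}"
            fh.write(
                f"{g.chrom}\t.\tmiRNA_primary_transcript\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
    write_cnv_table(cnvs, out_dir / "cnvs.tsv", params={"seed": spec.seed})
    spec_dict = asdict(spec)
    spec_dict["chrom_lengths"] = dict(spec.chrom_lengths)
    if isinstance(spec.enrichment, Mapping):
        spec_dict["enrichment"] = dict(spec.enrichment)
    with open(out_dir / "fixture_spec.json", "w") as fh:
        json.dump(spec_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return genome, genes, cnvs
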