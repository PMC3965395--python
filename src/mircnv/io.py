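"""Readers and writers for the genomic file formats used by the pipeline.

All coordinates are stored 1-based inclusive on both ends (the miRBase /
GFF3 convention, under which a locus spanning positions ``start..end`` has
length ``end - start + 1``).  BED input, which is 0-based half-open, is
converted at the boundary.  Chromosome labels are normalised by stripping a
leading ``chr`` prefix so that ``chr22`` and ``22`` refer to the same
chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd

log = logging.getLogger(__name__)

GAIN = "Gain"
LOSS = "Loss"
CNV_TYPES = (GAIN, LOSS)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr`` prefix from a chromosome label."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


def normalize_cnv_type(token: str) -> str:
    t = str(token).strip().lower()
    if t in ("gain", "duplication", "dup"):
        return GAIN
    if t in ("loss", "deletion", "del"):
        return LOSS
    raise FormatError(f"unrecognized CNV type token: {token!r} (expected Gain or Loss)")


@dataclass(frozen=True)
class ChromosomeModel:
    """A chromosome and its length G in base pairs."""

    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"chromosome {self.name!r}: length must be >= 1, got {self.length}")


@dataclass(frozen=True)
class MirnaGene:
    """One annotated miRNA gene locus (primary transcript / hairpin precursor)."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CnvRecord:
    """One copy-number variant call: a Gain (duplication) or Loss (deletion).

    ``patient_ids`` keeps the provenance of duplicate calls that were merged
    because they share (chrom, start, end, type).  ``source`` distinguishes
    case CNVs (de novo events in patients) from population CNVs used only
    for the candidate filter.
    """

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    cnv_type: str
    patient_ids: tuple[str, ...] = ()
    source: str = "case"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"CNV {self.chrom}:{self.start}-{self.end}: start > end")
        if self.start < 1:
            raise ValueError(f"CNV {self.chrom}:{self.start}-{self.end}: start must be >= 1")
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"CNV type must be one of {CNV_TYPES}, got {self.cnv_type!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_chrom_sizes(path: str | Path) -> list[ChromosomeModel]:
    """Read a two-column (name, length) chromosome-sizes table.

    Lines starting with ``#`` and blank lines are ignored; order is
    preserved and duplicate names are rejected.
    """
    models: list[ChromosomeModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected two columns, got {line!r}")
            name = normalize_chrom(fields[0])
            try:
                length = int(fields[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from None
            if length < 1:
                raise FormatError(f"{path}:{lineno}: non-positive length {length}")
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            models.append(ChromosomeModel(name=name, length=length))
    return models


def _validate_genes(
    genes: Sequence[MirnaGene], genome: Sequence[ChromosomeModel] | None
) -> list[MirnaGene]:
    ids: set[str] = set()
    for g in genes:
        if g.gene_id in ids:
            raise FormatError(f"duplicate miRNA gene id {g.gene_id!r}")
        ids.add(g.gene_id)
    if genome is not None:
        known = {c.name for c in genome}
        bad = sorted({g.gene_id for g in genes if g.chrom not in known})
        if bad:
            raise FormatError(
                "miRNA genes on chromosomes absent from the genome model: " + ", ".join(bad)
            )
    return list(genes)


def read_mirna_gff3(path: str | Path, genome: Sequence[ChromosomeModel] | None = None) -> list[MirnaGene]:
    """Read miRNA gene loci from a miRBase-style GFF3 file.

    Only ``miRNA_primary_transcript`` features are kept: these are the
    genomic hairpin loci; mature ``miRNA`` products nested inside them are
    ignored so that each gene is counted once.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("miRNA_primary_transcript", order_by="start"):
        name = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        genes.append(
            MirnaGene(
                gene_id=name,
                chrom=normalize_chrom(feat.seqid),
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else ".",
            )
        )
    return _validate_genes(genes, genome)


def read_mirna_bed(path: str | Path, genome: Sequence[ChromosomeModel] | None = None) -> list[MirnaGene]:
    """Read miRNA gene loci from a BED file (0-based half-open -> 1-based inclusive)."""
    genes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom = normalize_chrom(fields[0])
            try:
                bed_start, bed_end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer BED coordinates") from None
            if bed_start >= bed_end:
                raise FormatError(f"{path}:{lineno}: empty or inverted BED interval")
            name = fields[3] if len(fields) > 3 and fields[3] else f"feature_{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            genes.append(
                MirnaGene(gene_id=name, chrom=chrom, start=bed_start + 1, end=bed_end, strand=strand)
            )
    return _validate_genes(genes, genome)


def read_mirna_tsv(path: str | Path, genome: Sequence[ChromosomeModel] | None = None) -> list[MirnaGene]:
    """Read miRNA gene loci from a headered TSV with 1-based inclusive coordinates.

    Required columns: ``gene_id``, ``chrom``, ``start``, ``end``; optional ``strand``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    required = {"gene_id", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        try:
            genes.append(
                MirnaGene(
                    gene_id=str(row.gene_id),
                    chrom=normalize_chrom(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    strand=getattr(row, "strand", "."),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from None
    return _validate_genes(genes, genome)


def read_mirna_annotation(
    path: str | Path,
    dialect: str = "auto",
    genome: Sequence[ChromosomeModel] | None = None,
) -> list[MirnaGene]:
    """Read miRNA gene annotations, auto-detecting GFF3/BED/TSV by suffix."""
    path = Path(path)
    if dialect == "auto":
        suffix = path.suffix.lower()
        dialect = {"": "tsv", ".gff3": "gff3", ".gff": "gff3", ".bed": "bed", ".tsv": "tsv", ".txt": "tsv"}.get(
            suffix, "tsv"
        )
    readers = {"gff3": read_mirna_gff3, "bed": read_mirna_bed, "tsv": read_mirna_tsv}
    if dialect not in readers:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return readers[dialect](path, genome)


def dedup_cnvs(records: Iterable[CnvRecord]) -> list[CnvRecord]:
    """Collapse CNVs sharing (chrom, start, end, type), pooling patient ids.

    The study convention is to count each distinct genomic event once even
    when several patients carry it; provenance is retained so per-gene
    patient counts remain available.  Idempotent.
    """
    merged: dict[tuple, CnvRecord] = {}
    order: list[tuple] = []
    for rec in records:
        key = (rec.chrom, rec.start, rec.end, rec.cnv_type)
        if key in merged:
            prev = merged[key]
            pooled = prev.patient_ids + tuple(
                p for p in rec.patient_ids if p not in prev.patient_ids
            )
            merged[key] = replace(prev, patient_ids=pooled)
        else:
            merged[key] = rec
            order.append(key)
    return [merged[k] for k in order]


def read_cnv_table(
    path: str | Path,
    source: str = "case",
    genome: Sequence[ChromosomeModel] | None = None,
    keep_duplicates: bool = False,
) -> list[CnvRecord]:
    """Read a CNV table (TSV with columns chrom, start, end, type[, patient]).

    Coordinates are 1-based inclusive.  Type tokens are case-insensitive
    Gain/Loss.  Unless ``keep_duplicates`` is set, records identical on
    (chrom, start, end, type) are merged and the number removed is logged.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "patient": str})
    required = {"chrom", "start", "end", "type"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records: list[CnvRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError):
            raise FormatError(f"{path}: row {i + 1}: non-integer coordinates") from None
        if start > end:
            raise FormatError(f"{path}: row {i + 1}: start {start} > end {end}")
        cnv_type = normalize_cnv_type(row.type)
        patient = getattr(row, "patient", None)
        if patient is None or pd.isna(patient) or str(patient) == "":
            patients: tuple[str, ...] = ()
        else:
            # ';' separates the pooled patient ids of previously merged duplicates
            patients = tuple(p for p in str(patient).split(";") if p)
        records.append(
            CnvRecord(
                chrom=normalize_chrom(row.chrom),
                start=start,
                end=end,
                cnv_type=cnv_type,
                patient_ids=patients,
                source=source,
            )
        )
    if genome is not None:
        lengths = {c.name: c.length for c in genome}
        for rec in records:
            if rec.chrom not in lengths:
                raise FormatError(f"{path}: CNV on unknown chromosome {rec.chrom!r}")
            if rec.end > lengths[rec.chrom]:
                raise FormatError(
                    f"{path}: CNV {rec.chrom}:{rec.start}-{rec.end} exceeds chromosome length"
                )
    if keep_duplicates:
        return records
    deduped = dedup_cnvs(records)
    removed = len(records) - len(deduped)
    if removed:
        log.info("%s: merged %d duplicate CNV record(s)", path, removed)
    return deduped


def _header_lines(params: dict | None) -> list[str]:
    from mircnv import __version__

    lines = [f"# mircnv {__version__}"]
    if params:
        lines.append("# " + " ".join(f"{k}={v}" for k, v in params.items()))
    return lines


def write_cnv_table(records: Sequence[CnvRecord], path: str | Path, params: dict | None = None) -> None:
    """Write CNVs back to the TSV dialect ``read_cnv_table`` accepts (round-trips)."""
    with open(path, "w") as fh:
        for line in _header_lines(params):
            fh.write(line + "\n")
        fh.write("chrom\tstart\tend\ttype\tpatient\n")
        for rec in records:
            patient = ";".join(rec.patient_ids)
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.cnv_type}\t{patient}\n")


def write_tsv(df: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    """Write a DataFrame as TSV with ``#``-prefixed metadata header lines."""
    with open(path, "w") as fh:
        for line in _header_lines(params):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")
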