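"""Readers and writers for the external formats used by the pipeline.

This module is the single home for coordinate conventions.  Internally,
all coordinates are 1-based inclusive positions on a (by default circular)
chromosome, matching the convention used for published E. coli binding-site
tables.  BED input (0-based, half-open) is converted at the boundary.

A binding-site motif is always a 17-mer; its "center" is the top-strand
genome coordinate of the 9th base, regardless of motif strand.  A motif on
the "-" strand is read as the reverse complement of the top strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = set("ACGTN")
SITE_CLASSES = ("OS", "OA", "IS", "IA")


class FormatError(ValueError):
    """Raised when an input file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeRecord:
    """A chromosome sequence with an identifier."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise FormatError(f"genome record {self.id!r} has empty sequence")
        extra = set(self.sequence) - VALID_BASES
        if extra:
            raise FormatError(
                f"genome record {self.id!r} contains invalid bases {sorted(extra)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Return sequence for 1-based inclusive [start, end], wrapping if circular."""
        n = len(self.sequence)
        if start < 1 or end > n:
            if not self.circular:
                raise IndexError(f"[{start}, {end}] outside linear genome of length {n}")
            idx = (np.arange(start - 1, end) % n).astype(int)
            return "".join(self.sequence[i] for i in idx)
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    b_number: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: unknown strand {self.strand!r}")

    @property
    def coding_start(self) -> int:
        """Strand-aware first coding base (start field for +, end field for -)."""
        return self.start if self.strand == "+" else self.end


class GeneAnnotation:
    """Ordered gene records on a 1-based circular coordinate system."""

    def __init__(self, records: Iterable[Gene]):
        self.records: list[Gene] = sorted(records, key=lambda g: (g.start, g.end))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def coding_mask(self, genome_length: int) -> np.ndarray:
        """Boolean array (index 0 = position 1) marking positions inside any gene."""
        mask = np.zeros(genome_length, dtype=bool)
        for g in self.records:
            mask[g.start - 1 : g.end] = True
        return mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.gene_id, g.b_number, g.start, g.end, g.strand) for g in self.records],
            columns=["gene_id", "b_number", "start", "end", "strand"],
        )


@dataclass
class CoverageTrack:
    """Per-position read depth over a genome (slot i = position i+1)."""

    genome_id: str
    values: np.ndarray
    strand: str = "."  # '+', '-' or '.' for unstranded

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise FormatError("coverage values must be one-dimensional")
        if np.any(self.values < 0):
            raise FormatError("coverage values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SiteRecord:
    """One sigma54 binding site as printed in the reference tables."""

    site_id: str
    peak_center: int
    fat: int
    motif: str
    motif_center: int
    motif_strand: str
    overlapping_gene: str = ""
    downstream_gene: str = ""
    distance: int = 0
    pssm_score: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.motif) != 17:
            raise FormatError(f"{self.site_id}: motif must be a 17-mer, got {len(self.motif)}")
        if self.site_class not in SITE_CLASSES:
            raise FormatError(f"{self.site_id}: unknown site class prefix")
        if self.fat < 1:
            raise FormatError(f"{self.site_id}: FAT must be >= 1")
        if self.motif_strand not in "+-":
            raise FormatError(f"{self.site_id}: bad motif strand {self.motif_strand!r}")
        if self.site_class in ("IS", "IA") and not self.overlapping_gene:
            raise FormatError(f"{self.site_id}: intragenic site lacks overlapping gene")

    @property
    def site_class(self) -> str:
        return self.site_id[:2]

    @property
    def intragenic(self) -> bool:
        return self.site_class in ("IS", "IA")


@dataclass
class AnchorRecord:
    """Homologous coordinate of an E. coli site in a query genome."""

    site_id: str
    species: str
    mapped_position: Optional[int]
    mapped_strand: str = "+"
    evalue: Optional[float] = None
    match_fraction: Optional[float] = None

    @property
    def found(self) -> bool:
        return self.mapped_position is not None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[GenomeRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GenomeRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[GenomeRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# gene annotation (GFF3 / BED6)
# ---------------------------------------------------------------------------


def _parse_gff_attributes(attrs: str) -> dict:
    out = {}
    for item in attrs.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_annotation(path, dialect: str = "gff3") -> GeneAnnotation:
    """Read gene records from GFF3 (``gene`` features) or BED6.

    BED half-open 0-based intervals are converted to 1-based inclusive.
    Overlapping genes are allowed and all retained.
    """
    if dialect not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    genes: list[Gene] = []
    if dialect == "gff3":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise FormatError(f"{path}:{ln}: expected 9 GFF3 columns")
                if parts[2].lower() != "gene":
                    continue
                try:
                    start, end = int(parts[3]), int(parts[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{ln}: non-numeric coordinates") from exc
                if end < start:
                    raise FormatError(f"{path}:{ln}: end < start")
                strand = parts[6]
                if strand not in "+-":
                    raise FormatError(f"{path}:{ln}: unknown strand {strand!r}")
                attrs = _parse_gff_attributes(parts[8])
                gid = attrs.get("Name") or attrs.get("gene") or attrs.get("ID") or f"gene{ln}"
                bnum = attrs.get("locus_tag", "")
                genes.append(Gene(gid, bnum, start, end, strand))
    else:
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise FormatError(f"{path}:{ln}: expected >= 6 BED columns")
                try:
                    start0, end0 = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{ln}: non-numeric coordinates") from exc
                if end0 < start0:
                    raise FormatError(f"{path}:{ln}: end < start")
                strand = parts[5]
                if strand not in "+-":
                    raise FormatError(f"{path}:{ln}: unknown strand {strand!r}")
                # BED 0-based half-open -> 1-based inclusive
                genes.append(Gene(parts[3], "", start0 + 1, end0, strand))
    return GeneAnnotation(genes)


def write_annotation(annotation: GeneAnnotation, path, genome_id: str = "genome") -> None:
    """Write genes as GFF3 ``gene`` features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation:
            attrs = f"ID={g.gene_id};Name={g.gene_id}"
            if g.b_number:
                attrs += f";locus_tag={g.b_number}"
            fh.write(
                f"{genome_id}\tsigma54\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# coverage (bedGraph / fixed-step wiggle)
# ---------------------------------------------------------------------------


def read_coverage(path, genome_length: int, strand: str = ".") -> CoverageTrack:
    """Read a bedGraph or fixed-step wiggle file into a per-base track.

    Unspecified positions are zero.  bedGraph intervals (0-based half-open)
    are expanded per base.
    """
    values = np.zeros(genome_length, dtype=float)
    genome_id = "genome"
    with open(path) as fh:
        mode = "bedgraph"
        step = span = 1
        pos = 1
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                mode = "wiggle"
                fields = dict(f.split("=") for f in line.split()[1:])
                genome_id = fields.get("chrom", genome_id)
                pos = int(fields.get("start", 1))
                step = int(fields.get("step", 1))
                span = int(fields.get("span", 1))
                continue
            if mode == "wiggle":
                try:
                    v = float(line)
                except ValueError as exc:
                    raise FormatError(f"{path}:{ln}: bad wiggle value") from exc
                if pos + span - 1 > genome_length:
                    raise FormatError(f"{path}:{ln}: position beyond genome length")
                values[pos - 1 : pos - 1 + span] = v
                pos += step
            else:
                parts = line.split()
                if len(parts) != 4:
                    raise FormatError(f"{path}:{ln}: expected 4 bedGraph columns")
                genome_id = parts[0]
                try:
                    start0, end0, v = int(parts[1]), int(parts[2]), float(parts[3])
                except ValueError as exc:
                    raise FormatError(f"{path}:{ln}: bad bedGraph fields") from exc
                if end0 > genome_length:
                    raise FormatError(f"{path}:{ln}: interval beyond genome length")
                values[start0:end0] = v
    return CoverageTrack(genome_id=genome_id, values=values, strand=strand)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a coverage track as bedGraph, merging equal-valued runs."""
    v = track.values
    with open(path, "w") as fh:
        if len(v) == 0:
            return
        boundaries = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(v)]))
        for s, e in zip(starts, ends):
            if v[s] != 0:
                fh.write(f"{track.genome_id}\t{s}\t{e}\t{v[s]:g}\n")


# ---------------------------------------------------------------------------
# site tables
# ---------------------------------------------------------------------------

_SITE_COLUMNS = [
    "site_id",
    "peak_center",
    "fat",
    "motif",
    "motif_center",
    "motif_strand",
    "overlapping_gene",
    "downstream_gene",
    "distance",
    "pssm_score",
]


def read_site_table(path) -> list[SiteRecord]:
    """Read a TSV of binding-site records (the packaged fixture schema)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_SITE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        try:
            records.append(
                SiteRecord(
                    site_id=row["site_id"],
                    peak_center=int(row["peak_center"]),
                    fat=int(row["fat"]),
                    motif=row["motif"],
                    motif_center=int(row["motif_center"]),
                    motif_strand=row["motif_strand"],
                    overlapping_gene=row["overlapping_gene"],
                    downstream_gene=row["downstream_gene"],
                    distance=int(row["distance"]),
                    pssm_score=float(row["pssm_score"]),
                )
            )
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path}: row {row['site_id']!r}: {exc}") from exc
    return records


def write_site_table(sites: Sequence[SiteRecord], path) -> None:
    rows = [
        {
            "site_id": s.site_id,
            "peak_center": s.peak_center,
            "fat": s.fat,
            "motif": s.motif,
            "motif_center": s.motif_center,
            "motif_strand": s.motif_strand,
            "overlapping_gene": s.overlapping_gene,
            "downstream_gene": s.downstream_gene,
            "distance": s.distance,
            "pssm_score": s.pssm_score,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=_SITE_COLUMNS).to_csv(path, sep="\t", index=False)


def load_site_fixture() -> list[SiteRecord]:
    """Load the packaged table of the 135 E. coli sigma54 binding sites."""
    ref = resources.files("sigma54").joinpath("data/sigma54_sites.tsv")
    with resources.as_file(ref) as path:
        return read_site_table(path)


def load_site_fixture_frame() -> pd.DataFrame:
    """Packaged site table as a DataFrame (all transcription columns kept)."""
    ref = resources.files("sigma54").joinpath("data/sigma54_sites.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])


# ---------------------------------------------------------------------------
# anchor tables (BLAST tabular outfmt-6 dialect, or 5-column anchor TSV)
# ---------------------------------------------------------------------------


def read_anchor_table(path, evalue_max: float = 1e-4) -> list[AnchorRecord]:
    """Read homology anchors; keep the best (lowest E-value) hit per (site, species).

    Two layouts are accepted:

    * 12-column BLAST tabular (qseqid sseqid pident length mismatch gapopen
      qstart qend sstart send evalue bitscore), where ``qseqid`` is the site id,
      ``sseqid`` the species/genome id, and the query is the 300-nt fragment
      centered on the site (query position 150 = motif center).
    * a 5-column TSV: site_id, species, mapped_position, mapped_strand, evalue.

    Rows with E-value above ``evalue_max`` are dropped.  Ties on E-value keep
    the first row in file order.
    """
    best: dict[tuple[str, str], AnchorRecord] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if len(parts) >= 12:
                    site_id, species = parts[0], parts[1]
                    qstart, sstart, send = int(parts[6]), int(parts[8]), int(parts[9])
                    evalue = float(parts[10])
                    if sstart <= send:
                        pos, strand = sstart + (150 - qstart), "+"
                    else:
                        pos, strand = sstart - (150 - qstart), "-"
                elif len(parts) == 5:
                    site_id, species = parts[0], parts[1]
                    pos = int(parts[2])
                    strand = parts[3]
                    evalue = float(parts[4])
                else:
                    raise FormatError(
                        f"{path}:{ln}: expected 12 BLAST or 5 anchor columns, got {len(parts)}"
                    )
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: unparseable numeric field") from exc
            if evalue > evalue_max:
                continue
            key = (site_id, species)
            rec = AnchorRecord(site_id, species, pos, strand, evalue)
            if key not in best:
                best[key] = rec
                order.append(key)
            elif evalue < best[key].evalue:  # strict: ties keep first in file order
                best[key] = rec
    return [best[k] for k in order]


def write_anchor_table(anchors: Sequence[AnchorRecord], path) -> None:
    with open(path, "w") as fh:
        for a in anchors:
            if not a.found:
                continue
            ev = a.evalue if a.evalue is not None else 0.0
            fh.write(f"{a.site_id}\t{a.species}\t{a.mapped_position}\t{a.mapped_strand}\t{ev:g}\n")


def validate_file(path) -> str:
    """Best-effort format detection + validation; returns the detected format."""
    path = Path(path)
    text = path.read_text().lstrip()
    if text.startswith(">"):
        read_fasta(path)
        return "fasta"
    if text.startswith("##gff"):
        read_annotation(path, "gff3")
        return "gff3"
    first = text.splitlines()[0] if text else ""
    cols = first.split("\t")
    if first.startswith("site_id"):
        read_site_table(path)
        return "sites"
    if len(cols) == 6:
        read_annotation(path, "bed")
        return "bed"
    if len(cols) in (5, 12):
        read_anchor_table(path, evalue_max=math.inf)
        return "anchors"
    if len(cols) == 4 or first.startswith("fixedStep"):
        return "coverage"
    raise FormatError(f"{path}: unrecognized format")
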