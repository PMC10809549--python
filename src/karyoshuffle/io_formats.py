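"""Readers, writers and assembly summary metrics.

All coordinates inside the package are 0-based half-open. BED files are
taken as-is; GFF3 (1-based, inclusive) is converted on the way in. The
ortholog table is a BUSCO-full-table-like TSV that additionally carries a
strand column, since orientation is required to sign the anchors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import FormatError, ValidationError

ORTHOLOG_COLUMNS = ["ortholog_id", "species", "status", "chrom", "start", "end", "strand"]
COPY_STATUSES = {"single", "duplicated", "missing", "fragmented"}


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (FASTA record)."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome, 0-based."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class OrthologHit:
    """Placement of one ortholog in one species."""

    ortholog_id: str
    species: str
    chrom: str
    interval: GenomicInterval
    sign: int | None
    copy_status: str

    def __post_init__(self):
        if self.copy_status not in COPY_STATUSES:
            raise ValidationError(f"unknown copy status {self.copy_status!r}")
        if self.copy_status == "single" and self.sign not in (1, -1):
            raise ValidationError(
                f"single-copy ortholog {self.ortholog_id} in {self.species} "
                "requires a strand (+/-)"
            )


@dataclass(frozen=True)
class FragmentCounts:
    """Female and male alignment counts for one reference fragment."""

    fragment: GenomicInterval
    female_count: int
    male_count: int

    def __post_init__(self):
        if self.female_count < 0 or self.male_count < 0:
            raise ValidationError("alignment counts must be non-negative")


@dataclass(frozen=True)
class AssemblyMetrics:
    n_sequences: int
    total_length: int
    scaffold_n50: int
    contig_n50: int
    gap_run_threshold: int


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, preserving file order.

    The id is the header token before the first whitespace. Duplicate ids
    and empty files raise :class:`FormatError`.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# BED / GFF3 intervals
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path, dialect: str = "BED") -> list[GenomicInterval]:
    """Parse BED (kept 0-based half-open) or GFF3 (converted from 1-based).

    BED label comes from column 4, strand from column 6 when present;
    GFF3 label is the feature type (column 3), strand column 7.
    """
    dialect = dialect.upper()
    if dialect not in {"BED", "GFF3"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            cols = line.split("\t")
            try:
                if dialect == "BED":
                    chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                    label = cols[3] if len(cols) > 3 else ""
                    strand = cols[5] if len(cols) > 5 else "."
                else:
                    chrom = cols[0]
                    start, end = int(cols[3]) - 1, int(cols[4])
                    label = cols[2]
                    strand = cols[6] if len(cols) > 6 and cols[6] in "+-" else "."
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed {dialect} line") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: empty or inverted interval "
                    f"{chrom}:{start}-{end} after conversion"
                )
            out.append(GenomicInterval(chrom, start, end, strand=strand, label=label))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Ortholog tables
# ---------------------------------------------------------------------------

def read_ortholog_table(path: str | Path) -> list[OrthologHit]:
    """Read the TSV of per-species ortholog placements.

    Columns: ortholog_id, species, status, chrom, start, end, strand.
    A single-copy row with strand "." is a validation error, because
    downstream anchoring needs orientation.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "species": str})
    missing = [c for c in ORTHOLOG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return dataframe_to_hits(df)


def dataframe_to_hits(df: pd.DataFrame) -> list[OrthologHit]:
    hits = []
    bad = []
    for row in df.itertuples(index=False):
        status = row.status
        if status == "single" and row.strand not in ("+", "-"):
            bad.append(row.ortholog_id)
            continue
        sign = {"+": 1, "-": -1}.get(row.strand) if status == "single" else None
        interval = GenomicInterval(
            str(row.chrom), int(row.start), int(row.end),
            strand=row.strand if row.strand in "+-" else ".",
            label=str(row.ortholog_id),
        )
        hits.append(
            OrthologHit(
                ortholog_id=str(row.ortholog_id),
                species=str(row.species),
                chrom=str(row.chrom),
                interval=interval,
                sign=sign,
                copy_status=status,
            )
        )
    if bad:
        raise ValidationError(
            "single-copy rows without strand: " + ", ".join(sorted(set(bad)))
        )
    return hits


def hits_to_dataframe(hits: Iterable[OrthologHit]) -> pd.DataFrame:
    rows = [
        {
            "ortholog_id": h.ortholog_id,
            "species": h.species,
            "status": h.copy_status,
            "chrom": h.chrom,
            "start": h.interval.start,
            "end": h.interval.end,
            "strand": {1: "+", -1: "-"}.get(h.sign, "."),
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=ORTHOLOG_COLUMNS)


def write_ortholog_table(hits: Iterable[OrthologHit], path: str | Path) -> None:
    hits_to_dataframe(hits).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignment counts adapter
# ---------------------------------------------------------------------------

def _count_sam(path: str | Path, fragments: Sequence[GenomicInterval], mode: str) -> dict:
    """Count primary mapped alignments per fragment from a text SAM file."""
    counts: dict[tuple, int] = {}
    if mode == "fragmented":
        by_name = {f.label: (f.chrom, f.start) for f in fragments}
    else:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for f in fragments:
            by_chrom.setdefault(f.chrom, []).append(f)
        for lst in by_chrom.values():
            lst.sort(key=lambda f: f.start)
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if mode == "fragmented":
                name = aln.reference_name
                if name not in by_name:
                    raise ValidationError(
                        f"alignment reference {name!r} is not a known fragment"
                    )
                key = by_name[name]
            else:
                chrom = aln.reference_name
                pos = aln.reference_start
                frags = by_chrom.get(chrom)
                if not frags:
                    raise ValidationError(f"alignments on unknown chromosome {chrom!r}")
                # binary search for the fragment containing the leftmost base
                lo, hi = 0, len(frags) - 1
                key = None
                while lo <= hi:
                    mid = (lo + hi) // 2
                    f = frags[mid]
                    if pos < f.start:
                        hi = mid - 1
                    elif pos >= f.end:
                        lo = mid + 1
                    else:
                        key = (f.chrom, f.start)
                        break
                if key is None:
                    raise ValidationError(
                        f"alignment at {chrom}:{pos} falls in no fragment"
                    )
            counts[key] = counts.get(key, 0) + 1
    return counts


def alignment_to_fragment_counts(
    source,
    fragments: Sequence[GenomicInterval],
    mode: str = "fragmented",
) -> list[FragmentCounts]:
    """Derive per-fragment female/male counts.

    ``source`` is either a path to a 4-column TSV (chrom, start,
    female_count, male_count) or a ``(female_sam, male_sam)`` pair of text
    SAM paths. In ``fragmented`` mode each SAM reference name must equal a
    fragment label; in ``whole`` mode an alignment is credited to the
    fragment containing its leftmost mapped base. Unmapped, secondary and
    supplementary records are ignored.
    """
    keys = {(f.chrom, f.start): f for f in fragments}
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep="\t", dtype={"chrom": str})
        needed = {"chrom", "start", "female_count", "male_count"}
        if not needed.issubset(df.columns):
            raise FormatError(f"{source}: need columns {sorted(needed)}")
        female, male = {}, {}
        for row in df.itertuples(index=False):
            key = (str(row.chrom), int(row.start))
            if key not in keys:
                raise ValidationError(
                    f"counts given for unknown fragment {key[0]}:{key[1]}"
                )
            female[key] = int(row.female_count)
            male[key] = int(row.male_count)
    else:
        female_sam, male_sam = source
        female = _count_sam(female_sam, fragments, mode)
        male = _count_sam(male_sam, fragments, mode)
    return [
        FragmentCounts(f, female.get(k, 0), male.get(k, 0))
        for k, f in keys.items()
    ]


# ---------------------------------------------------------------------------
# Assembly metrics
# ---------------------------------------------------------------------------

def _n50(lengths: Sequence[int]) -> int:
    """Length of the shortest sequence in the smallest set of longest
    sequences jointly covering at least half of the total."""
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    return 0


def split_contigs(sequence: str, gap_run_threshold: int = 10) -> list[int]:
    """Contig lengths obtained by cutting at runs of >= threshold Ns."""
    parts = re.split(f"[Nn]{{{gap_run_threshold},}}", sequence)
    return [len(p) for p in parts if p]


def assembly_metrics(
    records: Sequence[SequenceRecord], gap_run_threshold: int = 10
) -> AssemblyMetrics:
    """Scaffold/contig N50 and total length for an assembly.

    Contigs are scaffolds split at runs of at least ``gap_run_threshold``
    consecutive Ns (the gap convention is not standardized, hence
    configurable).
    """
    if not records:
        raise ValidationError("assembly_metrics requires at least one record")
    scaffold_lengths = [len(r) for r in records]
    contig_lengths: list[int] = []
    for r in records:
        contig_lengths.extend(split_contigs(r.sequence, gap_run_threshold))
    return AssemblyMetrics(
        n_sequences=len(records),
        total_length=sum(scaffold_lengths),
        scaffold_n50=_n50(scaffold_lengths),
        contig_n50=_n50(contig_lengths) if contig_lengths else 0,
        gap_run_threshold=gap_run_threshold,
    )
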