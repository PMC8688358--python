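"""Readers/writers for every external format the pipeline touches.

Internal coordinate convention (used by every other module):

* 0-based, half-open intervals;
* precursor-local, always counted along the precursor's own 5'->3'
  direction, regardless of the genomic strand the locus lives on.

GFF3 (miRBase dialect), BAM and tag TSVs are converted to this convention at
the boundary, so downstream math never sees 1-based or strand-flipped
coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "FormatError",
    "GenomicInterval",
    "Interval",
    "HairpinRecord",
    "TagCountTable",
    "SrnaTagTable",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "read_tags",
    "read_structures",
    "write_table",
    "read_table",
    "OUTPUT_SCHEMAS",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    ref_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Interval:
    """A precursor-local interval, 0-based half-open, implicitly 5'->3'."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def shift(self, offset: int) -> "Interval":
        return Interval(self.start + offset, self.end + offset)


@dataclass
class HairpinRecord:
    """A miRNA precursor: sequence, mature-arm intervals, optional structure.

    ``mir5p``/``mir3p`` are precursor-local (see module docstring).  The
    dot-bracket ``structure``, when present, must match the sequence length.
    """

    precursor_id: str
    sequence: str
    genome_location: GenomicInterval | None = None
    mir5p: Interval | None = None
    mir3p: Interval | None = None
    structure: str | None = None
    family: str | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        L = len(self.sequence)
        for name in ("mir5p", "mir3p"):
            iv = getattr(self, name)
            if iv is not None and iv.end > L:
                raise ValueError(
                    f"{self.precursor_id}: {name} [{iv.start},{iv.end}) "
                    f"outside precursor of length {L}"
                )
        if self.structure is not None and len(self.structure) != L:
            raise ValueError(
                f"{self.precursor_id}: structure length {len(self.structure)} "
                f"!= sequence length {L}"
            )
        if self.mir5p and self.mir3p and self.mir5p.start >= self.mir3p.start:
            raise ValueError(
                f"{self.precursor_id}: miR-5p must precede miR-3p along the precursor"
            )


@dataclass
class TagCountTable:
    """Sparse 5'-end tag counts: (ref_id, position, strand) -> count."""

    library_id: str
    counts: dict[tuple[str, int, str], int] = field(default_factory=dict)

    def add(self, ref_id: str, pos: int, strand: str, n: int = 1) -> None:
        if n < 0:
            raise ValueError("negative tag count")
        key = (ref_id, pos, strand)
        self.counts[key] = self.counts.get(key, 0) + n

    def get(self, ref_id: str, pos: int, strand: str = "+") -> int:
        return self.counts.get((ref_id, pos, strand), 0)

    def total(self) -> int:
        return sum(self.counts.values())

    def refs(self) -> set[str]:
        return {k[0] for k in self.counts}


@dataclass
class SrnaTagTable:
    """Length-aware sRNA tag counts: (ref_id, pos, strand, read_len) -> count.

    Used by arm inference, which needs the exact read species (5' position
    plus length), not just 5'-end coverage.
    """

    library_id: str
    counts: dict[tuple[str, int, str, int], int] = field(default_factory=dict)

    def add(self, ref_id: str, pos: int, strand: str, length: int, n: int = 1) -> None:
        if n < 0:
            raise ValueError("negative tag count")
        key = (ref_id, pos, strand, length)
        self.counts[key] = self.counts.get(key, 0) + n

    def species_on(self, ref_id: str, strand: str = "+") -> dict[tuple[int, int], int]:
        """(pos, length) -> count for one reference/strand."""
        out: dict[tuple[int, int], int] = {}
        for (r, p, s, ln), n in self.counts.items():
            if r == ref_id and s == strand:
                out[(p, ln)] = out.get((p, ln), 0) + n
        return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, SEQUENCE), ...]``.

    Sequences are uppercased; both U and T are accepted and preserved as
    given (upper-cased).  An empty file yields an empty list.
    """
    from Bio import SeqIO

    path = Path(path)
    records: list[tuple[str, str]] = []
    # Pre-scan for malformed content Biopython silently tolerates.
    with open(path) as fh:
        seen_header = False
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if stripped == ">":
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                seen_header = True
            elif not seen_header:
                raise FormatError(f"{path}: sequence before first header at line {lineno}")
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for record {rec.id!r}")
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotations


def _genomic_to_local(pre: GenomicInterval, mat_start: int, mat_end: int) -> Interval:
    """Map a genomic (0-based half-open) mature interval into precursor-local
    5'->3' coordinates, honouring the precursor's strand."""
    if not (pre.start <= mat_start < mat_end <= pre.end):
        raise FormatError(
            f"mature interval [{mat_start},{mat_end}) outside precursor "
            f"{pre.ref_id}:[{pre.start},{pre.end})"
        )
    if pre.strand == "+":
        return Interval(mat_start - pre.start, mat_end - pre.start)
    return Interval(pre.end - mat_end, pre.end - mat_start)


def _local_to_genomic(pre: GenomicInterval, local: Interval) -> tuple[int, int]:
    """Inverse of :func:`_genomic_to_local` (0-based half-open output)."""
    if pre.strand == "+":
        return pre.start + local.start, pre.start + local.end
    return pre.end - local.end, pre.end - local.start


def _parse_gff3_attrs(field9: str) -> dict[str, str]:
    attrs = {}
    for part in field9.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"malformed GFF3 attribute {part!r}")
        k, v = part.split("=", 1)
        attrs[k.strip()] = v.strip()
    return attrs


def _read_gff3_mirbase(path: Path) -> list[HairpinRecord]:
    precursors: dict[str, GenomicInterval] = {}
    names: dict[str, str] = {}
    matures: list[tuple[str, str, int, int]] = []  # (derives_from, name, start0, end0)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attr9 = cols
            attrs = _parse_gff3_attrs(attr9)
            start0, end0 = int(start) - 1, int(end)
            if ftype == "miRNA_primary_transcript":
                pid = attrs.get("ID")
                if pid is None:
                    raise FormatError(f"{path}:{lineno}: precursor without ID")
                precursors[pid] = GenomicInterval(seqid, start0, end0, strand)
                names[pid] = attrs.get("Name", pid)
            elif ftype == "miRNA":
                parent = attrs.get("Derives_from")
                if parent is None:
                    raise FormatError(f"{path}:{lineno}: miRNA without Derives_from")
                matures.append((parent, attrs.get("Name", attrs.get("ID", "")), start0, end0))
    records: dict[str, HairpinRecord] = {}
    for pid, loc in precursors.items():
        records[pid] = HairpinRecord(
            precursor_id=names[pid], sequence="N" * len(loc), genome_location=loc
        )
    by_parent: dict[str, list[tuple[str, Interval]]] = {}
    for parent, name, s0, e0 in matures:
        if parent not in precursors:
            raise FormatError(f"miRNA {name!r} Derives_from unknown precursor {parent!r}")
        local = _genomic_to_local(precursors[parent], s0, e0)
        by_parent.setdefault(parent, []).append((name, local))
    for parent, mats in by_parent.items():
        rec = records[parent]
        named5 = [iv for nm, iv in mats if nm.endswith("-5p")]
        named3 = [iv for nm, iv in mats if nm.endswith("-3p")]
        if named5 or named3:
            rec.mir5p = named5[0] if named5 else None
            rec.mir3p = named3[0] if named3 else None
        else:  # fall back to positional order along the precursor
            ordered = sorted((iv for _, iv in mats), key=lambda iv: iv.start)
            rec.mir5p = ordered[0]
            if len(ordered) > 1:
                rec.mir3p = ordered[-1]
    return [records[pid] for pid in sorted(records, key=lambda p: records[p].precursor_id)]


_TSV_ANN_COLS = ["precursor_id", "mir5p_start", "mir5p_end", "mir3p_start", "mir3p_end"]


def _read_tsv_annotations(path: Path) -> list[HairpinRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TSV_ANN_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        mir5p = Interval(int(row.mir5p_start) - 1, int(row.mir5p_end))
        mir3p = Interval(int(row.mir3p_start) - 1, int(row.mir3p_end))
        # Sequence is supplied separately (FASTA); placeholder length spans the
        # annotated intervals so invariants can be checked now.
        length = max(mir5p.end, mir3p.end)
        rec = HairpinRecord(
            precursor_id=str(row.precursor_id),
            sequence="N" * length,
            mir5p=mir5p,
            mir3p=mir3p,
            family=str(row.family) if "family" in df.columns and not pd.isna(row.family) else None,
            species=str(row.species) if "species" in df.columns and not pd.isna(row.species) else None,
        )
        out.append(rec)
    return out


def read_annotations(path: str | Path, dialect: str = "tsv") -> list[HairpinRecord]:
    """Read miRNA annotations (precursor + mature arms) into HairpinRecords.

    ``dialect`` is ``"gff3-mirbase"`` (miRNA_primary_transcript / miRNA
    features linked by Derives_from; coordinates 1-based genomic) or
    ``"tsv"`` (precursor-local 1-based inclusive columns).  Output intervals
    are precursor-local 0-based half-open in all cases.  Sequences are not
    carried by either dialect; use :func:`attach_sequences`.
    """
    path = Path(path)
    if dialect == "gff3-mirbase":
        return _read_gff3_mirbase(path)
    if dialect == "tsv":
        return _read_tsv_annotations(path)
    raise FormatError(f"unknown annotation dialect {dialect!r}")


def attach_sequences(
    records: list[HairpinRecord], sequences: Mapping[str, str]
) -> list[HairpinRecord]:
    """Return copies of ``records`` with sequences from a FASTA mapping."""
    out = []
    for rec in records:
        seq = sequences.get(rec.precursor_id)
        if seq is None:
            raise FormatError(f"no sequence for precursor {rec.precursor_id!r}")
        out.append(replace(rec, sequence=seq.upper()))
    return out


def read_structures(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (precursor_id, dot-bracket) of structures."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


# ---------------------------------------------------------------------------
# PARE / sRNA tags


def read_tags(
    path: str | Path,
    format: str = "tsv",
    read_len_filter: int = 20,
    library_id: str | None = None,
) -> TagCountTable:
    """Read aligned PARE tags into a :class:`TagCountTable` of 5'-end counts.

    Only alignments whose read length equals ``read_len_filter`` are counted
    (MmeI degradome tags are 20 nt; EcoP15I libraries need 27).  The tag
    position is the biological 5' end: leftmost aligned base on '+', rightmost
    on '-'.  Secondary/supplementary and unmapped alignments are skipped;
    multi-mapper allocation is assumed to have happened upstream.
    """
    path = Path(path)
    lib = library_id or path.stem
    table = TagCountTable(library_id=lib)
    if format == "bam":
        import pysam

        with pysam.AlignmentFile(str(path), "rb") as bam:
            for aln in bam.fetch(until_eof=True):
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                if aln.query_length != read_len_filter:
                    continue
                ref = aln.reference_name
                if aln.is_reverse:
                    table.add(ref, aln.reference_end - 1, "-")
                else:
                    table.add(ref, aln.reference_start, "+")
    elif format == "tsv":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            dtype={"ref_id": str, "pos_1based": int, "strand": str, "count": int},
        )
        needed = ["ref_id", "pos_1based", "strand", "count"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing tag columns {missing}")
        if (df["count"] < 0).any():
            raise FormatError(f"{path}: negative count in tag table")
        # TSV tables are pre-filtered by length upstream; positions 1-based.
        for row in df.itertuples(index=False):
            table.add(str(row.ref_id), int(row.pos_1based) - 1, str(row.strand), int(row.count))
    else:
        raise FormatError(f"unknown tag format {format!r}")
    return table


def write_tags(table: TagCountTable, path: str | Path) -> None:
    """Write a TagCountTable to the 1-based tag TSV format."""
    rows = [
        {"ref_id": r, "pos_1based": p + 1, "strand": s, "count": n}
        for (r, p, s), n in sorted(table.counts.items())
    ]
    df = pd.DataFrame(rows, columns=["ref_id", "pos_1based", "strand", "count"])
    df.to_csv(path, sep="\t", index=False)


def read_srna_tags(path: str | Path, library_id: str | None = None) -> SrnaTagTable:
    """Read a length-aware sRNA tag TSV (ref_id, pos_1based, strand, length, count)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = ["ref_id", "pos_1based", "strand", "length", "count"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing sRNA tag columns {missing}")
    if (df["count"] < 0).any():
        raise FormatError(f"{path}: negative count in sRNA tag table")
    table = SrnaTagTable(library_id=library_id or path.stem)
    for row in df.itertuples(index=False):
        table.add(str(row.ref_id), int(row.pos_1based) - 1, str(row.strand), int(row.length), int(row.count))
    return table


def write_srna_tags(table: SrnaTagTable, path: str | Path) -> None:
    rows = [
        {"ref_id": r, "pos_1based": p + 1, "strand": s, "length": ln, "count": n}
        for (r, p, s, ln), n in sorted(table.counts.items())
    ]
    df = pd.DataFrame(rows, columns=["ref_id", "pos_1based", "strand", "length", "count"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Fixed-schema result tables

OUTPUT_SCHEMAS: dict[str, list[str]] = {
    "qc": [
        "library_id",
        "n_bl",
        "n_lb",
        "p_bl",
        "p_lb",
        "contamination_fraction",
        "passed",
    ],
    "modes": [
        "precursor_id",
        "library_id",
        "mode",
        "C0",
        "Ce",
        "Cup_total",
        "Cdown",
        "first_cut_accuracy",
    ],
    "corrections": [
        "precursor_id",
        "edge",
        "annotated_start",
        "annotated_end",
        "corrected_start",
        "corrected_end",
        "offset",
        "peak_count",
        "overhang_ok",
    ],
    "profiles": [
        "precursor_id",
        "library_id",
        "position_1based",
        "count",
    ],
}

_SORT_KEYS: dict[str, list[str]] = {
    "qc": ["library_id"],
    "modes": ["precursor_id", "library_id"],
    "corrections": ["precursor_id", "edge"],
    "profiles": ["precursor_id", "library_id", "position_1based"],
}


def write_table(records: Iterable[Mapping], path: str | Path, schema_name: str) -> None:
    """Write result records as a TSV with a fixed schema and deterministic order.

    ``schema_name`` is one of ``qc``, ``modes``, ``corrections``, ``profiles``.
    Rows are sorted by the schema's key columns; missing optional values are
    written as ``NA``.
    """
    if schema_name not in OUTPUT_SCHEMAS:
        raise FormatError(f"unknown output schema {schema_name!r}")
    cols = OUTPUT_SCHEMAS[schema_name]
    rows = []
    for rec in records:
        row = {c: rec.get(c) for c in cols}
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    if len(df):
        df = df.sort_values(_SORT_KEYS[schema_name], kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path: str | Path, schema_name: str) -> list[dict]:
    """Read back a TSV written by :func:`write_table` (round-trip inverse)."""
    if schema_name not in OUTPUT_SCHEMAS:
        raise FormatError(f"unknown output schema {schema_name!r}")
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    cols = OUTPUT_SCHEMAS[schema_name]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing} for schema {schema_name!r}")
    records = []
    for _, row in df.iterrows():
        rec = {}
        for c in cols:
            v = row[c]
            if pd.isna(v):
                rec[c] = None
            elif isinstance(v, float) and v.is_integer() and c not in (
                "p_bl", "p_lb", "contamination_fraction", "first_cut_accuracy",
            ):
                rec[c] = int(v)
            else:
                rec[c] = v.item() if hasattr(v, "item") else v
        for bcol in ("passed", "overhang_ok"):
            if bcol in rec and rec[bcol] is not None:
                v = rec[bcol]
                rec[bcol] = v == "True" if isinstance(v, str) else bool(v)
        records.append(rec)
    return records
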