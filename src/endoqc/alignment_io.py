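"""Readers and writers for the formats the pipeline touches.

SAM text is parsed in-repo so that plain-text fixtures need no compression
tooling; BAM is delegated to pysam.  FASTA goes through Biopython.  Reports
are plain TSV with a header row and deterministic column order.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Iterator
from typing import Any

import numpy as np
from Bio import SeqIO

from .records import AlignmentRecord, AlignmentError

FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800


class SamParseError(AlignmentError):
    """Malformed SAM input; message names the offending line."""


def _record_from_sam_fields(fields: list[str], lineno: int) -> AlignmentRecord:
    if len(fields) < 11:
        raise SamParseError(f"line {lineno}: expected >= 11 tab-separated fields, got {len(fields)}")
    try:
        flag = int(fields[1])
        pos = int(fields[3])
        mapq = int(fields[4])
    except ValueError as exc:
        raise SamParseError(f"line {lineno}: non-integer FLAG/POS/MAPQ: {exc}") from None
    is_mapped = not flag & FLAG_UNMAPPED
    seq = fields[9]
    if seq == "*":
        seq = ""
    md = None
    tags: dict[str, str] = {}
    for tag_field in fields[11:]:
        parts = tag_field.split(":", 2)
        if len(parts) != 3:
            raise SamParseError(f"line {lineno}: malformed optional field {tag_field!r}")
        tags[parts[0]] = parts[2]
        if parts[0] == "MD":
            md = parts[2]
    rec = AlignmentRecord(
        read_id=fields[0],
        sequence=seq.upper(),
        is_mapped=is_mapped,
        is_reverse=bool(flag & FLAG_REVERSE),
        mapq=mapq,
        cigar="" if fields[5] == "*" else fields[5],
        md=md if is_mapped else None,
        is_primary=not flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY),
        is_duplicate=bool(flag & FLAG_DUPLICATE),
        ref_name=None if fields[2] == "*" else fields[2],
        ref_start=pos - 1 if is_mapped else -1,
        tags=tags,
    )
    return rec


def iter_sam_text(text: str) -> Iterator[AlignmentRecord]:
    """Yield records from SAM text (header lines skipped)."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("@"):
            continue
        yield _record_from_sam_fields(line.rstrip("\n").split("\t"), lineno)


def read_alignments(path: str | os.PathLike, format: str | None = None) -> Iterator[AlignmentRecord]:
    """Stream :class:`AlignmentRecord` objects from a SAM or BAM file.

    ``format`` is ``"sam"`` or ``"bam"``; if omitted it is inferred from the
    file extension.  Records are yielded in file order.
    """
    path = os.fspath(path)
    if format is None:
        format = "bam" if path.endswith(".bam") else "sam"
    if format == "sam":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("@"):
                    continue
                yield _record_from_sam_fields(line.rstrip("\n").split("\t"), lineno)
    elif format == "bam":
        import pysam

        with pysam.AlignmentFile(path, "rb", check_sq=False) as bam:
            for aln in bam.fetch(until_eof=True):
                seq = aln.query_sequence or ""
                yield AlignmentRecord(
                    read_id=aln.query_name or "",
                    sequence=seq.upper(),
                    is_mapped=not aln.is_unmapped,
                    is_reverse=aln.is_reverse,
                    mapq=aln.mapping_quality,
                    cigar=aln.cigarstring or "",
                    md=aln.get_tag("MD") if aln.has_tag("MD") and not aln.is_unmapped else None,
                    is_primary=not (aln.is_secondary or aln.is_supplementary),
                    is_duplicate=aln.is_duplicate,
                    ref_name=aln.reference_name if not aln.is_unmapped else None,
                    ref_start=aln.reference_start if not aln.is_unmapped else -1,
                    tags={t: str(v) for t, v in aln.get_tags()},
                )
    else:
        raise ValueError(f"unknown alignment format: {format!r}")


def alignments_to_sam(
    records: Iterable[AlignmentRecord],
    reference_lengths: dict[str, int] | None = None,
) -> str:
    """Render records as SAM text with a minimal header."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name in sorted(reference_lengths or {}):
        lines.append(f"@SQ\tSN:{name}\tLN:{reference_lengths[name]}")
    for rec in records:
        flag = 0
        if not rec.is_mapped:
            flag |= FLAG_UNMAPPED
        if rec.is_reverse:
            flag |= FLAG_REVERSE
        if not rec.is_primary:
            flag |= FLAG_SECONDARY
        if rec.is_duplicate:
            flag |= FLAG_DUPLICATE
        fields = [
            rec.read_id,
            str(flag),
            rec.ref_name if rec.is_mapped and rec.ref_name else "*",
            str(rec.ref_start + 1) if rec.is_mapped else "0",
            str(rec.mapq),
            rec.cigar if rec.cigar else "*",
            "*",
            "0",
            "0",
            rec.sequence if rec.sequence else "*",
            "*",
        ]
        if rec.md is not None:
            fields.append(f"MD:Z:{rec.md}")
        for tag, val in rec.tags.items():
            if tag == "MD":
                continue
            fields.append(f"{tag}:Z:{val}")
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def write_alignments(
    path: str | os.PathLike,
    records: Iterable[AlignmentRecord],
    reference_lengths: dict[str, int] | None = None,
) -> None:
    """Write records as SAM text with a minimal header."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(alignments_to_sam(records, reference_lengths))


def read_reference(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into ``{name: upper-case sequence}``.

    Names are the first whitespace-delimited token of each header line.
    """
    reference: dict[str, str] = {}
    for seq_record in SeqIO.parse(os.fspath(path), "fasta"):
        name = seq_record.id
        if name in reference:
            raise ValueError(f"duplicate sequence name in FASTA: {name!r}")
        reference[name] = str(seq_record.seq).upper()
    if not reference:
        raise ValueError(f"no FASTA records found in {path}")
    return reference


def format_cell(value: Any) -> str:
    """Render one TSV cell: plain decimal notation, never scientific."""
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        if value != value:  # NaN
            return "NA"
        return np.format_float_positional(value, precision=10, trim="-")
    return str(value)


def write_report(path: str | os.PathLike, rows: list[dict[str, Any]], columns: list[str] | None = None) -> None:
    """Write rows (dicts sharing a schema) to a TSV file with a header.

    Column order is ``columns`` if given, else the key order of the first
    row.  An empty row set with explicit columns yields a header-only file.
    """
    if columns is None:
        if not rows:
            raise ValueError("empty row set requires explicit columns")
        columns = list(rows[0])
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(format_cell(row.get(col)) for col in columns) + "\n")
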