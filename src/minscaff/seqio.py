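"""Reading and writing of the sequence/scaffold formats the pipeline touches.

FASTA and FASTQ parsing is delegated to Biopython; this layer adds
transparent gzip handling, format auto-detection, base normalisation
(uppercase, non-ACGTN -> N) and the record-level validity checks the
downstream algorithms rely on.  AGP v2.1 is written directly (no installed
library emits it).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, TextIO

from Bio import SeqIO


class ParseError(ValueError):
    """A sequence file could not be parsed into valid records."""


_TABLE = bytearray(ord("N") for _ in range(256))
for _b in b"ACGTN":
    _TABLE[_b] = _b
    _TABLE[_b + 32] = _b  # lowercase
_TABLE = bytes(_TABLE)

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def normalise_seq(seq: str) -> str:
    """Uppercase a DNA string and replace non-ACGTN characters with N."""
    return seq.encode("ascii", errors="replace").translate(_TABLE).decode("ascii")


def reverse_complement(seq: str) -> str:
    return seq.encode("ascii").translate(_COMPLEMENT).decode("ascii")[::-1]


@dataclass
class SeqRecord:
    """One sequence record.

    ``id`` is the first whitespace-delimited header token; the full header
    is preserved in ``description`` but never used by the algorithms.
    ``qual`` (FASTQ) is parsed but ignored downstream — the methods here
    are quality-agnostic.
    """

    id: str
    seq: str
    qual: Optional[str] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("record with empty id")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ParseError(
                f"record {self.id!r}: quality length {len(self.qual)} != sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path: str | Path) -> TextIO:
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    return io.TextIOWrapper(raw)


def _detect_format(handle: TextIO) -> Optional[str]:
    pos = handle.tell()
    first = None
    while True:
        ch = handle.read(1)
        if ch == "":
            break
        if not ch.isspace():
            first = ch
            break
    handle.seek(pos)
    if first is None:
        return None
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ParseError(f"cannot detect format from leading character {first!r}")


def read_seq_file(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA or FASTQ file (plain or gzipped) into SeqRecords.

    Format is auto-detected from the first non-whitespace character,
    gzip from the magic bytes.  Bases are uppercased and non-ACGTN
    characters replaced with N.  Raises :class:`ParseError` for malformed
    records (mismatched FASTQ quality length, empty FASTA sequence,
    duplicate ids).
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        fmt = _detect_format(handle)
        if fmt is None:
            return records
        try:
            for i, rec in enumerate(SeqIO.parse(handle, fmt)):
                seq = normalise_seq(str(rec.seq))
                qual = None
                if fmt == "fastq":
                    qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
                if not seq:
                    raise ParseError(f"{path}: record {rec.id!r} (record #{i + 1}) has empty sequence")
                if rec.id in seen:
                    raise ParseError(f"{path}: duplicate record id {rec.id!r} (record #{i + 1})")
                seen.add(rec.id)
                records.append(SeqRecord(id=rec.id, seq=seq, qual=qual, description=rec.description))
        except ValueError as exc:  # Biopython parse failure
            if isinstance(exc, ParseError):
                raise
            raise ParseError(f"{path}: malformed record after {len(records)} records: {exc}") from exc
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, line_width: int = 60) -> None:
    """Write records as FASTA with sequence lines wrapped at ``line_width``."""
    if line_width < 1:
        raise ValueError("line_width must be positive")
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), line_width):
                out.write(rec.seq[i : i + line_width] + "\n")


def write_fastq(records: Iterable[SeqRecord], path: str | Path, default_qual: str = "I") -> None:
    """Write records as 4-line FASTQ, synthesising uniform qualities if absent."""
    with open(path, "w") as out:
        for rec in records:
            qual = rec.qual if rec.qual is not None else default_qual * len(rec.seq)
            out.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def clamped_gap(gap: Optional[int], min_gap: int) -> int:
    """Printed gap length: raw estimates below ``min_gap`` (incl. negative) are floored."""
    if gap is None:
        return min_gap
    return max(int(gap), min_gap)


def write_agp(
    paths: Sequence,
    contig_lengths: Mapping[str, int],
    out_path: str | Path,
    object_ids: Optional[Sequence[str]] = None,
    min_gap: int = 1,
) -> None:
    """Write scaffold paths as AGP v2.1.

    ``paths`` are :class:`~minscaff.layout.ScaffoldPath` objects (or any
    object with ``items``: a list of ``(contig_id, orientation, gap_after)``
    tuples).  Object coordinates are 1-based inclusive and contiguous;
    contigs are W components, gaps N components with the clamped gap length.
    """
    if object_ids is None:
        object_ids = [f"scaffold_{i + 1}" for i in range(len(paths))]
    with open(out_path, "w") as out:
        out.write("##agp-version\t2.1\n")
        for obj, spath in zip(object_ids, paths):
            pos = 0
            part = 0
            items = spath.items
            for idx, (cid, orient, gap_after) in enumerate(items):
                if cid not in contig_lengths:
                    raise ValueError(f"AGP path references unknown contig {cid!r}")
                clen = contig_lengths[cid]
                part += 1
                out.write(
                    f"{obj}\t{pos + 1}\t{pos + clen}\t{part}\tW\t{cid}\t1\t{clen}\t{orient}\n"
                )
                pos += clen
                if idx < len(items) - 1:
                    glen = clamped_gap(gap_after, min_gap)
                    part += 1
                    out.write(
                        f"{obj}\t{pos + 1}\t{pos + glen}\t{part}\tN\t{glen}\tscaffold\tyes\tpaired-ends\n"
                    )
                    pos += glen
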