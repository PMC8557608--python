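"""Pseudo-linked reads: tiling long reads into barcoded read pairs.

Linked-read correction logic expects barcoded short-read pairs whose
shared barcode marks a long source molecule.  Long reads provide that
molecule directly: each read is cut into non-overlapping tiles of
``fragment_size`` bp (default 500), every tile yields one FR-oriented pair
of fragment_size/2 mates, and all pairs from one read share a barcode.

Also here: automatic choice of the two correction parameters.  ``span``
(molecule extents required to bridge a position) scales with read depth as
0.25 x coverage; ``dist`` (merge distance for same-barcode placements) is
the median read length, so one read's tiles virtually always merge into a
single molecule extent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .seqio import SeqRecord, reverse_complement


@dataclass(frozen=True)
class CorrectionParams:
    """span: required spanning molecule extents; dist: bp merge distance
    for same-barcode placements; fragment_size: tile length in bp."""

    span: int
    dist: int
    fragment_size: int = 500

    def __post_init__(self) -> None:
        if self.span < 1:
            raise ValueError("span must be >= 1")
        if self.dist < 1:
            raise ValueError("dist must be >= 1")
        if self.fragment_size < 2 or self.fragment_size % 2:
            raise ValueError("fragment_size must be even and >= 2")


@dataclass(frozen=True)
class PseudoReadPair:
    """One tile of a long read as an FR pair sharing the read's barcode."""

    barcode: str
    read1: SeqRecord
    read2: SeqRecord
    source_read_id: str
    fragment_index: int
    fragment_start: int


def tile_reads(reads: Iterable[SeqRecord], fragment_size: int = 500) -> Iterator[PseudoReadPair]:
    """Cut each read into floor(len/fragment_size) tiles from position 0.

    Each tile becomes a pair: read1 = first half, read2 = reverse
    complement of the second half (standard FR mate geometry).  The
    trailing remainder shorter than a tile is discarded; reads shorter
    than one tile yield nothing.
    """
    if fragment_size < 2 or fragment_size % 2:
        raise ValueError("fragment_size must be even and >= 2")
    half = fragment_size // 2
    for ri, read in enumerate(reads):
        n_tiles = len(read.seq) // fragment_size
        if n_tiles == 0:
            continue
        barcode = f"{ri}_{read.id}"
        for t in range(n_tiles):
            start = t * fragment_size
            tile = read.seq[start : start + fragment_size]
            yield PseudoReadPair(
                barcode=barcode,
                read1=SeqRecord(id=f"{read.id}_f{t}/1 BX:Z:{barcode}", seq=tile[:half]),
                read2=SeqRecord(id=f"{read.id}_f{t}/2 BX:Z:{barcode}", seq=reverse_complement(tile[half:])),
                source_read_id=read.id,
                fragment_index=t,
                fragment_start=start,
            )


def compute_span(total_read_bp: int, G: int) -> int:
    """span = 0.25 x coverage (round half up), clamped to at least 1."""
    if G <= 0:
        raise ValueError("G must be positive")
    coverage = total_read_bp / G
    return max(1, int(0.25 * coverage + 0.5))


def compute_dist(reads: Iterable[SeqRecord], limit: int = 1_000_000) -> int:
    """Lower-median read length over the first ``limit`` reads."""
    lengths = []
    for i, read in enumerate(reads):
        if i >= limit:
            break
        lengths.append(len(read.seq))
    if not lengths:
        raise ValueError("no reads supplied")
    lengths.sort()
    return lengths[(len(lengths) - 1) // 2]


def write_interleaved(pairs: Iterable[PseudoReadPair], path: str) -> int:
    """Write pairs as interleaved FASTA with the barcode in the header.

    The output is consumable by linked-read tooling (for a downstream
    linked-read scaffolder, small k around 20 and a low Jaccard threshold
    around 0.05 are appropriate with these synthetic barcodes).  Returns
    the number of pairs written.
    """
    n = 0
    with open(path, "w") as out:
        for p in pairs:
            out.write(f">{p.read1.id}\n{p.read1.seq}\n>{p.read2.id}\n{p.read2.seq}\n")
            n += 1
    return n
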