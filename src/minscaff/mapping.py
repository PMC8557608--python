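"""Mapping long-read sketches against the unique-minimizer assembly index.

Each read minimizer found in the index yields a match; scanning matches in
read order and collapsing adjacent hits to the same contig produces an
ordered list of contig runs — the read's footprint across the draft.  Runs
are then filtered: contigs below the minimum size ``z`` are removed (small,
often repetitive sequences only add graph noise), as are *subsumed* runs,
whose read-coordinate extent lies entirely within another run's extent and
which therefore carry no ordering information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .sketch import AssemblyIndex, Sketch


@dataclass(frozen=True)
class MinimizerMatch:
    """A shared minimizer between a read and a contig."""

    hash: int
    read_pos: int
    read_strand: str
    contig_id: str
    contig_pos: int
    contig_strand: str

    @property
    def agree(self) -> bool:
        """True when the canonical k-mer lies on the same strand of read and contig."""
        return self.read_strand == self.contig_strand


@dataclass
class ContigRun:
    """A maximal run of consecutive read minimizers hitting one contig.

    ``orientation`` is the majority vote of per-match strand agreement:
    '+' when most matches agree in strand between read and contig, '-'
    when most disagree, ``None`` on an exact tie (weakly informative; such
    runs are excluded from pairing).
    """

    contig_id: str
    matches: list[MinimizerMatch]
    orientation: Optional[str]

    @classmethod
    def from_matches(cls, matches: list[MinimizerMatch]) -> "ContigRun":
        agree = sum(m.agree for m in matches)
        disagree = len(matches) - agree
        if agree > disagree:
            orient = "+"
        elif disagree > agree:
            orient = "-"
        else:
            orient = None
        return cls(matches[0].contig_id, matches, orient)

    @property
    def hit_count(self) -> int:
        return len(self.matches)

    @property
    def weakly_supported(self) -> bool:
        return self.hit_count == 1

    @property
    def read_start(self) -> int:
        return self.matches[0].read_pos

    @property
    def read_end(self) -> int:
        return self.matches[-1].read_pos

    @property
    def unanimous(self) -> bool:
        return all(m.agree for m in self.matches) or not any(m.agree for m in self.matches)


@dataclass
class ReadMapping:
    """Ordered contig runs of one read (no two consecutive runs share a contig)."""

    read_id: str
    runs: list[ContigRun]


def _collapse(matches: Sequence[MinimizerMatch]) -> list[ContigRun]:
    runs: list[ContigRun] = []
    block: list[MinimizerMatch] = []
    for m in matches:
        if block and m.contig_id != block[-1].contig_id:
            runs.append(ContigRun.from_matches(block))
            block = []
        block.append(m)
    if block:
        runs.append(ContigRun.from_matches(block))
    return runs


def map_read(read_sketch: Sketch, index: AssemblyIndex) -> ReadMapping:
    """Look up every read minimizer in the index and collapse into runs."""
    found, idx = index.lookup(read_sketch.hashes)
    matches: list[MinimizerMatch] = []
    for j in found.nonzero()[0]:
        i = int(idx[j])
        matches.append(
            MinimizerMatch(
                hash=int(read_sketch.hashes[j]),
                read_pos=int(read_sketch.pos[j]),
                read_strand="+" if read_sketch.fwd[j] else "-",
                contig_id=index.contig_ids[int(index.contig_idx[i])],
                contig_pos=int(index.pos[i]),
                contig_strand="+" if index.fwd[i] else "-",
            )
        )
    return ReadMapping(read_sketch.seq_id, _collapse(matches))


def _remove_subsumed(runs: list[ContigRun]) -> list[ContigRun]:
    """Drop runs whose read interval is contained in another run's interval.

    On identical intervals the run with more hits wins; remaining ties keep
    the earlier run.  Containment is judged on read coordinates (k-mer
    starts of the first/last match).
    """
    keep = []
    for i, ri in enumerate(runs):
        subsumed = False
        for j, rj in enumerate(runs):
            if i == j:
                continue
            if rj.read_start <= ri.read_start and ri.read_end <= rj.read_end:
                strictly = rj.read_start < ri.read_start or ri.read_end < rj.read_end
                if strictly or rj.hit_count > ri.hit_count or (
                    rj.hit_count == ri.hit_count and j < i
                ):
                    subsumed = True
                    break
        if not subsumed:
            keep.append(ri)
    return keep


def _merge_adjacent(runs: list[ContigRun]) -> list[ContigRun]:
    merged: list[ContigRun] = []
    for r in runs:
        if merged and merged[-1].contig_id == r.contig_id:
            merged[-1] = ContigRun.from_matches(merged[-1].matches + r.matches)
        else:
            merged.append(r)
    return merged


def filter_runs(mapping: ReadMapping, z: int, contig_lengths: Mapping[str, int]) -> ReadMapping:
    """Remove short-contig and subsumed runs, re-merging until stable.

    Removal can make two runs of the same contig adjacent; those are merged
    and the filter re-applied, so the operation is idempotent by
    construction.
    """
    runs = list(mapping.runs)
    while True:
        new = [r for r in runs if contig_lengths[r.contig_id] >= z]
        new = _remove_subsumed(new)
        new = _merge_adjacent(new)
        if [(r.contig_id, r.read_start, r.read_end, r.hit_count) for r in new] == [
            (r.contig_id, r.read_start, r.read_end, r.hit_count) for r in runs
        ]:
            return ReadMapping(mapping.read_id, new)
        runs = new


def mapping_tsv_row(mapping: ReadMapping) -> list[str]:
    """Verbose debug rows: read_id, contig, hits, orientation, read span."""
    return [
        f"{mapping.read_id}\t{r.contig_id}\t{r.hit_count}\t{r.orientation or '?'}\t{r.read_start}\t{r.read_end}"
        for r in mapping.runs
    ]
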