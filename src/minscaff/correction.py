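"""Misassembly detection and cutting from spanning molecule evidence.

Pseudo-linked read pairs are placed on the draft with the internal
minimizer mapper (small-read parameters, k=24/w=10 by default).  Same-
barcode placements on one contig that lie within ``dist`` bp of each other
merge into a *molecule extent* — a proxy for the span of the source long
read.  A contig position is considered correctly assembled when at least
``span`` extents bridge it with ``clearance`` bp to spare on both sides;
maximal unsupported stretches in the contig interior are cut at their
midpoint.  Contig ends (within ``terminal_exempt`` bp) are exempt: no
molecule can be expected to bridge past an end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .pseudo import CorrectionParams, compute_dist, compute_span, tile_reads
from .seqio import SeqRecord
from .sketch import AssemblyIndex, SketchParams, build_assembly_index, encode, hash_kmers, _select_minimizers, _UMAX


@dataclass(frozen=True)
class MoleculeExtent:
    """Merged same-barcode placement interval on one contig (0-based, half-open)."""

    barcode: str
    contig_id: str
    start: int
    end: int
    read_count: int


@dataclass(frozen=True)
class Breakpoint:
    """A putative misassembly: cut ``contig_id`` before position ``pos``."""

    contig_id: str
    pos: int


Placement = tuple[str, str, int, int]  # (barcode, contig_id, start, end)


def place_pseudo_reads(
    pairs: Iterable,
    index: AssemblyIndex,
    min_hits: int = 2,
) -> list[Placement]:
    """Place each pseudo-read mate on its best contig by minimizer votes.

    A mate is placed on the contig collecting most of its minimizer hits
    (ties: lowest contig index); the placement interval spans the matched
    minimizers, extended by k.  Mates with fewer than ``min_hits`` hits on
    the winning contig are discarded as unplaceable.
    """
    k = index.params.k
    w = index.params.w
    placements: list[Placement] = []
    for pair in pairs:
        for mate in (pair.read1, pair.read2):
            codes = encode(mate.seq)
            canon, _, valid = hash_kmers(codes, k)
            if len(canon) == 0:
                continue
            masked = np.where(valid, canon, _UMAX)
            pos = _select_minimizers(masked, w)
            if len(pos) == 0:
                continue
            found, idx = index.lookup(canon[pos])
            if not found.any():
                continue
            hit_idx = idx[found]
            cidx = index.contig_idx[hit_idx]
            counts = np.bincount(cidx)
            best = int(np.argmax(counts))
            on_best = hit_idx[cidx == best]
            if len(on_best) < min_hits:
                continue
            cpos = index.pos[on_best]
            placements.append(
                (
                    pair.barcode,
                    index.contig_ids[best],
                    int(cpos.min()),
                    int(cpos.max()) + k,
                )
            )
    return placements


def infer_molecules(
    placements: Sequence[Placement],
    dist: int,
    min_reads_per_molecule: int = 2,
) -> list[MoleculeExtent]:
    """Merge same-barcode placements within ``dist`` bp into molecule extents.

    Placements are grouped by (barcode, contig) and sorted by start; a
    placement starting within ``dist`` of the growing extent's end joins
    it, otherwise a new extent opens.  Extents backed by fewer than
    ``min_reads_per_molecule`` placements are discarded as noise.
    """
    out: list[MoleculeExtent] = []
    for barcode, contig, start, end in _iter_groups(placements, dist, min_reads_per_molecule):
        out.append(MoleculeExtent(barcode, contig, start, end[0], end[1]))
    return out


def _iter_groups(placements, dist, min_reads):
    ordered = sorted(placements)
    cur = None  # (barcode, contig, start, end, count)
    for barcode, contig, start, end in ordered:
        if cur is not None and cur[0] == barcode and cur[1] == contig and start - cur[3] <= dist:
            cur = (cur[0], cur[1], cur[2], max(cur[3], end), cur[4] + 1)
        else:
            if cur is not None and cur[4] >= min_reads:
                yield cur[0], cur[1], cur[2], (cur[3], cur[4])
            cur = (barcode, contig, start, end, 1)
    if cur is not None and cur[4] >= min_reads:
        yield cur[0], cur[1], cur[2], (cur[3], cur[4])


def support_depth(
    contig_length: int,
    extents: Sequence[MoleculeExtent],
    clearance: int = 250,
) -> np.ndarray:
    """Per-position count of molecule extents bridging with ``clearance`` to spare.

    Position p is bridged by an extent when start < p - clearance and
    end > p + clearance.
    """
    cover = np.zeros(contig_length + 1, dtype=np.int32)
    for ext in extents:
        a = max(ext.start + clearance + 1, 0)  # first bridged position
        b = min(ext.end - clearance, contig_length)  # one past the last
        if a < b:
            cover[a] += 1
            cover[b] -= 1
    return np.cumsum(cover[:-1])


def find_unsupported(
    contig_length: int,
    extents: Sequence[MoleculeExtent],
    span: int,
    clearance: int = 250,
    terminal_exempt: int = 0,
    contig_id: str = "",
) -> list[Breakpoint]:
    """Breakpoints at the midpoints of interior unsupported stretches.

    A position p is supported when >= ``span`` extents satisfy
    start < p - clearance and end > p + clearance.  Only positions in
    [terminal_exempt, L - terminal_exempt) are examined — nothing can
    bridge past a contig end.  ``span`` <= 0 disables cutting.
    """
    if span <= 0:
        return []
    lo = max(terminal_exempt, 1)
    hi = min(contig_length - terminal_exempt, contig_length - 1)
    if lo >= hi:
        return []
    depth = support_depth(contig_length, extents, clearance)
    unsupported = depth[lo:hi] < span
    breaks: list[Breakpoint] = []
    i = 0
    n = hi - lo
    while i < n:
        if unsupported[i]:
            j = i
            while j < n and unsupported[j]:
                j += 1
            mid = lo + (i + j) // 2
            if 0 < mid < contig_length:
                breaks.append(Breakpoint(contig_id, mid))
            i = j
        else:
            i += 1
    return breaks


def cut_assembly(
    contigs: Sequence[SeqRecord],
    breakpoints: Sequence[Breakpoint],
    min_fragment_len: int = 100,
) -> tuple[list[SeqRecord], list[tuple[str, int]]]:
    """Split contigs at their breakpoints.

    Fragments are named ``{id}-{ordinal}`` (1-based); fragments shorter
    than ``min_fragment_len`` are dropped and returned in the log as
    (fragment_id, length).  Contigs without breakpoints pass through with
    their original ids.
    """
    by_contig: dict[str, list[int]] = {}
    lengths = {c.id: len(c.seq) for c in contigs}
    for bp in breakpoints:
        if bp.contig_id not in lengths:
            raise ValueError(f"breakpoint on unknown contig {bp.contig_id!r}")
        if not 0 < bp.pos < lengths[bp.contig_id]:
            raise ValueError(
                f"breakpoint {bp.pos} outside contig {bp.contig_id!r} (length {lengths[bp.contig_id]})"
            )
        by_contig.setdefault(bp.contig_id, []).append(bp.pos)
    out: list[SeqRecord] = []
    dropped: list[tuple[str, int]] = []
    for contig in contigs:
        cuts = sorted(set(by_contig.get(contig.id, [])))
        if not cuts:
            out.append(contig)
            continue
        bounds = [0] + cuts + [len(contig.seq)]
        for i in range(len(bounds) - 1):
            frag = contig.seq[bounds[i] : bounds[i + 1]]
            fid = f"{contig.id}-{i + 1}"
            if len(frag) < min_fragment_len:
                dropped.append((fid, len(frag)))
            else:
                out.append(SeqRecord(id=fid, seq=frag))
    return out, dropped


@dataclass
class CorrectionResult:
    contigs: list[SeqRecord]
    breakpoints: list[Breakpoint]
    dropped: list[tuple[str, int]]
    params: CorrectionParams
    extents: list[MoleculeExtent]


def correct_assembly(
    contigs: Sequence[SeqRecord],
    reads: Sequence[SeqRecord],
    G: int,
    fragment_size: int = 500,
    span: Optional[int] = None,
    dist: Optional[int] = None,
    sketch_params: SketchParams = SketchParams(k=24, w=10),
    min_reads_per_molecule: int = 2,
    clearance: Optional[int] = None,
    terminal_exempt: Optional[int] = None,
    min_fragment_len: int = 100,
) -> CorrectionResult:
    """Full correction stage: tile, place, merge, detect, cut.

    ``span`` defaults to 0.25 x read coverage of G; ``dist`` to the median
    read length; ``clearance`` to fragment_size/2; ``terminal_exempt`` to
    ``dist``.
    """
    if dist is None:
        dist = compute_dist(reads)
    if span is None:
        span = compute_span(sum(len(r.seq) for r in reads), G)
    if clearance is None:
        clearance = fragment_size // 2
    if terminal_exempt is None:
        terminal_exempt = dist
    params = CorrectionParams(span=span, dist=dist, fragment_size=fragment_size)

    index = build_assembly_index(contigs, sketch_params)
    placements = place_pseudo_reads(tile_reads(reads, fragment_size), index)
    extents = infer_molecules(placements, dist, min_reads_per_molecule)

    per_contig: dict[str, list[MoleculeExtent]] = {}
    for ext in extents:
        per_contig.setdefault(ext.contig_id, []).append(ext)
    breakpoints: list[Breakpoint] = []
    for contig in contigs:
        breakpoints.extend(
            find_unsupported(
                len(contig.seq),
                per_contig.get(contig.id, []),
                span,
                clearance=clearance,
                terminal_exempt=terminal_exempt,
                contig_id=contig.id,
            )
        )
    corrected, dropped = cut_assembly(contigs, breakpoints, min_fragment_len)
    return CorrectionResult(corrected, breakpoints, dropped, params, extents)


def write_breakpoints_bed(breakpoints: Sequence[Breakpoint], path: str) -> None:
    """BED (0-based, half-open) single-base intervals at each cut position."""
    with open(path, "w") as out:
        for bp in breakpoints:
            out.write(f"{bp.contig_id}\t{bp.pos}\t{bp.pos + 1}\tbreakpoint\n")
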