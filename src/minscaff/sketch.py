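"""Ordered canonical-k-mer minimizer sketches and the unique-minimizer index.

A minimizer sketch thins a sequence to the k-mers that minimise a
strand-neutral 64-bit hash within each sliding window of ``w`` consecutive
k-mer starts.  Hashing follows the classic rolling scheme for nucleotide
k-mers: each base contributes a fixed 64-bit constant barrel-rotated by its
offset, XOR-combined over the k-mer; the canonical hash is the minimum of
the forward-strand and reverse-complement values, so a k-mer and its
reverse complement always hash identically.  The whole computation is
vectorised with numpy via prefix-XOR over per-position rotated constants.

The assembly index keeps only minimizers whose hash occurs exactly once
across all contig sketches; repeated minimizers would produce ambiguous
mappings and are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .seqio import SeqRecord, reverse_complement

_U64 = np.uint64
_UMAX = np.uint64(0xFFFFFFFFFFFFFFFF)

# Fixed per-base constants (arbitrary, seedless, shared across runs and
# platforms); index 4 is the N placeholder and never contributes to a
# valid k-mer hash.
_SEED = np.array(
    [
        0x3C8BFBB395C60474,
        0x3193C18562A02B4C,
        0x20323ED082572324,
        0x295549F54BE24456,
        0x0000000000000000,
    ],
    dtype=_U64,
)
# Complement: A<->T, C<->G, N->N.
_RCSEED = _SEED[[3, 2, 1, 0, 4]]

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i


@dataclass(frozen=True)
class SketchParams:
    """k-mer length ``k`` (bases) and window size ``w`` (k-mers)."""

    k: int = 32
    w: int = 100

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ValueError("k must be >= 4")
        if self.w < 1:
            raise ValueError("w must be >= 1")


@dataclass(frozen=True)
class MinimizerRecord:
    """One minimizer occurrence: canonical hash, source id, 0-based k-mer
    start on the forward strand, and '+' when the canonical k-mer is the
    forward-strand k-mer."""

    hash: int
    seq_id: str
    pos: int
    strand: str


@dataclass
class Sketch:
    """Ordered minimizer sketch of one sequence (positions strictly increasing).

    Stored as parallel numpy arrays for speed; ``records`` materialises
    :class:`MinimizerRecord` objects on demand.
    """

    seq_id: str
    pos: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    hashes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=_U64))
    fwd: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def records(self) -> list[MinimizerRecord]:
        return [
            MinimizerRecord(int(h), self.seq_id, int(p), "+" if f else "-")
            for h, p, f in zip(self.hashes, self.pos, self.fwd)
        ]


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A0 C1 G2 T3, anything else 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _rol(x: np.ndarray, r: np.ndarray) -> np.ndarray:
    r = r & _U64(63)
    return (x << r) | (x >> ((_U64(64) - r) & _U64(63)))


def _ror(x: np.ndarray, r: np.ndarray) -> np.ndarray:
    r = r & _U64(63)
    return (x >> r) | (x << ((_U64(64) - r) & _U64(63)))


def _forward_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling forward-strand hashes of all k-mers, vectorised.

    h(i) = XOR_{j<k} rol(seed[c[i+j]], k-1-j)  (rotations mod 64), computed
    as a windowed prefix-XOR of position-rotated constants followed by a
    window-dependent counter-rotation.
    """
    n = len(codes)
    t = np.arange(n, dtype=_U64)
    u = _ror(_SEED[codes], t)
    p = np.zeros(n + 1, dtype=_U64)
    np.bitwise_xor.accumulate(u, out=p[1:])
    x = p[k:] ^ p[: n - k + 1]
    i = np.arange(n - k + 1, dtype=_U64)
    return _rol(x, _U64(k - 1) + i)


def _reverse_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Hashes of the reverse complement of each k-mer (same scheme)."""
    n = len(codes)
    t = np.arange(n, dtype=_U64)
    v = _rol(_RCSEED[codes], t)
    p = np.zeros(n + 1, dtype=_U64)
    np.bitwise_xor.accumulate(v, out=p[1:])
    y = p[k:] ^ p[: n - k + 1]
    i = np.arange(n - k + 1, dtype=_U64)
    return _ror(y, i)


def hash_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical hash, forward-strand flag and validity for every k-mer start.

    A k-mer is invalid when it contains an N (code 4); its hash slot is
    undefined and masked by callers.
    """
    n = len(codes)
    if n < k:
        z = np.empty(0, dtype=_U64)
        return z, np.empty(0, dtype=bool), np.empty(0, dtype=bool)
    fh = _forward_hashes(codes, k)
    rh = _reverse_hashes(codes, k)
    canon = np.minimum(fh, rh)
    fwd = fh <= rh
    bad = np.cumsum(np.concatenate(([0], (codes == 4).astype(np.int64))))
    valid = (bad[k:] - bad[: n - k + 1]) == 0
    return canon, fwd, valid


def canonical_hash(kmer: str) -> tuple[int, str]:
    """Strand-neutral hash of a single k-mer, with the canonical strand.

    Reference (non-rolling) implementation: hashes the k-mer and its
    reverse complement independently and takes the minimum.  Returns
    ``(hash, '+')`` when the forward k-mer is the canonical representative
    (ties, e.g. palindromes, report '+').
    """
    k = len(kmer)
    seeds = {b: int(_SEED[c]) for b, c in zip("ACGT", range(4))}
    mask = (1 << 64) - 1

    def _plain(s: str) -> int:
        h = 0
        for j, base in enumerate(s):
            if base not in seeds:
                raise ValueError(f"invalid character in k-mer {kmer!r}")
            r = (k - 1 - j) % 64
            rolled = ((seeds[base] << r) | (seeds[base] >> (64 - r))) & mask if r else seeds[base]
            h ^= rolled
        return h

    fh = _plain(kmer)
    rh = _plain(reverse_complement(kmer))
    if fh <= rh:
        return fh, "+"
    return rh, "-"


_CHUNK = 1 << 18


def _select_minimizers(masked: np.ndarray, w: int) -> np.ndarray:
    """Positions selected as window minima (leftmost tie wins).

    ``masked`` holds canonical hashes with invalid k-mers set to uint64
    max.  Windows are ``w`` consecutive k-mer start positions, slid one
    position at a time; a window whose k-mers are all invalid emits
    nothing.  Sequences with fewer than ``w`` k-mers form one degenerate
    window over everything available.
    """
    nk = len(masked)
    if nk == 0:
        return np.empty(0, dtype=np.int64)
    if nk < w:
        a = int(np.argmin(masked))
        if masked[a] == _UMAX:
            return np.empty(0, dtype=np.int64)
        return np.array([a], dtype=np.int64)
    nwin = nk - w + 1
    sel = np.zeros(nk, dtype=bool)
    for s in range(0, nwin, _CHUNK):
        e = min(s + _CHUNK, nwin)
        view = np.lib.stride_tricks.sliding_window_view(masked[s : e + w - 1], w)
        arg = view.argmin(axis=1)
        posn = s + np.arange(e - s, dtype=np.int64) + arg
        sel[posn[masked[posn] != _UMAX]] = True
    return np.nonzero(sel)[0].astype(np.int64)


def sketch_codes(seq_id: str, codes: np.ndarray, params: SketchParams) -> Sketch:
    canon, fwd, valid = hash_kmers(codes, params.k)
    if len(canon) == 0:
        return Sketch(seq_id)
    masked = np.where(valid, canon, _UMAX)
    pos = _select_minimizers(masked, params.w)
    return Sketch(seq_id, pos=pos, hashes=canon[pos], fwd=fwd[pos])


def sketch_sequence(record: SeqRecord | tuple[str, str], params: SketchParams) -> Sketch:
    """Ordered minimizer sketch of one sequence.

    For each window of ``w`` consecutive k-mer starts the minimum-hash
    valid k-mer is selected (leftmost on ties); selections repeated by
    overlapping windows are collapsed.  Sequences shorter than ``k``
    yield an empty sketch.
    """
    if isinstance(record, tuple):
        seq_id, seq = record
    else:
        seq_id, seq = record.id, record.seq
    return sketch_codes(seq_id, encode(seq), params)


class AssemblyIndex:
    """Unique-minimizer index of a draft assembly.

    Maps each hash that occurs exactly once across all contig sketches to
    its (contig, position, strand); repeated hashes are discarded to avoid
    ambiguous repeat-driven mappings.
    """

    def __init__(
        self,
        params: SketchParams,
        contig_ids: list[str],
        contig_lengths: dict[str, int],
        hashes: np.ndarray,
        contig_idx: np.ndarray,
        pos: np.ndarray,
        fwd: np.ndarray,
    ) -> None:
        self.params = params
        self.contig_ids = contig_ids
        self.contig_lengths = contig_lengths
        order = np.argsort(hashes, kind="stable")
        self.hashes = hashes[order]
        self.contig_idx = contig_idx[order]
        self.pos = pos[order]
        self.fwd = fwd[order]

    def __len__(self) -> int:
        return len(self.hashes)

    def __contains__(self, h: int) -> bool:
        i = int(np.searchsorted(self.hashes, _U64(h)))
        return i < len(self.hashes) and self.hashes[i] == _U64(h)

    def lookup(self, hashes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised membership: (found mask, index into the index arrays)."""
        idx = np.searchsorted(self.hashes, hashes)
        idx = np.minimum(idx, max(len(self.hashes) - 1, 0))
        found = np.zeros(len(hashes), dtype=bool)
        if len(self.hashes):
            found = self.hashes[idx] == hashes
        return found, idx

    def get(self, h: int) -> MinimizerRecord | None:
        i = int(np.searchsorted(self.hashes, _U64(h)))
        if i >= len(self.hashes) or self.hashes[i] != _U64(h):
            return None
        return MinimizerRecord(
            int(self.hashes[i]),
            self.contig_ids[int(self.contig_idx[i])],
            int(self.pos[i]),
            "+" if self.fwd[i] else "-",
        )


def build_assembly_index(contigs: Sequence[SeqRecord], params: SketchParams) -> AssemblyIndex:
    """Sketch every contig and index the minimizers unique across the assembly."""
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate contig ids: {dupes}")
    lengths = {c.id: len(c.seq) for c in contigs}
    all_h, all_ci, all_p, all_f = [], [], [], []
    for ci, contig in enumerate(contigs):
        sk = sketch_sequence(contig, params)
        all_h.append(sk.hashes)
        all_ci.append(np.full(len(sk), ci, dtype=np.int32))
        all_p.append(sk.pos)
        all_f.append(sk.fwd)
    hashes = np.concatenate(all_h) if all_h else np.empty(0, dtype=_U64)
    uniq, counts = np.unique(hashes, return_counts=True)
    unique_hashes = uniq[counts == 1]
    keep = np.isin(hashes, unique_hashes, assume_unique=False)
    return AssemblyIndex(
        params,
        ids,
        lengths,
        hashes[keep],
        np.concatenate(all_ci)[keep] if all_ci else np.empty(0, dtype=np.int32),
        np.concatenate(all_p)[keep] if all_p else np.empty(0, dtype=np.int64),
        np.concatenate(all_f)[keep] if all_f else np.empty(0, dtype=bool),
    )


def dump_sketch_tsv(sketch: Sketch, path: str) -> None:
    """Debug dump: seq_id, pos, strand, hash — one minimizer per line."""
    with open(path, "w") as out:
        for h, p, f in zip(sketch.hashes, sketch.pos, sketch.fwd):
            out.write(f"{sketch.seq_id}\t{int(p)}\t{'+' if f else '-'}\t{int(h)}\n")
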