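"""Synthetic genomes, fragmented/chimeric drafts and error-bearing long reads.

Every stage of the pipeline is testable without downloads: a random genome
is fragmented into contigs (with the inter-contig gap bases removed, so the
true gaps are known), optional chimeric contigs are planted by joining
halves of contigs from distant genome regions, and long reads are sampled
from the *genome* (not the draft) with an ONT-like error profile.  All
generators are pure functions of their parameters and seed, and return
truth tables sufficient to score join recovery, orientation accuracy, gap
error and breakpoint recovery.

Coordinates are 0-based half-open throughout; strands '+'/'-'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .correction import Breakpoint
from .seqio import SeqRecord, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TruthTable:
    """Ground truth for a simulation.

    ``contig_order``: contigs as (id, orientation) in genome order;
    ``gaps``: true gap sizes between consecutive contigs;
    ``intervals``: contig id -> (genome start, genome end, orientation);
    ``junctions``: planted chimera junctions as (contig id, position);
    ``read_intervals``: read id -> (genome start, genome end, strand).
    """

    contig_order: list[tuple[str, str]] = field(default_factory=list)
    gaps: list[int] = field(default_factory=list)
    intervals: dict[str, tuple[int, int, str]] = field(default_factory=dict)
    junctions: list[tuple[str, int]] = field(default_factory=list)
    read_intervals: dict[str, tuple[int, int, str]] = field(default_factory=dict)

    def true_adjacencies(self) -> dict[frozenset, tuple[tuple[str, str], tuple[str, str], int]]:
        """Unordered contig pair -> (oriented left, oriented right, gap)."""
        adj = {}
        for i in range(len(self.contig_order) - 1):
            a, b = self.contig_order[i], self.contig_order[i + 1]
            adj[frozenset((a[0], b[0]))] = (a, b, self.gaps[i])
        return adj


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_genome(length: int, gc: float = 0.5, seed: int = 0, seq_id: str = "genome") -> SeqRecord:
    """Random genome with i.i.d. bases at the given GC content."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1 - gc) / 2
    probs = [at, gc / 2, gc / 2, at]  # A C G T
    codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
    return SeqRecord(id=seq_id, seq=_codes_to_str(codes))


def fragment_genome(
    genome: SeqRecord,
    n_contigs: int,
    gap_range: tuple[int, int] = (50, 500),
    seed: int = 0,
    min_len: int = 2000,
) -> tuple[list[SeqRecord], TruthTable]:
    """Partition the genome into contigs with gaps removed between them.

    Gap sizes are drawn uniformly from ``gap_range`` (inclusive) and those
    bases are dropped from the contigs; a random subset of contigs is
    reverse-complemented and the output order shuffled.  The truth table
    records genome order, orientations and gap sizes.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    rng = np.random.default_rng(seed)
    L = len(genome.seq)
    gaps = [int(rng.integers(gap_range[0], gap_range[1] + 1)) for _ in range(n_contigs - 1)]
    extra = L - sum(gaps) - n_contigs * min_len
    if extra < 0:
        raise ValueError("genome too short for requested contigs and gaps")
    cuts = np.sort(rng.integers(0, extra + 1, size=n_contigs - 1))
    block_extra = np.diff(np.concatenate(([0], cuts, [extra])))
    block_lens = (min_len + block_extra).astype(int)

    truth = TruthTable()
    contigs: list[SeqRecord] = []
    pos = 0
    for i, blen in enumerate(block_lens):
        cid = f"ctg{i + 1}"
        orient = "-" if rng.random() < 0.5 and n_contigs > 1 else "+"
        seq = genome.seq[pos : pos + blen]
        contigs.append(SeqRecord(id=cid, seq=seq if orient == "+" else reverse_complement(seq)))
        truth.contig_order.append((cid, orient))
        truth.intervals[cid] = (pos, pos + blen, orient)
        pos += blen
        if i < n_contigs - 1:
            pos += gaps[i]
    truth.gaps = gaps
    order = rng.permutation(len(contigs))
    return [contigs[i] for i in order], truth


def induce_chimeras(
    contigs: Sequence[SeqRecord],
    n_junctions: int,
    seed: int = 0,
    truth: Optional[TruthTable] = None,
) -> tuple[list[SeqRecord], TruthTable]:
    """Plant chimeric contigs by joining halves from distant genome regions.

    Each junction consumes two donor contigs that are not adjacent in the
    true genome order (when ``truth`` is given): the chimera is the first
    half of one donor concatenated with the second half of the other, with
    the junction position recorded.  The unused donor halves are kept as
    truncated contigs so no sequence is lost.
    """
    if n_junctions == 0:
        return list(contigs), TruthTable()
    if 2 * n_junctions > len(contigs):
        raise ValueError("not enough contigs to donate halves")
    rng = np.random.default_rng(seed)
    order_of = {}
    if truth is not None:
        order_of = {cid: i for i, (cid, _) in enumerate(truth.contig_order)}

    ids = list(range(len(contigs)))
    donors: list[tuple[int, int]] = []
    used: set[int] = set()
    attempts = 0
    while len(donors) < n_junctions and attempts < 10000:
        attempts += 1
        i, j = (int(x) for x in rng.choice(len(contigs), size=2, replace=False))
        if i in used or j in used:
            continue
        if order_of and abs(order_of[contigs[i].id] - order_of[contigs[j].id]) <= 1:
            continue
        donors.append((i, j))
        used.update((i, j))
    if len(donors) < n_junctions:
        raise ValueError("could not select enough non-adjacent donor pairs")

    chimera_truth = TruthTable()
    out: list[SeqRecord] = []
    for t, (i, j) in enumerate(donors):
        a, b = contigs[i], contigs[j]
        ha, hb = len(a.seq) // 2, len(b.seq) // 2
        cid = f"chimera{t + 1}"
        out.append(SeqRecord(id=cid, seq=a.seq[:ha] + b.seq[hb:]))
        chimera_truth.junctions.append((cid, ha))
        out.append(SeqRecord(id=f"{a.id}_r", seq=a.seq[ha:]))
        out.append(SeqRecord(id=f"{b.id}_l", seq=b.seq[:hb]))
    for idx, c in enumerate(contigs):
        if idx not in used:
            out.append(c)
    return out, chimera_truth


def simulate_reads(
    genome: SeqRecord,
    coverage: float,
    mean_len: int = 15000,
    error_rate: float = 0.0,
    sub_ins_del: tuple[float, float, float] = (0.4, 0.3, 0.3),
    seed: int = 0,
    min_len: int = 1000,
    sigma: float = 0.25,
) -> tuple[list[SeqRecord], TruthTable]:
    """Sample long reads uniformly from both strands of the genome.

    Lengths are lognormal with the requested mean (log-sd ``sigma``),
    truncated to [min_len, genome length]; errors are i.i.d. per base and
    split into substitutions/insertions/deletions by ``sub_ins_del``
    (default 40/30/30, a simple nanopore-like profile).  Reads are drawn
    until total bp reaches coverage x genome length.  True source
    intervals and strands are recorded.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if abs(sum(sub_ins_del) - 1.0) > 1e-9:
        raise ValueError("sub/ins/del fractions must sum to 1")
    rng = np.random.default_rng(seed)
    L = len(genome.seq)
    genome_codes = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    code_of = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code_of[b] = i
    gcodes = code_of[genome_codes]

    target_bp = coverage * L
    mu = np.log(mean_len) - sigma**2 / 2
    reads: list[SeqRecord] = []
    truth = TruthTable()
    total = 0
    i = 0
    while total < target_bp:
        rlen = int(np.clip(rng.lognormal(mu, sigma), min_len, L))
        start = int(rng.integers(0, L - rlen + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        codes = gcodes[start : start + rlen].copy()
        if strand == "-":
            codes = (3 - codes)[::-1]
        if error_rate > 0:
            codes = _apply_errors(codes, error_rate, sub_ins_del, rng)
        rid = f"read{i + 1}"
        reads.append(SeqRecord(id=rid, seq=_codes_to_str(codes)))
        truth.read_intervals[rid] = (start, start + rlen, strand)
        total += len(codes)
        i += 1
    return reads, truth


def _apply_errors(codes: np.ndarray, rate: float, split, rng) -> np.ndarray:
    n = len(codes)
    err = rng.random(n) < rate
    kind = rng.choice(3, size=n, p=list(split))  # 0 sub, 1 ins, 2 del
    sub = err & (kind == 0)
    ins = err & (kind == 1)
    dele = err & (kind == 2)
    codes = codes.copy()
    if sub.any():
        codes[sub] = (codes[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
    counts = np.ones(n, dtype=np.int64)
    counts[ins] = 2
    counts[dele] = 0
    out = np.repeat(codes, counts)
    if ins.any():
        # the duplicated copy (second of the pair) becomes a random base
        ins_out = np.cumsum(counts)[ins] - 1
        out[ins_out] = rng.integers(0, 4, size=len(ins_out))
    return out


# ---------------------------------------------------------------------------
# Scoring against truth


@dataclass
class JoinScore:
    n_true: int
    recovered: int
    false_joins: int
    orientation_errors: int
    gap_errors: list[int]  # estimate - truth, for recovered true joins


def score_joins(paths: Sequence, truth: TruthTable) -> JoinScore:
    """Score layout joins against the true contig order.

    A join between consecutive path entries counts as recovered when the
    contig pair is adjacent in the genome; its orientation is correct when
    the oriented pair (or its mirror) matches truth.  Joins between
    non-adjacent pairs are false joins.
    """
    adj = truth.true_adjacencies()
    recovered = 0
    false_joins = 0
    orientation_errors = 0
    gap_errors: list[int] = []
    for path in paths:
        for i in range(len(path.items) - 1):
            a_id, a_o, gap = path.items[i]
            b_id, b_o, _ = path.items[i + 1]
            key = frozenset((a_id, b_id))
            if key not in adj:
                false_joins += 1
                continue
            (ta, toa), (tb, tob), tgap = adj[key]
            if (a_id, a_o, b_id, b_o) == (ta, toa, tb, tob) or (
                a_id,
                a_o,
                b_id,
                b_o,
            ) == (tb, _flip(tob), ta, _flip(toa)):
                recovered += 1
                if gap is not None:
                    gap_errors.append(int(gap) - tgap)
            else:
                orientation_errors += 1
    return JoinScore(
        n_true=len(adj),
        recovered=recovered,
        false_joins=false_joins,
        orientation_errors=orientation_errors,
        gap_errors=gap_errors,
    )


def _flip(o: str) -> str:
    return "-" if o == "+" else "+"


@dataclass
class BreakpointScore:
    n_junctions: int
    detected: int
    cuts_on_clean_contigs: int


def score_breakpoints(
    breakpoints: Sequence[Breakpoint],
    chimera_truth: TruthTable,
    tol: int = 500,
) -> BreakpointScore:
    """Count junctions detected within ``tol`` bp and cuts on clean contigs."""
    junctions = chimera_truth.junctions
    chimeric = {cid for cid, _ in junctions}
    detected = 0
    for cid, pos in junctions:
        if any(bp.contig_id == cid and abs(bp.pos - pos) <= tol for bp in breakpoints):
            detected += 1
    clean_cuts = sum(1 for bp in breakpoints if bp.contig_id not in chimeric)
    return BreakpointScore(len(junctions), detected, clean_cuts)


def write_truth_tsv(truth: TruthTable, path: str) -> None:
    """Dump a truth table as TSV sections (order, gaps, junctions, reads)."""
    with open(path, "w") as out:
        for (cid, orient) in truth.contig_order:
            out.write(f"ORDER\t{cid}\t{orient}\n")
        for g in truth.gaps:
            out.write(f"GAP\t{g}\n")
        for cid, pos in truth.junctions:
            out.write(f"JUNCTION\t{cid}\t{pos}\n")
        for rid, (s, e, strand) in truth.read_intervals.items():
            out.write(f"READ\t{rid}\t{s}\t{e}\t{strand}\n")
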