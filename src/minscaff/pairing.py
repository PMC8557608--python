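"""Turning a read's filtered contig runs into oriented contig pairs.

Consecutive runs give the obvious adjacent pairings; for run lists of up
to ``f`` contigs every ordered pair (transitive pairings included) is
emitted, while longer lists only bridge across *weakly supported*
intervening contigs (single minimizer hit) to bound the combinatorics.

Orientation and gap size come from the terminal minimizer hits of the two
runs: mA, the last minimizer of the upstream run, and mB, the first of the
downstream run.  A contig is oriented '+' when its terminal minimizer lies
on the same strand in the contig as in the read.  The gap is the read-space
distance between mA and mB corrected by each minimizer's distance to its
contig end (in oriented contig coordinates); it can be negative when the
contigs overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .mapping import ContigRun, ReadMapping


@dataclass(frozen=True)
class PairingParams:
    """``f``: maximum run-list length for exhaustive transitive pairing;
    ``a``: minimum anchoring-read support per pair (applied in the graph)."""

    f: int = 10
    a: int = 1

    def __post_init__(self) -> None:
        if self.f < 2:
            raise ValueError("f must be >= 2")
        if self.a < 0:
            raise ValueError("a must be >= 0")


@dataclass(frozen=True)
class OrientedPair:
    """An inferred join cA -> cB with orientations, per-read gap estimate,
    and whether the supporting read anchors both contigs (>= 2 minimizers
    on each)."""

    source: tuple[str, str]
    target: tuple[str, str]
    gap_estimate: int
    is_anchor: bool
    read_id: str


def _flip(o: str) -> str:
    return "-" if o == "+" else "+"


def orient_pair(run_a: ContigRun, run_b: ContigRun) -> tuple[str, str]:
    """Orientations of (cA, cB) from the strands of the terminal minimizers."""
    m_a = run_a.matches[-1]
    m_b = run_b.matches[0]
    return ("+" if m_a.agree else "-", "+" if m_b.agree else "-")


def oriented_pos(pos: int, orientation: str, contig_len: int, k: int) -> int:
    """k-mer start in oriented-contig coordinates ('-' mirrors the k-mer)."""
    if orientation == "+":
        return pos
    return contig_len - k - pos


def estimate_gap(
    run_a: ContigRun,
    run_b: ContigRun,
    orientations: tuple[str, str],
    contig_lengths: Mapping[str, int],
    k: int,
) -> int:
    """Signed gap between oriented cA and cB suggested by one read.

    With terminal minimizers at read positions rA <= rB and oriented contig
    positions pA', pB', the gap is (rB - rA) - (LA - pA') - pB': the read
    distance between the two k-mer starts minus the stretch of each contig
    that lies between its minimizer and the joined end.  Exact on
    error-free reads; negative values indicate overlap.
    """
    o_a, o_b = orientations
    m_a = run_a.matches[-1]
    m_b = run_b.matches[0]
    la = contig_lengths[run_a.contig_id]
    lb = contig_lengths[run_b.contig_id]
    pa = oriented_pos(m_a.contig_pos, o_a, la, k)
    pb = oriented_pos(m_b.contig_pos, o_b, lb, k)
    return (m_b.read_pos - m_a.read_pos) - (la - pa) - pb


def infer_pairs(
    mapping: ReadMapping,
    contig_lengths: Mapping[str, int],
    k: int,
    params: PairingParams = PairingParams(),
) -> list[OrientedPair]:
    """All oriented pairs suggested by one filtered read mapping.

    Runs with tied strand votes, or with internal strand disagreement
    (an apparent inversion within the run), are excluded: their
    orientation evidence is not trustworthy.  Pairs are recorded in
    read-coordinate order; the reverse twin is materialised by the graph.
    """
    runs = [r for r in mapping.runs if r.orientation is not None and r.unanimous]
    m = len(runs)
    pairs: list[OrientedPair] = []
    if m < 2:
        return pairs
    for i in range(m):
        for j in range(i + 1, m):
            if m > params.f and j > i + 1:
                if not all(runs[t].weakly_supported for t in range(i + 1, j)):
                    continue
            run_a, run_b = runs[i], runs[j]
            if run_a.contig_id == run_b.contig_id:
                continue
            orients = orient_pair(run_a, run_b)
            gap = estimate_gap(run_a, run_b, orients, contig_lengths, k)
            pairs.append(
                OrientedPair(
                    source=(run_a.contig_id, orients[0]),
                    target=(run_b.contig_id, orients[1]),
                    gap_estimate=gap,
                    is_anchor=run_a.hit_count >= 2 and run_b.hit_count >= 2,
                    read_id=mapping.read_id,
                )
            )
    return pairs
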