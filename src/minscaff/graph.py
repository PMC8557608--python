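"""The doubled directed scaffold graph.

Every contig appears as two nodes, one per orientation.  A tallied pair
(A^oA -> B^oB) is therefore represented twice: once as stated and once as
its *twin* (B^~oB -> A^~oA) — traversing B reverse-complemented and then A
reverse-complemented describes the same join from the other side.  Edges
are stored once under a canonical key, with the twin view materialised on
access, so the two directions can never drift apart.

Edge weights: the number of distinct supporting reads, the number of
distinct *anchoring* reads (>= 2 minimizers on both contigs), and the
median (lower median) of the per-read gap estimates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

from .pairing import OrientedPair

Node = tuple[str, str]  # (contig_id, orientation)
EdgeKey = tuple[str, str, str, str]  # (cA, oA, cB, oB)


def _flip(o: str) -> str:
    return "-" if o == "+" else "+"


def twin_key(key: EdgeKey) -> EdgeKey:
    a, oa, b, ob = key
    return (b, _flip(ob), a, _flip(oa))


def canonical_key(key: EdgeKey) -> EdgeKey:
    t = twin_key(key)
    return key if key <= t else t


@dataclass
class _EdgeData:
    read_ids: set = field(default_factory=set)
    anchor_ids: set = field(default_factory=set)
    gaps: list = field(default_factory=list)

    @property
    def read_support(self) -> int:
        return len(self.read_ids)

    @property
    def anchor_support(self) -> int:
        return len(self.anchor_ids)

    @property
    def median_gap(self) -> int:
        g = sorted(self.gaps)
        return g[(len(g) - 1) // 2]


@dataclass(frozen=True)
class EdgeView:
    """Read-only edge attributes, identical for an edge and its twin."""

    read_support: int
    anchor_support: int
    median_gap: int
    n_estimates: int


class ScaffoldGraph:
    """Doubled directed graph of oriented contigs with support-weighted edges."""

    def __init__(self, contig_lengths: Mapping[str, int]):
        self.contig_lengths = dict(contig_lengths)
        self._edges: dict[EdgeKey, _EdgeData] = {}
        self.skipped_self_pairs = 0

    # -- construction -------------------------------------------------
    def add_pair(self, pair: OrientedPair) -> None:
        a, oa = pair.source
        b, ob = pair.target
        if a == b:
            self.skipped_self_pairs += 1
            return
        key = canonical_key((a, oa, b, ob))
        data = self._edges.setdefault(key, _EdgeData())
        data.read_ids.add(pair.read_id)
        if pair.is_anchor:
            data.anchor_ids.add(pair.read_id)
        data.gaps.append(int(pair.gap_estimate))

    # -- views ---------------------------------------------------------
    @property
    def nodes(self) -> list[Node]:
        return [(c, o) for c in sorted(self.contig_lengths) for o in "+-"]

    def canonical_edges(self) -> Iterator[tuple[EdgeKey, EdgeView]]:
        for key in sorted(self._edges):
            yield key, self._view(key)

    def edges(self) -> Iterator[tuple[EdgeKey, EdgeView]]:
        """Both directions of every edge (canonical plus twin)."""
        for key in sorted(self._edges):
            v = self._view(key)
            yield key, v
            yield twin_key(key), v

    def _view(self, key: EdgeKey) -> EdgeView:
        d = self._edges[key]
        return EdgeView(d.read_support, d.anchor_support, d.median_gap, len(d.gaps))

    def get_edge(self, key: EdgeKey) -> Optional[EdgeView]:
        c = canonical_key(key)
        if c not in self._edges:
            return None
        return self._view(c)

    def has_edge(self, key: EdgeKey) -> bool:
        return canonical_key(key) in self._edges

    @property
    def n_edges(self) -> int:
        """Number of canonical (undoubled) edges."""
        return len(self._edges)

    def remove_edges(self, keys: Iterable[EdgeKey]) -> None:
        """Remove edges (twins removed implicitly via canonicalisation)."""
        for key in keys:
            self._edges.pop(canonical_key(key), None)

    def copy(self) -> "ScaffoldGraph":
        g = ScaffoldGraph(self.contig_lengths)
        for key, d in self._edges.items():
            g._edges[key] = _EdgeData(set(d.read_ids), set(d.anchor_ids), list(d.gaps))
        g.skipped_self_pairs = self.skipped_self_pairs
        return g

    def check_twin_symmetry(self) -> None:
        """Assert the doubled-view invariant (cheap; used by tests and the CLI)."""
        seen = {}
        for key, view in self.edges():
            tk = twin_key(key)
            if tk in seen and seen[tk] != view:
                raise AssertionError(f"twin asymmetry at {key} / {tk}")
            seen[key] = view
        for key in seen:
            if twin_key(key) not in seen:
                raise AssertionError(f"missing twin of {key}")


def build_graph(pairs: Iterable[OrientedPair], contig_lengths: Mapping[str, int]) -> ScaffoldGraph:
    """Tally per-read oriented pairs into a scaffold graph."""
    g = ScaffoldGraph(contig_lengths)
    for p in pairs:
        g.add_pair(p)
    return g


def filter_noisy(graph: ScaffoldGraph, a: int) -> ScaffoldGraph:
    """Drop edges (and twins) whose anchoring-read support is below ``a``."""
    g = graph.copy()
    g.remove_edges([key for key, v in graph.canonical_edges() if v.anchor_support < a])
    return g


def write_dot(graph: ScaffoldGraph, path: str) -> None:
    """DOT export: oriented-contig nodes, edges with d (median gap),
    n (read support) and a (anchor support) attributes."""
    with open(path, "w") as out:
        out.write("digraph scaffold {\n")
        for c, o in graph.nodes:
            out.write(f'"{c}{o}";\n')
        for key, v in graph.edges():
            a, oa, b, ob = key
            out.write(
                f'"{a}{oa}" -> "{b}{ob}" [d={v.median_gap}, n={v.read_support}, a={v.anchor_support}];\n'
            )
        out.write("}\n")


_DOT_EDGE = re.compile(
    r'^"(?P<a>.+)(?P<oa>[+-])" -> "(?P<b>.+)(?P<ob>[+-])" \[d=(?P<d>-?\d+), n=(?P<n>\d+), a=(?P<anch>\d+)\];$'
)
_DOT_NODE = re.compile(r'^"(?P<c>.+)(?P<o>[+-])";$')


def read_dot(path: str) -> ScaffoldGraph:
    """Parse a graph written by :func:`write_dot`.

    Support counts are reconstructed with synthetic read ids and the gap
    list collapsed to the stored median, which is what layout consumes.
    """
    contigs: dict[str, int] = {}
    edges: dict[EdgeKey, tuple[int, int, int]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            m = _DOT_EDGE.match(line)
            if m:
                key = canonical_key((m["a"], m["oa"], m["b"], m["ob"]))
                edges[key] = (int(m["n"]), int(m["anch"]), int(m["d"]))
                continue
            m = _DOT_NODE.match(line)
            if m:
                contigs.setdefault(m["c"], 0)
    g = ScaffoldGraph(contigs)
    for key, (n, anch, d) in edges.items():
        data = _EdgeData()
        data.read_ids = {f"_dot{i}" for i in range(n)}
        data.anchor_ids = {f"_dot{i}" for i in range(anch)}
        data.gaps = [d]
        g._edges[key] = data
    return g
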