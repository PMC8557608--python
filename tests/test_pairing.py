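"""Oriented pair inference: combinatorics, orientation and gap algebra."""

import numpy as np
import pytest

from minscaff.mapping import ReadMapping, filter_runs, map_read
from minscaff.pairing import PairingParams, estimate_gap, infer_pairs, orient_pair
from minscaff.seqio import SeqRecord, reverse_complement
from minscaff.sketch import SketchParams, build_assembly_index, sketch_sequence
from tests.test_mapping import make_run, random_seq


def _pairs_of(mapping, lengths, k=16, **kw):
    return infer_pairs(mapping, lengths, k, PairingParams(**kw))


LENGTHS = {c: 5000 for c in "ABCDEFG"}


def test_single_run_yields_no_pairs():
    mapping = ReadMapping("r", [make_run("A", [0, 10])])
    assert _pairs_of(mapping, LENGTHS) == []


def test_worked_run_list_gives_adjacent_and_transitive_pairs():
    """Runs A{2}, B{2}, C{1} -> pairs exactly {A->B, B->C, A->C}."""
    mapping = ReadMapping(
        "r", [make_run("A", [0, 10]), make_run("B", [20, 30]), make_run("C", [40])]
    )
    pairs = _pairs_of(mapping, LENGTHS)
    assert {(p.source[0], p.target[0]) for p in pairs} == {("A", "B"), ("B", "C"), ("A", "C")}
    anchors = {(p.source[0], p.target[0]): p.is_anchor for p in pairs}
    assert anchors == {("A", "B"): True, ("B", "C"): False, ("A", "C"): False}


def test_pair_count_is_m_choose_2_below_f():
    mapping = ReadMapping("r", [make_run(c, [i * 20, i * 20 + 5]) for i, c in enumerate("ABCDE")])
    assert len(_pairs_of(mapping, LENGTHS)) == 10


def test_above_f_transitive_only_over_weak_runs():
    runs = [
        make_run("A", [0, 5]),
        make_run("B", [10]),  # weak
        make_run("C", [20, 25]),
        make_run("D", [30, 35]),
        make_run("E", [40]),
    ]
    pairs = _pairs_of(ReadMapping("r", runs), LENGTHS, f=2)
    got = {(p.source[0], p.target[0]) for p in pairs}
    adjacent = {("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")}
    assert adjacent <= got
    assert ("A", "C") in got  # bridges only weak B
    assert ("B", "D") not in got  # C is strongly supported
    assert ("A", "D") not in got


def test_tied_or_conflicting_runs_excluded_from_pairing():
    from minscaff.mapping import ContigRun, MinimizerMatch

    tied = ContigRun.from_matches(
        [MinimizerMatch(0, 0, "+", "A", 0, "+"), MinimizerMatch(0, 9, "+", "A", 9, "-")]
    )
    good = make_run("B", [20, 30])
    pairs = _pairs_of(ReadMapping("r", [tied, good]), LENGTHS)
    assert pairs == []


@pytest.fixture(scope="module")
def junction_world():
    rng = np.random.default_rng(51)
    params = SketchParams(k=16, w=8)
    return rng, params


def _junction_case(rng, params, gap, orient_a, orient_b):
    """Two 3-kb genome segments separated by ``gap`` unknown bases; contigs
    stored in the requested orientations; one error-free read spans the
    junction.  Returns the scored pair."""
    seg_a = random_seq(rng, 3000)
    seg_b = random_seq(rng, 3000)
    contig_a = seg_a if orient_a == "+" else reverse_complement(seg_a)
    contig_b = seg_b if orient_b == "+" else reverse_complement(seg_b)
    contigs = [SeqRecord(id="A", seq=contig_a), SeqRecord(id="B", seq=contig_b)]
    index = build_assembly_index(contigs, params)
    genome = seg_a + random_seq(rng, gap) + seg_b
    read = genome[1000 : len(genome) - 1000]
    mapping = filter_runs(
        map_read(sketch_sequence(("r", read), params), index), 0, index.contig_lengths
    )
    pairs = infer_pairs(mapping, index.contig_lengths, params.k)
    direct = [p for p in pairs if p.source[0] == "A" and p.target[0] == "B"]
    assert len(direct) == 1
    return direct[0]


def test_forward_abutting_contigs_orient_plus_plus_gap_zero(junction_world):
    rng, params = junction_world
    p = _junction_case(rng, params, 0, "+", "+")
    assert (p.source[1], p.target[1]) == ("+", "+")
    assert p.gap_estimate == 0


def test_reversed_target_contig_detected(junction_world):
    rng, params = junction_world
    p = _junction_case(rng, params, 100, "+", "-")
    assert (p.source[1], p.target[1]) == ("+", "-")
    assert p.gap_estimate == 100


def test_orientation_and_gap_recovered_over_random_junctions(junction_world):
    """Planted junctions with random orientations: orientation recovered in
    every error-free case and the gap estimate is exact."""
    rng, params = junction_world
    for _ in range(30):
        oa = "+" if rng.random() < 0.5 else "-"
        ob = "+" if rng.random() < 0.5 else "-"
        gap = int(rng.integers(0, 400))
        p = _junction_case(rng, params, gap, oa, ob)
        assert (p.source[1], p.target[1]) == (oa, ob)
        assert p.gap_estimate == gap


def test_reversed_read_gives_mirror_pairs_with_same_gaps(junction_world):
    rng, params = junction_world
    seg_a = random_seq(rng, 3000)
    seg_b = random_seq(rng, 3000)
    contigs = [SeqRecord(id="A", seq=seg_a), SeqRecord(id="B", seq=seg_b)]
    index = build_assembly_index(contigs, params)
    read = (seg_a + random_seq(rng, 150) + seg_b)[1000:-1000]
    flip = {"+": "-", "-": "+"}

    def pairs_for(r):
        mapping = filter_runs(
            map_read(sketch_sequence(("r", r), params), index), 0, index.contig_lengths
        )
        return infer_pairs(mapping, index.contig_lengths, params.k)

    fwd = pairs_for(read)
    rev = pairs_for(reverse_complement(read))
    fwd_set = {(p.source, p.target, p.gap_estimate) for p in fwd}
    mirrored = {
        ((p.target[0], flip[p.target[1]]), (p.source[0], flip[p.source[1]]), p.gap_estimate)
        for p in rev
    }
    assert fwd_set == mirrored


def test_gap_formula_on_hand_built_runs():
    """(rB - rA) - (LA - pA') - pB' with oriented positions."""
    run_a = make_run("A", [100], contig_positions=[900])
    run_b = make_run("B", [400], contig_positions=[50])
    lengths = {"A": 1000, "B": 1000}
    k = 16
    gap = estimate_gap(run_a, run_b, ("+", "+"), lengths, k)
    assert gap == (400 - 100) - (1000 - 900) - 50
    assert orient_pair(run_a, run_b) == ("+", "+")
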