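"""Minimizer sketching against a brute-force window-enumeration oracle."""

import numpy as np
import pytest

from minscaff.seqio import SeqRecord, reverse_complement
from minscaff.sketch import (
    SketchParams,
    build_assembly_index,
    canonical_hash,
    sketch_sequence,
)


def random_seq(rng, length):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, length))


def brute_force_sketch(seq, k, w):
    """Independent oracle: enumerate every window, take the argmin by
    (hash, position) — leftmost wins ties; k-mers with N excluded;
    fewer than w k-mers form one degenerate window."""
    n = len(seq) - k + 1
    if n < 1:
        return []
    vals = []
    for i in range(n):
        kmer = seq[i : i + k]
        if set(kmer) <= set("ACGT"):
            h, s = canonical_hash(kmer)
            vals.append((h, s))
        else:
            vals.append(None)
    selected = set()
    windows = [range(n)] if n < w else [range(j, j + w) for j in range(n - w + 1)]
    for window in windows:
        cand = [(vals[i][0], i) for i in window if vals[i] is not None]
        if cand:
            selected.add(min(cand)[1])
    return [(i, vals[i][0], vals[i][1]) for i in sorted(selected)]


def as_tuples(sketch):
    return [
        (int(p), int(h), "+" if f else "-")
        for p, h, f in zip(sketch.pos, sketch.hashes, sketch.fwd)
    ]


def test_canonical_hash_palindrome_and_symmetry():
    h_fwd, _ = canonical_hash("ACGT")
    h_rc, _ = canonical_hash(reverse_complement("ACGT"))
    assert h_fwd == h_rc
    h_a, s_a = canonical_hash("AAAA")
    h_t, s_t = canonical_hash("TTTT")
    assert h_a == h_t
    assert sorted((s_a, s_t)) == ["+", "-"] or (s_a == s_t == "+")


def test_canonical_hash_rc_invariance_random_24mers():
    rng = np.random.default_rng(21)
    for _ in range(1000):
        kmer = random_seq(rng, 24)
        assert canonical_hash(kmer)[0] == canonical_hash(reverse_complement(kmer))[0]


def test_canonical_hash_rejects_invalid_character():
    with pytest.raises(ValueError):
        canonical_hash("ACGN")


def test_window_of_one_keeps_every_kmer():
    rng = np.random.default_rng(22)
    seq = random_seq(rng, 80)
    sk = sketch_sequence(("s", seq), SketchParams(k=8, w=1))
    assert list(sk.pos) == list(range(len(seq) - 8 + 1))


def test_sequence_of_length_k_yields_one_record():
    rng = np.random.default_rng(23)
    seq = random_seq(rng, 16)
    sk = sketch_sequence(("s", seq), SketchParams(k=16, w=10))
    assert list(sk.pos) == [0]
    sk2 = sketch_sequence(("s", seq[:10]), SketchParams(k=16, w=10))
    assert len(sk2) == 0


@pytest.mark.parametrize("k,w", [(8, 3), (16, 5), (16, 32), (24, 100)])
def test_sketch_matches_brute_force_oracle(k, w):
    rng = np.random.default_rng(24)
    for _ in range(10):
        seq = random_seq(rng, int(rng.integers(max(k, 50), 600)))
        got = as_tuples(sketch_sequence(("s", seq), SketchParams(k=k, w=w)))
        assert got == brute_force_sketch(seq, k, w)


def test_sketch_with_ns_matches_oracle():
    rng = np.random.default_rng(25)
    for _ in range(10):
        seq = list(random_seq(rng, 300))
        for i in rng.integers(0, 300, 12):
            seq[int(i)] = "N"
        seq = "".join(seq)
        got = as_tuples(sketch_sequence(("s", seq), SketchParams(k=12, w=8)))
        assert got == brute_force_sketch(seq, 12, 8)


def test_all_n_sequence_yields_empty_sketch():
    sk = sketch_sequence(("s", "N" * 100), SketchParams(k=8, w=4))
    assert len(sk) == 0


def test_reverse_complement_sketch_is_mirrored_and_flipped():
    rng = np.random.default_rng(26)
    k, w = 16, 10
    for _ in range(20):
        seq = random_seq(rng, 500)
        fwd = as_tuples(sketch_sequence(("s", seq), SketchParams(k=k, w=w)))
        rev = as_tuples(sketch_sequence(("s", reverse_complement(seq)), SketchParams(k=k, w=w)))
        mirrored = sorted(
            (len(seq) - k - p, h, "+" if s == "-" else "-") for p, h, s in fwd
        )
        assert rev == mirrored


def test_density_decreases_with_window_size():
    rng = np.random.default_rng(27)
    seq = random_seq(rng, 2000)
    sizes = [
        len(sketch_sequence(("s", seq), SketchParams(k=16, w=w)))
        for w in (1, 5, 20, 100, 500)
    ]
    assert sizes == sorted(sizes, reverse=True)


def test_index_of_identical_contigs_is_empty():
    rng = np.random.default_rng(28)
    seq = random_seq(rng, 2000)
    idx = build_assembly_index(
        [SeqRecord(id="a", seq=seq), SeqRecord(id="b", seq=seq)],
        SketchParams(k=16, w=10),
    )
    assert len(idx) == 0


def test_index_of_unique_contig_matches_sketch_size():
    rng = np.random.default_rng(29)
    rec = SeqRecord(id="a", seq=random_seq(rng, 5000))
    params = SketchParams(k=16, w=10)
    idx = build_assembly_index([rec], params)
    assert len(idx) == len(sketch_sequence(rec, params))


def test_shared_block_excluded_from_index():
    rng = np.random.default_rng(30)
    shared = random_seq(rng, 10_000)
    a = SeqRecord(id="a", seq=random_seq(rng, 5000) + shared)
    b = SeqRecord(id="b", seq=shared + random_seq(rng, 5000))
    k = 16
    idx = build_assembly_index([a, b], SketchParams(k=k, w=10))
    for i in range(len(idx)):
        rec = idx.get(int(idx.hashes[i]))
        if rec.seq_id == "a":
            # k-mers fully inside the shared suffix of a must be absent
            assert rec.pos < 5000 + 10_000 - k + 1 or rec.pos >= len(a.seq) - k + 1
    # positional check: no indexed minimizer fully inside the shared block
    for i in range(len(idx)):
        cid = idx.contig_ids[int(idx.contig_idx[i])]
        pos = int(idx.pos[i])
        if cid == "a":
            assert not (5000 <= pos <= len(a.seq) - k)
        else:
            assert not (0 <= pos <= 10_000 - k)


def test_duplicate_contig_ids_rejected():
    with pytest.raises(ValueError):
        build_assembly_index(
            [SeqRecord(id="a", seq="ACGT" * 10), SeqRecord(id="a", seq="TTTT" * 10)],
            SketchParams(k=8, w=2),
        )
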