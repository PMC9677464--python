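from collections import Counter
from itertools import product

import numpy as np
import pytest

from microbin.features import (
    SelectionConfig,
    build_features,
    clr,
    kmer_frequencies,
    mask_intervals_for_kmers,
    n_canonical_kmers,
    nx_select,
    size_select,
)
from microbin.io_formats import ContigRecord

_COMP = str.maketrans("ACGT", "TGCA")


def canonical(kmer: str) -> str:
    rc = kmer.translate(_COMP)[::-1]
    return min(kmer, rc)


def brute_force_kmers(seq, intervals, k):
    """Window-enumeration oracle: count canonical k-mers, skipping any
    window that overlaps a masked interval or contains non-ACGT."""
    counts = Counter()
    for p in range(1, len(seq) - k + 2):  # 1-based starts
        lo, hi = p, p + k - 1
        if any(lo <= e and s <= hi for s, e in intervals):
            continue
        kmer = seq[p - 1: p + k - 1]
        if set(kmer) <= set("ACGT"):
            counts[canonical(kmer)] += 1
    return counts


def vector_to_counter(vec, k):
    kmers = sorted({canonical("".join(t)) for t in product("ACGT", repeat=k)})
    return Counter({km: int(c) for km, c in zip(kmers, vec) if c})


def test_nx_select_hand_example():
    lengths = {"c1": 600, "c2": 300, "c3": 100}
    assert nx_select(lengths, 90) == {"c1", "c2"}
    assert nx_select(lengths, 100) == {"c1", "c2", "c3"}
    assert nx_select({"only": 50}, 10) == {"only"}
    assert nx_select({}, 90) == set()


def test_nx_select_matches_exhaustive_prefix_search():
    rng = np.random.default_rng(7)
    for _ in range(100):
        n = int(rng.integers(1, 20))
        lengths = {f"c{i}": int(rng.integers(1, 1000)) for i in range(n)}
        x = float(rng.uniform(1, 100))
        got = nx_select(lengths, x)
        # oracle: shortest prefix of the descending-length order
        order = sorted(lengths, key=lambda c: (-lengths[c], c))
        total = sum(lengths.values())
        cum, expected = 0, set()
        for cid in order:
            expected.add(cid)
            cum += lengths[cid]
            if cum >= x / 100 * total:
                break
        assert got == expected


def test_size_select_union_rule():
    cfg = SelectionConfig()
    # big assembly dominated by one huge contig so N90 = {big}
    lengths = {"big": 100_000, "m1": 2_300, "n1": 2_000, "n2": 600}
    marked = {"m1"}
    kept = size_select(lengths, lambda c: c in marked, cfg)
    assert "big" in kept            # inside the N90 prefix
    assert "m1" in kept             # 2300 >= 2250 with markers
    assert "n1" not in kept         # 2000 < 2250, outside prefix
    assert "n2" not in kept


def test_size_select_keeps_short_contig_inside_prefix():
    cfg = SelectionConfig()
    lengths = {"a": 600, "b": 550, "c": 50}
    kept = size_select(lengths, lambda c: False, cfg)
    assert {"a", "b"} <= kept  # N90 prefix, far below 2250 bp


def test_mask_window_starts_hand_example():
    rec = ContigRecord("c", "A" * 10, masked_intervals=[(6, 6)])
    assert mask_intervals_for_kmers(rec, k=2) == [5, 6]
    rec2 = ContigRecord("c", "A" * 10)
    assert mask_intervals_for_kmers(rec2, k=2) == []
    rec3 = ContigRecord("c", "A" * 10, masked_intervals=[(1, 10)])
    assert mask_intervals_for_kmers(rec3, k=3) == list(range(1, 9))


def test_kmer_frequencies_hand_examples():
    # ACGT: windows AC, CG, GT; GT pools with its reverse complement AC
    assert vector_to_counter(kmer_frequencies("ACGT", ks=(2,)), 2) == Counter(
        {"AC": 2, "CG": 1}
    )
    # mask [6,6] kills windows starting at 5 and 6
    vec = kmer_frequencies("AAAAACAAAA", [(6, 6)], ks=(2,))
    assert vector_to_counter(vec, 2) == Counter({"AA": 7})
    # N breaks a window
    assert vector_to_counter(
        kmer_frequencies("ANT", ks=(2,)), 2
    ) == Counter()


def test_kmer_frequencies_fully_masked_contig_is_zero():
    vec = kmer_frequencies("ACGTACGT", [(1, 8)], ks=(2, 3))
    assert vec.sum() == 0


def test_masked_kmer_counting_matches_window_oracle():
    rng = np.random.default_rng(11)
    alphabet = np.array(list("ACGTN"))
    for _ in range(500):
        L = int(rng.integers(1, 60))
        seq = "".join(rng.choice(alphabet, size=L, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        n_iv = int(rng.integers(0, 3))
        intervals = []
        for _ in range(n_iv):
            s = int(rng.integers(1, L + 1))
            e = min(L, s + int(rng.integers(0, 10)))
            intervals.append((s, e))
        k = int(rng.integers(2, 5))
        got = vector_to_counter(kmer_frequencies(seq, intervals, ks=(k,)), k)
        assert got == brute_force_kmers(seq, intervals, k)


def test_clr_hand_examples():
    assert np.allclose(clr(np.array([[5.0, 5.0, 5.0]]), 1e-12), 0.0)
    row = clr(np.array([[2.0, 8.0]]), 1e-12)[0]
    assert row == pytest.approx([np.log(0.5), np.log(2.0)], abs=1e-9)


def test_clr_rows_sum_to_zero():
    rng = np.random.default_rng(5)
    X = rng.integers(0, 50, size=(40, 17)).astype(float)
    out = clr(X, 1.0)
    assert np.all(np.abs(out.sum(axis=1)) < 1e-9)


def _contig(cid, seq, depths):
    return ContigRecord(cid, seq, depths=np.asarray(depths, float))


def test_build_features_shapes_and_blocks():
    rng = np.random.default_rng(8)
    seqs = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(6)]
    contigs = [_contig(f"c{i}", s, [float(i + 1)]) for i, s in enumerate(seqs)]
    fm = build_features(contigs, ks=(2,))
    assert n_canonical_kmers(2) == 10
    assert fm.matrix.shape == (6, 10 + 1)  # canonical 2-mers + 1 depth col
    fm34 = build_features(contigs, ks=(2, 3, 4))
    assert fm34.matrix.shape[1] == 10 + 32 + 136 + 1


def test_build_features_permutation_equivariant():
    rng = np.random.default_rng(9)
    seqs = ["".join(rng.choice(list("ACGT"), size=150)) for _ in range(5)]
    contigs = [
        _contig(f"c{i}", s, rng.uniform(1, 10, size=3)) for i, s in enumerate(seqs)
    ]
    fm = build_features(contigs)
    perm = [3, 0, 4, 1, 2]
    fm_p = build_features([contigs[i] for i in perm])
    assert np.allclose(fm_p.matrix, fm.matrix[perm])
    assert fm_p.contig_ids == [fm.contig_ids[i] for i in perm]


def test_build_features_identical_contigs_identical_rows():
    c1 = _contig("a", "ACGT" * 40, [2.0, 3.0])
    c2 = _contig("b", "ACGT" * 40, [2.0, 3.0])
    fm = build_features([c1, c2])
    assert np.allclose(fm.matrix[0], fm.matrix[1])


def test_build_features_multisample_depth_block_is_clr():
    rng = np.random.default_rng(10)
    contigs = [
        _contig(f"c{i}", "".join(rng.choice(list("ACGT"), size=100)),
                rng.uniform(1, 20, size=4))
        for i in range(5)
    ]
    fm = build_features(contigs, ks=(2,))
    depth_block = fm.matrix[:, -4:]
    assert np.all(np.abs(depth_block.sum(axis=1)) < 1e-9)
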