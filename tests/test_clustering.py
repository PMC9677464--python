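import math

import numpy as np
import pytest

from microbin.clustering import (
    ClusterParams,
    ThresholdState,
    accept_or_split,
    cluster_embedding,
    extract_single_contig_mags,
    min_cluster_size,
    required_purity,
)
from microbin.io_formats import ContigRecord
from microbin.markers import QualityEstimate


@pytest.mark.parametrize("n,expected", [(1000, 7), (10, 2), (3, 2), (2, 2)])
def test_min_cluster_size_examples(n, expected):
    assert min_cluster_size(n) == expected


def test_min_cluster_size_matches_formula_on_log_grid():
    for n in np.unique(np.logspace(np.log10(2), 6, 60).astype(int)):
        assert min_cluster_size(int(n)) == max(2, int(math.floor(math.log(n) + 0.5)))


def test_cluster_embedding_two_blobs():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(100, 2))
    b = rng.normal(size=(100, 2)) + 50.0
    coords = np.vstack([a, b])
    labels = cluster_embedding(coords, mcs=min_cluster_size(200), min_samples=5)
    non_noise = labels[labels >= 0]
    assert len(set(non_noise)) == 2
    assert (labels >= 0).mean() >= 0.95
    # blob membership is pure
    assert len(set(labels[:100]) - {-1}) == 1
    assert len(set(labels[100:]) - {-1}) == 1


def test_cluster_embedding_uniform_noise_mostly_unclustered():
    rng = np.random.default_rng(1)
    coords = rng.uniform(0, 1, size=(50, 2))
    labels = cluster_embedding(coords, mcs=25, min_samples=10)
    assert (labels == -1).mean() > 0.5


def test_cluster_embedding_deterministic():
    rng = np.random.default_rng(2)
    coords = rng.normal(size=(80, 2))
    l1 = cluster_embedding(coords, 4, 5, 0.25)
    l2 = cluster_embedding(coords, 4, 5, 0.25)
    assert np.array_equal(l1, l2)


def test_cluster_embedding_fewer_points_than_min_cluster_size():
    coords = np.zeros((3, 2))
    assert list(cluster_embedding(coords, mcs=5, min_samples=1)) == [-1] * 3


def test_required_purity_base_and_escalation():
    high = ThresholdState(completeness_threshold=92.5)
    low = ThresholdState(completeness_threshold=82.5)
    assert required_purity(high, 95.0, "class") == 95.0
    assert required_purity(low, 70.0, "class") == 95.0
    assert required_purity(low, 70.0, "domain") == 99.0
    # linear escalation between completeness 90 and 70
    assert required_purity(low, 80.0, "class") == pytest.approx((92.5 + 95) / 2)
    assert required_purity(low, 95.0, "class") == 92.5


def test_required_purity_final_stage_relaxation():
    final = ThresholdState(completeness_threshold=72.5, final_stage=True)
    assert required_purity(final, 92.0, "class") == 87.5
    # below 90% completeness the relaxation does not apply
    assert required_purity(final, 80.0, "class") > 87.5


def test_accept_or_split_accepts_passing_cluster():
    est = QualityEstimate("X", "class", 0.93, 0.96)
    acc, left = accept_or_split(
        ["c1", "c2"], np.zeros((2, 2)), np.ones((2, 1)),
        lambda ids: est, ThresholdState(), ClusterParams(), min_samples=1,
    )
    assert left == []
    assert acc == [(["c1", "c2"], est)]


def test_accept_or_split_splits_mixed_genomes_on_depth():
    # two genomes co-located in the embedding but with distinct depths
    rng = np.random.default_rng(3)
    n = 40
    coords = rng.normal(scale=0.5, size=(n, 2))
    depths = np.vstack([
        np.full((20, 1), 5.0) + rng.normal(0, 0.2, (20, 1)),
        np.full((20, 1), 50.0) + rng.normal(0, 2.0, (20, 1)),
    ])
    ids = [f"a{i}" for i in range(20)] + [f"b{i}" for i in range(20)]

    def assess_group(group_ids):
        has_a = any(g.startswith("a") for g in group_ids)
        has_b = any(g.startswith("b") for g in group_ids)
        if has_a and has_b:  # mixed: duplicated markers, low purity
            return QualityEstimate("X", "class", 1.0, 0.5)
        return QualityEstimate("X", "class", 0.95, 1.0)

    acc, left = accept_or_split(
        ids, coords, depths, assess_group, ThresholdState(), ClusterParams(),
        min_samples=5,
    )
    assert len(acc) == 2
    a_set = {f"a{i}" for i in range(20)}
    b_set = {f"b{i}" for i in range(20)}
    accepted_sets = sorted((set(a[0]) for a in acc), key=len)
    for got in accepted_sets:
        assert got <= a_set or got <= b_set  # each sub-MAG is pure
    assert sum(len(s) for s in accepted_sets) + len(left) == 40
    assert len(left) <= 8  # only density-noise points return to the pool
    assert all(len(s) >= 12 for s in accepted_sets)


def test_accept_or_split_returns_all_when_attempts_exhausted():
    est = QualityEstimate("X", "class", 1.0, 0.5)
    ids = [f"c{i}" for i in range(10)]
    acc, left = accept_or_split(
        ids, np.zeros((10, 2)), np.ones((10, 1)),
        lambda g: est, ThresholdState(), ClusterParams(max_split_attempts=0),
        min_samples=1,
    )
    assert acc == []
    assert sorted(left) == ids


def test_accept_or_split_never_accepts_below_required_purity():
    rng = np.random.default_rng(4)
    state = ThresholdState(completeness_threshold=82.5)

    def noisy_assess(group_ids):
        return QualityEstimate(
            "X", "class",
            float(rng.uniform(0.7, 1.0)), float(rng.uniform(0.8, 1.0)),
        )

    for _ in range(20):
        n = int(rng.integers(4, 30))
        ids = [f"c{i}" for i in range(n)]
        coords = rng.normal(size=(n, 2))
        depths = rng.uniform(1, 10, size=(n, 2))
        acc, left = accept_or_split(
            ids, coords, depths, noisy_assess, state,
            ClusterParams(), min_samples=1,
        )
        for got_ids, est in acc:
            comp = est.completeness * 100
            assert comp >= state.completeness_threshold
            assert est.purity * 100 >= required_purity(state, comp, est.rank)
        assert sorted([c for a in acc for c in a[0]] + left) == sorted(ids)


def _contig_with_markers(cid, markers):
    return ContigRecord(cid, "ACGT" * 1000, marker_hits=list(markers))


def test_single_contig_rescue_thresholds(hierarchy):
    complement = []
    for taxon in ("Bacteria", "Proteobacteria", "Alphaproteobacteria"):
        for ms in hierarchy.node(taxon).marker_sets:
            complement.extend(sorted(ms))
    full = _contig_with_markers("full", complement)
    few = _contig_with_markers("few", complement[:39])
    # 45+ distinct markers but each duplicated -> purity 0.5, not rescued
    impure = _contig_with_markers("impure", complement[:60] * 2)
    contigs = {"full": full, "few": few, "impure": impure}
    rescued, remaining = extract_single_contig_mags(contigs, hierarchy)
    assert [cid for cid, _ in rescued] == ["full"]
    assert rescued[0][1].completeness >= 0.925
    assert sorted(remaining) == ["few", "impure"]
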