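from collections import Counter

import numpy as np
import pytest

from microbin.markers import (
    MarkerSetNode,
    assess,
    completeness,
    load_marker_hierarchy,
    marker_counts,
    parse_marker_sets,
    purity,
    serialize_marker_sets,
)


def brute_force_completeness(counts, sets):
    """Mean over sets of the fraction of genes present at least once."""
    total = 0.0
    for ms in sets:
        present = 0
        for g in ms:
            if counts.get(g, 0) >= 1:
                present += 1
        total += present / len(ms)
    return total / len(sets)


def brute_force_purity(counts, sets):
    """Mean over non-empty sets of mean reciprocal copy number."""
    outer = []
    for ms in sets:
        inner = []
        for g in ms:
            c = counts.get(g, 0)
            if c >= 1:
                inner.append(1.0 / c)
        if inner:
            outer.append(sum(inner) / len(inner))
    return sum(outer) / len(outer) if outer else 1.0


def node(sets, taxon="T", rank="domain"):
    return MarkerSetNode(taxon=taxon, rank=rank,
                         marker_sets=[frozenset(s) for s in sets])


def test_completeness_hand_example():
    n = node([{"a", "b"}, {"c", "d"}, {"e"}])
    counts = {"a": 1, "c": 1, "d": 2}
    assert completeness(counts, n) == pytest.approx(0.5)


def test_completeness_boundaries():
    n = node([{"a", "b"}, {"c"}])
    assert completeness({"a": 1, "b": 1, "c": 1}, n) == 1.0
    assert completeness({}, n) == 0.0


def test_purity_hand_examples():
    assert purity({"a": 2, "b": 1}, node([{"a", "b"}])) == pytest.approx(0.75)
    assert purity({"a": 1, "b": 1}, node([{"a", "b"}])) == 1.0
    # sets without present genes are skipped from the outer mean
    assert purity({"a": 3}, node([{"a", "b"}, {"c"}])) == pytest.approx(1 / 3)
    # markerless group is vacuously pure
    assert purity({}, node([{"a"}])) == 1.0


def test_marker_math_matches_brute_force_on_fuzzed_instances():
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(30)]
    for _ in range(1000):
        n_sets = int(rng.integers(1, 6))
        sets = []
        for _ in range(n_sets):
            size = int(rng.integers(1, 7))
            sets.append(set(rng.choice(genes, size=size, replace=False)))
        counts = {
            g: int(rng.integers(0, 4))
            for g in rng.choice(genes, size=rng.integers(0, 20), replace=False)
        }
        counts = {g: c for g, c in counts.items() if c > 0}
        n = node(sets)
        assert completeness(counts, n) == pytest.approx(
            brute_force_completeness(counts, sets), abs=1e-12
        )
        assert purity(counts, n) == pytest.approx(
            brute_force_purity(counts, sets), abs=1e-12
        )


def test_completeness_monotone_under_added_contigs():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(15)]
    sets = [set(rng.choice(genes, size=4, replace=False)) for _ in range(3)]
    n = node(sets)
    hits = {f"c{i}": list(rng.choice(genes, size=3)) for i in range(8)}
    ids = list(hits)
    prev = 0.0
    for stop in range(len(ids) + 1):
        c = completeness(marker_counts(ids[:stop], hits), n)
        p = purity(marker_counts(ids[:stop], hits), n)
        assert c >= prev
        assert 0.0 <= p <= 1.0
        prev = c


def test_marker_counts_additive():
    hits = {"c1": ["m1", "m1", "m2"], "c2": ["m2", "m3"]}
    assert marker_counts(["c1"], hits) == Counter({"m1": 2, "m2": 1})
    assert marker_counts([], hits) == Counter()
    combined = marker_counts(["c1"], hits) + marker_counts(["c2"], hits)
    assert marker_counts(["c1", "c2"], hits) == combined


def test_serialization_roundtrip():
    sets = [frozenset({"m1", "m2"}), frozenset({"m3"})]
    assert parse_marker_sets(serialize_marker_sets(sets)) == sets


HIERARCHY_TSV = """#rank\ttaxon\tparent_taxon\tmarker_sets
domain\tBacteria\troot\t[[a,b],[c,d]]
domain\tArchaea\troot\t[[x,y],[z]]
phylum\tProteo\tBacteria\t[[p,q]]
class\tAlpha\tProteo\t[[r,s]]
"""


def test_load_marker_hierarchy(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text(HIERARCHY_TSV)
    h = load_marker_hierarchy(p)
    assert [d.taxon for d in h.domains] == ["Archaea", "Bacteria"]
    assert len(h.node("Bacteria").marker_sets) == 2
    assert h.node("Alpha").rank == "class"


def test_load_marker_hierarchy_exclusions_drop_subtree(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text(HIERARCHY_TSV)
    h = load_marker_hierarchy(p, excluded_taxa={"Proteo"})
    assert "Proteo" not in h
    assert "Alpha" not in h
    assert "Bacteria" in h


def test_load_marker_hierarchy_orphan_errors(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text(
        "#rank\ttaxon\tparent_taxon\tmarker_sets\n"
        "phylum\tProteo\tBacteria\t[[p,q]]\n"
    )
    with pytest.raises(ValueError, match="Proteo"):
        load_marker_hierarchy(p)


def test_load_marker_hierarchy_empty_errors(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text("#rank\ttaxon\tparent_taxon\tmarker_sets\n")
    with pytest.raises(ValueError):
        load_marker_hierarchy(p)


def _two_level_hierarchy(tmp_path):
    p = tmp_path / "h.tsv"
    # domain with 5 single-gene sets; two classes directly below
    p.write_text(
        "#rank\ttaxon\tparent_taxon\tmarker_sets\n"
        "domain\tBacteria\troot\t[[d1],[d2],[d3],[d4],[d5]]\n"
        "class\tX\tBacteria\t[[x1],[x2]]\n"
        "class\tY\tBacteria\t[[y1],[y2]]\n"
    )
    return load_marker_hierarchy(p)


def test_assess_averages_subdomain_with_domain(tmp_path):
    h = _two_level_hierarchy(tmp_path)
    # domain completeness 0.8, purity 1.0; class X raw 1.0 / 0.9-ish:
    # x1 present twice, x2 once -> purity (0.5 + 1)/2 = 0.75, completeness 1.0
    counts = {"d1": 1, "d2": 1, "d3": 1, "d4": 1, "x1": 2, "x2": 1}
    est = assess(counts, h)
    assert est.taxon == "X"
    assert est.rank == "class"
    assert est.completeness == pytest.approx((1.0 + 0.8) / 2)
    assert est.purity == pytest.approx((0.75 + 1.0) / 2)


def test_assess_prefers_more_complete_sibling(tmp_path):
    h = _two_level_hierarchy(tmp_path)
    counts = {f"d{i}": 1 for i in range(1, 6)} | {"x1": 1, "x2": 1, "y1": 1}
    est = assess(counts, h)
    assert est.taxon == "X"  # averaged 1.0 beats 0.75


def test_assess_single_domain_no_traversal(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text(
        "#rank\ttaxon\tparent_taxon\tmarker_sets\n"
        "domain\tBacteria\troot\t[[a,b],[c]]\n"
    )
    h = load_marker_hierarchy(p)
    est = assess({"a": 1}, h)
    assert (est.taxon, est.rank) == ("Bacteria", "domain")
    assert est.completeness == pytest.approx(0.25)


def test_assess_empty_counts_gives_domain_level_zero(tmp_path):
    h = _two_level_hierarchy(tmp_path)
    est = assess({}, h)
    assert est.rank == "domain"
    assert est.completeness == 0.0


def test_assess_respects_max_rank(hierarchy):
    # full complement of a class lineage, but assessment capped at phylum
    comp = {}
    for taxon in ("Bacteria", "Proteobacteria", "Alphaproteobacteria"):
        for ms in hierarchy.node(taxon).marker_sets:
            for g in ms:
                comp[g] = 1
    est = assess(comp, hierarchy, max_rank="phylum")
    assert est.rank in ("domain", "phylum")
    est_class = assess(comp, hierarchy, max_rank="class")
    assert est_class.rank == "class"
    assert est_class.taxon == "Alphaproteobacteria"
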