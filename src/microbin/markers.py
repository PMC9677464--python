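"""Lineage-specific single-copy marker sets and bin quality estimation.

A marker hierarchy is a rooted taxon graph (domain -> phylum -> class by
default). Each node carries its collocated marker sets: groups of
single-copy genes known to co-occur in genomes of that lineage.
Completeness of a contig group is the mean, over marker sets, of the
fraction of each set's genes present at least once (Parks-style).
Purity is the mean, over marker sets with at least one present gene, of
the mean reciprocal copy number of the present genes — 1.0 means no
duplicated single-copy marker.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

RANK_ORDER = ("domain", "phylum", "class", "order", "family", "genus", "species")

ROOT = "__root__"


@dataclass
class MarkerSetNode:
    taxon: str
    rank: str
    marker_sets: list[frozenset[str]]

    @property
    def n_markers(self) -> int:
        return len(set().union(*self.marker_sets)) if self.marker_sets else 0


@dataclass
class QualityEstimate:
    """Assessed quality of a contig group at its best-fitting taxon."""

    taxon: str
    rank: str
    completeness: float
    purity: float
    marker_set_size: int = 0

    def __post_init__(self):
        if not (0.0 <= self.completeness <= 1.0 and 0.0 <= self.purity <= 1.0):
            raise ValueError("completeness and purity must lie in [0, 1]")


class MarkerHierarchy:
    """Rooted directed graph of taxon marker-set nodes."""

    def __init__(self, graph: nx.DiGraph):
        self.graph = graph

    @property
    def domains(self) -> list[MarkerSetNode]:
        return [self.node(t) for t in sorted(self.graph.successors(ROOT))]

    def node(self, taxon: str) -> MarkerSetNode:
        return self.graph.nodes[taxon]["node"]

    def children(self, taxon: str) -> list[MarkerSetNode]:
        return [self.node(t) for t in sorted(self.graph.successors(taxon))]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.graph

    def taxa(self) -> list[str]:
        return [t for t in self.graph.nodes if t != ROOT]


_SET_TOKEN = re.compile(r"[^\[\],\s']+")


def parse_marker_sets(serialized: str) -> list[frozenset[str]]:
    """Parse a ``[[m1,m2],[m3]]``-style serialized list of marker sets."""
    text = serialized.strip()
    if not (text.startswith("[") and text.endswith("]")):
        raise ValueError(f"malformed marker set list: {serialized!r}")
    sets: list[frozenset[str]] = []
    depth = 0
    current: list[str] = []
    for chunk in re.split(r"([\[\]])", text[1:-1]):
        if chunk == "[":
            depth += 1
            current = []
        elif chunk == "]":
            depth -= 1
            if current:
                sets.append(frozenset(current))
        elif depth == 1:
            current.extend(_SET_TOKEN.findall(chunk))
    return sets


def serialize_marker_sets(sets: Iterable[Iterable[str]]) -> str:
    return "[" + ",".join("[" + ",".join(sorted(s)) + "]" for s in sets) + "]"


def convert_checkm_table(path: str | Path, out_path: str | Path) -> None:
    """Convert a CheckM ``taxon_marker_sets.tsv`` into the native dialect.

    CheckM rows are (rank, taxon, ..., python-repr of a list of sets).
    The native table has columns (rank, taxon, parent_taxon, marker_sets);
    parents are inferred from rank nesting order of the rows.
    """
    rows = []
    last_at_rank: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or fields[0] not in RANK_ORDER:
                continue
            rank, taxon, raw = fields[0], fields[1], fields[-1]
            markers = re.findall(r"'([^']+)'", raw)
            groups = re.findall(r"set\(\[(.*?)\]\)", raw)
            sets = [frozenset(re.findall(r"'([^']+)'", g)) for g in groups] or [
                frozenset(markers)
            ]
            ridx = RANK_ORDER.index(rank)
            parent = last_at_rank.get(ridx - 1, ROOT) if ridx > 0 else ROOT
            last_at_rank[ridx] = taxon
            rows.append((rank, taxon, parent, serialize_marker_sets(sets)))
    with open(out_path, "w") as fh:
        fh.write("#rank\ttaxon\tparent_taxon\tmarker_sets\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def load_marker_hierarchy(
    path: str | Path, excluded_taxa: Iterable[str] = ()
) -> MarkerHierarchy:
    """Load the taxon marker-set table into a rooted hierarchy.

    Columns: rank, taxon, parent_taxon, marker_sets (bracketed-list
    serialization). Taxa in ``excluded_taxa`` are dropped together with
    their whole subtree (very small marker sets are excluded this way
    rather than hard-coded).
    """
    with open(path) as fh:
        first = fh.readline()
    header = 0 if first.startswith("#") else None
    df = pd.read_csv(path, sep="\t", header=header, dtype=str)
    if df.empty:
        raise ValueError(f"empty marker hierarchy table: {path}")
    df.columns = ["rank", "taxon", "parent_taxon", "marker_sets"]

    graph = nx.DiGraph()
    graph.add_node(ROOT)
    known = {ROOT}
    for _, row in df.iterrows():
        taxon = row["taxon"]
        parent = row["parent_taxon"] if pd.notna(row["parent_taxon"]) else ROOT
        if parent in ("", "root"):
            parent = ROOT
        if parent not in known:
            raise ValueError(
                f"taxon {taxon!r} references missing parent {parent!r} "
                "(parents must precede children in the table)"
            )
        sets = parse_marker_sets(row["marker_sets"])
        if any(len(s) == 0 for s in sets):
            raise ValueError(f"empty marker set for taxon {taxon!r}")
        node = MarkerSetNode(taxon=taxon, rank=row["rank"], marker_sets=sets)
        graph.add_node(taxon, node=node)
        graph.add_edge(parent, taxon)
        known.add(taxon)

    excluded = set(excluded_taxa)
    for taxon in excluded & set(graph.nodes):
        graph.remove_nodes_from(
            [taxon, *nx.descendants(graph, taxon)]
        )
    if graph.number_of_nodes() <= 1:
        raise ValueError("marker hierarchy has no taxa after exclusions")
    return MarkerHierarchy(graph)


def marker_counts(
    contig_ids: Iterable[str],
    hits: Mapping[str, Iterable[str]] | pd.DataFrame,
) -> Counter:
    """Aggregate marker hit multiplicities over a contig group.

    ``hits`` is either a mapping contig_id -> list of accessions or a
    marker-hit DataFrame with contig_id / marker_accession columns.
    """
    counts: Counter = Counter()
    ids = set(contig_ids)
    if isinstance(hits, pd.DataFrame):
        sub = hits[hits["contig_id"].isin(ids)]
        counts.update(sub["marker_accession"])
    else:
        for cid in ids:
            counts.update(hits.get(cid, ()))
    return counts


def completeness(counts: Mapping[str, int], node: MarkerSetNode) -> float:
    """Mean over marker sets of the fraction of the set's genes present."""
    if not node.marker_sets:
        raise ValueError(f"taxon {node.taxon!r} has no marker sets")
    fractions = [
        sum(1 for g in ms if counts.get(g, 0) >= 1) / len(ms)
        for ms in node.marker_sets
    ]
    return sum(fractions) / len(fractions)


def purity(counts: Mapping[str, int], node: MarkerSetNode) -> float:
    """Mean reciprocal copy number of present markers, averaged over sets.

    Genes with zero copies are excluded from each set's inner average,
    and sets with no present gene are excluded from the outer mean
    (absent genes are the completeness score's business, not purity's).
    A group with no marker gene at all is vacuously pure (1.0); it can
    never pass a completeness threshold anyway.
    """
    if not node.marker_sets:
        raise ValueError(f"taxon {node.taxon!r} has no marker sets")
    set_scores = []
    for ms in node.marker_sets:
        present = [counts[g] for g in ms if counts.get(g, 0) >= 1]
        if present:
            set_scores.append(sum(1.0 / c for c in present) / len(present))
    return sum(set_scores) / len(set_scores) if set_scores else 1.0


def assess(
    counts: Mapping[str, int],
    hierarchy: MarkerHierarchy,
    max_rank: str = "class",
) -> QualityEstimate:
    """Pick the best-fitting taxon for a contig group and score it.

    Assessment starts at the domain level with the domain maximizing
    completeness. It then walks down one rank at a time: each sub-domain
    candidate is scored as the arithmetic mean of its own completeness /
    purity and its domain's, combining the general power of the domain
    set with the specificity of the lineage set. A deeper taxon replaces
    the current best if its (averaged) completeness is equal or higher —
    the most complete marker set is the least likely chance match. Ties
    break to the lexicographically smallest taxon name. Traversal never
    goes deeper than ``max_rank``.
    """
    max_depth = RANK_ORDER.index(max_rank)

    def score(node: MarkerSetNode) -> tuple[float, float]:
        return completeness(counts, node), purity(counts, node)

    domains = hierarchy.domains
    if not domains:
        raise ValueError("marker hierarchy has no domain-level nodes")
    scored = [(score(d), d) for d in domains]
    best = None
    for (c, p), d in scored:
        if best is None or c > best[0][0] or (c == best[0][0] and d.taxon < best[1].taxon):
            best = ((c, p), d)
    (dom_comp, dom_pur), dom = best

    current = QualityEstimate(
        taxon=dom.taxon, rank=dom.rank, completeness=dom_comp,
        purity=dom_pur, marker_set_size=dom.n_markers,
    )
    if not any(counts.values()):
        return current  # markerless group: report the domain level
    node = dom
    while True:
        children = [
            ch for ch in hierarchy.children(node.taxon)
            if ch.rank in RANK_ORDER and RANK_ORDER.index(ch.rank) <= max_depth
        ]
        if not children:
            break
        best_child = None
        for ch in children:
            c, p = score(ch)
            avg_c = (c + dom_comp) / 2.0
            avg_p = (p + dom_pur) / 2.0
            key = (-avg_c, ch.taxon)
            if best_child is None or key < best_child[0]:
                best_child = (key, ch, avg_c, avg_p)
        _, ch, avg_c, avg_p = best_child
        if avg_c >= current.completeness:
            current = QualityEstimate(
                taxon=ch.taxon, rank=ch.rank, completeness=avg_c,
                purity=avg_p, marker_set_size=ch.n_markers,
            )
            node = ch
        else:
            break
    return current
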