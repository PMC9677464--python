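"""Density-based clustering of the 2-D embedding and cluster vetting.

Clusters come from HDBSCAN (Manhattan metric) run as a sweep over
min_samples values. Each candidate cluster is assessed with marker
sets; clusters passing the dynamic completeness/purity thresholds
become MAGs, contaminated ones are re-clustered with the raw depth(s)
of coverage appended as extra dimensions, and everything else returns
to the un-binned pool. Single contigs carrying a large share of a
marker complement are rescued before any embedding happens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.cluster import HDBSCAN

from .io_formats import ContigRecord
from .markers import MarkerHierarchy, QualityEstimate, assess, marker_counts

NOISE = -1

SINGLE_CONTIG_MIN_MARKERS = 40
SINGLE_CONTIG_MIN_PURITY = 90.0
SINGLE_CONTIG_MIN_COMPLETENESS = 92.5

FINAL_STAGE_PURITY = 87.5
DOMAIN_MAX_PURITY = 99.0
SUBDOMAIN_MAX_PURITY = 95.0


@dataclass
class ClusterParams:
    """HDBSCAN sweep configuration."""

    min_samples_sweep: tuple[int, ...] = (1, 5, 10)
    cluster_selection_epsilon: float = 0.25
    metric: str = "manhattan"
    max_split_attempts: int = 1

    def __post_init__(self):
        if not self.min_samples_sweep:
            raise ValueError("min_samples sweep must be non-empty")
        if self.cluster_selection_epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass
class ThresholdState:
    """Dynamic acceptance thresholds (percent scales)."""

    completeness_threshold: float = 92.5
    completeness_floor: float = 72.5
    final_stage: bool = False


@dataclass
class Mag:
    """An accepted contig cluster with its acceptance record."""

    bin_id: str
    contig_ids: list[str]
    quality: QualityEstimate
    iteration: int
    total_bp: int = 0
    tier_flags: set[str] = field(default_factory=set)
    accepted_at: dict = field(default_factory=dict)


def min_cluster_size(n_contigs: int) -> int:
    """HDBSCAN minimum cluster size: ln(n contigs), rounded half-up.

    Floored at 2, the smallest value the clustering backend accepts.
    """
    if n_contigs < 2:
        raise ValueError("need at least 2 contigs")
    return max(2, int(math.floor(math.log(n_contigs) + 0.5)))


def cluster_embedding(
    coords: np.ndarray,
    mcs: int,
    min_samples: int,
    cluster_selection_epsilon: float = 0.0,
    metric: str = "manhattan",
) -> np.ndarray:
    """HDBSCAN labels for the 2-D coordinates; noise labelled -1."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < mcs or n <= min_samples or n < 2:
        return np.full(n, NOISE)
    labels = HDBSCAN(
        min_cluster_size=mcs,
        min_samples=min_samples,
        cluster_selection_epsilon=cluster_selection_epsilon,
        metric=metric,
        copy=True,
    ).fit_predict(coords)
    return labels


def required_purity(
    state: ThresholdState, cluster_completeness: float, marker_rank: str
) -> float:
    """Purity (percent) a cluster must reach to be accepted.

    The base requirement is 95 while the completeness threshold is at
    least 90, then 92.5. Toward low cluster completeness it escalates
    linearly, reaching 95 at completeness <= 70 — 99 when the chosen
    marker set is a whole domain (Bacteria/Archaea), whose sets are too
    generic to vouch for purity on their own. In the final binning
    stage clusters that are >= 90 complete only need 87.5.
    """
    if state.final_stage and cluster_completeness >= 90.0:
        return FINAL_STAGE_PURITY
    base = 95.0 if state.completeness_threshold >= 90.0 else 92.5
    ceiling = DOMAIN_MAX_PURITY if marker_rank == "domain" else SUBDOMAIN_MAX_PURITY
    if cluster_completeness >= 90.0:
        req = base
    elif cluster_completeness <= 70.0:
        req = ceiling
    else:
        req = base + (90.0 - cluster_completeness) / 20.0 * (ceiling - base)
    return max(base, req)


def passes_thresholds(est: QualityEstimate, state: ThresholdState) -> bool:
    comp = est.completeness * 100.0
    pur = est.purity * 100.0
    return comp >= state.completeness_threshold and pur >= required_purity(
        state, comp, est.rank
    )


def _scaled_depth_columns(coords: np.ndarray, depths: np.ndarray) -> np.ndarray:
    """Rescale raw depth columns to the spread of the 2-D coordinates.

    Each depth column is divided by its own standard deviation and
    multiplied by the mean coordinate standard deviation, so a single
    high-coverage sample cannot drown the embedding geometry.
    """
    coord_scale = float(np.mean(np.std(coords, axis=0)))
    if coord_scale == 0:
        coord_scale = 1.0
    out = np.zeros_like(depths, dtype=float)
    for j in range(depths.shape[1]):
        sd = depths[:, j].std()
        if sd > 0:
            out[:, j] = depths[:, j] / sd * coord_scale
    return out


def accept_or_split(
    contig_ids: Sequence[str],
    coords: np.ndarray,
    raw_depths: np.ndarray,
    assess_group: Callable[[Sequence[str]], QualityEstimate],
    state: ThresholdState,
    params: ClusterParams,
    min_samples: int,
    attempts: int | None = None,
) -> tuple[list[tuple[list[str], QualityEstimate]], list[str]]:
    """Vet one candidate cluster; split contaminated ones on depth.

    Returns (accepted, leftover): accepted is a list of
    (contig id list, quality) pairs, leftover the contigs returned to
    the un-binned pool. Splitting re-clusters the candidate's points in
    (2-D coords || rescaled raw depth columns) and recurses into each
    sub-cluster until no new clusters appear or the attempt budget is
    exhausted.
    """
    if attempts is None:
        attempts = params.max_split_attempts
    ids = list(contig_ids)
    est = assess_group(ids)
    if passes_thresholds(est, state):
        return [(ids, est)], []
    n = len(ids)
    if attempts <= 0 or n < 4:
        return [], ids
    X = np.hstack([coords, _scaled_depth_columns(coords, raw_depths)])
    labels = cluster_embedding(
        X, mcs=min_cluster_size(n), min_samples=min_samples,
        cluster_selection_epsilon=0.0, metric=params.metric,
    )
    uniq = sorted(set(labels) - {NOISE})
    if not uniq or (len(uniq) == 1 and np.sum(labels != NOISE) == n):
        return [], ids  # no new structure found
    accepted: list[tuple[list[str], QualityEstimate]] = []
    leftover: list[str] = [ids[i] for i in np.flatnonzero(labels == NOISE)]
    for lab in uniq:
        idx = np.flatnonzero(labels == lab)
        sub_ids = [ids[i] for i in idx]
        sub_acc, sub_left = accept_or_split(
            sub_ids, coords[idx], raw_depths[idx], assess_group, state,
            params, min_samples, attempts=attempts - 1,
        )
        accepted.extend(sub_acc)
        leftover.extend(sub_left)
    return accepted, leftover


def extract_single_contig_mags(
    contigs: Mapping[str, ContigRecord],
    hierarchy: MarkerHierarchy,
    max_rank: str = "class",
) -> tuple[list[tuple[str, QualityEstimate]], list[str]]:
    """Rescue near-complete genomes sitting on a single contig.

    Contigs carrying at least 40 distinct markers are assessed alone;
    those at >= 90% purity and >= 92.5% completeness are emitted as
    single-contig MAGs and skipped by the iterative procedure (such
    contigs would otherwise risk being treated as noise or merged with
    similar contigs of fragmented genomes).
    """
    rescued: list[tuple[str, QualityEstimate]] = []
    remaining: list[str] = []
    for cid, rec in contigs.items():
        if len(set(rec.marker_hits)) >= SINGLE_CONTIG_MIN_MARKERS:
            est = assess(
                marker_counts([cid], {cid: rec.marker_hits}), hierarchy, max_rank
            )
            if (
                est.purity * 100.0 >= SINGLE_CONTIG_MIN_PURITY
                and est.completeness * 100.0 >= SINGLE_CONTIG_MIN_COMPLETENESS
            ):
                rescued.append((cid, est))
                continue
        remaining.append(cid)
    return rescued, remaining
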