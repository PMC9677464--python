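"""The iterative binning state machine.

Single-sample mode embeds and clusters the size-selected un-binned
contigs, then loosens its thresholds on a fixed schedule: the minimum
contig size drops by 500 bp whenever fewer than half of the min_samples
sweep runs yielded MAGs; once the floor (500 bp) is reached, the
completeness threshold drops by 10 points (92.5 -> 82.5 -> 72.5) and
the size resets. At the completeness floor a final stage relaxes purity
to 87.5% for clusters >= 90% complete and doubles the split attempts;
the run ends when a final-stage iteration accepts nothing.

Co-assembly mode (more than one depth sample) embeds all un-binned
contigs >= 500 bp, decrements the completeness threshold by 10 per
iteration down to 70, applies the same final-stage relaxation, and
finishes with terminal rounds at minimum contig sizes 2000 -> 1500 ->
1000 -> 500.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .clustering import (
    ClusterParams,
    Mag,
    ThresholdState,
    accept_or_split,
    cluster_embedding,
    extract_single_contig_mags,
    min_cluster_size,
    required_purity,
)
from .embedding import EmbeddingParams, embed, pca_reduce
from .evaluation import classify_tiers
from .features import SelectionConfig, build_features, size_select
from .io_formats import ContigRecord
from .markers import MarkerHierarchy, assess, marker_counts

logger = logging.getLogger(__name__)

EPSILON_CYCLE = (0.25, 0.125, 0.0)
SIZE_STEP = 500
SIZE_FLOOR = 500
COMPLETENESS_STEP = 10.0
COASSEMBLY_TERMINAL_SIZES = (2000, 1500, 1000, 500)


def epsilon_for_iteration(
    iteration: int, cycle: Sequence[float] = EPSILON_CYCLE
) -> float:
    """Cluster-selection epsilon, cycling 0.25 -> 0.125 -> 0.0."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    return cycle[iteration % len(cycle)]


def update_size_threshold(current: int, fraction_yielding: float) -> int:
    """Lower the min contig size by 500 bp on a poorly yielding iteration.

    Applies when fewer than half of the sweep's clustering runs
    returned MAGs; floored at 500 bp.
    """
    if fraction_yielding < 0.5:
        return max(SIZE_FLOOR, current - SIZE_STEP)
    return current


@dataclass
class BinningConfig:
    """All knobs of the binning engine with their defaults."""

    ks: tuple[int, ...] = (2, 3, 4)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    completeness_start: float = 92.5
    completeness_floor_single: float = 72.5
    completeness_floor_coassembly: float = 70.0
    min_samples_sweep: tuple[int, ...] = (1, 5, 10)
    max_split_attempts: int = 1
    final_split_attempts: int = 2
    epsilon_cycle: tuple[float, ...] = EPSILON_CYCLE
    max_rank: str = "class"
    mode: str = "auto"  # auto | single | coassembly
    masking: bool = True
    seed: int = 0
    max_iterations: int = 60

    def __post_init__(self):
        if self.completeness_floor_single > self.completeness_start:
            raise ValueError("completeness floor exceeds start")
        if self.mode not in ("auto", "single", "coassembly"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class RunResult:
    mags: list[Mag]
    unbinned: list[str]
    log: list[dict]

    @property
    def contig_assignment(self) -> dict[str, str]:
        return {
            cid: mag.bin_id for mag in self.mags for cid in mag.contig_ids
        }


def _make_mags(
    accepted: list[tuple[list[str], object, dict]],
    contigs: Mapping[str, ContigRecord],
    iteration: int,
) -> list[Mag]:
    """Deterministic bin ids: bin_<iteration>_<ordinal> by descending bp."""
    sized = [
        (sum(contigs[c].length for c in ids), ids, est, rec)
        for ids, est, rec in accepted
    ]
    sized.sort(key=lambda t: (-t[0], t[1][0]))
    return [
        Mag(
            bin_id=f"bin_{iteration}_{i + 1}",
            contig_ids=sorted(ids),
            quality=est,
            iteration=iteration,
            total_bp=bp,
            accepted_at=rec,
        )
        for i, (bp, ids, est, rec) in enumerate(sized)
    ]


def _run_iteration(
    pool: Mapping[str, ContigRecord],
    selected_ids: Sequence[str],
    iteration: int,
    thr: ThresholdState,
    cparams: ClusterParams,
    cfg: BinningConfig,
    hierarchy: MarkerHierarchy,
    log: list[dict],
) -> tuple[list[tuple[list[str], object, dict]], float]:
    """One embedding plus the min_samples sweep.

    Returns (accepted groups, fraction of sweep runs that yielded MAGs).
    """
    selected = [pool[c] for c in sorted(selected_ids)]
    feats = build_features(selected, ks=cfg.ks)
    X = pca_reduce(feats.matrix)
    nuc = len(selected)
    # iteration is 1-based for bin ids and logs; schedules are 0-based
    eparams = EmbeddingParams.for_iteration(
        nuc, iteration - 1, seed=(cfg.seed + iteration) % (2**31)
    )
    coords = embed(X, eparams)
    raw_depths = np.stack([np.asarray(c.depths, float) for c in selected])
    ids = [c.contig_id for c in selected]
    id_pos = {cid: i for i, cid in enumerate(ids)}
    hits = {c.contig_id: c.marker_hits for c in selected}

    def assess_group(group_ids):
        return assess(marker_counts(group_ids, hits), hierarchy, cfg.max_rank)

    epsilon = epsilon_for_iteration(iteration - 1, cfg.epsilon_cycle)
    accepted: list[tuple[list[str], object, dict]] = []
    active = np.ones(len(ids), dtype=bool)
    sweeps_yielding = 0
    n_clusters_total = 0
    for min_samples in cfg.min_samples_sweep:
        idx = np.flatnonzero(active)
        if idx.size < 4:
            break
        labels = cluster_embedding(
            coords[idx],
            mcs=min_cluster_size(idx.size),
            min_samples=min_samples,
            cluster_selection_epsilon=epsilon,
            metric=cparams.metric,
        )
        yielded = False
        for lab in sorted(set(labels) - {-1}):
            n_clusters_total += 1
            sub = idx[labels == lab]
            cand_ids = [ids[i] for i in sub]
            acc, _left = accept_or_split(
                cand_ids,
                coords[sub],
                raw_depths[sub],
                assess_group,
                thr,
                cparams,
                min_samples=min_samples,
                attempts=cparams.max_split_attempts,
            )
            for got_ids, est in acc:
                record = {
                    "iteration": iteration,
                    "min_samples": min_samples,
                    "epsilon": epsilon,
                    "completeness_threshold": thr.completeness_threshold,
                    "required_purity": required_purity(
                        thr, est.completeness * 100.0, est.rank
                    ),
                    "final_stage": thr.final_stage,
                    "completeness": est.completeness * 100.0,
                    "purity": est.purity * 100.0,
                }
                accepted.append((got_ids, est, record))
                active[[id_pos[c] for c in got_ids]] = False
                yielded = True
        if yielded:
            sweeps_yielding += 1

    fraction = sweeps_yielding / len(cfg.min_samples_sweep)
    log.append(
        {
            "iteration": iteration,
            "pool_size": len(pool),
            "nuc": nuc,
            "ex": eparams.ex,
            "lr_ex": eparams.lr_ex,
            "lr": eparams.lr,
            "perplexities": eparams.perplexities,
            "epsilon": epsilon,
            "clusters": n_clusters_total,
            "mags_accepted": len(accepted),
            "sweep_fraction_yielding": fraction,
            "completeness_threshold": thr.completeness_threshold,
            "final_stage": thr.final_stage,
        }
    )
    logger.info(
        "iteration %d: NUC=%d EX=%.1f LR=%.0f perp=%s eps=%.3f -> "
        "%d clusters, %d MAGs (thr=%.1f%s)",
        iteration, nuc, eparams.ex, eparams.lr, eparams.perplexities,
        epsilon, n_clusters_total, len(accepted),
        thr.completeness_threshold, ", final" if thr.final_stage else "",
    )
    return accepted, fraction


def _rescue_single_contigs(
    pool: dict[str, ContigRecord],
    hierarchy: MarkerHierarchy,
    cfg: BinningConfig,
    mags: list[Mag],
) -> dict[str, ContigRecord]:
    rescued, remaining = extract_single_contig_mags(pool, hierarchy, cfg.max_rank)
    singles = []
    for cid, est in rescued:
        singles.append(
            (
                [cid],
                est,
                {
                    "iteration": 0,
                    "single_contig_rescue": True,
                    "completeness_threshold": 92.5,
                    "required_purity": 90.0,
                    "final_stage": False,
                    "completeness": est.completeness * 100.0,
                    "purity": est.purity * 100.0,
                },
            )
        )
    mags.extend(_make_mags(singles, pool, iteration=0))
    return {cid: pool[cid] for cid in remaining}


def run_single_sample(
    contigs: Mapping[str, ContigRecord],
    hierarchy: MarkerHierarchy,
    cfg: BinningConfig | None = None,
) -> RunResult:
    """Iterative binning for one depth sample."""
    cfg = cfg or BinningConfig()
    log: list[dict] = []
    mags: list[Mag] = []
    pool = {
        cid: rec
        for cid, rec in contigs.items()
        if rec.length >= cfg.selection.global_min_len
    }
    if not pool:
        logger.warning("no contigs pass the %d bp filter",
                       cfg.selection.global_min_len)
        return RunResult(mags=[], unbinned=[], log=log)
    pool = _rescue_single_contigs(pool, hierarchy, cfg, mags)

    thr = ThresholdState(
        completeness_threshold=cfg.completeness_start,
        completeness_floor=cfg.completeness_floor_single,
    )
    size_reset = max(
        cfg.selection.min_len_with_markers, cfg.selection.min_len_without_markers
    )
    cur_min_size = size_reset
    cparams = ClusterParams(
        min_samples_sweep=cfg.min_samples_sweep,
        max_split_attempts=cfg.max_split_attempts,
    )
    iteration = 1
    while iteration <= cfg.max_iterations and len(pool) >= 4:
        sel_cfg = replace(
            cfg.selection,
            min_len_with_markers=min(
                cfg.selection.min_len_with_markers, cur_min_size
            ),
            min_len_without_markers=min(
                cfg.selection.min_len_without_markers, cur_min_size
            ),
        )
        lengths = {cid: rec.length for cid, rec in pool.items()}
        selected = size_select(
            lengths, lambda c: bool(pool[c].marker_hits), sel_cfg
        )
        accepted, fraction = [], 0.0
        if len(selected) >= 4:
            accepted, fraction = _run_iteration(
                pool, selected, iteration, thr, cparams, cfg, hierarchy, log
            )
            mags.extend(_make_mags(accepted, pool, iteration))
            for ids, _est, _rec in accepted:
                for cid in ids:
                    pool.pop(cid)
        iteration += 1
        if thr.final_stage and not accepted:
            break
        if fraction < 0.5:
            if cur_min_size > SIZE_FLOOR:
                cur_min_size = update_size_threshold(cur_min_size, fraction)
            elif thr.completeness_threshold > thr.completeness_floor:
                thr.completeness_threshold = max(
                    thr.completeness_floor,
                    thr.completeness_threshold - COMPLETENESS_STEP,
                )
                cur_min_size = size_reset
            elif not thr.final_stage:
                thr.final_stage = True
                cparams = replace(
                    cparams, max_split_attempts=cfg.final_split_attempts
                )
                cur_min_size = SIZE_FLOOR
    return RunResult(mags=mags, unbinned=sorted(pool), log=log)


def run_coassembly(
    contigs: Mapping[str, ContigRecord],
    hierarchy: MarkerHierarchy,
    cfg: BinningConfig | None = None,
) -> RunResult:
    """Iterative binning for multi-sample depth (co-assembly) runs."""
    cfg = cfg or BinningConfig()
    n_samples = {len(rec.depths) for rec in contigs.values()}
    if n_samples == {1}:
        logger.warning("single depth column: deferring to single-sample mode")
        return run_single_sample(contigs, hierarchy, cfg)
    log: list[dict] = []
    mags: list[Mag] = []
    pool = {
        cid: rec
        for cid, rec in contigs.items()
        if rec.length >= cfg.selection.global_min_len
    }
    if not pool:
        logger.warning("no contigs pass the %d bp filter",
                       cfg.selection.global_min_len)
        return RunResult(mags=[], unbinned=[], log=log)
    pool = _rescue_single_contigs(pool, hierarchy, cfg, mags)

    thr = ThresholdState(
        completeness_threshold=cfg.completeness_start,
        completeness_floor=cfg.completeness_floor_coassembly,
    )
    cparams = ClusterParams(
        min_samples_sweep=cfg.min_samples_sweep,
        max_split_attempts=cfg.max_split_attempts,
    )
    iteration = 1
    # main loop: all un-binned contigs >= 500 bp, threshold -10 / iteration
    while iteration <= cfg.max_iterations and len(pool) >= 4:
        accepted, _fraction = _run_iteration(
            pool, list(pool), iteration, thr, cparams, cfg, hierarchy, log
        )
        mags.extend(_make_mags(accepted, pool, iteration))
        for ids, _est, _rec in accepted:
            for cid in ids:
                pool.pop(cid)
        iteration += 1
        if thr.completeness_threshold > thr.completeness_floor:
            thr.completeness_threshold = max(
                thr.completeness_floor,
                thr.completeness_threshold - COMPLETENESS_STEP,
            )
        elif not thr.final_stage:
            thr.final_stage = True
            cparams = replace(
                cparams, max_split_attempts=cfg.final_split_attempts
            )
        elif not accepted:
            break
    # terminal rounds with decreasing minimum contig sizes
    for min_size in COASSEMBLY_TERMINAL_SIZES:
        if iteration > cfg.max_iterations:
            break
        selected = [c for c, r in pool.items() if r.length >= min_size]
        if len(selected) < 4:
            continue
        accepted, _fraction = _run_iteration(
            pool, selected, iteration, thr, cparams, cfg, hierarchy, log
        )
        mags.extend(_make_mags(accepted, pool, iteration))
        for ids, _est, _rec in accepted:
            for cid in ids:
                pool.pop(cid)
        iteration += 1
    return RunResult(mags=mags, unbinned=sorted(pool), log=log)


def run_binning(
    contigs: Mapping[str, ContigRecord],
    hierarchy: MarkerHierarchy,
    cfg: BinningConfig | None = None,
) -> RunResult:
    """Dispatch on mode: co-assembly iff more than one depth column."""
    cfg = cfg or BinningConfig()
    n_samples = max((len(r.depths) for r in contigs.values()), default=1)
    mode = cfg.mode
    if mode == "auto":
        mode = "coassembly" if n_samples > 1 else "single"
    if mode == "coassembly" and n_samples > 1:
        return run_coassembly(contigs, hierarchy, cfg)
    return run_single_sample(contigs, hierarchy, cfg)


def attach_tier_flags(
    result: RunResult,
    rna_features: Mapping[str, tuple[set[str], set[str]]] | None,
) -> None:
    """Fill each MAG's tier flags from marker quality and RNA inventory."""
    for mag in result.mags:
        rna = None
        if rna_features is not None:
            isotypes: set[str] = set()
            subunits: set[str] = set()
            for cid in mag.contig_ids:
                iso, sub = rna_features.get(cid, (set(), set()))
                isotypes |= iso
                subunits |= sub
            rna = (len(isotypes), subunits)
        mag.tier_flags = classify_tiers(mag.quality, rna)
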