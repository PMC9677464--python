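"""Gold-standard scoring of binning output and MAG quality tiers.

bp-based metrics follow the AMBER conventions: each bin's reference is
the gold-standard genome contributing the most base pairs to it;
bp purity is the reference's share of the bin, bp completeness the
share of the reference genome recovered. Overall metrics sum the
majority-genome base pairs over all bins.

Quality tiers use the marker-based estimates (as a CheckM filter
would): HQ means purity > 90% and completeness > 70%; near-complete
(NC) means purity > 95% and completeness > 90%; the MIMAG high-quality
draft standard additionally demands >= 18 unique tRNA isotypes and the
three rRNA types (5S, 16S, 23S).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from sklearn.metrics import adjusted_rand_score

from .markers import QualityEstimate
from .synthetic_data import GoldStandard

HQ_PURITY, HQ_COMPLETENESS = 90.0, 70.0
NC_PURITY, NC_COMPLETENESS = 95.0, 90.0
MIMAG_TRNA, MIMAG_RRNA = 18, 3


@dataclass
class BinScore:
    bin_id: str
    reference_genome: str
    bp_purity: float
    bp_completeness: float
    bin_bp: int
    tier_flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not (0 <= self.bp_purity <= 1 and 0 <= self.bp_completeness <= 1):
            raise ValueError("bp fractions must lie in [0, 1]")


def _bin_reference(
    contig_ids: Iterable[str], gold: GoldStandard, lengths: Mapping[str, int]
) -> tuple[str, int, int]:
    """(majority genome, its bp in the bin, total bin bp)."""
    bp_by_genome: dict[str, int] = {}
    total = 0
    for cid in contig_ids:
        ln = lengths[cid]
        total += ln
        bp_by_genome[gold.contig_to_genome[cid]] = (
            bp_by_genome.get(gold.contig_to_genome[cid], 0) + ln
        )
    best = min(bp_by_genome.items(), key=lambda kv: (-kv[1], kv[0]))
    return best[0], best[1], total


def score_bins(
    bins: Mapping[str, Sequence[str]],
    gold: GoldStandard,
    lengths: Mapping[str, int],
) -> list[BinScore]:
    """Per-bin bp purity and completeness against the gold standard.

    ``bins`` maps bin id -> contig ids. bp ties for the majority genome
    break to the lexicographically smaller genome id. Empty bins are
    skipped with a warning.
    """
    scores = []
    for bin_id in sorted(bins):
        contig_ids = bins[bin_id]
        if not contig_ids:
            warnings.warn(f"bin {bin_id!r} is empty; skipped")
            continue
        ref, ref_bp, total = _bin_reference(contig_ids, gold, lengths)
        genome_total = gold.genome_bp.get(ref)
        if genome_total is None:
            genome_total = sum(
                lengths[c] for c, g in gold.contig_to_genome.items() if g == ref
            )
        scores.append(
            BinScore(
                bin_id=bin_id,
                reference_genome=ref,
                bp_purity=ref_bp / total,
                bp_completeness=ref_bp / genome_total if genome_total else 0.0,
                bin_bp=total,
            )
        )
    return scores


def overall_metrics(
    bins: Mapping[str, Sequence[str]],
    gold: GoldStandard,
    lengths: Mapping[str, int],
) -> tuple[float, float]:
    """(overall purity, overall completeness) over all bins.

    Overall purity: sum of majority-genome bp over bins divided by the
    sum of bp in all bins. Overall completeness: the same numerator
    divided by the total bp of the gold-standard genomes. With no bins,
    purity is NaN (undefined) and completeness 0.
    """
    majority_bp = 0
    bin_bp = 0
    for bin_id in bins:
        if not bins[bin_id]:
            continue
        _, ref_bp, total = _bin_reference(bins[bin_id], gold, lengths)
        majority_bp += ref_bp
        bin_bp += total
    if bin_bp == 0:
        return float("nan"), 0.0
    gold_bp = sum(gold.genome_bp.values()) or sum(
        lengths[c] for c in gold.contig_to_genome
    )
    return majority_bp / bin_bp, majority_bp / gold_bp


def adjusted_rand_index(
    bin_labels: Mapping[str, str], gold_labels: Mapping[str, str]
) -> float:
    """ARI between the binning and the gold partition, over binned contigs.

    Un-binned contigs are excluded: pairwise agreement is measured on
    contigs the binner actually placed. Identical single-cluster
    labelings score 1.0 by convention.
    """
    common = sorted(set(bin_labels) & set(gold_labels))
    if not common:
        raise ValueError("no contigs shared between labelings")
    a = [bin_labels[c] for c in common]
    b = [gold_labels[c] for c in common]
    return float(adjusted_rand_score(a, b))


def classify_tiers(
    marker_quality: QualityEstimate,
    rna: tuple[int, set[str]] | None = None,
) -> set[str]:
    """Tier flags {HQ, NC, MIMAG-HQ} from marker-based quality estimates.

    Thresholds are strict inequalities on the percent scale. MIMAG-HQ
    additionally needs the tRNA/rRNA inventory (``rna`` = unique tRNA
    isotype count and set of rRNA types found).
    """
    purity = marker_quality.purity * 100.0
    completeness = marker_quality.completeness * 100.0
    flags: set[str] = set()
    if purity > HQ_PURITY and completeness > HQ_COMPLETENESS:
        flags.add("HQ")
    if purity > NC_PURITY and completeness > NC_COMPLETENESS:
        flags.add("NC")
        if rna is not None:
            n_trna, rrna_types = rna
            if n_trna >= MIMAG_TRNA and len(rrna_types) >= MIMAG_RRNA:
                flags.add("MIMAG-HQ")
    return flags
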