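"""Contig selection and the composition + coverage feature matrix.

Features per contig are canonical k-mer counts for each k (default
k = 2, 3, 4) and per-sample average read depth, each block centered
log-ratio (CLR) transformed. k-mers are counted strand-pooled: a k-mer
and its reverse complement share the lexicographically smaller
representative, making the signature invariant to contig orientation.
Windows overlapping masked regions (rRNA genes, CRISPR arrays) are
skipped — the sequence itself is never edited.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .io_formats import ContigRecord

_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass
class SelectionConfig:
    """Length-based contig selection parameters (all in bp)."""

    global_min_len: int = 500
    nx: float = 90.0
    min_len_with_markers: int = 2250
    min_len_without_markers: int = 2250

    def __post_init__(self):
        if not (0 < self.nx <= 100):
            raise ValueError("nx must be in (0, 100]")
        if min(self.global_min_len, self.min_len_with_markers,
               self.min_len_without_markers) <= 0:
            raise ValueError("length thresholds must be positive")


@dataclass
class FeatureMatrix:
    contig_ids: list[str]
    matrix: np.ndarray
    ks: tuple[int, ...]
    n_samples: int

    def __post_init__(self):
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite entries")


def nx_select(lengths: Mapping[str, int], x: float) -> set[str]:
    """Contigs forming the shortest descending-length prefix covering x%.

    Contigs are sorted by length (descending, ties broken by id) and the
    first ones that together make up x% of the assembly are retained.
    """
    if not lengths:
        return set()
    items = sorted(lengths.items(), key=lambda kv: (-kv[1], kv[0]))
    target = x / 100.0 * sum(lengths.values())
    kept: set[str] = set()
    cum = 0
    for cid, ln in items:
        kept.add(cid)
        cum += ln
        if cum >= target:
            break
    return kept


def size_select(
    lengths: Mapping[str, int],
    has_markers: Callable[[str], bool],
    cfg: SelectionConfig,
) -> set[str]:
    """Union of the Nx prefix and the per-category minimum-length rule.

    A contig is kept if it lies in the Nx prefix OR its length reaches
    the minimum for its category (with / without marker genes). The
    union keeps the information loss to the short, markerless tail.
    Inputs are assumed pre-filtered to ``global_min_len``.
    """
    keep = nx_select(lengths, cfg.nx)
    for cid, ln in lengths.items():
        floor = (
            cfg.min_len_with_markers if has_markers(cid)
            else cfg.min_len_without_markers
        )
        if ln >= floor:
            keep.add(cid)
    return keep


@lru_cache(maxsize=None)
def canonical_kmer_map(k: int) -> tuple[np.ndarray, int]:
    """Map each of the 4**k k-mer codes to its canonical column index.

    Returns (map array of length 4**k, number of canonical k-mers).
    """
    n = 4**k
    codes = np.arange(n)
    digits = np.empty((n, k), dtype=np.int64)
    tmp = codes.copy()
    for j in range(k - 1, -1, -1):
        digits[:, j] = tmp % 4
        tmp //= 4
    rc_digits = 3 - digits[:, ::-1]
    rc = np.zeros(n, dtype=np.int64)
    for j in range(k):
        rc = rc * 4 + rc_digits[:, j]
    canon = np.minimum(codes, rc)
    uniq = np.unique(canon)
    col = np.searchsorted(uniq, canon)
    return col, len(uniq)


def n_canonical_kmers(k: int) -> int:
    return canonical_kmer_map(k)[1]


def mask_intervals_for_kmers(
    contig: ContigRecord, k: int
) -> list[int]:
    """1-based start positions of k-windows overlapping a masked region.

    A window of width k starting at p covers [p, p+k-1]; it is skipped
    iff that range intersects any masked interval.
    """
    last_start = contig.length - k + 1
    skipped: set[int] = set()
    for s, e in contig.masked_intervals:
        lo = max(1, s - k + 1)
        hi = min(e, last_start)
        skipped.update(range(lo, hi + 1))
    return sorted(skipped)


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_frequencies(
    seq: str,
    masked_intervals: Sequence[tuple[int, int]] = (),
    ks: Iterable[int] = (2, 3, 4),
) -> np.ndarray:
    """Canonical k-mer counts, skipping masked or ambiguous windows.

    Windows containing characters outside {A,C,G,T} are not counted.
    Per-k blocks are concatenated in ascending k.
    """
    ks = tuple(sorted(ks))
    if not ks:
        raise ValueError("ks must be non-empty")
    codes = _encode(seq)
    L = len(codes)
    masked = np.zeros(L, dtype=bool)
    for s, e in masked_intervals:
        masked[max(0, s - 1): min(L, e)] = True

    blocks = []
    for k in ks:
        col_map, n_cols = canonical_kmer_map(k)
        counts = np.zeros(n_cols, dtype=np.int64)
        if L >= k:
            win = np.lib.stride_tricks.sliding_window_view(codes, k)
            valid = ~(win >= 4).any(axis=1)
            if masked.any():
                mwin = np.lib.stride_tricks.sliding_window_view(masked, k)
                valid &= ~mwin.any(axis=1)
            if valid.any():
                idx = win[valid] @ (4 ** np.arange(k - 1, -1, -1))
                counts = np.bincount(col_map[idx], minlength=n_cols)
        blocks.append(counts)
    return np.concatenate(blocks)


def clr(matrix: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Row-wise centered log-ratio transform.

    Adds the pseudocount, divides by the row geometric mean and takes
    the natural log; every output row sums to zero.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = np.asarray(matrix, dtype=float) + pseudocount
    if np.any(x <= 0):
        raise ValueError("CLR requires non-negative input")
    logx = np.log(x)
    return logx - logx.mean(axis=1, keepdims=True)


def build_features(
    contigs: Sequence[ContigRecord],
    ks: Iterable[int] = (2, 3, 4),
    kmer_pseudocount: float = 1.0,
    depth_pseudocount: float = 1e-5,
) -> FeatureMatrix:
    """Assemble the CLR composition + CLR depth feature matrix.

    CLR is applied separately per k-mer size block and to the depth
    block. With a single sample a row-wise CLR would be identically
    zero, so the depth column is instead log-transformed and centered
    by its median across contigs.
    """
    ks = tuple(sorted(ks))
    if not contigs:
        raise ValueError("no contigs to build features from")
    n_samples = len(contigs[0].depths)
    if n_samples == 0:
        raise ValueError("contigs carry no depth values")

    kmer_rows = np.stack([
        kmer_frequencies(c.sequence, c.masked_intervals, ks) for c in contigs
    ])
    blocks = []
    offset = 0
    for k in ks:
        width = n_canonical_kmers(k)
        blocks.append(clr(kmer_rows[:, offset: offset + width], kmer_pseudocount))
        offset += width

    depths = np.stack([np.asarray(c.depths, dtype=float) for c in contigs])
    if n_samples > 1:
        blocks.append(clr(depths, depth_pseudocount))
    else:
        logd = np.log(depths + depth_pseudocount)
        blocks.append(logd - np.median(logd, axis=0, keepdims=True))

    matrix = np.concatenate(blocks, axis=1)
    return FeatureMatrix(
        contig_ids=[c.contig_id for c in contigs],
        matrix=matrix, ks=ks, n_samples=n_samples,
    )
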