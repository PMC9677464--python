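"""Readers and writers for the external formats the binner touches.

All tables are tab-separated with a single ``#``-prefixed header line.
GFF coordinates are 1-based inclusive throughout, matching the GFF3
standard; interval lists stored on :class:`ContigRecord` keep that
convention.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

FASTA_WRAP = 80


@dataclass
class ContigRecord:
    """One assembly sequence plus everything the binner knows about it."""

    contig_id: str
    sequence: str
    masked_intervals: list[tuple[int, int]] = field(default_factory=list)
    depths: np.ndarray = field(default_factory=lambda: np.zeros(0))
    marker_hits: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self, n_samples: int | None = None) -> None:
        for start, end in self.masked_intervals:
            if not (1 <= start <= end <= self.length):
                raise ValueError(
                    f"masked interval [{start},{end}] outside contig "
                    f"{self.contig_id!r} of length {self.length}"
                )
        if np.any(np.asarray(self.depths) < 0):
            raise ValueError(f"negative depth on contig {self.contig_id!r}")
        if n_samples is not None and len(self.depths) != n_samples:
            raise ValueError(
                f"contig {self.contig_id!r} has {len(self.depths)} depth "
                f"values, expected {n_samples}"
            )


def read_fasta(path: str | Path) -> list[ContigRecord]:
    """Read an assembly FASTA into :class:`ContigRecord` objects.

    Ids are the first whitespace-delimited token of each header and must
    be unique; sequences are uppercased.
    """
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        cid = rec.id
        if cid in seen:
            raise ValueError(f"duplicate contig id in FASTA: {cid!r}")
        seen.add(cid)
        records.append(ContigRecord(contig_id=cid, sequence=str(rec.seq).upper()))
    if not records:
        warnings.warn(f"FASTA file {path} contains no sequences")
    return records


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals, sorted and non-overlapping."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ivs:
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


DEFAULT_MASK_TYPES = frozenset({"rRNA", "repeat_region"})


def _iter_gff_rows(path: str | Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):  # trailing FASTA section (Prokka GFFs)
                break
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated GFF "
                    f"columns, found {len(fields)}"
                )
            yield lineno, fields


def parse_gff_masks(
    path: str | Path,
    mask_feature_types: Iterable[str] = DEFAULT_MASK_TYPES,
    contig_lengths: Mapping[str, int] | None = None,
) -> dict[str, list[tuple[int, int]]]:
    """Extract mask intervals (rRNA genes, CRISPR repeat regions) from GFF3.

    Only features whose type is in ``mask_feature_types`` are returned;
    strand is ignored. Overlapping intervals per contig are merged. If
    ``contig_lengths`` is given, intervals are clipped to contig bounds
    and unknown contigs trigger a warning (they are still returned — the
    join with the assembly happens later).
    """
    wanted = set(mask_feature_types)
    raw: dict[str, list[tuple[int, int]]] = {}
    for lineno, fields in _iter_gff_rows(path):
        seqid, _source, ftype, start_s, end_s = fields[:5]
        if ftype not in wanted:
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ValueError(
                f"{path}: line {lineno}: non-integer GFF coordinates"
            ) from exc
        if contig_lengths is not None:
            if seqid not in contig_lengths:
                warnings.warn(
                    f"GFF feature on unknown contig {seqid!r} (line {lineno})"
                )
            else:
                start = max(1, start)
                end = min(contig_lengths[seqid], end)
                if start > end:
                    continue
        raw.setdefault(seqid, []).append((start, end))
    return {cid: merge_intervals(ivs) for cid, ivs in raw.items()}


_TRNA_ISOTYPE = re.compile(r"tRNA-([A-Za-z]{3}|\?\?\?|SeC|Pyl|fMet|Undet)")
_RRNA_TYPES = ("5S", "16S", "23S")


def _gff_attributes(attr_field: str) -> dict[str, str]:
    attrs = {}
    for part in attr_field.split(";"):
        if "=" in part:
            key, val = part.split("=", 1)
            attrs[key.strip()] = val.strip()
    return attrs


def parse_gff_rna_features(
    path: str | Path,
) -> dict[str, tuple[set[str], set[str]]]:
    """Per-contig sets of tRNA isotypes and rRNA subunit types.

    tRNA uniqueness is keyed on the amino-acid isotype parsed from the
    ``product`` attribute (``tRNA-Ala`` and a second ``tRNA-Ala`` count
    once); rRNA types are drawn from {5S, 16S, 23S}. Used by the MIMAG
    high-quality draft criterion (>=18 unique tRNAs, three rRNAs);
    bin-level inventories are unions of these sets.
    """
    trnas: dict[str, set[str]] = {}
    rrnas: dict[str, set[str]] = {}
    for lineno, fields in _iter_gff_rows(path):
        seqid, _src, ftype = fields[0], fields[1], fields[2]
        if ftype not in ("tRNA", "rRNA"):
            continue
        attrs = _gff_attributes(fields[8])
        product = attrs.get("product", "")
        if not product:
            warnings.warn(
                f"{path}: line {lineno}: {ftype} feature without product "
                "attribute; not counted as unique"
            )
            continue
        if ftype == "tRNA":
            m = _TRNA_ISOTYPE.search(product)
            if m:
                trnas.setdefault(seqid, set()).add(m.group(1))
        else:
            for sub in _RRNA_TYPES:
                if re.search(rf"\b{sub}\b", product):
                    rrnas.setdefault(seqid, set()).add(sub)
                    break
    out: dict[str, tuple[set[str], set[str]]] = {}
    for cid in set(trnas) | set(rrnas):
        out[cid] = (trnas.get(cid, set()), rrnas.get(cid, set()))
    return out


def parse_gff_rna_counts(
    path: str | Path,
) -> dict[str, tuple[int, set[str]]]:
    """Unique tRNA isotype count and rRNA subunit types per contig."""
    return {
        cid: (len(isotypes), subunits)
        for cid, (isotypes, subunits) in parse_gff_rna_features(path).items()
    }


def read_depth_table(path: str | Path) -> pd.DataFrame:
    """Read the per-sample average-depth table.

    First column: contig id; remaining columns: numeric x-fold coverage,
    one per sample. An optional single ``#``-prefixed header line names
    the samples. Returns a DataFrame indexed by contig id.
    """
    with open(path) as fh:
        first = fh.readline()
    header = 0 if first.startswith("#") else None
    df = pd.read_csv(path, sep="\t", header=header, index_col=0)
    if header == 0:
        df.index.name = df.index.name.lstrip("#") if df.index.name else None
    else:
        df.columns = [f"sample_{i + 1}" for i in range(df.shape[1])]
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate contig ids in depth table: {dups}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric depth value in {path}: {exc}") from exc
    if (df.values < 0).any():
        raise ValueError(f"negative depth value in {path}")
    df.index = df.index.astype(str)
    return df


def read_marker_hits(path: str | Path) -> pd.DataFrame:
    """Read the marker-hit table: (contig_id, orf_id, marker_accession)."""
    with open(path) as fh:
        first = fh.readline()
    header = 0 if first.startswith("#") else None
    df = pd.read_csv(path, sep="\t", header=header, dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"marker hit table {path} needs >=3 columns")
    df = df.iloc[:, :3]
    df.columns = ["contig_id", "orf_id", "marker_accession"]
    if df["marker_accession"].isna().any() or (df["marker_accession"] == "").any():
        raise ValueError(f"empty marker accession in {path}")
    return df


def join_assembly(
    contigs: Sequence[ContigRecord],
    depth: pd.DataFrame | None = None,
    masks: Mapping[str, list[tuple[int, int]]] | None = None,
    marker_hits: pd.DataFrame | None = None,
) -> dict[str, ContigRecord]:
    """Attach depths, masks and marker hits to contig records in place.

    Contigs missing from the depth table get zero depth with a warning
    (zero-coverage contigs do occur in real assemblies); depth rows for
    unknown contigs are ignored.
    """
    by_id = {c.contig_id: c for c in contigs}
    if len(by_id) != len(contigs):
        raise ValueError("duplicate contig ids in assembly")
    n_samples = depth.shape[1] if depth is not None else 1
    missing = []
    for cid, rec in by_id.items():
        if depth is not None:
            if cid in depth.index:
                rec.depths = depth.loc[cid].to_numpy(dtype=float)
            else:
                rec.depths = np.zeros(n_samples)
                missing.append(cid)
        if masks is not None and cid in masks:
            clipped = [
                (max(1, s), min(rec.length, e))
                for s, e in masks[cid]
                if s <= rec.length and e >= 1
            ]
            rec.masked_intervals = merge_intervals(
                (s, e) for s, e in clipped if s <= e
            )
    if missing:
        warnings.warn(
            f"{len(missing)} contigs absent from depth table; zero depth "
            f"assumed (first: {missing[0]!r})"
        )
    if marker_hits is not None:
        for cid, group in marker_hits.groupby("contig_id"):
            if cid in by_id:
                by_id[cid].marker_hits = group["marker_accession"].tolist()
    for rec in by_id.values():
        rec.validate(n_samples=n_samples if depth is not None else None)
    return by_id


def load_inputs(
    assembly_path: str | Path,
    gff_path: str | Path | None = None,
    marker_path: str | Path | None = None,
    depth_path: str | Path | None = None,
    masking: bool = True,
    mask_feature_types: Iterable[str] = DEFAULT_MASK_TYPES,
) -> dict[str, ContigRecord]:
    """Read and join all binning inputs into contig records."""
    contigs = read_fasta(assembly_path)
    lengths = {c.contig_id: c.length for c in contigs}
    masks = (
        parse_gff_masks(gff_path, mask_feature_types, contig_lengths=lengths)
        if (gff_path and masking)
        else None
    )
    depth = read_depth_table(depth_path) if depth_path else None
    hits = read_marker_hits(marker_path) if marker_path else None
    return join_assembly(contigs, depth=depth, masks=masks, marker_hits=hits)


def write_bins(mags, assembly: Mapping[str, ContigRecord], out_dir: str | Path) -> None:
    """Write one FASTA per MAG, a contig-to-bin table and a run summary.

    MAG sequences are the untouched input contig sequences — masking
    only ever affects feature computation, never output. Raises if any
    contig appears in more than one MAG (bins must partition contigs).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bins_dir = out_dir / "bins"
    bins_dir.mkdir(exist_ok=True)

    claimed: dict[str, str] = {}
    for mag in mags:
        for cid in mag.contig_ids:
            if cid in claimed:
                raise ValueError(
                    f"contig {cid!r} assigned to both {claimed[cid]!r} "
                    f"and {mag.bin_id!r}"
                )
            claimed[cid] = mag.bin_id

    c2b_rows = []
    summary_rows = []
    for mag in mags:
        recs = [
            SeqRecord(Seq(assembly[cid].sequence), id=cid, description="")
            for cid in mag.contig_ids
        ]
        with open(bins_dir / f"{mag.bin_id}.fasta", "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
            writer.write_file(recs)
        q = mag.quality
        for cid in mag.contig_ids:
            c2b_rows.append(
                (cid, mag.bin_id, q.taxon, f"{q.completeness:.6f}",
                 f"{q.purity:.6f}", ";".join(sorted(mag.tier_flags)))
            )
        summary_rows.append(
            (mag.bin_id, len(mag.contig_ids), mag.total_bp, q.taxon, q.rank,
             f"{q.completeness:.6f}", f"{q.purity:.6f}",
             ";".join(sorted(mag.tier_flags)))
        )

    with open(out_dir / "contig_to_bin.tsv", "w") as fh:
        fh.write("#contig_id\tbin_id\ttaxon\tcompleteness\tpurity\ttiers\n")
        for row in c2b_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    with open(out_dir / "summary.tsv", "w") as fh:
        fh.write(
            "#bin_id\tn_contigs\ttotal_bp\ttaxon\trank\tcompleteness"
            "\tpurity\ttiers\n"
        )
        for row in summary_rows:
            fh.write("\t".join(map(str, row)) + "\n")
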