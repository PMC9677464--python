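"""Seeded synthetic communities for exercising the whole binning engine.

Each genome is sampled from its own order-2 Markov chain over {A,C,G,T}
(transition rows drawn from a Dirichlet; the concentration controls how
distinct genome signatures are — order 2 so that tetranucleotide
features carry genome identity, mirroring the k-mer-signature biology
without real genomes). Genomes are fragmented at uniform random
breakpoints into a requested number of contigs, marker complements of
an assigned taxon from the bundled hierarchy are planted once each with
placement probability proportional to contig length, and per-sample
depths are genome abundance times lognormal per-contig noise. rRNA and
CRISPR features are planted on a small share of contigs to exercise
masking, and tRNA/rRNA products to exercise MIMAG tiering.

Everything is deterministic under the community seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import clr, kmer_frequencies
from .io_formats import ContigRecord, merge_intervals
from .markers import ROOT, MarkerHierarchy, load_marker_hierarchy

_ALPHABET = np.array(list("ACGT"))

DEFAULT_CLASS_TAXA = (
    "Alphaproteobacteria", "Gammaproteobacteria", "Bacilli",
    "Clostridia", "Methanomicrobia", "Thermoprotei",
)

RRNA_PRODUCTS = {
    "16S": ("16S ribosomal RNA", 1200),
    "23S": ("23S ribosomal RNA", 1800),
    "5S": ("5S ribosomal RNA", 115),
}
TRNA_ISOTYPES = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro "
    "Ser Thr Trp Tyr Val"
).split()


def bundled_hierarchy_path() -> Path:
    return Path(
        importlib.resources.files("microbin").joinpath(
            "data/marker_hierarchy.tsv"
        )
    )


def load_bundled_hierarchy() -> MarkerHierarchy:
    return load_marker_hierarchy(bundled_hierarchy_path())


@dataclass
class CommunitySpec:
    """Study conditions for one synthetic community."""

    n_genomes: int = 5
    genome_length_range: tuple[int, int] = (400_000, 800_000)
    contigs_per_genome: tuple[int, int] = (20, 60)
    n_samples: int = 1
    abundance_mu: float = np.log(10.0)   # lognormal location of x-fold depth
    abundance_sigma: float = 1.0
    depth_noise_sigma: float = 0.1       # per-contig lognormal noise
    dirichlet_concentration: float = 1.0  # lower = more distinct signatures
    min_fragment_len: int = 500
    mask_contig_fraction: float = 0.05
    taxa: Sequence[str] | None = None    # taxon per genome; cycles default
    composition_groups: Sequence[int] | None = None  # genomes sharing a chain
    abundances: np.ndarray | None = None  # (n_genomes, n_samples) override
    seed: int = 0

    def __post_init__(self):
        if self.n_genomes < 1 or self.n_samples < 1:
            raise ValueError("counts must be positive")
        if self.abundance_sigma < 0 or self.depth_noise_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if self.contigs_per_genome[0] < 1:
            raise ValueError("need at least one contig per genome")


@dataclass
class GoldStandard:
    """Truth mapping contig -> genome with per-genome assembly sizes."""

    contig_to_genome: dict[str, str]
    genome_bp: dict[str, int]


@dataclass
class CommunityBundle:
    """In-memory fixture: contigs, tables, annotations and the truth."""

    spec: CommunitySpec
    contigs: list[ContigRecord]
    depth_table: pd.DataFrame
    marker_hits: pd.DataFrame
    gff_lines: list[str]
    gold: GoldStandard
    genome_taxa: dict[str, str]
    abundances: pd.DataFrame  # genomes x samples, the drawn truth
    contaminated_ids: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "assembly": out / "assembly.fasta",
            "gff": out / "annotations.gff",
            "depth": out / "depth.tsv",
            "markers": out / "marker_hits.tsv",
            "gold": out / "gold_standard.tsv",
        }
        with open(paths["assembly"], "w") as fh:
            for rec in self.contigs:
                fh.write(f">{rec.contig_id}\n")
                for i in range(0, rec.length, 80):
                    fh.write(rec.sequence[i: i + 80] + "\n")
        with open(paths["gff"], "w") as fh:
            fh.write("##gff-version 3\n")
            fh.writelines(line + "\n" for line in self.gff_lines)
        with open(paths["depth"], "w") as fh:
            cols = "\t".join(self.depth_table.columns)
            fh.write(f"#contig_id\t{cols}\n")
            for cid, row in self.depth_table.iterrows():
                vals = "\t".join(f"{v:.4f}" for v in row)
                fh.write(f"{cid}\t{vals}\n")
        with open(paths["markers"], "w") as fh:
            fh.write("#contig_id\torf_id\tmarker_accession\n")
            for _, r in self.marker_hits.iterrows():
                fh.write(f"{r.contig_id}\t{r.orf_id}\t{r.marker_accession}\n")
        with open(paths["gold"], "w") as fh:
            fh.write("#contig_id\tgenome_id\n")
            for cid, gid in self.gold.contig_to_genome.items():
                fh.write(f"{cid}\t{gid}\n")
        return paths


def read_gold_standard(path: str | Path) -> GoldStandard:
    with open(path) as fh:
        first = fh.readline()
    header = 0 if first.startswith("#") else None
    df = pd.read_csv(path, sep="\t", header=header, dtype=str)
    df.columns = ["contig_id", "genome_id"] + list(df.columns[2:])
    mapping = dict(zip(df["contig_id"], df["genome_id"]))
    return GoldStandard(contig_to_genome=mapping, genome_bp={})


def _markov_sequence(length: int, transitions: np.ndarray, rng) -> str:
    """Sample ``length`` bases from an order-2 chain (16 states x 4)."""
    cdf = np.cumsum(transitions, axis=1)
    cdf[:, -1] = 1.0
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    out[0] = rng.integers(4)
    out[1] = rng.integers(4)
    _walk(cdf, u, out)
    return "".join(_ALPHABET[out])


def _walk_py(cdf, u, out):
    state = out[0] * 4 + out[1]
    for t in range(2, out.shape[0]):
        row = cdf[state]
        x = u[t]
        b = 0
        while row[b] < x:
            b += 1
        out[t] = b
        state = (state % 4) * 4 + b


try:  # numba shaves the chain walk from seconds to milliseconds
    from numba import njit

    _walk = njit(cache=False)(_walk_py)
except Exception:  # pragma: no cover - accelerator only
    _walk = _walk_py


def _fragment_lengths(total: int, n: int, min_len: int, rng) -> np.ndarray:
    """Uniform random breakpoints with a minimum fragment length."""
    if total < n * min_len:
        raise ValueError(
            f"genome of {total} bp cannot host {n} contigs of >= {min_len} bp"
        )
    slack = total - n * min_len
    parts = rng.dirichlet(np.ones(n)) * slack
    lengths = np.floor(parts).astype(int) + min_len
    lengths[0] += total - int(lengths.sum())
    return lengths


def generate_community(spec: CommunitySpec) -> CommunityBundle:
    """Build a full seeded fixture bundle from a :class:`CommunitySpec`."""
    rng = np.random.default_rng(spec.seed)
    hierarchy = load_bundled_hierarchy()
    taxa = list(spec.taxa) if spec.taxa else [
        DEFAULT_CLASS_TAXA[i % len(DEFAULT_CLASS_TAXA)]
        for i in range(spec.n_genomes)
    ]
    if len(taxa) != spec.n_genomes:
        raise ValueError("need one taxon per genome")

    # lineage marker complements (domain + phylum + class sets, once each)
    complements = {}
    for taxon in set(taxa):
        lineage = []
        node = taxon
        while node != ROOT:
            lineage.append(node)
            node = next(iter(hierarchy.graph.predecessors(node)))
        comp = []
        for t in lineage:
            for ms in hierarchy.node(t).marker_sets:
                comp.extend(sorted(ms))
        complements[taxon] = comp

    groups = list(spec.composition_groups) if spec.composition_groups else list(
        range(spec.n_genomes)
    )
    if len(groups) != spec.n_genomes:
        raise ValueError("composition_groups must name one group per genome")
    chains: dict[int, np.ndarray] = {}
    for g in sorted(set(groups)):
        chains[g] = rng.dirichlet(
            np.full(4, spec.dirichlet_concentration), size=16
        )

    if spec.abundances is not None:
        abundances = np.asarray(spec.abundances, dtype=float)
        if abundances.shape != (spec.n_genomes, spec.n_samples):
            raise ValueError("abundances must be (n_genomes, n_samples)")
    else:
        abundances = rng.lognormal(
            spec.abundance_mu, spec.abundance_sigma,
            size=(spec.n_genomes, spec.n_samples),
        )

    contigs: list[ContigRecord] = []
    hit_rows: list[tuple[str, str, str]] = []
    gff_lines: list[str] = []
    gold_map: dict[str, str] = {}
    genome_bp: dict[str, int] = {}
    genome_taxa: dict[str, str] = {}
    depth_rows: dict[str, np.ndarray] = {}

    for gi in range(spec.n_genomes):
        gid = f"genome_{gi + 1:03d}"
        genome_taxa[gid] = taxa[gi]
        length = int(rng.integers(*spec.genome_length_range, endpoint=True))
        n_contigs = int(rng.integers(*spec.contigs_per_genome, endpoint=True))
        seq = _markov_sequence(length, chains[groups[gi]], rng)
        lens = _fragment_lengths(length, n_contigs, spec.min_fragment_len, rng)
        genome_bp[gid] = length

        offsets = np.concatenate([[0], np.cumsum(lens)])
        genome_contigs = []
        for ci in range(n_contigs):
            cid = f"{gid}_c{ci + 1:04d}"
            rec = ContigRecord(
                contig_id=cid,
                sequence=seq[offsets[ci]: offsets[ci + 1]],
            )
            gold_map[cid] = gid
            genome_contigs.append(rec)
            contigs.append(rec)

        # plant the taxon's full complement, one copy per marker
        comp = complements[taxa[gi]]
        if length < 2 * len(comp):
            raise ValueError(f"genome {gid} too short for {len(comp)} markers")
        probs = lens / lens.sum()
        placements = rng.choice(n_contigs, size=len(comp), p=probs)
        for mi, (marker, ci) in enumerate(zip(comp, placements)):
            rec = genome_contigs[ci]
            rec.marker_hits.append(marker)
            hit_rows.append((rec.contig_id, f"{gid}_orf{mi + 1:05d}", marker))

        # depth: genome abundance x lognormal per-contig noise
        for rec in genome_contigs:
            noise = rng.lognormal(0.0, spec.depth_noise_sigma, spec.n_samples)
            rec.depths = abundances[gi] * noise
            depth_rows[rec.contig_id] = rec.depths

        # MIMAG features: 20 tRNA isotypes + the three rRNA types
        big = [r for r in genome_contigs if r.length >= 2500] or genome_contigs
        for iso in TRNA_ISOTYPES:
            rec = big[int(rng.integers(len(big)))]
            start = int(rng.integers(1, max(2, rec.length - 80)))
            gff_lines.append(
                f"{rec.contig_id}\tsynthetic\ttRNA\t{start}\t{start + 75}\t."
                f"\t+\t.\tID={rec.contig_id}_t{iso};product=tRNA-{iso}"
            )
        for sub, (product, flen) in RRNA_PRODUCTS.items():
            rec = big[int(rng.integers(len(big)))]
            flen = min(flen, rec.length - 1)
            start = int(rng.integers(1, max(2, rec.length - flen)))
            end = start + flen - 1
            gff_lines.append(
                f"{rec.contig_id}\tsynthetic\trRNA\t{start}\t{end}\t.\t+\t."
                f"\tID={rec.contig_id}_r{sub};product={product}"
            )
            rec.masked_intervals = merge_intervals(
                rec.masked_intervals + [(start, end)]
            )

    # CRISPR-like repeat regions on a small share of contigs
    candidates = [r for r in contigs if r.length >= 1500]
    n_mask = int(round(spec.mask_contig_fraction * len(candidates)))
    for idx in rng.choice(len(candidates), size=n_mask, replace=False):
        rec = candidates[int(idx)]
        start = int(rng.integers(1, rec.length - 400))
        end = start + 299
        gff_lines.append(
            f"{rec.contig_id}\tsynthetic\trepeat_region\t{start}\t{end}\t."
            f"\t+\t.\tID={rec.contig_id}_crispr;rpt_family=CRISPR"
        )
        rec.masked_intervals = merge_intervals(
            rec.masked_intervals + [(start, end)]
        )

    depth_table = pd.DataFrame.from_dict(
        depth_rows, orient="index",
        columns=[f"sample_{s + 1}" for s in range(spec.n_samples)],
    )
    depth_table.index = depth_table.index.astype(str)
    marker_hits = pd.DataFrame(
        hit_rows, columns=["contig_id", "orf_id", "marker_accession"]
    )
    return CommunityBundle(
        spec=spec,
        contigs=contigs,
        depth_table=depth_table,
        marker_hits=marker_hits,
        gff_lines=gff_lines,
        gold=GoldStandard(contig_to_genome=gold_map, genome_bp=genome_bp),
        genome_taxa=genome_taxa,
        abundances=pd.DataFrame(
            abundances,
            index=list(genome_bp),
            columns=[f"sample_{s + 1}" for s in range(spec.n_samples)],
        ),
    )


def composition_separation(bundle: CommunityBundle, k: int = 4) -> float:
    """Inter- over intra-genome Manhattan distance of CLR k-mer profiles.

    Both terms are contig-to-genome-profile distances: intra compares
    each contig with its own genome's pooled profile, inter with the
    other genomes' profiles, so sampling noise from short contigs
    cancels in the ratio. Values well above 1 mean genome signatures
    are separable by composition alone; ~1 means contigs are no closer
    to their own genome than to others. Returns ``inf`` when every
    genome has a single contig (no intra-genome distance exists).
    """
    by_genome: dict[str, list[ContigRecord]] = {}
    for rec in bundle.contigs:
        by_genome.setdefault(bundle.gold.contig_to_genome[rec.contig_id], []).append(rec)
    if len(by_genome) < 2:
        raise ValueError("need at least 2 genomes")

    genome_profiles = {}
    contig_profiles: dict[str, list[np.ndarray]] = {}
    for gid, recs in by_genome.items():
        counts = [kmer_frequencies(r.sequence, ks=(k,)) for r in recs]
        genome_profiles[gid] = clr(np.sum(counts, axis=0)[None, :])[0]
        contig_profiles[gid] = [clr(c[None, :])[0] for c in counts]

    gids = sorted(genome_profiles)
    inter = [
        np.abs(cp - genome_profiles[other]).sum()
        for gid, cps in contig_profiles.items()
        for cp in cps
        for other in gids
        if other != gid
    ]
    intra = [
        np.abs(cp - genome_profiles[gid]).sum()
        for gid, cps in contig_profiles.items()
        for cp in cps
        if len(cps) > 1
    ]
    if not intra or np.mean(intra) == 0:
        return float("inf")
    return float(np.mean(inter) / np.mean(intra))


def inject_contamination(
    bundle: CommunityBundle, fraction: float, seed: int = 0
) -> CommunityBundle:
    """Swap a fraction of contigs' depth profiles onto another genome's.

    Creates mixed-signal clusters (composition says one genome, depth
    says another) to exercise cluster splitting. The gold standard is
    left unchanged; altered contig ids are recorded on the bundle.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0:
        return bundle
    rng = np.random.default_rng(seed)
    gids = sorted(bundle.abundances.index)
    n_swap = int(round(fraction * len(bundle.contigs)))
    chosen = rng.choice(len(bundle.contigs), size=n_swap, replace=False)
    altered = []
    for idx in sorted(int(i) for i in chosen):
        rec = bundle.contigs[idx]
        own = bundle.gold.contig_to_genome[rec.contig_id]
        others = [g for g in gids if g != own]
        target = others[int(rng.integers(len(others)))]
        noise = rng.lognormal(0.0, bundle.spec.depth_noise_sigma,
                              bundle.spec.n_samples)
        rec.depths = bundle.abundances.loc[target].to_numpy() * noise
        bundle.depth_table.loc[rec.contig_id] = rec.depths
        altered.append(rec.contig_id)
    bundle.contaminated_ids = altered
    return bundle
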