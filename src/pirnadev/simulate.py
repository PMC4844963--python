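"""Synthetic miniature study: genome, annotations, raw small-RNA reads,
truth alignments, CTSS tables and auxiliary tables.

The generator emulates the statistical structure the analysis relies on,
at desk scale, with full ground truth:

* a random genome carved into non-overlapping piRNA clusters, a configurable
  fraction of them intergenic;
* per-sample read populations in which a stage/tissue-specific fraction of
  reads originates inside clusters, cluster-derived inserts start with T
  (1U) with a profile-specific probability, and insert lengths follow a
  mixture over modal lengths (unimodal 26-27 vs bimodal 26-27 + 29-30);
* samples sharing a ``shared_pool_id`` draw inserts from the same population
  of cluster positions, so exact-sequence sharing between them is high;
* raw reads carry a 4-base 5' barcode, a 3' adapter, and two-state Phred
  qualities (Q30 with occasional low-quality tails) so every preprocessing
  rule is exercised;
* CTSS counts follow a power law with a configurable reverse-cumulative
  exponent, concentrated in promoter windows of truth-expressed genes;
* complementary guide/sense read pairs can be planted at known loci for
  target-scan recovery tests.

Identical seeds give byte-identical outputs.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import zeta

from . import io as pio
from .model import (AlignmentRecord, GeneModel, PiRNACluster, RepeatElement,
                    reverse_complement)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_CONSENSUS = {"SINE": 300, "LINE": 6000, "LTR": 500, "other": 1000}


class ConfigurationError(ValueError):
    pass


@dataclass
class StageProfile:
    """Signal structure of one tissue/stage sample."""

    sample_id: str
    n_reads: int
    cluster_read_fraction: float
    u1_fraction: float
    length_mixture: Sequence[tuple[int, float]] = ((26, 1.0),)
    shared_pool_id: str = "default"

    def __post_init__(self) -> None:
        weights = [w for _, w in self.length_mixture]
        if abs(sum(weights) - 1.0) > 1e-6:
            raise ConfigurationError("length mixture weights must sum to 1")
        if any(not 25 <= m <= 35 for m, _ in self.length_mixture):
            raise ConfigurationError("modal lengths must lie in [25, 35]")
        if not 0.0 <= self.cluster_read_fraction <= 1.0:
            raise ConfigurationError("cluster_read_fraction must be in [0, 1]")
        if not 0.0 <= self.u1_fraction <= 1.0:
            raise ConfigurationError("u1_fraction must be in [0, 1]")


@dataclass
class SimulationConfig:
    genome_length: int = 400_000
    n_chromosomes: int = 2
    n_clusters: int = 40
    cluster_length_range: tuple[int, int] = (1500, 3000)
    intergenic_fraction: float = 0.8
    profiles: list[StageProfile] = field(default_factory=list)
    rng_seed: int = 0
    # generator conditions beyond the core fields
    active_cluster_fraction: float = 0.25
    pool_size: int = 600
    n_genes: int = 30
    n_repeats: int = 40
    n_ncrnas: int = 20
    adapter: str = DEFAULT_ADAPTER
    barcode: str = "ACGT"
    read_length: int = 40
    low_quality_rate: float = 0.02
    multimap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.intergenic_fraction <= 1.0:
            raise ConfigurationError("intergenic_fraction must be in [0, 1]")
        if self.cluster_length_range[0] > self.cluster_length_range[1]:
            raise ConfigurationError("bad cluster length range")
        profiles = [
            StageProfile(**p) if isinstance(p, dict) else p for p in self.profiles
        ]
        for p in profiles:
            if isinstance(p.length_mixture, list):
                p.length_mixture = [tuple(t) for t in p.length_mixture]
        self.profiles = profiles

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class Reference:
    config: SimulationConfig
    genome: dict[str, str]
    clusters: list[PiRNACluster]
    genes: list[GeneModel]
    repeats: list[RepeatElement]
    ncrnas: dict[str, str]
    _pools: dict = field(default_factory=dict, repr=False)


@dataclass
class TruthAlignment:
    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    origin: str  # cluster_id or "background"

    def to_alignment(self, sequence: Optional[str] = None) -> AlignmentRecord:
        return AlignmentRecord(self.read_id, self.chrom, self.start, self.end,
                               self.strand, sequence)


@dataclass
class SampleTruth:
    sample_id: str
    alignments: list[TruthAlignment]
    expressed_clusters: list[str]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


def _place_intervals(
    rng: np.random.Generator, region_length: int, lengths: Sequence[int], margin: int = 50
) -> list[tuple[int, int]]:
    """Non-overlapping intervals of the given lengths, uniformly spaced gaps."""
    total = sum(lengths) + 2 * margin
    free = region_length - total
    if free < 0:
        raise ConfigurationError(
            f"{len(lengths)} intervals totalling {sum(lengths)} bp do not fit "
            f"in {region_length} bp without overlap"
        )
    gaps = rng.dirichlet(np.ones(len(lengths) + 1)) * free
    out = []
    cursor = margin
    for length, gap in zip(lengths, gaps):
        cursor += int(gap)
        out.append((cursor, cursor + length))
        cursor += length
    return out


def generate_reference(config: SimulationConfig) -> Reference:
    """Genome + cluster/gene/repeat/ncRNA annotations with ground truth."""
    rng = np.random.default_rng(config.rng_seed)
    chrom_len = config.genome_length // config.n_chromosomes
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome = {c: _random_sequence(rng, chrom_len) for c in chrom_names}

    # clusters, round-robin across chromosomes, non-overlapping
    lo, hi = config.cluster_length_range
    clusters: list[PiRNACluster] = []
    if config.n_clusters > 0:
        per_chrom: dict[str, list[int]] = {c: [] for c in chrom_names}
        lengths = rng.integers(lo, hi + 1, size=config.n_clusters)
        for i, length in enumerate(lengths):
            per_chrom[chrom_names[i % len(chrom_names)]].append(int(length))
        n_intergenic = round(config.n_clusters * config.intergenic_fraction)
        klasses = ["intergenic"] * n_intergenic + ["genic"] * (config.n_clusters - n_intergenic)
        rng.shuffle(klasses)
        idx = 0
        for chrom in chrom_names:
            for start, end in _place_intervals(rng, chrom_len, per_chrom[chrom]):
                clusters.append(
                    PiRNACluster(f"cluster_{idx:04d}", chrom, start, end, klasses[idx])
                )
                idx += 1
        clusters.sort(key=lambda c: c.cluster_id)

    # optional multi-mapping: copy a segment of some clusters elsewhere
    if config.multimap_fraction > 0 and clusters:
        n_dup = int(round(config.multimap_fraction * len(clusters)))
        for c in rng.choice(clusters, size=n_dup, replace=False):
            seg_len = min(200, c.length)
            seg = genome[c.chrom][c.start:c.start + seg_len]
            target_chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            pos = _random_background_position(rng, {target_chrom: chrom_len},
                                              clusters, seg_len)[1]
            g = genome[target_chrom]
            genome[target_chrom] = g[:pos] + seg + g[pos + seg_len:]

    genes = _make_genes(rng, config, genome, clusters)
    repeats = _make_repeats(rng, config, chrom_names, chrom_len)
    ncrnas = {
        f"ncRNA_{i:04d}": _random_sequence(rng, int(rng.integers(70, 201)))
        for i in range(config.n_ncrnas)
    }
    return Reference(config, genome, clusters, genes, repeats, ncrnas)


def _cluster_index(clusters: Sequence[PiRNACluster]) -> dict[str, list[tuple[int, int]]]:
    idx: dict[str, list[tuple[int, int]]] = {}
    for c in clusters:
        idx.setdefault(c.chrom, []).append((c.start, c.end))
    for lst in idx.values():
        lst.sort()
    return idx


def _in_any(intervals: Sequence[tuple[int, int]], start: int, end: int) -> bool:
    return any(s < end and start < e for s, e in intervals)


def _random_background_position(
    rng: np.random.Generator,
    chrom_lens: Mapping[str, int],
    clusters: Sequence[PiRNACluster],
    length: int,
) -> tuple[str, int]:
    """Uniform genomic position whose interval avoids every cluster."""
    idx = _cluster_index(clusters)
    chroms = list(chrom_lens)
    weights = np.array([chrom_lens[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(10_000):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        pos = int(rng.integers(0, chrom_lens[chrom] - length))
        if not _in_any(idx.get(chrom, []), pos, pos + length):
            return chrom, pos
    raise ConfigurationError("could not place a background interval outside clusters")


def _make_genes(rng, config, genome, clusters) -> list[GeneModel]:
    genes = []
    chrom_lens = {c: len(s) for c, s in genome.items()}
    genic = [c for c in clusters if c.klass == "genic"]
    serial = 0
    for c in genic:  # each genic cluster overlaps a gene
        strand = "+" if rng.random() < 0.5 else "-"
        start = max(0, c.start - 500)
        end = min(chrom_lens[c.chrom], c.end + 500)
        tss = start if strand == "+" else end - 1
        genes.append(GeneModel(f"gene_{serial:04d}", c.chrom, strand, start, end, (tss,)))
        serial += 1
    while serial < len(genic) + config.n_genes:
        length = int(rng.integers(1500, 3001))
        chrom, start = _random_background_position(rng, chrom_lens, clusters, length)
        strand = "+" if rng.random() < 0.5 else "-"
        n_tss = int(rng.integers(1, 3))
        if strand == "+":
            tss = tuple(sorted(int(start + rng.integers(0, 200)) for _ in range(n_tss)))
        else:
            tss = tuple(sorted(int(start + length - 1 - rng.integers(0, 200))
                               for _ in range(n_tss)))
        genes.append(GeneModel(f"gene_{serial:04d}", chrom, strand, start,
                               start + length, tss))
        serial += 1
    return genes


def _make_repeats(rng, config, chrom_names, chrom_len) -> list[RepeatElement]:
    repeats = []
    families = list(_CONSENSUS)
    for i in range(config.n_repeats):
        family = families[int(rng.integers(len(families)))]
        consensus = _CONSENSUS[family]
        length = max(30, int(consensus * rng.uniform(0.4, 1.1)))
        length = min(length, chrom_len - 10)
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        start = int(rng.integers(0, chrom_len - length))
        strand = "+" if rng.random() < 0.5 else "-"
        repeats.append(RepeatElement(chrom, start, start + length, strand, family,
                                     consensus, name=f"repeat_{i:04d}"))
    return repeats


# ------------------------------------------------------------------- pools

@dataclass
class _Pool:
    active_clusters: list[str]
    # anchors: (cluster_id, chrom, start_offset_absolute, strand); split by 5' base
    t_anchors: list[tuple[str, str, int, str]]
    other_anchors: list[tuple[str, str, int, str]]


def _pool_seed(base_seed: int, pool_id: str) -> int:
    return (int(base_seed) ^ zlib.crc32(pool_id.encode())) % (2**31 - 1)


def _anchor_first_base(genome, chrom, pos, strand, max_len=35) -> str:
    if strand == "+":
        return genome[chrom][pos]
    return reverse_complement(genome[chrom][pos + max_len - 1])


def _get_pool(reference: Reference, pool_id: str) -> _Pool:
    if pool_id in reference._pools:
        return reference._pools[pool_id]
    config = reference.config
    if not reference.clusters:
        raise ConfigurationError("cluster reads requested but reference has no clusters")
    rng = np.random.default_rng(_pool_seed(config.rng_seed, pool_id))
    n_active = max(1, round(config.active_cluster_fraction * len(reference.clusters)))
    chosen = rng.choice(len(reference.clusters), size=n_active, replace=False)
    active = [reference.clusters[i] for i in sorted(chosen)]
    t_anchors, other_anchors = [], []
    max_len = 35
    for _ in range(config.pool_size):
        c = active[int(rng.integers(n_active))]
        offset = int(rng.integers(c.start, c.end - max_len))
        strand = "+" if rng.random() < 0.5 else "-"
        anchor = (c.cluster_id, c.chrom, offset, strand)
        first = _anchor_first_base(reference.genome, c.chrom, offset, strand)
        (t_anchors if first == "T" else other_anchors).append(anchor)
    # guarantee both 5'-base classes exist so any u1_fraction is realizable
    if not t_anchors or not other_anchors:
        need_t = not t_anchors
        for c in active:
            for pos in range(c.start, c.end - max_len):
                for strand in ("+", "-"):
                    first = _anchor_first_base(reference.genome, c.chrom, pos, strand)
                    if (first == "T") == need_t:
                        anchor = (c.cluster_id, c.chrom, pos, strand)
                        (t_anchors if need_t else other_anchors).append(anchor)
                        break
                if (t_anchors if need_t else other_anchors):
                    break
            if (t_anchors if need_t else other_anchors):
                break
    pool = _Pool([c.cluster_id for c in active], t_anchors, other_anchors)
    reference._pools[pool_id] = pool
    return pool


# ----------------------------------------------------------- small RNA reads

def _draw_lengths(rng, profile: StageProfile, n: int) -> np.ndarray:
    """Insert lengths: pick a mixture component, then its modal length or the
    next one up with equal probability (e.g. the 26~27 peak), clipped to 25-35."""
    modes = np.array([m for m, _ in profile.length_mixture])
    weights = np.array([w for _, w in profile.length_mixture])
    comp = rng.choice(len(modes), size=n, p=weights)
    jitter = rng.integers(0, 2, size=n)
    return np.clip(modes[comp] + jitter, 25, 35)


def simulate_small_rna_sample(
    reference: Reference, profile: StageProfile, seed: int
) -> tuple[list[tuple[str, str, list[int]]], SampleTruth]:
    """Raw FASTQ-style records (id, sequence, qualities) plus ground truth.

    Each record is barcode + insert + adapter prefix, truncated to the
    platform read length.  Cluster-derived inserts start with T with
    probability ``profile.u1_fraction``; background reads are uniform over
    the non-cluster genome.
    """
    config = reference.config
    if profile.cluster_read_fraction > 0 and not reference.clusters:
        raise ConfigurationError("cluster_read_fraction > 0 with empty cluster set")
    rng = np.random.default_rng(seed)
    pool = (_get_pool(reference, profile.shared_pool_id)
            if profile.cluster_read_fraction > 0 else None)
    chrom_lens = {c: len(s) for c, s in reference.genome.items()}

    n = profile.n_reads
    from_cluster = rng.random(n) < profile.cluster_read_fraction
    lengths = _draw_lengths(rng, profile, n)
    records: list[tuple[str, str, list[int]]] = []
    truth: list[TruthAlignment] = []

    for i in range(n):
        read_id = f"{profile.sample_id}:{i:07d}"
        L = int(lengths[i])
        if from_cluster[i]:
            use_t = rng.random() < profile.u1_fraction
            anchors = pool.t_anchors if use_t else pool.other_anchors
            cluster_id, chrom, pos, strand = anchors[int(rng.integers(len(anchors)))]
            origin = cluster_id
        else:
            chrom, pos = _random_background_position(rng, chrom_lens,
                                                     reference.clusters, 35)
            strand = "+" if rng.random() < 0.5 else "-"
            origin = "background"
        if strand == "+":
            start, end = pos, pos + L
            insert = reference.genome[chrom][start:end]
        else:
            # anchor marks the 5' end base at pos+34 on the minus strand
            end = pos + 35
            start = end - L
            insert = reverse_complement(reference.genome[chrom][start:end])
        truth.append(TruthAlignment(read_id, chrom, start, end, strand, origin))

        full = (config.barcode + insert + config.adapter)[: config.read_length]
        quals = [30] * len(full)
        if rng.random() < config.low_quality_rate:
            t = int(rng.integers(0, len(full)))
            for j in range(t, len(full)):
                quals[j] = int(rng.integers(2, 16))
        records.append((read_id, full, quals))

    expressed = pool.active_clusters if pool is not None else []
    return records, SampleTruth(profile.sample_id, truth, list(expressed))


def truth_alignments_for(
    processed_ids: Sequence[str], truth: SampleTruth,
    inserts: Mapping[str, str] | None = None,
) -> list[AlignmentRecord]:
    """Alignments of retained reads, looked up from ground truth (the stand-in
    for genome alignment, which is outside this package's scope).

    A read whose retained insert no longer matches its true insert (a
    low-quality tail can leave a spurious shorter adapter match) would not
    align at its origin; such reads are dropped, as an aligner would drop
    them.
    """
    by_id = {t.read_id: t for t in truth.alignments}
    out = []
    for rid in processed_ids:
        t = by_id[rid]
        seq = inserts.get(rid) if inserts else None
        if seq is not None and len(seq) != t.end - t.start:
            continue
        out.append(t.to_alignment(seq))
    return out


# ------------------------------------------------------------------- CTSS

def random_gene_tpm(
    reference: Reference, expressed_fraction: float = 0.6, seed: int = 0,
    mean_log_tpm: float = 2.0,
) -> dict[str, float]:
    """Truth expression: a fraction of genes silent (tpm 0), the rest lognormal."""
    rng = np.random.default_rng(seed)
    tpm = {}
    for g in reference.genes:
        if rng.random() < expressed_fraction:
            tpm[g.gene_id] = float(np.exp(rng.normal(mean_log_tpm, 1.0)))
        else:
            tpm[g.gene_id] = 0.0
    return tpm


def simulate_ctss_sample(
    reference: Reference,
    gene_tpm_truth: Mapping[str, float],
    alpha: float = 1.25,
    total_tags: int = 1_000_000,
    seed: int = 0,
    upstream: int = 1000,
    downstream: int = 500,
) -> pd.DataFrame:
    """CTSS count table with a power-law count distribution (reverse-cumulative
    exponent ``alpha``), sites placed in promoter windows of genes with
    truth tpm > 0 and allocated proportionally to tpm."""
    if alpha <= 1:
        raise ConfigurationError("alpha must exceed 1")
    if total_tags <= 0:
        raise ConfigurationError("total_tags must be positive")
    rng = np.random.default_rng(seed)
    genes = {g.gene_id: g for g in reference.genes}
    ids = [g for g, t in gene_tpm_truth.items() if t > 0 and g in genes]
    if not ids:
        raise ConfigurationError("no expressed genes in the truth table")
    weights = np.array([gene_tpm_truth[g] for g in ids], dtype=float)
    weights /= weights.sum()
    n_sites = max(2, int(total_tags / float(zeta(alpha))))
    site_genes = rng.choice(len(ids), size=n_sites, p=weights)
    # counts with P(count >= x) = x^-alpha: floor of a continuous Pareto draw
    u = rng.random(n_sites)
    counts = np.minimum(np.floor(u ** (-1.0 / alpha)), 1e7).astype(np.int64)
    records: dict[tuple[str, int, str], int] = {}
    chrom_lens = {c: len(s) for c, s in reference.genome.items()}
    for gi, count in zip(site_genes, counts):
        g = genes[ids[gi]]
        tss = g.tss_positions[int(rng.integers(len(g.tss_positions)))]
        if g.strand == "+":
            lo, hi = tss - upstream, tss + downstream
        else:
            lo, hi = tss - downstream, tss + upstream
        lo = max(0, lo)
        hi = min(chrom_lens[g.chrom] - 1, hi)
        pos = int(rng.integers(lo, hi + 1))
        key = (g.chrom, pos, g.strand)
        records[key] = records.get(key, 0) + int(count)
    rows = [
        {"chrom": c, "position": p, "strand": s, "count": n}
        for (c, p, s), n in sorted(records.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "position", "strand", "count"])


# --------------------------------------------------------- planted targets

def plant_target_sites(
    reference: Reference,
    n_sites: int = 5,
    seed: int = 0,
    guide_len: int = 26,
    n_mismatches: int = 2,
    seed_len: int = 10,
) -> tuple[dict[str, str], dict[str, str], list[dict]]:
    """Plant guide/sense pairs at gene loci.

    The sense read matches the locus exactly (+ strand); the guide read is
    the reverse complement with ``n_mismatches`` substitutions confined to
    non-seed read positions, so the scan must recover every site.
    """
    rng = np.random.default_rng(seed)
    if not reference.genes:
        raise ConfigurationError("reference has no genes to plant sites in")
    guides, senses, sites = {}, {}, []
    complement = {"A": "C", "C": "A", "G": "T", "T": "G"}  # guaranteed substitution
    for i in range(n_sites):
        g = reference.genes[int(rng.integers(len(reference.genes)))]
        pos = int(rng.integers(g.start, g.end - guide_len))
        locus = reference.genome[g.chrom][pos: pos + guide_len]
        sense = locus
        guide = list(reverse_complement(locus))
        mm_positions = rng.choice(np.arange(seed_len, guide_len),
                                  size=n_mismatches, replace=False)
        for p in mm_positions:
            guide[p] = complement[guide[p]]
        guides[f"guide_{i:03d}"] = "".join(guide)
        senses[f"sense_{i:03d}"] = sense
        sites.append({"chrom": g.chrom, "start": pos, "end": pos + guide_len,
                      "gene_id": g.gene_id, "guide_id": f"guide_{i:03d}",
                      "sense_id": f"sense_{i:03d}"})
    return guides, senses, sites


def synthetic_gfold(
    tpm_a: Mapping[str, float], tpm_b: Mapping[str, float]
) -> dict[str, float]:
    """log2((a+1)/(b+1)) stand-in for a generalized fold change table."""
    genes = set(tpm_a) | set(tpm_b)
    return {
        g: float(np.log2((tpm_a.get(g, 0.0) + 1.0) / (tpm_b.get(g, 0.0) + 1.0)))
        for g in genes
    }


# ------------------------------------------------------------------ writing

def write_reference(reference: Reference, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_fasta(reference.genome, outdir / "genome.fasta")
    pio.write_clusters_bed(reference.clusters, outdir / "clusters.bed")
    pio.write_gene_table(reference.genes, outdir / "genes.tsv")
    pio.write_repeat_table(reference.repeats, outdir / "repeats.tsv")
    pio.write_fasta(reference.ncrnas, outdir / "ncrna.fasta")


def write_sample(
    records: Sequence[tuple[str, str, Sequence[int]]],
    truth: SampleTruth,
    outdir: str | Path,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_fastq(records, outdir / f"{truth.sample_id}.fastq")
    pio.write_alignments_bed(
        (t.to_alignment() for t in truth.alignments),
        outdir / f"{truth.sample_id}.truth.bed",
    )
    origin_counts: dict[str, int] = {}
    for t in truth.alignments:
        origin_counts[t.origin] = origin_counts.get(t.origin, 0) + 1
    manifest = {
        "sample_id": truth.sample_id,
        "n_reads": len(truth.alignments),
        "expressed_clusters": truth.expressed_clusters,
        "origin_counts": origin_counts,
    }
    pio.write_json(manifest, outdir / f"{truth.sample_id}.truth.json")
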