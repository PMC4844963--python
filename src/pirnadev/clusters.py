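"""piRNA cluster expression calling.

A cluster is called expressed when it has (i) >= 100 contained reads,
(ii) RPKM >= 10, and (iii) maximum per-base depth / read count < 0.9 — the
last criterion guards against a single PCR-duplicated stack dominating the
signal.  "Mapped within" means the whole alignment interval is contained in
the cluster interval (an any-overlap mode is available); multi-mapping reads
are kept and contribute once per containing cluster.
"""
from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .model import AlignmentRecord, PiRNACluster, intervals_overlap

READ_COUNT_MIN = 100
RPKM_MIN = 10.0
DEPTH_RATIO_MAX = 0.9


@dataclass
class ClusterExpressionRecord:
    cluster_id: str
    read_count: int
    rpkm: float
    max_depth: int
    depth_ratio: float
    expressed: bool


def _validate_nonoverlap(clusters: Sequence[PiRNACluster]) -> None:
    by_chrom: dict[str, list[PiRNACluster]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, cs in by_chrom.items():
        cs.sort(key=lambda c: c.start)
        for a, b in zip(cs, cs[1:]):
            if b.start < a.end:
                warnings.warn(
                    f"overlapping clusters on {chrom}: {a.cluster_id}/{b.cluster_id}; "
                    "alignments will be credited to every containing cluster"
                )
                return


def assign_alignments(
    alignments: Iterable[AlignmentRecord],
    clusters: Sequence[PiRNACluster],
    mode: str = "contained",
) -> dict[str, tuple[int, np.ndarray]]:
    """Per-cluster read count and per-base depth of contained alignments.

    mode="contained" (default): an alignment counts iff fully inside the
    cluster.  mode="overlap": >=1 shared base suffices (depth still clipped
    to the cluster interval).
    """
    if mode not in ("contained", "overlap"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    _validate_nonoverlap(clusters)
    by_chrom: dict[str, list[PiRNACluster]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chrom, []).append(c)
    starts_by_chrom = {}
    max_len_by_chrom = {}
    for chrom, cs in by_chrom.items():
        cs.sort(key=lambda c: c.start)
        starts_by_chrom[chrom] = [c.start for c in cs]
        max_len_by_chrom[chrom] = max(c.length for c in cs)

    result = {c.cluster_id: [0, np.zeros(c.length, dtype=np.int32)] for c in clusters}
    cluster_by_id = {c.cluster_id: c for c in clusters}

    for aln in alignments:
        cs = by_chrom.get(aln.chrom)
        if not cs:
            continue
        starts = starts_by_chrom[aln.chrom]
        # candidate clusters start at most one max cluster length to the left
        lo = bisect_right(starts, aln.start - max_len_by_chrom[aln.chrom])
        hi = bisect_right(starts, aln.end - 1 if mode == "overlap" else aln.start)
        for c in cs[max(lo - 1, 0):hi]:
            if mode == "contained":
                hit = c.start <= aln.start and aln.end <= c.end
            else:
                hit = intervals_overlap(aln.start, aln.end, c.start, c.end)
            if hit:
                entry = result[c.cluster_id]
                entry[0] += 1
                s = max(aln.start, c.start) - c.start
                e = min(aln.end, c.end) - c.start
                entry[1][s:e] += 1

    return {cid: (n, depth) for cid, (n, depth) in result.items()}


def rpkm(read_count: int, cluster_length_bp: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of cluster per million genome-mapped reads."""
    if cluster_length_bp <= 0:
        raise ValueError("cluster length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    return read_count / ((cluster_length_bp / 1000.0) * (total_mapped_reads / 1e6))


def call_expressed(
    read_count: int,
    rpkm_value: float,
    depth_ratio: float,
    min_reads: int = READ_COUNT_MIN,
    min_rpkm: float = RPKM_MIN,
    max_depth_ratio: float = DEPTH_RATIO_MAX,
) -> bool:
    """Expression call: count >= 100, RPKM >= 10 (inclusive), ratio < 0.9 (exclusive)."""
    return read_count >= min_reads and rpkm_value >= min_rpkm and depth_ratio < max_depth_ratio


def expression_table(
    alignments: Iterable[AlignmentRecord],
    clusters: Sequence[PiRNACluster],
    total_mapped_reads: int,
    mode: str = "contained",
) -> pd.DataFrame:
    assigned = assign_alignments(alignments, clusters, mode=mode)
    rows = []
    for c in clusters:
        count, depth = assigned[c.cluster_id]
        max_depth = int(depth.max()) if count else 0
        ratio = max_depth / count if count else 0.0
        value = rpkm(count, c.length, total_mapped_reads)
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "klass": c.klass,
                "read_count": count,
                "rpkm": value,
                "max_depth": max_depth,
                "depth_ratio": ratio,
                "expressed": call_expressed(count, value, ratio),
            }
        )
    return pd.DataFrame(rows)


def intergenic_enrichment(
    expressed_ids: Iterable[str], clusters: Sequence[PiRNACluster]
) -> float:
    """One-tailed Fisher exact test for intergenic enrichment among expressed clusters.

    Upper hypergeometric tail P(X >= observed expressed-and-intergenic count)
    with population = all clusters, successes = intergenic clusters, draws =
    expressed clusters.
    """
    expressed = set(expressed_ids)
    if not expressed:
        raise ValueError("empty expressed set")
    ids = {c.cluster_id for c in clusters}
    if not expressed <= ids:
        raise ValueError("expressed ids not a subset of cluster ids")
    N = len(clusters)
    K = sum(1 for c in clusters if c.klass == "intergenic")
    n = len(expressed)
    k = sum(1 for c in clusters if c.klass == "intergenic" and c.cluster_id in expressed)
    return float(hypergeom.sf(k - 1, N, K, n))


# ------------------------------------------------------------------ summary

def round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_string(numerator: int, denominator: int, decimals: int | None = None) -> str:
    """Half-up rounded percentage as printed in the report tables.

    decimals=None picks the convention used for cluster-mapping fractions:
    two decimals below 1%, whole percent otherwise.
    """
    if denominator == 0:
        return "NA"
    pct = 100.0 * numerator / denominator
    if decimals is None:
        decimals = 2 if 0.0 < pct < 1.0 else 0
    value = round_half_up(pct, decimals)
    return f"{value:.{decimals}f}" if decimals else f"{int(value)}"


def mapping_summary(per_sample: Sequence[Mapping]) -> pd.DataFrame:
    """Counts and printed-style percentages of genome- and cluster-mapped reads.

    Each entry needs: sample, sequenced, genome_mapped, cluster_mapped.
    Genome-mapping rates print as whole percent; cluster fractions as whole
    percent, or two decimals when below 1%.
    """
    rows = []
    for s in per_sample:
        rows.append(
            {
                "sample": s["sample"],
                "sequenced": s["sequenced"],
                "genome_mapped": s["genome_mapped"],
                "pct_mapped": percent_string(s["genome_mapped"], s["sequenced"], 0),
                "cluster_mapped": s["cluster_mapped"],
                "pct_in_clusters": percent_string(s["cluster_mapped"], s["genome_mapped"]),
            }
        )
    return pd.DataFrame(rows)
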