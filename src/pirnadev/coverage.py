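"""piRNA production profiles along clusters and cross-sample correlation.

Each expressed cluster is cut into non-overlapping 100-base windows; the
profile is the fraction of cluster reads falling in each window (a read is
assigned to the window holding its 5'-most coordinate; the trailing partial
window is kept).  Profiles of the same cluster in two samples are compared
by Pearson correlation; only correlations with p <= 0.001 are retained, and
the retained values are summarized by their median.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import AlignmentRecord, PiRNACluster


@dataclass
class WindowProfile:
    cluster_id: str
    window_size: int
    fractions: np.ndarray


def window_fractions(
    cluster: PiRNACluster,
    alignments: Iterable[AlignmentRecord],
    window_size: int = 100,
) -> WindowProfile:
    """Per-window read fractions for one cluster.

    Only alignments fully contained in the cluster contribute; each is
    assigned to exactly one window by its 5'-most genomic coordinate.
    """
    n_windows = math.ceil(cluster.length / window_size)
    counts = np.zeros(n_windows, dtype=np.int64)
    for aln in alignments:
        if aln.chrom != cluster.chrom:
            continue
        if aln.start < cluster.start or aln.end > cluster.end:
            continue
        counts[(aln.five_prime - cluster.start) // window_size] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError(f"no contained reads in cluster {cluster.cluster_id}")
    return WindowProfile(cluster.cluster_id, window_size, counts / total)


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with a two-sided t-approximation p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_summary(
    profile_pairs: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    p_cutoff: float = 0.001,
) -> tuple[pd.DataFrame, float | None]:
    """Per-cluster correlations for one sample pair, plus the median retained r.

    ``profile_pairs`` maps cluster_id -> (profile in sample A, profile in
    sample B) for clusters expressed in both samples.  Pairs whose
    correlation is undefined (constant profile) are skipped with a warning.
    """
    rows = []
    for cluster_id, (x, y) in profile_pairs.items():
        try:
            r, p = pearson_with_p(x, y)
        except ValueError as exc:
            warnings.warn(f"skipping {cluster_id}: {exc}")
            continue
        rows.append({"cluster_id": cluster_id, "r": r, "p": p, "retained": p <= p_cutoff})
    table = pd.DataFrame(rows, columns=["cluster_id", "r", "p", "retained"])
    retained = table.loc[table["retained"], "r"]
    median = float(retained.median()) if len(retained) else None
    return table, median


def sample_pair_profiles(
    clusters: Sequence[PiRNACluster],
    expressed_a: Iterable[str],
    expressed_b: Iterable[str],
    alignments_a: Sequence[AlignmentRecord],
    alignments_b: Sequence[AlignmentRecord],
    window_size: int = 100,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Window profiles for every cluster called expressed in BOTH samples."""
    shared = set(expressed_a) & set(expressed_b)
    pairs = {}
    for cluster in clusters:
        if cluster.cluster_id not in shared:
            continue
        pa = window_fractions(cluster, alignments_a, window_size)
        pb = window_fractions(cluster, alignments_b, window_size)
        pairs[cluster.cluster_id] = (pa.fractions, pb.fractions)
    return pairs


def correlation_matrix(
    profiles_by_sample: Mapping[str, Mapping[str, np.ndarray]]
) -> pd.DataFrame:
    """Median cross-sample correlation over shared clusters (export convenience)."""
    samples = list(profiles_by_sample)
    mat = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            shared = set(profiles_by_sample[a]) & set(profiles_by_sample[b])
            rs = []
            for cid in shared:
                try:
                    r, _ = pearson_with_p(profiles_by_sample[a][cid], profiles_by_sample[b][cid])
                except ValueError:
                    continue
                rs.append(r)
            value = float(np.median(rs)) if rs else np.nan
            mat.loc[a, b] = mat.loc[b, a] = value
    return mat
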