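"""piRNA target prediction.

Two complementary routes:

1. Hit-table route — keep alignment hits with score >= 160, take each
   piRNA's single top-scoring gene target, then ask whether targets are
   preferentially down-regulated: compare non-zero generalized fold-change
   values of target vs non-target genes with a Mann-Whitney test (the
   deadenylation test).

2. Signature route — exploit the divergent partial complementarity of sense
   and guide piRNAs.  Sense reads are placed at every exact zero-mismatch
   genomic occurrence; guide reads at every genomic alignment with zero
   mismatches in the 5'-most 10 bases (the seed) and a summed Phred quality
   of non-seed mismatches within a budget of 160 (at uniform Q30 that allows
   at most 5 non-seed mismatches).  A signature site is a guide alignment
   overlapping (>= 1 base) a sense alignment on the opposite genomic strand.
   Any mRNA or repeat element overlapping a site is a candidate target;
   repeats are pre-filtered to elements >= 75% of their family consensus
   length.
"""
from __future__ import annotations

import itertools
import warnings
from bisect import bisect_left
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .model import (GeneModel, RepeatElement, TargetSignatureSite,
                    intervals_overlap, reverse_complement)

SCORE_MIN = 160
SEED_LEN = 10
QUALITY_BUDGET = 160
DEFAULT_PHRED = 30


# ------------------------------------------------------------ hit-table route

def select_top_gene_targets(
    hit_table: pd.DataFrame,
    min_score: float = SCORE_MIN,
    expressed_genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-piRNA single best gene target among hits scoring >= min_score.

    Ties are broken toward the lexicographically smallest gene_id.  When
    ``expressed_genes`` is given, hits to other genes are dropped first.
    """
    df = hit_table.copy()
    if expressed_genes is not None:
        df = df[df["gene_id"].isin(set(expressed_genes))]
    df = df[df["score"] >= min_score]
    if df.empty:
        return pd.DataFrame(columns=["pirna_id", "gene_id", "score"])
    df = df.sort_values(["pirna_id", "score", "gene_id"],
                        ascending=[True, False, True], kind="mergesort")
    best = df.groupby("pirna_id", as_index=False).first()
    return best[["pirna_id", "gene_id", "score"]].reset_index(drop=True)


def _exact_u_distribution(n1: int, n2: int) -> np.ndarray:
    """P(U = u) for u = 0..n1*n2 under the null, via rank-sum counting."""
    N = n1 + n2
    # dp[k][s]: number of size-k subsets of ranks 1..N with rank sum s
    max_sum = N * (N + 1) // 2
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for rank in range(1, N + 1):
        for k in range(min(rank, n1), 0, -1):
            dp[k, rank:] += dp[k - 1, :-rank] if rank else dp[k - 1, :]
    sums = dp[n1]
    offset = n1 * (n1 + 1) // 2  # U = ranksum - offset
    u_counts = sums[offset: offset + n1 * n2 + 1]
    return u_counts / u_counts.sum()


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (for x, midranks) with a two-sided p-value.

    Exact p by null enumeration when n1+n2 <= 12 without ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    U1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    has_ties = np.unique(combined).size < combined.size

    if n1 + n2 <= 12 and not has_ties:
        dist = _exact_u_distribution(n1, n2)
        u_low = min(U1, n1 * n2 - U1)
        us = np.arange(n1 * n2 + 1)
        p = float(dist[np.minimum(us, n1 * n2 - us) <= u_low + 1e-9].sum())
        return U1, min(p, 1.0)

    mean = n1 * n2 / 2.0
    N = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return U1, 1.0
    diff = abs(U1 - mean)
    z = max(diff - 0.5, 0.0) / np.sqrt(var)
    p = 2.0 * float(stats.norm.sf(z))
    return U1, min(p, 1.0)


def deadenylation_test(
    target_genes: Iterable[str],
    gfold_values: Mapping[str, float],
) -> dict:
    """Compare non-zero fold changes of target vs non-target genes.

    Zero fold-change genes (no evidence of differential expression) are
    dropped from both groups before the Mann-Whitney test.
    """
    targets = set(target_genes)
    x = [v for g, v in gfold_values.items() if g in targets and v != 0]
    y = [v for g, v in gfold_values.items() if g not in targets and v != 0]
    if not x or not y:
        raise ValueError(
            f"empty group after zero filtering (targets: {len(x)}, non-targets: {len(y)})"
        )
    U, p = mann_whitney(x, y)
    return {
        "U": U,
        "p_value": p,
        "n_targets": len(x),
        "n_nontargets": len(y),
        "median_target": float(np.median(x)),
        "median_nontarget": float(np.median(y)),
    }


def read_gfold_table(path, fdr_cutoff: float | None = 0.01) -> dict[str, float]:
    """GFOLD-style TSV (gene_id, gfold[, fdr]) -> mapping; optional FDR filter."""
    df = pd.read_csv(path, sep="\t")
    if fdr_cutoff is not None and "fdr" in df.columns:
        df = df[df["fdr"] <= fdr_cutoff]
    return dict(zip(df["gene_id"], df["gfold"].astype(float)))


# ------------------------------------------------------------ signature route

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _exact_match_starts(pattern: np.ndarray, chrom_arr: np.ndarray) -> np.ndarray:
    L = pattern.size
    if chrom_arr.size < L:
        return np.empty(0, dtype=np.int64)
    windows = sliding_window_view(chrom_arr, L)
    return np.nonzero((windows == pattern).all(axis=1))[0]


def sense_sites(
    sense_seqs: Mapping[str, str], genome: Mapping[str, str]
) -> list[tuple[str, int, int, str, str]]:
    """All exact zero-mismatch genomic occurrences of each sense read, both
    strands; tuples (chrom, start, end, strand, sense_id)."""
    out = []
    arrays = {c: _encode(s) for c, s in genome.items()}
    for sid, seq in sense_seqs.items():
        for strand, pattern in (("+", seq), ("-", reverse_complement(seq))):
            pat = _encode(pattern)
            for chrom, arr in arrays.items():
                for start in _exact_match_starts(pat, arr):
                    out.append((chrom, int(start), int(start) + len(seq), strand, sid))
    return out


def guide_sites(
    guide_seqs: Mapping[str, str],
    genome: Mapping[str, str],
    guide_quals: Mapping[str, Sequence[int]] | None = None,
    seed_len: int = SEED_LEN,
    quality_budget: int = QUALITY_BUDGET,
    default_phred: int = DEFAULT_PHRED,
) -> list[tuple[str, int, int, str, str, tuple[int, ...]]]:
    """Genomic guide alignments: zero mismatches in the 5'-most ``seed_len``
    bases, summed Phred of non-seed mismatches <= ``quality_budget``.

    Tuples (chrom, start, end, strand, guide_id, mismatch read positions).
    Guides shorter than the seed are rejected with a warning.
    """
    out = []
    arrays = {c: _encode(s) for c, s in genome.items()}
    for gid, seq in guide_seqs.items():
        L = len(seq)
        if L < seed_len:
            warnings.warn(f"guide {gid} shorter than seed ({L} < {seed_len}); rejected")
            continue
        quals = np.asarray(
            guide_quals[gid] if guide_quals and gid in guide_quals
            else [default_phred] * L,
            dtype=np.int64,
        )
        for strand in ("+", "-"):
            if strand == "+":
                pattern = _encode(seq)
                read_pos = np.arange(L)           # pattern col j -> read pos j
            else:
                pattern = _encode(reverse_complement(seq))
                read_pos = L - 1 - np.arange(L)   # read 5' sits at genomic 3' end
            seed_cols = np.nonzero(read_pos < seed_len)[0]
            tail_cols = np.nonzero(read_pos >= seed_len)[0]
            qual_by_col = quals[read_pos]
            for chrom, arr in arrays.items():
                if arr.size < L:
                    continue
                windows = sliding_window_view(arr, L)
                mm = windows != pattern
                seed_ok = ~mm[:, seed_cols].any(axis=1)
                budget = mm[:, tail_cols].astype(np.int64) @ qual_by_col[tail_cols]
                hits = np.nonzero(seed_ok & (budget <= quality_budget))[0]
                for start in hits:
                    positions = tuple(sorted(int(read_pos[j]) for j in np.nonzero(mm[start])[0]))
                    out.append((chrom, int(start), int(start) + L, strand, gid, positions))
    return out


def signature_scan(
    guide_seqs: Mapping[str, str],
    sense_seqs: Mapping[str, str],
    genome: Mapping[str, str],
    guide_quals: Mapping[str, Sequence[int]] | None = None,
    seed_len: int = SEED_LEN,
    quality_budget: int = QUALITY_BUDGET,
    default_phred: int = DEFAULT_PHRED,
    ping_pong: bool = False,
) -> list[TargetSignatureSite]:
    """Emit a site wherever a guide alignment and a sense alignment lie on
    opposite genomic strands with >= 1 base of overlap.

    With ``ping_pong=True`` the classic secondary-piRNA register is required
    in addition: the two 5' ends must overlap by exactly 10 bases.
    """
    senses = sense_sites(sense_seqs, genome)
    guides = guide_sites(guide_seqs, genome, guide_quals, seed_len,
                         quality_budget, default_phred)
    # index sense sites by (chrom, strand), sorted by start
    index: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for chrom, s, e, strand, sid in senses:
        index.setdefault((chrom, strand), []).append((s, e, sid))
    max_sense_len = max((len(s) for s in sense_seqs.values()), default=0)
    for lst in index.values():
        lst.sort()

    sites = []
    for chrom, gs, ge, gstrand, gid, mismatches in guides:
        opposite = "-" if gstrand == "+" else "+"
        candidates = index.get((chrom, opposite), [])
        lo = bisect_left(candidates, (gs - max_sense_len, -1, ""))
        supporting = []
        for ss, se, sid in candidates[lo:]:
            if ss >= ge:
                break
            if not intervals_overlap(gs, ge, ss, se):
                continue
            if ping_pong:
                if gstrand == "-":
                    overlap_5p = ge - ss  # guide 5' at ge-1, sense 5' at ss
                else:
                    overlap_5p = se - gs  # sense 5' at se-1, guide 5' at gs
                if overlap_5p != 10:
                    continue
            supporting.append(sid)
        if supporting:
            sites.append(
                TargetSignatureSite(chrom, gs, ge, gid, gstrand,
                                    tuple(sorted(set(supporting))), mismatches)
            )
    return sites


def filter_repeats(
    repeats: Sequence[RepeatElement], min_fraction: float = 0.75
) -> tuple[list[RepeatElement], int]:
    """Keep elements whose length reaches ``min_fraction`` of the family
    consensus length; rows with missing/zero consensus are skipped."""
    kept, skipped = [], 0
    for r in repeats:
        if not r.consensus_length or r.consensus_length <= 0:
            skipped += 1
            continue
        if r.element_length >= min_fraction * r.consensus_length:
            kept.append(r)
    if skipped:
        warnings.warn(f"skipped {skipped} repeat rows without a consensus length")
    return kept, skipped


def annotate_targets(
    sites: Sequence[TargetSignatureSite],
    gene_models: Sequence[GeneModel],
    filtered_repeats: Sequence[RepeatElement],
) -> dict:
    """Genes and repeats overlapped (>= 1 base) by any signature site.

    Each gene/repeat is reported once regardless of how many sites support
    it; repeat targets are also tallied by family.  Sites touching neither
    annotation count as unannotated.
    """
    gene_hits: set[str] = set()
    repeat_hits: set[int] = set()
    unannotated = 0
    for site in sites:
        hit_any = False
        for g in gene_models:
            if g.chrom == site.chrom and intervals_overlap(site.start, site.end, g.start, g.end):
                gene_hits.add(g.gene_id)
                hit_any = True
        for i, r in enumerate(filtered_repeats):
            if r.chrom == site.chrom and intervals_overlap(site.start, site.end, r.start, r.end):
                repeat_hits.add(i)
                hit_any = True
        if not hit_any:
            unannotated += 1
    family_counts: dict[str, int] = {}
    for i in repeat_hits:
        fam = filtered_repeats[i].family
        family_counts[fam] = family_counts.get(fam, 0) + 1
    return {
        "mrna_targets": sorted(gene_hits),
        "n_mrna_targets": len(gene_hits),
        "repeat_targets_by_family": family_counts,
        "n_repeat_targets": len(repeat_hits),
        "unannotated_sites": unannotated,
    }
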