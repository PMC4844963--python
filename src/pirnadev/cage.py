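"""CAGE-based gene expression: CTSS aggregation, power-law normalization,
promoter-window expression calls, and the TF scenario filter.

CTSS counts across a CAGE library follow an approximate power law: the
reverse cumulative R(x) = #{CTSS with count >= x} is close to c * x^-alpha
on a log-log scale.  Normalization maps every sample onto a common reference
law (alpha_ref, totalling total_ref tags) by matching reverse cumulatives,
which removes depth and distribution differences between libraries and puts
all samples on a tags-per-million (tpm) scale.

Gene expression is the sum of normalized tpm of every unique CTSS falling
in the union of promoter windows [TSS - 1 kb, TSS + 0.5 kb] (strand
oriented, inclusive) over all TSSs of the gene; genes at >= 0.5 tpm are
called expressed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import zeta

from .model import AlignmentRecord, GeneModel

EXPRESSED_TPM = 0.5
DEFAULT_ALPHA_REF = 1.25
DEFAULT_TOTAL_REF = 1e6


def aggregate_ctss(cage_alignments: Iterable[AlignmentRecord]) -> pd.DataFrame:
    """Accumulate forward-mate 5' ends into per-base CTSS counts.

    The CTSS of a + strand alignment is its interval start; of a - strand
    alignment, end - 1.  No mapping-quality filter is applied.
    """
    counts: dict[tuple[str, int, str], int] = {}
    for aln in cage_alignments:
        key = (aln.chrom, aln.five_prime, aln.strand)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"chrom": c, "position": p, "strand": s, "count": n}
        for (c, p, s), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "position", "strand", "count"])


@dataclass(frozen=True)
class PowerLawFit:
    alpha: float
    c: float
    fit_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.c <= 0:
            raise ValueError("power-law fit requires alpha > 0 and c > 0")


def fit_power_law(
    ctss_counts: Sequence[int] | np.ndarray, fit_range: tuple[int, int] = (1, 1000)
) -> PowerLawFit:
    """Least-squares fit of log R(x) = log c - alpha log x.

    R(x) is the number of CTSSs with raw count >= x, evaluated at the
    distinct count values observed inside ``fit_range``.
    """
    counts = np.asarray(ctss_counts, dtype=np.int64)
    counts = counts[counts >= 1]
    lo, hi = fit_range
    xs = np.unique(counts)
    xs = xs[(xs >= lo) & (xs <= hi)]
    if xs.size < 2:
        raise ValueError("need >= 2 distinct count values inside the fit range")
    # R(x): counts sorted ascending; number >= x via searchsorted
    sorted_counts = np.sort(counts)
    R = counts.size - np.searchsorted(sorted_counts, xs, side="left")
    slope, intercept = np.polyfit(np.log(xs), np.log(R), 1)
    return PowerLawFit(alpha=float(-slope), c=float(np.exp(intercept)), fit_range=(lo, hi))


def reference_intercept(alpha_ref: float = DEFAULT_ALPHA_REF,
                        total_ref: float = DEFAULT_TOTAL_REF) -> float:
    """Intercept c_ref of the reference law R(x) = c_ref * x^-alpha_ref chosen so
    the reference library totals ``total_ref`` tags.

    Total tags under the law equal sum_{x>=1} R(x) = c_ref * zeta(alpha_ref),
    so c_ref = total_ref / zeta(alpha_ref).  Requires alpha_ref > 1 for the
    total to converge.
    """
    if alpha_ref <= 1:
        raise ValueError("reference exponent must exceed 1 for a finite tag total")
    return total_ref / float(zeta(alpha_ref))


def powerlaw_normalize(
    raw_count,
    fit: PowerLawFit,
    alpha_ref: float = DEFAULT_ALPHA_REF,
    total_ref: float = DEFAULT_TOTAL_REF,
    c_ref: float | None = None,
):
    """Map raw CTSS counts onto the reference power law (tpm).

    Matching reverse cumulatives between the fitted sample law and the
    reference law gives tpm = (c_ref / c_s)^(1/alpha_ref) * x^(alpha_s/alpha_ref),
    strictly monotone in x and the identity when the sample fit equals the
    reference.
    """
    x = np.asarray(raw_count, dtype=float)
    if np.any(x <= 0):
        raise ValueError("raw counts must be positive")
    if c_ref is None:
        c_ref = reference_intercept(alpha_ref, total_ref)
    tpm = (c_ref / fit.c) ** (1.0 / alpha_ref) * x ** (fit.alpha / alpha_ref)
    return float(tpm) if np.isscalar(raw_count) else tpm


def normalize_ctss_table(
    ctss: pd.DataFrame,
    fit_range: tuple[int, int] = (1, 1000),
    alpha_ref: float = DEFAULT_ALPHA_REF,
    total_ref: float = DEFAULT_TOTAL_REF,
) -> tuple[pd.DataFrame, PowerLawFit]:
    fit = fit_power_law(ctss["count"].to_numpy(), fit_range)
    out = ctss.copy()
    out["tpm"] = powerlaw_normalize(ctss["count"].to_numpy(), fit, alpha_ref, total_ref)
    return out, fit


def _promoter_windows(gene: GeneModel, upstream: int, downstream: int) -> list[tuple[int, int]]:
    """Merged inclusive windows around all TSSs, oriented against transcription."""
    raw = []
    for tss in gene.tss_positions:
        if gene.strand == "+":
            raw.append((tss - upstream, tss + downstream))
        else:
            raw.append((tss - downstream, tss + upstream))
    raw.sort()
    merged = [list(raw[0])]
    for s, e in raw[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def gene_expression(
    ctss: pd.DataFrame,
    gene_models: Sequence[GeneModel],
    upstream: int = 1000,
    downstream: int = 500,
    expressed_cutoff: float = EXPRESSED_TPM,
    match_strand: bool = True,
) -> pd.DataFrame:
    """Per-gene tpm (sum over unique promoter CTSSs) and expressed flag.

    Each unique CTSS contributes once even when it falls in the windows of
    several TSSs of the same gene.
    """
    if "tpm" not in ctss.columns:
        raise ValueError("CTSS table must carry a tpm column (normalize first)")
    rows = []
    for gene in gene_models:
        sel = ctss["chrom"] == gene.chrom
        if match_strand:
            sel &= ctss["strand"] == gene.strand
        sub = ctss.loc[sel]
        windows = _promoter_windows(gene, upstream, downstream)
        pos = sub["position"].to_numpy()
        mask = np.zeros(len(sub), dtype=bool)
        for s, e in windows:
            mask |= (pos >= s) & (pos <= e)
        hit = sub.loc[mask].drop_duplicates(subset=["chrom", "position", "strand"])
        total = float(hit["tpm"].sum())
        rows.append(
            {"gene_id": gene.gene_id, "tpm": total, "expressed": total >= expressed_cutoff}
        )
    return pd.DataFrame(rows, columns=["gene_id", "tpm", "expressed"])


# --------------------------------------------------------- TF scenario filter

TESTES_SAMPLES = ("testes_10dpp", "testes_14dpp", "testes_adult")
BRAIN_SAMPLE = "brain_adult"

_ROLE_FOR_SCENARIO = {1: ("activator", "both"), 2: ("repressor", "both")}


def tf_scenario_filter(
    tf_candidates: pd.DataFrame,
    threshold: float = EXPRESSED_TPM,
    brain_sample: str = BRAIN_SAMPLE,
    testes_samples: Sequence[str] = TESTES_SAMPLES,
) -> pd.DataFrame:
    """Filter discriminatory TF candidates by the two regulatory scenarios.

    Scenario 1 (activator side): motif enriched in promoters of clusters
    expressed in adult brain (enriched_in == "BT"); the TF must be expressed
    above threshold in adult brain AND in every testes stage.
    Scenario 2 (repressor side): motif enriched in clusters expressed only in
    adult testes (enriched_in == "nonBT"); the TF must be above threshold in
    adult brain and AT OR BELOW threshold in every testes stage.

    Expects columns tf_id, enriched_in ("BT"/"nonBT"), role, and one
    expression column per sample.  Returns retained candidates with scenario
    and a role-consistency flag; rejected rows carry a reason.
    """
    required = [brain_sample, *testes_samples]
    out = []
    for row in tf_candidates.itertuples(index=False):
        rec = row._asdict()
        values = {}
        missing = False
        for s in required:
            v = rec.get(s)
            if v is None or pd.isna(v):
                missing = True
                break
            values[s] = float(v)
        if missing:
            out.append({**rec, "retained": False, "scenario": None,
                        "role_consistent": None, "reason": "missing_expression"})
            continue
        if values[brain_sample] <= threshold:
            out.append({**rec, "retained": False, "scenario": None,
                        "role_consistent": None, "reason": "not_expressed_in_brain"})
            continue
        testes = [values[s] for s in testes_samples]
        if rec["enriched_in"] == "BT":
            ok, scenario, reason = all(v > threshold for v in testes), 1, "testes_expression"
        elif rec["enriched_in"] == "nonBT":
            ok, scenario, reason = all(v <= threshold for v in testes), 2, "testes_expression"
        else:
            raise ValueError(f"bad enriched_in label {rec['enriched_in']!r}")
        if not ok:
            out.append({**rec, "retained": False, "scenario": None,
                        "role_consistent": None, "reason": reason})
            continue
        consistent = rec.get("role") in _ROLE_FOR_SCENARIO[scenario]
        out.append({**rec, "retained": True, "scenario": scenario,
                    "role_consistent": consistent, "reason": None})
    return pd.DataFrame(out)
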