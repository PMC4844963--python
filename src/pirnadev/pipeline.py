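"""End-to-end convenience: simulate a sample, clean it, look up truth
alignments, and run cluster expression + hallmark characterization.

This glues the module surfaces together the way the study's analysis chains
them; it is what the worked example and the acceptance checks drive.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import character, clusters, preprocess
from .model import AlignmentRecord
from .simulate import Reference, SampleTruth, StageProfile, simulate_small_rna_sample, truth_alignments_for


@dataclass
class SmallRNASampleResult:
    sample_id: str
    truth: SampleTruth
    preprocess_counts: dict
    alignments: list[AlignmentRecord]
    expression: pd.DataFrame
    u1: character.U1BiasResult
    length_modes: list[int]
    cluster_sequences: list[str]
    all_sequences: list[str]

    @property
    def expressed_clusters(self) -> list[str]:
        return list(self.expression.loc[self.expression["expressed"], "cluster_id"])


def run_small_rna_sample(
    reference: Reference, profile: StageProfile, seed: int
) -> SmallRNASampleResult:
    """Simulate -> preprocess -> truth-align -> expression call -> hallmarks."""
    records, truth = simulate_small_rna_sample(reference, profile, seed)
    inserts, counts = preprocess.process_small_rna(records, reference.config.adapter)
    insert_by_id = {i.read_id: i.insert for i in inserts}
    alignments = truth_alignments_for(list(insert_by_id), truth, insert_by_id)
    expression = clusters.expression_table(
        alignments, reference.clusters, total_mapped_reads=len(alignments)
    )
    all_seqs = [a.sequence for a in alignments]
    # sequences of cluster-contained reads (for sharing / ncRNA checks)
    cluster_seqs = []
    for a in alignments:
        for c in reference.clusters:
            if c.chrom == a.chrom and c.start <= a.start and a.end <= c.end:
                cluster_seqs.append(a.sequence)
                break
    u1 = character.u1_bias_test(all_seqs)
    _, modes = character.length_distribution(all_seqs)
    return SmallRNASampleResult(
        sample_id=profile.sample_id,
        truth=truth,
        preprocess_counts=dict(counts),
        alignments=alignments,
        expression=expression,
        u1=u1,
        length_modes=modes,
        cluster_sequences=cluster_seqs,
        all_sequences=all_seqs,
    )


def recovery_rates(result: SmallRNASampleResult) -> tuple[float, float]:
    """(fraction of truth-expressed clusters called expressed,
    fraction of truth-silent clusters called expressed)."""
    called = set(result.expressed_clusters)
    truth_set = set(result.truth.expressed_clusters)
    all_ids = set(result.expression["cluster_id"])
    silent = all_ids - truth_set
    recall = len(called & truth_set) / len(truth_set) if truth_set else float("nan")
    false_rate = len(called & silent) / len(silent) if silent else 0.0
    return recall, false_rate
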