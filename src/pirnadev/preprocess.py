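"""Read-cleaning rules for small-RNA tags and CAGE forward mates.

Small-RNA reads are 5'-barcoded and 3'-adapter-ligated single-end tags.
Cleaning proceeds in two steps: (1) truncate each read at the first base
with Phred quality <= 15 (that base and everything after it is dropped);
(2) strip the 4-base 5' barcode and at least one base of 3' adapter, then
gate the insert length to 25..35 nt (piRNA-sized).  A read from which no
adapter base could be removed is discarded, as are inserts of <=24 nt.
CAGE forward mates lose a fixed 9-base prefix (6-base barcode + GGG from
template switching) and are discarded at <=15 nt.

Counts are conserved: every input read is either retained or discarded with
a reason code.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

from . import io as pio

# discard reason codes
OK = "retained"
TOO_SHORT_FOR_BARCODE = "too_short_for_barcode"
NO_ADAPTER = "no_adapter"
INSERT_TOO_SHORT = "insert_too_short"
MATE_TOO_SHORT = "mate_too_short"


@dataclass(frozen=True)
class ProcessedInsert:
    read_id: str
    insert: str
    n_quality_trimmed: int
    n_barcode: int
    n_adapter: int


@dataclass(frozen=True)
class ReadOutcome:
    read_id: str
    reason: str
    insert: Optional[ProcessedInsert] = None

    @property
    def retained(self) -> bool:
        return self.reason == OK


def truncate_at_low_quality(
    sequence: str, qualities: Sequence[int], qmin: int = 15
) -> tuple[str, list[int]]:
    """Longest prefix in which every base has quality > qmin.

    The first base at or below ``qmin`` and all subsequent bases are removed.
    Idempotent; may return an empty read.
    """
    if len(sequence) != len(qualities):
        raise ValueError("sequence/quality length mismatch")
    for i, q in enumerate(qualities):
        if q <= qmin:
            return sequence[:i], list(qualities[:i])
    return sequence, list(qualities)


def _adapter_strip_position(remainder: str, adapter: str, min_overlap: int = 1) -> Optional[int]:
    """Leftmost i such that remainder[i:] is a prefix of the adapter.

    The match is anchored at the read's 3' end (it must extend to the end of
    the remainder) and must cover >= min_overlap adapter bases.  'N' never
    matches.  Returns None when no adapter evidence is found.
    """
    n = len(remainder)
    for i in range(0, n - min_overlap + 1):
        tail = remainder[i:]
        if len(tail) > len(adapter):
            continue
        if all(a == b and a != "N" for a, b in zip(tail, adapter)):
            return i
    return None


def extract_small_rna_insert(
    read_id: str,
    sequence: str,
    adapter: str,
    n_quality_trimmed: int = 0,
    barcode_len: int = 4,
    min_len_exclusive: int = 24,
    max_len: int = 35,
    adapter_min_overlap: int = 1,
) -> ReadOutcome:
    """Strip the 5' barcode and >=1 base of 3' adapter; gate insert length.

    ``sequence`` must already be quality-truncated.
    """
    if len(sequence) < barcode_len:
        return ReadOutcome(read_id, TOO_SHORT_FOR_BARCODE)
    remainder = sequence[barcode_len:]
    pos = _adapter_strip_position(remainder, adapter, adapter_min_overlap)
    if pos is None:
        return ReadOutcome(read_id, NO_ADAPTER)
    insert = remainder[:pos]
    if len(insert) <= min_len_exclusive:
        return ReadOutcome(read_id, INSERT_TOO_SHORT)
    n_adapter = len(remainder) - pos
    insert = insert[:max_len]
    return ReadOutcome(
        read_id,
        OK,
        ProcessedInsert(read_id, insert, n_quality_trimmed, barcode_len, n_adapter),
    )


def process_small_rna_read(
    read_id: str,
    sequence: str,
    qualities: Sequence[int],
    adapter: str,
    qmin: int = 15,
    **kwargs,
) -> ReadOutcome:
    seq, _ = truncate_at_low_quality(sequence, qualities, qmin)
    return extract_small_rna_insert(
        read_id, seq, adapter, n_quality_trimmed=len(sequence) - len(seq), **kwargs
    )


def extract_cage_forward_mate(
    read_id: str, sequence: str, prefix_len: int = 9, min_len_exclusive: int = 15
) -> ReadOutcome:
    """Remove the 9-base barcode+GGG prefix positionally; discard <=15 nt mates."""
    if len(sequence) < prefix_len:
        return ReadOutcome(read_id, TOO_SHORT_FOR_BARCODE)
    mate = sequence[prefix_len:]
    if len(mate) <= min_len_exclusive:
        return ReadOutcome(read_id, MATE_TOO_SHORT)
    return ReadOutcome(read_id, OK, ProcessedInsert(read_id, mate, 0, prefix_len, 0))


def process_small_rna(
    records: Iterable[tuple[str, str, Sequence[int]]], adapter: str, **kwargs
) -> tuple[list[ProcessedInsert], Counter]:
    """Clean a whole sample; returns retained inserts and per-reason counts."""
    inserts: list[ProcessedInsert] = []
    counts: Counter = Counter()
    for read_id, seq, quals in records:
        outcome = process_small_rna_read(read_id, seq, quals, adapter, **kwargs)
        counts[outcome.reason] += 1
        if outcome.retained:
            inserts.append(outcome.insert)
    counts["input"] = sum(v for k, v in counts.items() if k != "input")
    return inserts, counts


def process_cage(
    records: Iterable[tuple[str, str, Sequence[int]]],
    qmin: int = 15,
    prefix_len: int = 9,
    min_len_exclusive: int = 15,
) -> tuple[list[ProcessedInsert], Counter]:
    inserts: list[ProcessedInsert] = []
    counts: Counter = Counter()
    for read_id, seq, quals in records:
        trimmed, _ = truncate_at_low_quality(seq, quals, qmin)
        outcome = extract_cage_forward_mate(read_id, trimmed, prefix_len, min_len_exclusive)
        counts[outcome.reason] += 1
        if outcome.retained:
            inserts.append(outcome.insert)
    counts["input"] = sum(v for k, v in counts.items() if k != "input")
    return inserts, counts


def report_table(counts_by_sample: dict[str, Counter]) -> pd.DataFrame:
    reasons = sorted({k for c in counts_by_sample.values() for k in c} - {"input"})
    rows = []
    for sample, counts in counts_by_sample.items():
        row = {"sample": sample, "input": counts.get("input", 0)}
        row.update({r: counts.get(r, 0) for r in reasons})
        rows.append(row)
    return pd.DataFrame(rows)


def preprocess_small_rna_fastq(
    in_path: str | Path,
    out_path: str | Path,
    adapter: str,
    report_path: str | Path | None = None,
    phred64: bool = False,
    **kwargs,
) -> Counter:
    records = pio.read_fastq(in_path, phred64=phred64)
    inserts, counts = process_small_rna(records, adapter, **kwargs)
    pio.write_fastq(((i.read_id, i.insert, [40] * len(i.insert)) for i in inserts), out_path)
    if report_path is not None:
        report_table({Path(in_path).stem: counts}).to_csv(report_path, sep="\t", index=False)
    return counts
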