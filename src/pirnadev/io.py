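"""Plain-text readers/writers for the formats the pipeline consumes and emits.

BED is 0-based half-open. Cluster BED6 carries the genic/intergenic class in
the name field as ``<cluster_id>|<class>``. SAM input goes through pysam.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import AlignmentRecord, GeneModel, PiRNACluster, RepeatElement


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path, phred64: bool = False) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (read_id, sequence, phred qualities)."""
    fmt = "fastq-illumina" if phred64 else "fastq"
    for rec in SeqIO.parse(str(path), fmt):
        yield rec.id, str(rec.seq).upper(), list(rec.letter_annotations["phred_quality"])


def write_fastq(records: Iterable[tuple[str, str, Sequence[int]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, quals in records:
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{read_id}\n{seq}\n+\n{qstr}\n")


# ----------------------------------------------------------------------- BED

def read_clusters_bed(path: str | Path) -> list[PiRNACluster]:
    clusters = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name = line.rstrip("\n").split("\t")[:4]
            cluster_id, _, klass = name.partition("|")
            clusters.append(
                PiRNACluster(cluster_id, chrom, int(start), int(end), klass or "intergenic")
            )
    return clusters


def write_clusters_bed(clusters: Iterable[PiRNACluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.cluster_id}|{c.klass}\t0\t+\n")


def read_alignments_bed(path: str | Path) -> list[AlignmentRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) > 5 else "+"
            out.append(AlignmentRecord(name, chrom, int(start), int(end), strand))
    return out


def write_alignments_bed(alignments: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.read_id}\t0\t{a.strand}\n")


def read_alignments_sam(path: str | Path) -> list[AlignmentRecord]:
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            out.append(
                AlignmentRecord(
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                    rec.query_sequence,
                )
            )
    return out


def read_alignments(path: str | Path) -> list[AlignmentRecord]:
    path = Path(path)
    if path.suffix.lower() == ".sam":
        return read_alignments_sam(path)
    return read_alignments_bed(path)


# -------------------------------------------------------------------- tables

def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Tab-separated: gene_id, chrom, strand, start, end, comma-joined TSSs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    genes = []
    for row in df.itertuples(index=False):
        tss = tuple(int(p) for p in str(row.tss_positions).split(",") if p)
        genes.append(GeneModel(row.gene_id, row.chrom, row.strand,
                               int(row.start), int(row.end), tss))
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "start": g.start,
            "end": g.end,
            "tss_positions": ",".join(str(p) for p in g.tss_positions),
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_repeat_table(path: str | Path) -> list[RepeatElement]:
    df = pd.read_csv(path, sep="\t")
    return [
        RepeatElement(r.chrom, int(r.start), int(r.end), r.strand, r.family,
                      int(r.consensus_length), str(getattr(r, "name", "")))
        for r in df.itertuples(index=False)
    ]


def write_repeat_table(repeats: Iterable[RepeatElement], path: str | Path) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
            "family": r.family,
            "element_length": r.element_length,
            "consensus_length": r.consensus_length,
            "name": r.name,
        }
        for r in repeats
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ctss_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"chrom", "position", "strand", "count"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"CTSS table missing columns: {sorted(missing)}")
    return df


def write_ctss_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
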