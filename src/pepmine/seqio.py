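"""Thin FASTA/FASTQ adapters between Biopython records and RawRead."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .read_qc import RawRead

__all__ = ["read_sequences", "write_sequences"]


def _to_record(read: RawRead) -> SeqRecord:
    rec = SeqRecord(Seq(read.bases), id=read.read_id, description="")
    if read.qualities is not None:
        rec.letter_annotations["phred_quality"] = list(read.qualities)
    return rec


def read_sequences(path: str | Path, fmt: str | None = None) -> list[RawRead]:
    """Load FASTA/FASTQ into RawReads (format inferred from suffix if None)."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        quals = rec.letter_annotations.get("phred_quality")
        reads.append(RawRead(rec.id, str(rec.seq).upper(),
                             None if quals is None else list(quals)))
    return reads


def write_sequences(reads, path: str | Path, fmt: str | None = None) -> None:
    """Write RawReads as FASTA or FASTQ (Sanger Phred+33)."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    SeqIO.write([_to_record(r) for r in reads], str(path), fmt)
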