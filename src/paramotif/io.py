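"""FASTA/FASTQ readers-writers and provenance helpers.

Parsing delegates to Biopython; records are reduced to a light tuple of
(id, sequence, qualities) since nothing downstream needs more.  FASTA input
has no qualities: bases are assumed reliable (quality 40).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, List, Optional, Union

from Bio import SeqIO

from . import __version__
from .refs import ReferencePair

FASTA_QUALITY = 40  # assumed base quality when the input carries none


@dataclass(frozen=True)
class ReadRecord:
    id: str
    seq: str
    quals: Optional[List[int]]  # Phred scores, None for FASTA input


def read_fasta(path: Union[str, Path]) -> Iterator[ReadRecord]:
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {i + 1} ({rec.id}) has an empty sequence")
        yield ReadRecord(rec.id, seq, None)


def read_fastq(path: Union[str, Path]) -> Iterator[ReadRecord]:
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield ReadRecord(
                rec.id, str(rec.seq).upper(), list(rec.letter_annotations["phred_quality"])
            )
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FASTQ ({exc})") from exc


def read_reads(path: Union[str, Path]) -> Iterator[ReadRecord]:
    """Dispatch on extension; FASTA records get synthetic quality 40."""
    p = str(path)
    if p.endswith((".fq", ".fastq")):
        yield from read_fastq(p)
    else:
        for rec in read_fasta(p):
            yield ReadRecord(rec.id, rec.seq, [FASTA_QUALITY] * len(rec.seq))


def write_fastq(records, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"@{r.read_id if hasattr(r, 'read_id') else r.id}\n{r.seq}\n+\n{r.qual}\n")


def load_reference_pair(
    gene_fa: Union[str, Path], pseudo_fa: Union[str, Path]
) -> ReferencePair:
    """Build a ReferencePair from one- or two-file FASTA input.

    When both arguments name the same file, its first two records are taken
    as gene and pseudogene respectively.
    """
    if str(gene_fa) == str(pseudo_fa):
        records = list(read_fasta(gene_fa))
        if len(records) < 2:
            raise ValueError(f"{gene_fa}: need two records for a single-file reference pair")
        g, p = records[0], records[1]
    else:
        g = next(iter(read_fasta(gene_fa)))
        p = next(iter(read_fasta(pseudo_fa)))
    return ReferencePair(g.id, g.seq, p.id, p.seq)


def file_checksum(path: Union[str, Path]) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def provenance_lines(config, inputs: dict) -> List[str]:
    """Standard provenance block echoed into every output file."""
    lines = [f"paramotif {__version__} config_hash={config.digest()}"]
    for name, path in inputs.items():
        lines.append(f"input {name}={path} sha1={file_checksum(path)}")
    return lines
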