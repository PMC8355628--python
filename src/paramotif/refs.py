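"""Reference handling and discriminating-motif enumeration.

A *motif* is a k-mer centered on a base that differs between a gene and its
highly homologous pseudogene, flanked on both sides by alignable (gap-free)
sequence.  A gene motif occurs in the gene reference but nowhere in the
pseudogene reference, and vice versa; every downstream stage uses these
k-mers as paralog-discriminating anchors.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO, Union

from Bio import Align

GENE = "gene"
PSEUDO = "pseudo"
VALID_BASES = set("ACGTN")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMP)[::-1]


def count_occurrences(needle: str, haystack: str) -> int:
    """Number of (possibly overlapping) occurrences of ``needle``."""
    n, start = 0, 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


class NotHomologousError(ValueError):
    """Raised when the two references align below the identity floor."""


@dataclass(frozen=True)
class ReferencePair:
    """A gene reference and its pseudogene reference.

    Coordinates throughout the package are 0-based half-open within each
    reference's own coordinate system.  ``gene_origin`` / ``pseudo_origin``
    optionally record where each region sits on a genome (contig, start) for
    reporting; they play no role in the analysis itself.
    """

    gene_name: str
    gene_seq: str
    pseudo_name: str
    pseudo_seq: str
    gene_origin: tuple = ("", 0)
    pseudo_origin: tuple = ("", 0)

    def __post_init__(self):
        for name, seq in ((self.gene_name, self.gene_seq), (self.pseudo_name, self.pseudo_seq)):
            if not seq:
                raise ValueError(f"reference {name!r} is empty")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"reference {name!r} has invalid characters: {sorted(bad)}")
        lg, lp = len(self.gene_seq), len(self.pseudo_seq)
        if max(lg, lp) > 2 * min(lg, lp):
            raise ValueError(
                f"reference lengths differ by more than 2x ({lg} vs {lp}); "
                "inputs do not look like a highly homologous pair"
            )

    def seq(self, region: str) -> str:
        return self.gene_seq if region == GENE else self.pseudo_seq


@dataclass(frozen=True)
class Motif:
    """One discriminating k-mer.

    ``id`` is the 1-based rank of the motif within its region, ordered by
    ``ref_pos`` (the 0-based start of the k-mer in its own reference).
    ``center_offset`` locates the differentiating base within the k-mer.
    """

    id: int
    region: str
    seq: str
    ref_pos: int
    center_offset: int


@dataclass
class MotifSet:
    """Paired lists of gene and pseudogene motifs, each sorted by ref_pos."""

    gene: list
    pseudo: list
    k: int
    _pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._pos = {(m.region, m.id): m.ref_pos for m in self.gene + self.pseudo}

    def by_region(self, region: str) -> list:
        return self.gene if region == GENE else self.pseudo

    def position(self, region: str, motif_id: int) -> int:
        return self._pos[(region, motif_id)]

    def __len__(self) -> int:
        return len(self.gene) + len(self.pseudo)

    def __iter__(self):
        return iter(self.gene + self.pseudo)

    def checksum(self) -> str:
        payload = "\n".join(f"{m.region}\t{m.id}\t{m.ref_pos}\t{m.seq}" for m in self)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# pairwise reference alignment


@dataclass(frozen=True)
class AlignedColumn:
    """One column of the gene/pseudogene alignment.

    ``gene_pos`` / ``pseudo_pos`` are 0-based positions or ``None`` for a gap;
    ``match`` is True when both bases are present and equal.
    """

    gene_pos: Optional[int]
    pseudo_pos: Optional[int]
    match: bool


def align_pair(pair: ReferencePair, min_identity: float = 0.80) -> list:
    """Globally align the two references and return per-column records.

    Uses an end-to-end affine-gap alignment (match +1, mismatch -2, gap open
    -4, gap extend -1).  Raises :class:`NotHomologousError` when the fraction
    of match columns falls below ``min_identity`` -- the motif model only
    makes sense for highly homologous pairs.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    aln = aligner.align(pair.gene_seq, pair.pseudo_seq)[0]
    indices = aln.indices  # 2 x n_columns, -1 for gaps

    columns = []
    n_match = 0
    for g_i, p_i in zip(indices[0], indices[1]):
        g = int(g_i) if g_i >= 0 else None
        p = int(p_i) if p_i >= 0 else None
        match = (
            g is not None
            and p is not None
            and pair.gene_seq[g] == pair.pseudo_seq[p]
        )
        n_match += match
        columns.append(AlignedColumn(g, p, match))
    if n_match / len(columns) < min_identity:
        raise NotHomologousError(
            f"alignment identity {n_match / len(columns):.2%} is below the "
            f"{min_identity:.0%} floor; references not homologous"
        )
    return columns


def enumerate_motifs(columns: list, pair: ReferencePair, k: int = 11) -> MotifSet:
    """Enumerate discriminating k-mers from an aligned reference pair.

    For every mismatch column whose flanking floor(k/2) columns on each side
    are gap-free, the gene-side and pseudogene-side k-mers centered on the
    column become candidates.  A candidate survives only if it is absent
    from the other reference and occurs exactly once in its own.
    """
    if k % 2 == 0:
        raise ValueError(f"k must be odd so motifs have a well-defined center (got {k})")
    if not 5 <= k <= 31:
        raise ValueError(f"k must be in [5, 31] (got {k})")
    half = k // 2

    candidates = {GENE: {}, PSEUDO: {}}  # ref_pos -> seq
    for c in range(half, len(columns) - half):
        col = columns[c]
        if col.match or col.gene_pos is None or col.pseudo_pos is None:
            continue
        window = columns[c - half : c + half + 1]
        if any(w.gene_pos is None or w.pseudo_pos is None for w in window):
            continue  # gap within the k-mer window: centering undefined
        g_start = col.gene_pos - half
        p_start = col.pseudo_pos - half
        candidates[GENE][g_start] = pair.gene_seq[g_start : g_start + k]
        candidates[PSEUDO][p_start] = pair.pseudo_seq[p_start : p_start + k]

    def survivors(region: str, own: str, other: str) -> list:
        out = []
        for ref_pos in sorted(candidates[region]):
            seq = candidates[region][ref_pos]
            if count_occurrences(seq, other) > 0:
                continue
            if count_occurrences(seq, own) != 1:
                continue
            out.append((ref_pos, seq))
        return out

    gene_motifs = [
        Motif(i + 1, GENE, seq, ref_pos, half)
        for i, (ref_pos, seq) in enumerate(survivors(GENE, pair.gene_seq, pair.pseudo_seq))
    ]
    pseudo_motifs = [
        Motif(i + 1, PSEUDO, seq, ref_pos, half)
        for i, (ref_pos, seq) in enumerate(survivors(PSEUDO, pair.pseudo_seq, pair.gene_seq))
    ]
    return MotifSet(gene_motifs, pseudo_motifs, k)


def find_motifs(pair: ReferencePair, k: int = 11, min_identity: float = 0.80) -> MotifSet:
    """Convenience composition of :func:`align_pair` and :func:`enumerate_motifs`."""
    return enumerate_motifs(align_pair(pair, min_identity), pair, k)


# ---------------------------------------------------------------------------
# TSV round-trip

MOTIF_TSV_HEADER = "id\tregion\tref_pos\tcenter_offset\tseq"


def motifs_to_tsv(motif_set: MotifSet, handle: TextIO, provenance: Iterable[str] = ()) -> None:
    for line in provenance:
        handle.write(f"# {line}\n")
    handle.write(MOTIF_TSV_HEADER + "\n")
    for m in motif_set:
        handle.write(f"{m.id}\t{m.region}\t{m.ref_pos}\t{m.center_offset}\t{m.seq}\n")


def motifs_from_tsv(handle: Union[TextIO, Iterable[str]]) -> MotifSet:
    gene, pseudo, k = [], [], None
    for line in handle:
        line = line.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("id\t"):
            continue
        sid, region, ref_pos, center_offset, seq = line.split("\t")
        m = Motif(int(sid), region, seq, int(ref_pos), int(center_offset))
        if k is None:
            k = len(seq)
        elif len(seq) != k:
            raise ValueError("inconsistent k-mer lengths in motif table")
        (gene if region == GENE else pseudo).append(m)
    if k is None:
        raise ValueError("motif table contains no motifs")
    return MotifSet(gene, pseudo, k)
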