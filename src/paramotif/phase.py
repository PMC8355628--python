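"""Read-backed variant phasing within a cluster of reads.

Given a set of variant sites on the gene reference and the reads supporting
one rearrangement cluster, an allele matrix is built by locally realigning
each read around each site against a reference-allele and an alternate-
allele context and keeping the allele with the lower edit distance.  Reads
are then clustered hierarchically (Ward linkage over missing-aware Hamming
distances) and the dendrogram cut into haplotype groups, whose per-site
consensus alleles are written as phased genotypes to a VCF.

Read-to-reference coordinates are interpolated from the read's motif
anchors, which is adequate in the amplicon setting where reads span the
whole region; no full realignment is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, TextIO, Tuple

import edlib
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .refs import GENE
from .scan import FWD, ReadMotifProfile

REF, ALT, MISSING = 0, 1, -1


@dataclass(frozen=True)
class VariantSite:
    """A candidate small variant on the gene reference (0-based)."""

    ref_pos: int
    ref_allele: str
    alt_allele: str
    tag: str = ""

    def __post_init__(self):
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class AlleleMatrix:
    """m reads x n sites of {ref, alt, missing} calls."""

    entries: np.ndarray  # int8, values REF/ALT/MISSING
    read_ids: List[str]
    sites: List[VariantSite]

    @property
    def m(self) -> int:
        return self.entries.shape[0]

    @property
    def n(self) -> int:
        return self.entries.shape[1]


def read_sites_tsv(handle) -> List[VariantSite]:
    """Parse a `pos  ref  alt  tag` TSV (0-based positions)."""
    sites = []
    for line in handle:
        line = line.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("pos\t"):
            continue
        parts = line.split("\t")
        pos, ref, alt = parts[:3]
        tag = parts[3] if len(parts) > 3 else ""
        sites.append(VariantSite(int(pos), ref, alt, tag))
    return sorted(sites, key=lambda s: s.ref_pos)


def read_sites_vcf(path: str) -> List[VariantSite]:
    """Read sites from a VCF (first ALT per record); positions become 0-based."""
    import pysam

    sites = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            if not rec.alts:
                continue
            sites.append(VariantSite(rec.pos - 1, rec.ref, rec.alts[0], rec.id or ""))
    return sorted(sites, key=lambda s: s.ref_pos)


# ---------------------------------------------------------------------------
# allele matrix


def _anchor_map(profile: ReadMotifProfile, motif_set) -> Tuple[np.ndarray, np.ndarray]:
    """(ref_positions, read_positions) anchor pairs from gene-region hits."""
    refs, reads = [], []
    for g in profile.groups:
        if g.region != GENE or g.strand != FWD:
            continue
        for h in g.hits:
            refs.append(motif_set.position(h.region, h.motif_id))
            reads.append(h.read_pos)
    if not refs:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    order = np.argsort(refs)
    return np.asarray(refs)[order], np.asarray(reads)[order]


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def build_allele_matrix(
    reads: Dict[str, str],
    profiles: Sequence[ReadMotifProfile],
    gene_ref: str,
    sites: Sequence[VariantSite],
    motif_set,
    window: int = 25,
) -> AlleleMatrix:
    """Assign each read x site to {ref, alt, missing} by local realignment.

    For each site, the read segment around the motif-interpolated position is
    aligned against the reference context and the alternate context (the
    same window with the alt allele substituted); the lower edit distance
    wins and ties are left missing.  Reads whose anchors do not bracket the
    site within a window's reach are missing at that site.
    """
    for s in sites:
        if not 0 <= s.ref_pos < len(gene_ref):
            raise ValueError(f"site position {s.ref_pos} outside the gene reference")
        if gene_ref[s.ref_pos : s.ref_pos + len(s.ref_allele)] != s.ref_allele:
            raise ValueError(f"reference allele mismatch at position {s.ref_pos}")

    entries = np.full((len(profiles), len(sites)), MISSING, dtype=np.int8)
    read_ids = [p.read_id for p in profiles]
    for i, p in enumerate(profiles):
        seq = reads[p.read_id]
        refs, read_pos = _anchor_map(p, motif_set)
        if refs.size == 0:
            continue
        for j, s in enumerate(sites):
            rp = int(np.interp(s.ref_pos, refs, read_pos))
            # np.interp clamps outside the anchor range; extrapolate by offset
            if s.ref_pos < refs[0]:
                rp = int(read_pos[0] - (refs[0] - s.ref_pos))
            elif s.ref_pos > refs[-1]:
                rp = int(read_pos[-1] + (s.ref_pos - refs[-1]))
            lo, hi = rp - window, rp + window + len(s.ref_allele)
            if lo < -window or hi > len(seq) + window:
                continue  # site falls outside the read
            segment = seq[max(lo, 0) : min(hi, len(seq))]
            if not segment:
                continue
            c_lo = max(s.ref_pos - window, 0)
            c_hi = min(s.ref_pos + window + len(s.ref_allele), len(gene_ref))
            ref_ctx = gene_ref[c_lo:c_hi]
            alt_ctx = (
                gene_ref[c_lo : s.ref_pos]
                + s.alt_allele
                + gene_ref[s.ref_pos + len(s.ref_allele) : c_hi]
            )
            d_ref = _edit_distance(segment, ref_ctx)
            d_alt = _edit_distance(segment, alt_ctx)
            if d_ref < d_alt:
                entries[i, j] = REF
            elif d_alt < d_ref:
                entries[i, j] = ALT
    return AlleleMatrix(entries, read_ids, list(sites))


# ---------------------------------------------------------------------------
# haplotype clustering


def hamming_distances(entries: np.ndarray) -> np.ndarray:
    """Missing-aware normalized Hamming distances (condensed form).

    distance = disagreeing observed columns / columns observed in both rows;
    rows sharing no observed column are maximally distant (1).
    """
    m = entries.shape[0]
    obs = entries != MISSING
    out = []
    for i in range(m):
        for j in range(i + 1, m):
            both = obs[i] & obs[j]
            n_both = int(both.sum())
            if n_both == 0:
                out.append(1.0)
            else:
                out.append(float((entries[i, both] != entries[j, both]).sum() / n_both))
    return np.asarray(out)


def cluster_haplotypes(
    matrix: AlleleMatrix,
    n_haplotypes: int = 2,
    cut_height: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Partition reads into haplotype groups and derive consensus alleles.

    Ward-linkage agglomeration over pairwise Hamming distances; the tree is
    cut either at ``cut_height`` or into ``n_haplotypes`` groups (default 2,
    the diploid expectation).  Returns (labels per read starting at 0,
    consensus matrix of shape n_groups x n_sites with majority alleles,
    MISSING where a group has no observation).
    """
    if matrix.m < 2:
        raise ValueError("phasing requires at least two reads")
    if (matrix.entries == MISSING).all():
        raise ValueError("allele matrix is entirely missing")
    d = hamming_distances(matrix.entries)
    Z = linkage(d, method="ward")
    if cut_height is not None:
        labels = fcluster(Z, t=cut_height, criterion="distance")
    else:
        labels = fcluster(Z, t=n_haplotypes, criterion="maxclust")
    labels = labels - labels.min()
    n_groups = labels.max() + 1
    consensus = np.full((n_groups, matrix.n), MISSING, dtype=np.int8)
    for g in range(n_groups):
        rows = matrix.entries[labels == g]
        for j in range(matrix.n):
            col = rows[:, j]
            col = col[col != MISSING]
            if col.size == 0:
                continue
            n_alt = int((col == ALT).sum())
            # majority vote; ties resolve to the reference allele
            consensus[g, j] = ALT if n_alt * 2 > col.size else REF
    return labels, consensus


# ---------------------------------------------------------------------------
# VCF output


def emit_phased_vcf(
    consensus: np.ndarray,
    sites: Sequence[VariantSite],
    contig: str,
    contig_length: int,
    handle: TextIO,
    phase_set: int = 0,
    sample: str = "SAMPLE",
    provenance: Sequence[str] = (),
) -> None:
    """Write phased genotypes (one haplotype per consensus row) as VCF 4.2.

    Genotypes use the phased separator with a PS tag carrying the cluster id
    so phase sets from different clusters stay distinct.
    """
    handle.write("##fileformat=VCFv4.2\n")
    for line in provenance:
        handle.write(f"##paramotif={line}\n")
    handle.write(f"##contig=<ID={contig},length={contig_length}>\n")
    handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    handle.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
    handle.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
    for j, s in enumerate(sites):
        alleles = ["." if consensus[g, j] == MISSING else str(int(consensus[g, j]))
                   for g in range(consensus.shape[0])]
        gt = "|".join(alleles)
        handle.write(
            f"{contig}\t{s.ref_pos + 1}\t{s.tag or '.'}\t{s.ref_allele}\t{s.alt_allele}\t"
            f".\tPASS\t.\tGT:PS\t{gt}:{phase_set}\n"
        )
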