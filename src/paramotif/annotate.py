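"""Classifying read clusters and estimating copy numbers.

Each cluster's representative t(R) is binned by its gene/pseudogene junction
structure into five categories: normal gene, normal pseudogene, a
pseudogene-to-gene chimera (the unequal-crossover product), a gene-to-
pseudogene switch, or "other" for anything with two or more junctions.
Copy numbers are apportioned from supporting-read proportions, corrected for
the expected background of in-vitro PCR chimerism, and cross-checked against
supplied heterozygous variant allele fractions: at copy number c, a true het
VAF must sit near j/c for some integer 1 <= j < c.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, TextIO, Tuple

import numpy as np

from .cluster import ClusterSet
from .refs import GENE, PSEUDO

CATEGORY_NORMAL_GENE = "normal_gene"
CATEGORY_NORMAL_PSEUDO = "normal_pseudogene"
CATEGORY_P2G = "pseudo_to_gene_chimera"
CATEGORY_G2P = "gene_to_pseudo"
CATEGORY_OTHER = "other"

CHIMERIC_CATEGORIES = {CATEGORY_P2G, CATEGORY_G2P}


class UnclassifiableError(ValueError):
    """Raised when a cluster has no motif groups to classify."""


@dataclass
class RearrangementCall:
    cluster_id: int
    category: str
    n_junctions: int
    junction_intervals: List[Tuple[int, int]]  # (last motif ref before, first after)
    n_reads: int
    copy_number: int = 0
    chimera_label: Optional[str] = None
    flags: List[str] = field(default_factory=list)


def classify_cluster(t: Sequence[Tuple[int, int, str]]) -> Tuple[str, int, list, list]:
    """Bin a representative t(R) by its region-switch structure.

    Returns (category, n_junctions, junction_intervals, flags).  A junction
    is a switch of region between consecutive groups.  Two-junction patterns
    returning to the starting region are flagged ``conversion_like`` (an
    internal tract of the other region, the gene-conversion signature) but
    binned as ``other``.
    """
    if not t:
        raise UnclassifiableError("empty t(R): cluster has no motif groups")
    regions = [r for _, _, r in t]
    junctions = [
        (t[i][1], t[i + 1][0])
        for i in range(len(t) - 1)
        if regions[i] != regions[i + 1]
    ]
    n = len(junctions)
    flags: List[str] = []
    if n == 0:
        category = CATEGORY_NORMAL_GENE if regions[0] == GENE else CATEGORY_NORMAL_PSEUDO
    elif n == 1:
        first, second = regions[0], regions[-1]
        category = CATEGORY_P2G if (first, second) == (PSEUDO, GENE) else CATEGORY_G2P
    else:
        category = CATEGORY_OTHER
        switch_regions = [regions[0]] + [
            regions[i + 1] for i in range(len(regions) - 1) if regions[i] != regions[i + 1]
        ]
        if len(switch_regions) == 3 and switch_regions[0] == switch_regions[2]:
            flags.append("conversion_like")
    return category, n, junctions, flags


def apportion_copy_numbers(weights: Sequence[float], total_copies: int) -> List[int]:
    """Largest-remainder apportionment of ``total_copies`` by weight.

    Unlike independent rounding, the result always sums to ``total_copies``.
    Ties in the fractional remainders go to the heavier cluster, then to the
    earlier one.
    """
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("cannot apportion copy numbers: total weight is zero")
    quota = total_copies * w / w.sum()
    floors = np.floor(quota).astype(int)
    short = total_copies - int(floors.sum())
    order = sorted(range(len(w)), key=lambda i: (-(quota[i] - floors[i]), -w[i], i))
    out = floors.copy()
    for i in order[:short]:
        out[i] += 1
    return out.tolist()


def vaf_consistent(vafs: Iterable[float], copy_number: int, tol: float = 0.08) -> bool:
    """Check each het VAF against the integer fractions j/copy_number."""
    vafs = list(vafs)
    if not vafs:
        return True
    if copy_number < 2:
        return False
    return all(
        any(abs(v - j / copy_number) <= tol for j in range(1, copy_number))
        for v in vafs
    )


def estimate_copy_numbers(
    calls: List[RearrangementCall],
    total_copies: int = 4,
    vaf_table: Optional[Dict[int, Sequence[float]]] = None,
    pcr_chimera_frac: float = 0.05,
    vaf_tol: float = 0.08,
) -> None:
    """Fill ``copy_number`` (and ``cn_conflict`` flags) in-place.

    Read proportions are corrected before apportionment: the expected PCR-
    chimera background (``pcr_chimera_frac`` of all reads) inflates chimeric
    clusters, so that share is deducted from them pro rata.  When a VAF table
    (cluster id -> het VAFs) is supplied, each cluster's estimate is cross-
    checked and flagged ``cn_conflict`` on failure; allele fractions are the
    final arbiter precisely because read counts alone are inflatable.
    """
    if total_copies < 1:
        raise ValueError("total_copies must be >= 1")
    if not calls:
        return
    weights = np.array([c.n_reads for c in calls], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("cannot estimate copy numbers: no supporting reads")
    chimeric = np.array([c.category in CHIMERIC_CATEGORIES for c in calls])
    if chimeric.any() and pcr_chimera_frac > 0:
        background = pcr_chimera_frac * weights.sum()
        share = weights * chimeric
        deduction = background * share / share.sum()
        weights = np.maximum(weights - deduction, 1e-9)
    cns = apportion_copy_numbers(weights, total_copies)
    for call, cn in zip(calls, cns):
        call.copy_number = int(cn)
        if vaf_table and call.cluster_id in vaf_table:
            if not vaf_consistent(vaf_table[call.cluster_id], call.copy_number, vaf_tol):
                call.flags.append("cn_conflict")


# ---------------------------------------------------------------------------
# chimera junction labelling


@dataclass(frozen=True)
class BreakpointRow:
    label: str
    ref_region: str
    start: int
    end: int  # 0-based half-open, gene-reference space


def load_breakpoint_table(handle) -> List[BreakpointRow]:
    """Parse a `label  ref_region  start  end` TSV; intervals must not overlap."""
    rows: List[BreakpointRow] = []
    for line in handle:
        line = line.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("label\t"):
            continue
        label, region, start, end = line.split("\t")
        rows.append(BreakpointRow(label, region, int(start), int(end)))
    rows_sorted = sorted(rows, key=lambda r: r.start)
    for a, b in zip(rows_sorted, rows_sorted[1:]):
        if b.start < a.end:
            raise ValueError(
                f"breakpoint table intervals overlap: {a.label} [{a.start},{a.end}) "
                f"and {b.label} [{b.start},{b.end})"
            )
    return rows


def label_chimera(
    junction_interval: Tuple[int, int], table: Sequence[BreakpointRow]
) -> str:
    """Label of the interval containing the junction midpoint, or 'unlabeled'.

    Junction coordinates from highly homologous pairs are treated as
    commensurable with gene-reference space (the labelling convention's
    coordinate system).
    """
    mid = (junction_interval[0] + junction_interval[1]) / 2
    for row in table:
        if row.start <= mid < row.end:
            return row.label
    return "unlabeled"


# ---------------------------------------------------------------------------
# cluster-set driver


def annotate_clusters(
    cluster_set: ClusterSet,
    total_copies: int = 4,
    vaf_table: Optional[Dict[int, Sequence[float]]] = None,
    breakpoint_table: Sequence[BreakpointRow] = (),
    pcr_chimera_frac: float = 0.05,
    vaf_tol: float = 0.08,
) -> List[RearrangementCall]:
    """Classify every cluster, estimate copy numbers, and attach labels.

    Clusters with empty representatives are skipped (unclassifiable).
    """
    calls: List[RearrangementCall] = []
    for c in cluster_set.clusters:
        rep = cluster_set.representative_t(c)
        if not rep:
            continue
        category, n, junctions, flags = classify_cluster(rep)
        if cluster_set.is_weak(c):
            flags = flags + ["weak"]
        call = RearrangementCall(
            cluster_id=c.id,
            category=category,
            n_junctions=n,
            junction_intervals=junctions,
            n_reads=cluster_set.weight(c),
            flags=flags,
        )
        if category == CATEGORY_P2G and breakpoint_table:
            call.chimera_label = label_chimera(junctions[0], breakpoint_table)
        calls.append(call)
    if calls:
        estimate_copy_numbers(calls, total_copies, vaf_table, pcr_chimera_frac, vaf_tol)
    return calls


CALLS_TSV_HEADER = "cluster_id\tcategory\tn_junctions\tchimera_label\tn_reads\tcopy_number\tflags"


def calls_to_tsv(calls: Sequence[RearrangementCall], handle: TextIO, provenance=()) -> None:
    for line in provenance:
        handle.write(f"# {line}\n")
    handle.write(CALLS_TSV_HEADER + "\n")
    for c in calls:
        handle.write(
            f"{c.cluster_id}\t{c.category}\t{c.n_junctions}\t{c.chimera_label or '.'}\t"
            f"{c.n_reads}\t{c.copy_number}\t{','.join(c.flags) or '.'}\n"
        )
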