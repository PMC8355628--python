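"""Collapsing identical motif profiles and greedy intermediate-linkage clustering.

Reads with identical motif sequences are collapsed into weighted unique
profiles.  The distance between two profiles is the L1 difference of their
group-tuple lists t(R), position-wise, and infinite when the group counts
(or group regions) differ.  Clustering is greedy with *intermediate linkage*:
a profile joins an existing cluster when at least a fraction beta of the
cluster's weight lies within distance alpha; otherwise it founds a new
cluster.  High-weight profiles are processed first so that well-supported
sequences become cluster seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, TextIO, Tuple

import numpy as np

from .scan import ReadMotifProfile

INF = math.inf


def profile_key(profile: ReadMotifProfile) -> tuple:
    """Hashable identity of a read's motif sequence (per-group id runs)."""
    return tuple(
        (g.region, g.strand, tuple(h.motif_id for h in g.hits)) for g in profile.groups
    )


@dataclass
class UniqueProfileTable:
    """Distinct motif sequences with supporting-read weights.

    Rows are ordered by descending weight (ties: first seen), so iteration
    order is the clustering order.  ``t`` holds each sequence's tuple list
    [(start_ref, end_ref, region), ...].
    """

    keys: List[tuple]
    t: List[List[Tuple[int, int, str]]]
    weights: np.ndarray
    members: List[List[str]]  # read ids per unique sequence

    def __len__(self) -> int:
        return len(self.keys)

    @property
    def total_weight(self) -> int:
        return int(self.weights.sum())


def collapse_profiles(profiles: Sequence[ReadMotifProfile]) -> UniqueProfileTable:
    """Group reads with identical motif sequences, counting support."""
    index: dict = {}
    keys: List[tuple] = []
    t: List[list] = []
    members: List[List[str]] = []
    counts: List[int] = []
    for p in profiles:
        key = profile_key(p)
        i = index.get(key)
        if i is None:
            i = len(keys)
            index[key] = i
            keys.append(key)
            t.append(p.t)
            members.append([])
            counts.append(0)
        members[i].append(p.read_id)
        counts[i] += 1
    order = sorted(range(len(keys)), key=lambda i: (-counts[i], i))
    return UniqueProfileTable(
        keys=[keys[i] for i in order],
        t=[t[i] for i in order],
        weights=np.array([counts[i] for i in order], dtype=np.int64),
        members=[members[i] for i in order],
    )


def profile_distance(t_i: Sequence[tuple], t_j: Sequence[tuple]) -> float:
    """L1 distance between two group-tuple lists; infinity when incomparable.

    Profiles with differing group counts are infinitely distant, as are
    position-wise pairs of groups from different regions (their coordinate
    systems are not commensurable).
    """
    if len(t_i) != len(t_j):
        return INF
    d = 0
    for (s1, e1, r1), (s2, e2, r2) in zip(t_i, t_j):
        if r1 != r2:
            return INF
        d += abs(s1 - s2) + abs(e1 - e2)
    return float(d)


def distance_matrix(table: UniqueProfileTable) -> np.ndarray:
    n = len(table)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = profile_distance(table.t[i], table.t[j])
    return D


@dataclass
class Cluster:
    id: int
    member_idx: List[int] = field(default_factory=list)

    def weight(self, table: UniqueProfileTable) -> int:
        return int(table.weights[self.member_idx].sum())

    def representative(self, table: UniqueProfileTable) -> int:
        """Index of the highest-weight member sequence (ties: joined first)."""
        return max(self.member_idx, key=lambda i: (table.weights[i], -self.member_idx.index(i)))


@dataclass
class ClusterSet:
    """A partition of the unique profiles, with the audit distance matrix."""

    table: UniqueProfileTable
    clusters: List[Cluster]
    D: np.ndarray
    min_reads: int = 3

    def weight(self, c: Cluster) -> int:
        return c.weight(self.table)

    def representative_t(self, c: Cluster) -> List[Tuple[int, int, str]]:
        return self.table.t[c.representative(self.table)]

    def is_weak(self, c: Cluster) -> bool:
        return self.weight(c) < self.min_reads

    def read_assignments(self) -> dict:
        """read_id -> cluster id for every retained read."""
        out = {}
        for c in self.clusters:
            for i in c.member_idx:
                for rid in self.table.members[i]:
                    out[rid] = c.id
        return out


def greedy_cluster(
    table: UniqueProfileTable,
    alpha: float = 10,
    beta: float = 0.5,
    beta_basis: str = "reads",
    min_reads: int = 3,
    D: Optional[np.ndarray] = None,
) -> ClusterSet:
    """Greedy intermediate-linkage clustering of unique profiles.

    Profiles are visited in table order (descending weight).  For each, every
    existing cluster is scored by the fraction of its membership within
    distance ``alpha`` -- weighted by supporting reads (``beta_basis='reads'``)
    or counted over unique sequences (``'seqs'``).  The profile joins the
    qualifying cluster (fraction >= ``beta``) with the highest fraction,
    breaking ties by lower mean distance and then by creation order;
    otherwise it founds a new cluster.
    """
    if beta_basis not in ("reads", "seqs"):
        raise ValueError(f"beta_basis must be 'reads' or 'seqs', got {beta_basis!r}")
    if D is None:
        D = distance_matrix(table)
    clusters: List[Cluster] = []
    for i in range(len(table)):
        best = None  # (fraction, -mean_dist, -cluster_id)
        for c in clusters:
            d = D[i, c.member_idx]
            if beta_basis == "reads":
                w = table.weights[c.member_idx].astype(float)
            else:
                w = np.ones(len(c.member_idx))
            frac = float(w[d <= alpha].sum() / w.sum())
            if frac >= beta and frac > 0:
                finite = np.isfinite(d)
                mean_d = float((d[finite] * w[finite]).sum() / w[finite].sum()) if finite.any() else INF
                key = (frac, -mean_d, -c.id)
                if best is None or key > best[0]:
                    best = (key, c)
        if best is not None:
            best[1].member_idx.append(i)
        else:
            clusters.append(Cluster(id=len(clusters), member_idx=[i]))
    return ClusterSet(table, clusters, D, min_reads)


# ---------------------------------------------------------------------------
# report output

CLUSTER_TSV_HEADER = "cluster_id\tn_reads\tn_unique_seqs\trepresentative_tR\tflag"


def clusters_to_tsv(cluster_set: ClusterSet, handle: TextIO, provenance: Iterable[str] = ()) -> None:
    for line in provenance:
        handle.write(f"# {line}\n")
    handle.write(CLUSTER_TSV_HEADER + "\n")
    for c in cluster_set.clusters:
        rep = cluster_set.representative_t(c)
        rep_str = ";".join(f"{r}:{s}-{e}" for s, e, r in rep) or "."
        flag = "weak" if cluster_set.is_weak(c) else "."
        handle.write(
            f"{c.id}\t{cluster_set.weight(c)}\t{len(c.member_idx)}\t{rep_str}\t{flag}\n"
        )
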