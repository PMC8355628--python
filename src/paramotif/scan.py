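"""Scanning reads for motif hits and assembling them into consistent groups.

A read is summarized as an ordered list of *motif groups*: runs of
same-region motif hits whose order and spacing agree with the reference.
The group structure -- its t(R) tuple list of (start, end) reference
coordinates per group -- is the unit everything downstream clusters and
classifies.  True rearrangement junctions always separate groups, because
either the motif region changes, the motif order reverses, or the read/
reference spacing disagrees by far more than sequencing indels can explain.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, TextIO, Tuple

import numpy as np

from .refs import MotifSet, revcomp

FWD = "+"
REV = "-"

_ENCODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class MotifHit:
    """An exact motif occurrence in (canonical-orientation) read coordinates."""

    region: str
    motif_id: int
    read_pos: int
    strand: str  # '+': motif k-mer as-is; '-': its reverse complement


@dataclass
class MotifGroup:
    """A spacing-consistent run of same-region, same-strand motif hits."""

    region: str
    strand: str
    hits: List[MotifHit]
    start_ref: int
    end_ref: int
    residual: int  # summed |read spacing - reference spacing| over the chain

    @property
    def start_read(self) -> int:
        return self.hits[0].read_pos

    @property
    def end_read(self) -> int:
        return self.hits[-1].read_pos

    @property
    def n_motifs(self) -> int:
        return len(self.hits)

    @property
    def id_first(self) -> int:
        return self.hits[0].motif_id

    @property
    def id_last(self) -> int:
        return self.hits[-1].motif_id

    def span(self, k: int) -> int:
        """Read-length covered by the group, first k-mer start to last k-mer end."""
        return self.end_read - self.start_read + k

    def id_range(self) -> Tuple[int, int]:
        lo, hi = self.hits[0].motif_id, self.hits[-1].motif_id
        return (lo, hi) if lo <= hi else (hi, lo)


@dataclass
class ReadMotifProfile:
    """Per-read summary: surviving motif groups and their t(R) tuples.

    ``hit_span`` records the read interval from the first to the last raw
    motif hit (quality-passed, before grouping).  Isolated hits carry no
    structural evidence, but they still mark sequence as on-target, so the
    off-target filter measures coverage from this span.
    """

    read_id: str
    length: int
    groups: List[MotifGroup]
    orientation: str = FWD  # orientation of the canonical scan vs the input read
    hit_span: Optional[Tuple[int, int]] = None  # (first hit start, last hit start)

    @property
    def t(self) -> List[Tuple[int, int, str]]:
        """t(R): (start_ref, end_ref, region) per group, in read order."""
        return [(g.start_ref, g.end_ref, g.region) for g in self.groups]


@dataclass(frozen=True)
class ScanParams:
    """Tunables of the scan stage.

    min_qual -- minimum base quality at every position of a motif match.
    max_dist (D) -- base spacing tolerance between consecutive hits in a group.
    drift_frac -- extra tolerance per base of reference distance, absorbing
        the indel drift accumulated between distant motifs.
    max_skip (M) -- maximum motif-id gap bridged inside one group; ``None``
        leaves the gap unbounded and relies on the spacing check alone.
    """

    min_qual: int = 10
    max_dist: int = 10
    drift_frac: float = 0.05
    max_skip: Optional[int] = None


class _MotifIndex:
    """Hash index of motif k-mers and their reverse complements."""

    def __init__(self, motif_set: MotifSet):
        self.k = motif_set.k
        self._weights = 4 ** np.arange(self.k - 1, -1, -1, dtype=np.int64)
        table = {}
        for m in motif_set:
            table.setdefault(self._hash_str(m.seq), []).append((m.region, m.id, FWD))
            table.setdefault(self._hash_str(revcomp(m.seq)), []).append((m.region, m.id, REV))
        self.table = table
        self.keys = np.fromiter(table.keys(), dtype=np.int64, count=len(table))

    def _hash_str(self, seq: str) -> int:
        enc = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        if (enc > 3).any():
            raise ValueError(f"motif k-mer contains non-ACGT characters: {seq}")
        return int(enc @ self._weights)

    def window_hashes(self, seq: str) -> Tuple[np.ndarray, np.ndarray]:
        """(hashes, valid) for every k-window of ``seq``; N windows invalid."""
        enc = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        if len(enc) < self.k:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
        win = np.lib.stride_tricks.sliding_window_view(enc, self.k)
        return win @ self._weights, (win < 4).all(axis=1)


_INDEX_CACHE: dict = {}


def _index_for(motif_set: MotifSet) -> _MotifIndex:
    key = (id(motif_set), motif_set.checksum())
    idx = _INDEX_CACHE.get(key)
    if idx is None:
        _INDEX_CACHE.clear()  # single-entry cache; one motif set per run
        idx = _MotifIndex(motif_set)
        _INDEX_CACHE[key] = idx
    return idx


def scan_read(
    read_seq: str,
    read_quals: Optional[Sequence[int]],
    motif_set: MotifSet,
    min_qual: int = 10,
) -> Tuple[List[MotifHit], str]:
    """Find exact motif matches under the base-quality constraint.

    Both the motif k-mers and their reverse complements are searched, so a
    single pass sees forward-strand hits (``+``) and reverse-strand hits
    (``-``).  The canonical orientation is whichever of the read or its
    reverse complement carries more forward-strand hits (ties go to the
    input orientation); all coordinates are reported in that orientation.

    Returns ``(hits sorted by read_pos, orientation flag)`` where the flag is
    '-' when the canonical orientation is the reverse complement of the input.
    """
    index = _index_for(motif_set)
    k = index.k
    hashes, valid = index.window_hashes(read_seq)
    if hashes.size == 0:
        return [], FWD
    ok = valid & np.isin(hashes, index.keys)
    if read_quals is not None:
        q = np.asarray(read_quals, dtype=np.int16)
        if len(q) != len(read_seq):
            raise ValueError("read sequence and quality lengths differ")
        qmin = np.lib.stride_tricks.sliding_window_view(q, k).min(axis=1)
        ok &= qmin >= min_qual

    plus, minus = [], []
    for pos in np.flatnonzero(ok):
        for region, mid, strand in index.table[int(hashes[pos])]:
            (plus if strand == FWD else minus).append(MotifHit(region, mid, int(pos), strand))

    orientation = FWD
    hits = plus + minus
    if len(minus) > len(plus):
        # canonicalize to the reverse complement: flip positions and strands
        orientation = REV
        L = len(read_seq)
        hits = [
            MotifHit(h.region, h.motif_id, L - k - h.read_pos, FWD if h.strand == REV else REV)
            for h in hits
        ]
    hits.sort(key=lambda h: (h.read_pos, h.region, h.motif_id))
    return hits, orientation


def _spacing_ok(d_read: int, d_ref: int, params: ScanParams) -> Tuple[bool, int]:
    tol = params.max_dist + params.drift_frac * d_ref
    resid = abs(d_read - d_ref)
    return resid <= tol, resid


def _chainable(a: MotifHit, b: MotifHit, motif_set: MotifSet, params: ScanParams):
    """Can hit ``b`` extend a group ending at hit ``a``?  Returns (ok, residual).

    Same region and strand; motif ids advance along the read (forward strand:
    increasing, reverse strand: decreasing) by at most ``max_skip``; and the
    read spacing matches the reference spacing within tolerance.
    """
    if a.region != b.region or a.strand != b.strand or b.read_pos <= a.read_pos:
        return False, 0
    if a.strand == FWD:
        id_step = b.motif_id - a.motif_id
        d_ref = motif_set.position(b.region, b.motif_id) - motif_set.position(
            a.region, a.motif_id
        )
    else:
        id_step = a.motif_id - b.motif_id
        d_ref = motif_set.position(a.region, a.motif_id) - motif_set.position(
            b.region, b.motif_id
        )
    if id_step < 1 or (params.max_skip is not None and id_step > params.max_skip):
        return False, 0
    return _spacing_ok(b.read_pos - a.read_pos, d_ref, params)


def build_groups(
    hits: Sequence[MotifHit],
    motif_set: MotifSet,
    params: ScanParams = ScanParams(),
) -> List[MotifGroup]:
    """Select the highest-scoring path of motifs through the read.

    The path visits hits in read order; consecutive path hits either *chain*
    (extend the current group under the region/strand, id-order, id-gap and
    spacing rules) or *break* (start a new group, allowed only when the new
    k-mer starts past the previous one).  The path maximizing the number of
    motifs in groups of size >= 2 wins; singleton runs carry no structural
    evidence and score nothing (the "groups of 2 or greater" rule).  Ties
    prefer fewer groups (a break is never free when a chain explains the
    same motifs), then the smaller summed spacing residual.

    This per-motif search is what arbitrates a span of read supporting
    conflicting groups: a stray hit (e.g., a sequencing error turning one
    region's motif into the other's) cannot hijack a whole group, because
    splitting around it scores higher than discarding the group it collides
    with.  Returns the surviving groups sorted by read coordinate.
    """
    hs = sorted(hits, key=lambda h: (h.read_pos, h.region, h.strand, h.motif_id))
    n = len(hs)
    if n == 0:
        return []
    k = motif_set.k
    NEG = (-1, 0, 0)
    # per hit, two states: run length exactly 1, and run length >= 2;
    # value = (counted motifs, -groups, -summed residual);
    # backpointer = (prev index, state)
    v1 = [(0, 0, 0)] * n
    v2 = [NEG] * n
    b1: List[Optional[Tuple[int, int]]] = [None] * n
    b2: List[Optional[Tuple[int, int]]] = [None] * n
    for j in range(n):
        for i in range(j):
            # break: a new run starts at j after the group ending at i
            if v2[i] > NEG and hs[i].read_pos + k <= hs[j].read_pos and v2[i] > v1[j]:
                v1[j] = v2[i]
                b1[j] = (i, 2)
            ok, resid = _chainable(hs[i], hs[j], motif_set, params)
            if not ok:
                continue
            # i's singleton run becomes a counted pair: one new group
            cand = (v1[i][0] + 2, v1[i][1] - 1, v1[i][2] - resid)
            if cand > v2[j]:
                v2[j] = cand
                b2[j] = (i, 1)
            if v2[i] > NEG:
                cand = (v2[i][0] + 1, v2[i][1], v2[i][2] - resid)
                if cand > v2[j]:
                    v2[j] = cand
                    b2[j] = (i, 2)
    end = max(range(n), key=lambda j: v2[j], default=None)
    if end is None or v2[end] <= NEG or v2[end][0] == 0:
        return []

    # reconstruct the path and cut it into runs at break transitions
    path: List[Tuple[int, int]] = []
    j, state = end, 2
    while j is not None:
        path.append((j, state))
        back = b2[j] if state == 2 else b1[j]
        if back is None:
            break
        j, state = back
    path.reverse()
    runs: List[List[MotifHit]] = []
    for idx, state in path:
        if state == 1 or not runs:
            runs.append([hs[idx]])
        else:
            runs[-1].append(hs[idx])

    groups = []
    for chain in runs:
        if len(chain) < 2:
            continue
        resid = sum(
            _chainable(a, b, motif_set, params)[1] for a, b in zip(chain, chain[1:])
        )
        groups.append(
            MotifGroup(
                region=chain[0].region,
                strand=chain[0].strand,
                hits=list(chain),
                start_ref=motif_set.position(chain[0].region, chain[0].motif_id),
                end_ref=motif_set.position(chain[-1].region, chain[-1].motif_id),
                residual=resid,
            )
        )
    groups.sort(key=lambda g: (g.start_read, g.end_read))
    return groups


def resolve_conflicts(groups: Sequence[MotifGroup], k: int) -> List[MotifGroup]:
    """Keep the non-overlapping subset of groups with the best total score.

    Groups compete where their read intervals [start_read, end_read + k)
    overlap.  The retained subset maximizes total motif count (a group's
    score), breaking ties first by the smaller summed spacing residual and
    then by preferring groups that start earlier in the read.  Solved as
    weighted interval scheduling over the interval DAG.
    """
    if not groups:
        return []
    order = sorted(range(len(groups)), key=lambda i: groups[i].end_read + k)
    starts = [groups[i].start_read for i in order]
    ends = [groups[i].end_read + k for i in order]

    # value tuples: (motifs, -residual, -sum of starts) -- maximized
    best: List[tuple] = [(0, 0, 0, frozenset())]
    for j in range(len(order)):
        g = groups[order[j]]
        prev = bisect_right(ends, starts[j], hi=j)
        take_v = best[prev]
        take = (
            take_v[0] + g.n_motifs,
            take_v[1] - g.residual,
            take_v[2] - g.start_read,
            take_v[3] | {order[j]},
        )
        skip = best[j]
        best.append(max(take, skip, key=lambda v: v[:3]))
    chosen = best[-1][3]
    return [groups[i] for i in sorted(chosen, key=lambda i: groups[i].start_read)]


def profile_read(
    read_id: str,
    read_seq: str,
    read_quals: Optional[Sequence[int]],
    motif_set: MotifSet,
    params: ScanParams = ScanParams(),
) -> ReadMotifProfile:
    """Full per-read composition: scan -> group -> resolve -> profile."""
    hits, orientation = scan_read(read_seq, read_quals, motif_set, params.min_qual)
    groups = build_groups(hits, motif_set, params)
    groups = resolve_conflicts(groups, motif_set.k)
    span = (hits[0].read_pos, hits[-1].read_pos) if hits else None
    return ReadMotifProfile(read_id, len(read_seq), groups, orientation, span)


# ---------------------------------------------------------------------------
# profile table round-trip

PROFILE_TSV_HEADER = (
    "read_id\tlength\tgroup_index\tregion\tmotif_id_first\tmotif_id_last\t"
    "read_start\tread_end\tref_start\tref_end\tstrand"
)


def profiles_to_tsv(profiles: Iterable[ReadMotifProfile], handle: TextIO, provenance=()) -> None:
    """Write profiles; every read gets a summary row (group_index -1) whose
    read_start/read_end columns carry the raw hit span, followed by one row
    per surviving group."""
    for line in provenance:
        handle.write(f"# {line}\n")
    handle.write(PROFILE_TSV_HEADER + "\n")
    for p in profiles:
        hs = (str(p.hit_span[0]), str(p.hit_span[1])) if p.hit_span else (".", ".")
        handle.write(
            f"{p.read_id}\t{p.length}\t-1\t.\t.\t.\t{hs[0]}\t{hs[1]}\t.\t.\t{p.orientation}\n"
        )
        for i, g in enumerate(p.groups):
            handle.write(
                f"{p.read_id}\t{p.length}\t{i}\t{g.region}\t{g.id_first}\t{g.id_last}\t"
                f"{g.start_read}\t{g.end_read}\t{g.start_ref}\t{g.end_ref}\t{g.strand}\n"
            )


def profiles_from_tsv(handle, motif_set: MotifSet) -> List[ReadMotifProfile]:
    """Rebuild profiles from the TSV; hit lists are restored end-points only.

    Interior hits of a group are not serialized, so reconstructed groups
    carry their first/last hits (enough for filtering, clustering and
    classification, which use group end-points exclusively).
    """
    profiles: dict = {}
    order: List[str] = []
    for line in handle:
        line = line.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("read_id\t"):
            continue
        (rid, length, gi, region, id_first, id_last, rs, re_, ref_s, ref_e, strand) = line.split("\t")
        if rid not in profiles:
            profiles[rid] = ReadMotifProfile(rid, int(length), [], FWD)
            order.append(rid)
        p = profiles[rid]
        if gi == "-1":
            p.orientation = strand
            if rs != ".":
                p.hit_span = (int(rs), int(re_))
            continue
        first = MotifHit(region, int(id_first), int(rs), strand)
        last = MotifHit(region, int(id_last), int(re_), strand)
        hits = [first] if (id_first == id_last and rs == re_) else [first, last]
        p.groups.append(
            MotifGroup(region, strand, hits, int(ref_s), int(ref_e), residual=0)
        )
    return [profiles[rid] for rid in order]
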