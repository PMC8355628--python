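"""Amplicon artifact filters applied to read motif profiles.

Two read-level artifacts common to amplicon long-read libraries are removed
before clustering:

* palindromic reads -- circular-consensus reads in which a missed adapter
  leaves the template and its reverse complement concatenated, visible as a
  motif-group run mirrored later in the read on the opposite strand;
* off-target reads -- molecules from unrelated loci whose sequence is mostly
  unexplained by gene or pseudogene motifs.

Both filters are pure predicates on the profile, so their order is
irrelevant; the report attributes each discarded read to a single reason
(palindrome takes precedence) so tallies always partition the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Tuple

from .scan import ReadMotifProfile

KEEP = "keep"
DISCARD_PALINDROME = "palindrome"
DISCARD_OFFTARGET = "offtarget"


def _ranges_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def palindrome_filter(profile: ReadMotifProfile, k: int, max_mirrored_frac: float = 0.5) -> bool:
    """True (keep) unless mirrored motif groups cover too much of the read.

    A pair of groups is *mirrored* when a later group repeats an earlier
    group's motif ids (same region, overlapping id ranges) on the opposite
    strand -- the signature of a template/reverse-complement concatenation.
    The read is discarded when the read-length covered by mirrored groups
    exceeds ``max_mirrored_frac`` of the read length.
    """
    if profile.length == 0 or len(profile.groups) < 2:
        return True
    mirrored = [False] * len(profile.groups)
    for i, gi in enumerate(profile.groups):
        for j in range(i + 1, len(profile.groups)):
            gj = profile.groups[j]
            if (
                gi.region == gj.region
                and gi.strand != gj.strand
                and _ranges_overlap(gi.id_range(), gj.id_range())
            ):
                mirrored[i] = mirrored[j] = True
    covered = sum(g.span(k) for g, m in zip(profile.groups, mirrored) if m)
    return covered <= max_mirrored_frac * profile.length


def offtarget_filter(
    profile: ReadMotifProfile, k: int, max_unexplained_frac: float = 0.30
) -> bool:
    """True (keep) unless too much of the read is unexplained by motif groups.

    The explained length runs from the first to the last motif hit in the
    read: sequence between motif-anchored coordinates is either verified by
    group spacing checks, lost motif sites, or a junction -- all on-target --
    so only the leading and trailing motif-free stretches count as
    unexplained.  Off-target molecules yield at most a couple of spurious
    hits, which rarely cover enough of the read to pass.  Reads whose hits
    all failed grouping (no structural evidence at all) are discarded.
    """
    if profile.length == 0 or not profile.groups:
        return False
    if profile.hit_span is not None:
        first, last = profile.hit_span
    else:
        first, last = profile.groups[0].start_read, profile.groups[-1].end_read
    explained = last + k - first
    return profile.length - explained <= max_unexplained_frac * profile.length


@dataclass
class FilterReport:
    """Per-read decisions and summary tallies of the filtering stage."""

    total: int = 0
    kept: int = 0
    palindrome: int = 0
    offtarget: int = 0
    decisions: dict = field(default_factory=dict)  # read_id -> reason code

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "kept": self.kept,
            "discarded_palindrome": self.palindrome,
            "discarded_offtarget": self.offtarget,
        }


def apply_filters(
    profiles: Iterable[ReadMotifProfile],
    k: int,
    max_palindrome_frac: float = 0.5,
    max_unexplained_frac: float = 0.30,
) -> Tuple[List[ReadMotifProfile], FilterReport]:
    """Apply both filters; return surviving profiles and the report."""
    kept: List[ReadMotifProfile] = []
    report = FilterReport()
    for p in profiles:
        report.total += 1
        if not palindrome_filter(p, k, max_palindrome_frac):
            report.palindrome += 1
            report.decisions[p.read_id] = DISCARD_PALINDROME
        elif not offtarget_filter(p, k, max_unexplained_frac):
            report.offtarget += 1
            report.decisions[p.read_id] = DISCARD_OFFTARGET
        else:
            report.kept += 1
            report.decisions[p.read_id] = KEEP
            kept.append(p)
    return kept, report
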