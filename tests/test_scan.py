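"""Read scanning, motif grouping, and conflict resolution."""

import numpy as np
import pytest

from paramotif.refs import revcomp
from paramotif.scan import (
    FWD,
    REV,
    MotifGroup,
    MotifHit,
    ScanParams,
    build_groups,
    profile_read,
    profiles_from_tsv,
    profiles_to_tsv,
    resolve_conflicts,
    scan_read,
)
from paramotif.simulate import (
    DEFAULT_BREAKPOINTS,
    SimScenario,
    build_haplotype,
    simulate_reads,
)

from conftest import make_motif_set


class TestScanRead:
    def test_reference_read_finds_every_gene_motif(self, toy_pair, toy_motifs):
        quals = [30] * len(toy_pair.gene_seq)
        hits, orientation = scan_read(toy_pair.gene_seq, quals, toy_motifs)
        assert orientation == FWD
        assert [(h.region, h.motif_id) for h in hits] == [
            ("gene", m.id) for m in toy_motifs.gene
        ]
        assert all(h.read_pos == toy_motifs.position("gene", h.motif_id) for h in hits)

    def test_low_quality_base_suppresses_motif(self, toy_pair, toy_motifs):
        quals = [30] * len(toy_pair.gene_seq)
        m2 = toy_motifs.gene[1]
        quals[m2.ref_pos + 4] = 5  # one base inside the k-mer below threshold
        hits, _ = scan_read(toy_pair.gene_seq, quals, toy_motifs, min_qual=10)
        found = {h.motif_id for h in hits}
        assert m2.id not in found
        assert found == {m.id for m in toy_motifs.gene} - {m2.id}

    def test_reverse_complement_read_canonicalizes(self, toy_pair, toy_motifs):
        fwd = profile_read("f", toy_pair.gene_seq, [30] * 600, toy_motifs)
        rev = profile_read("r", revcomp(toy_pair.gene_seq), [30] * 600, toy_motifs)
        assert rev.orientation == REV
        assert fwd.t == rev.t

    def test_no_quals_means_no_quality_gate(self, toy_pair, toy_motifs):
        hits, _ = scan_read(toy_pair.gene_seq, None, toy_motifs)
        assert len(hits) == len(toy_motifs.gene)

    def test_raising_min_qual_never_adds_hits(self, toy_pair, toy_motifs):
        rng = np.random.default_rng(17)
        quals = rng.integers(2, 41, size=len(toy_pair.gene_seq)).tolist()
        previous = None
        for q in (2, 10, 20, 35):
            hits, _ = scan_read(toy_pair.gene_seq, quals, toy_motifs, min_qual=q)
            ids = {(h.region, h.motif_id, h.read_pos) for h in hits}
            if previous is not None:
                assert ids <= previous
            previous = ids


# motif coordinate layout used by the grouping tests: ten gene motifs 100 bp
# apart and ten pseudogene motifs 120 bp apart
GROUP_MS = make_motif_set(
    gene_positions=[100 * (i + 1) for i in range(10)],
    pseudo_positions=[120 * (i + 1) for i in range(10)],
)


def hit(region, mid, pos, strand=FWD):
    return MotifHit(region, mid, pos, strand)


class TestBuildGroups:
    def test_consistent_pair_forms_group(self):
        # read spacing 80 equals reference spacing: one group
        ms = make_motif_set(gene_positions=[500, 580])
        groups = build_groups([hit("gene", 1, 100), hit("gene", 2, 180)], ms)
        assert len(groups) == 1
        assert [h.motif_id for h in groups[0].hits] == [1, 2]
        assert (groups[0].start_ref, groups[0].end_ref) == (500, 580)

    def test_spacing_violation_discards_both_as_singletons(self):
        # |(read spacing) - (reference spacing)| = 25 > tolerance
        ms = make_motif_set(gene_positions=[500, 580])
        groups = build_groups([hit("gene", 1, 100), hit("gene", 2, 205)], ms)
        assert groups == []

    def test_skip_recovery_bridges_one_lost_motif(self):
        # g2 lost to an error: g1 and g3 still group when max_skip >= 2
        groups = build_groups(
            [hit("gene", 1, 50), hit("gene", 3, 250)],
            GROUP_MS,
            ScanParams(max_skip=2),
        )
        assert len(groups) == 1
        assert [h.motif_id for h in groups[0].hits] == [1, 3]
        assert build_groups(
            [hit("gene", 1, 50), hit("gene", 3, 250)], GROUP_MS, ScanParams(max_skip=1)
        ) == []

    def test_worked_example_three_groups(self):
        # R = [g1,g2,g3, g1,g2,g3, p8,p9,p10] -> three contiguous groups
        hits = [
            hit("gene", 1, 0), hit("gene", 2, 100), hit("gene", 3, 200),
            hit("gene", 1, 300), hit("gene", 2, 400), hit("gene", 3, 500),
            hit("pseudo", 8, 620), hit("pseudo", 9, 740), hit("pseudo", 10, 860),
        ]
        groups = build_groups(hits, GROUP_MS)
        t = [(g.start_ref, g.end_ref, g.region) for g in groups]
        g1, g3 = GROUP_MS.position("gene", 1), GROUP_MS.position("gene", 3)
        p8, p10 = GROUP_MS.position("pseudo", 8), GROUP_MS.position("pseudo", 10)
        assert t == [(g1, g3, "gene"), (g1, g3, "gene"), (p8, p10, "pseudo")]

    def test_reverse_strand_groups_decreasing_ids(self):
        hits = [hit("gene", 5, 100, REV), hit("gene", 4, 200, REV), hit("gene", 3, 300, REV)]
        groups = build_groups(hits, GROUP_MS)
        assert len(groups) == 1
        assert [h.motif_id for h in groups[0].hits] == [5, 4, 3]
        assert groups[0].strand == REV

    def test_stray_cross_region_hit_cannot_hijack_a_group(self):
        """A lone converted hit between two legitimate runs is dropped."""
        hits = [
            hit("pseudo", 1, 0), hit("pseudo", 2, 120), hit("pseudo", 3, 240),
            hit("gene", 4, 280),  # stray: chains with nothing upstream
            hit("pseudo", 4, 360), hit("pseudo", 5, 480),
        ]
        groups = build_groups(hits, GROUP_MS)
        assert len(groups) == 1
        assert [h.motif_id for h in groups[0].hits] == [1, 2, 3, 4, 5]


def random_groups(rng, n, k=11):
    """Random synthetic MotifGroups for conflict-resolution tests."""
    out = []
    for _ in range(n):
        start = int(rng.integers(0, 2000))
        length = int(rng.integers(0, 400))
        n_motifs = int(rng.integers(2, 9))
        g = MotifGroup(
            region="gene",
            strand=FWD,
            hits=[MotifHit("gene", i + 1, start, FWD) for i in range(n_motifs)],
            start_ref=0,
            end_ref=0,
            residual=int(rng.integers(0, 30)),
        )
        g.hits[-1] = MotifHit("gene", n_motifs, start + length, FWD)
        out.append(g)
    return out


def exhaustive_best(groups, k):
    """Oracle: best (total motifs, -total residual) over all non-overlapping subsets."""
    best = (0, 0)
    n = len(groups)
    for mask in range(1 << n):
        sel = [groups[i] for i in range(n) if mask >> i & 1]
        sel.sort(key=lambda g: g.start_read)
        if any(
            a.end_read + k > b.start_read for a, b in zip(sel, sel[1:])
        ):
            continue
        val = (sum(g.n_motifs for g in sel), -sum(g.residual for g in sel))
        best = max(best, val)
    return best


class TestResolveConflicts:
    def test_non_overlapping_groups_all_kept(self):
        ms = GROUP_MS
        groups = build_groups(
            [hit("gene", 1, 0), hit("gene", 2, 100), hit("pseudo", 1, 300), hit("pseudo", 2, 420)],
            ms,
        )
        assert len(resolve_conflicts(groups, ms.k)) == 2

    def test_bigger_group_wins_overlap(self):
        rng = np.random.default_rng(0)
        big, small = random_groups(rng, 2)
        big.hits = [MotifHit("gene", i + 1, 100 + 5 * i, FWD) for i in range(5)]
        small.hits = [MotifHit("gene", i + 1, 110 + 5 * i, FWD) for i in range(2)]
        kept = resolve_conflicts([big, small], k=11)
        assert kept == [big]

    def test_chain_of_three_prefers_flanks(self):
        # A(4) overlaps B(3) overlaps C(2); A,C disjoint -> {A, C}
        def grp(n, start, end):
            hits = [MotifHit("gene", i + 1, start, FWD) for i in range(n)]
            hits[-1] = MotifHit("gene", n, end, FWD)
            return MotifGroup("gene", FWD, hits, 0, 0, 0)

        A, B, C = grp(4, 0, 100), grp(3, 105, 200), grp(2, 220, 300)
        kept = resolve_conflicts([A, B, C], k=11)
        assert kept == [A, C]

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        groups = random_groups(rng, int(rng.integers(1, 11)))
        kept = resolve_conflicts(groups, k=11)
        # kept subset is valid (pairwise non-overlapping)
        kept_sorted = sorted(kept, key=lambda g: g.start_read)
        assert all(
            a.end_read + 11 <= b.start_read for a, b in zip(kept_sorted, kept_sorted[1:])
        )
        val = (sum(g.n_motifs for g in kept), -sum(g.residual for g in kept))
        assert val == exhaustive_best(groups, k=11)


class TestProfiles:
    def test_error_free_reference_read_single_group(self, toy_pair, toy_motifs):
        p = profile_read("r", toy_pair.gene_seq, None, toy_motifs)
        assert len(p.groups) == 1
        assert p.t == [
            (toy_motifs.gene[0].ref_pos, toy_motifs.gene[-1].ref_pos, "gene")
        ]

    def test_read_with_no_hits_has_empty_profile(self, toy_motifs):
        p = profile_read("r", "ACGT" * 50, None, toy_motifs)
        assert p.groups == [] and p.t == []

    @pytest.mark.parametrize("cls", sorted(DEFAULT_BREAKPOINTS))
    def test_error_free_recovery_of_truth_structure(self, cls, bundled):
        """Error-free reads of every rearrangement class recover the truth t(R)."""
        pair, motifs = bundled
        scenario = SimScenario(cls, cls, DEFAULT_BREAKPOINTS[cls], 0.0, 4, seed=5)
        hap, segments = build_haplotype(scenario, pair, motifs)
        for read in simulate_reads(hap, 4, 0.0, seed=5):
            p = profile_read(read.read_id, read.seq, read.quals, motifs)
            assert p.t == [(s, e, r) for r, s, e in segments]

    def test_profile_tsv_round_trip(self, toy_pair, toy_motifs, tmp_path):
        profiles = [
            profile_read("a", toy_pair.gene_seq, None, toy_motifs),
            profile_read("b", revcomp(toy_pair.pseudo_seq), None, toy_motifs),
            profile_read("c", "ACGT" * 50, None, toy_motifs),
        ]
        path = tmp_path / "profiles.tsv"
        with open(path, "w") as fh:
            profiles_to_tsv(profiles, fh, provenance=["unit test"])
        with open(path) as fh:
            back = profiles_from_tsv(fh, toy_motifs)
        assert [p.read_id for p in back] == ["a", "b", "c"]
        for orig, rec in zip(profiles, back):
            assert rec.length == orig.length
            assert rec.orientation == orig.orientation
            assert rec.hit_span == orig.hit_span
            assert rec.t == orig.t
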