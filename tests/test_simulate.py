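"""Synthetic haplotypes, the read error model, artifacts, and accuracy scoring."""

import edlib
import numpy as np
import pytest

from paramotif.cluster import collapse_profiles, greedy_cluster
from paramotif.refs import revcomp
from paramotif.simulate import (
    DEFAULT_BREAKPOINTS,
    SimScenario,
    TruthRecord,
    build_haplotype,
    inject_artifacts,
    matches_truth,
    paper_grid,
    run_dataset,
    score_accuracy,
    simulate_dataset,
    simulate_reads,
)
from paramotif.scan import profile_read


def scenario(cls, error=0.0, n=10, seed=3, bp=None):
    return SimScenario(f"{cls}_t", cls, bp or DEFAULT_BREAKPOINTS[cls], error, n, seed)


class TestBuildHaplotype:
    def test_chimera_length_is_reference_length(self, bundled):
        pair, motifs = bundled
        for cls in ("pseudo_to_gene_chimera", "gene_to_pseudo_chimera"):
            hap, segments = build_haplotype(scenario(cls, bp=(3000,)), pair, motifs)
            assert len(hap) == len(pair.gene_seq)
            assert len(segments) == 2

    def test_deletion_shortens_by_segment(self, bundled):
        pair, motifs = bundled
        hap, _ = build_haplotype(scenario("deletion", bp=(2700, 3300)), pair, motifs)
        assert len(hap) == len(pair.gene_seq) - 600

    def test_tandem_duplication_lengthens_by_segment(self, bundled):
        pair, motifs = bundled
        hap, segments = build_haplotype(
            scenario("tandem_duplication", bp=(1800, 4200)), pair, motifs
        )
        assert len(hap) == len(pair.gene_seq) + 2400
        # the two copies overlap in reference coordinates
        (r1, s1, e1), (r2, s2, e2) = segments
        assert s2 < e1

    def test_dispersed_duplication_layout(self, bundled):
        pair, motifs = bundled
        hap, segments = build_haplotype(
            scenario("dispersed_duplication", bp=(800, 3200, 3800)), pair, motifs
        )
        assert len(hap) == len(pair.gene_seq) + 2400
        assert len(segments) == 3

    def test_breakpoints_out_of_range(self, bundled):
        pair, motifs = bundled
        with pytest.raises(ValueError):
            build_haplotype(scenario("deletion", bp=(5000, 9000)), pair, motifs)

    def test_bad_scenario_parameters(self):
        with pytest.raises(ValueError):
            SimScenario("x", "inversion", (1, 2), 0.0, 10, 1)
        with pytest.raises(ValueError):
            SimScenario("x", "deletion", (1, 2), 0.6, 10, 1)


class TestSimulateReads:
    def test_error_free_reads_equal_haplotype(self, bundled):
        pair, motifs = bundled
        hap, _ = build_haplotype(scenario("deletion"), pair, motifs)
        for r in simulate_reads(hap, 6, 0.0, seed=9):
            assert r.seq in (hap, revcomp(hap))
            assert set(r.qual) == {chr(33 + 40)}

    def test_same_seed_byte_identical(self, bundled):
        pair, motifs = bundled
        hap, _ = build_haplotype(scenario("tandem_duplication"), pair, motifs)
        a = simulate_reads(hap, 20, 0.08, seed=13)
        b = simulate_reads(hap, 20, 0.08, seed=13)
        assert [(r.read_id, r.seq, r.qual) for r in a] == [
            (r.read_id, r.seq, r.qual) for r in b
        ]

    def test_error_rate_matches_edit_distance(self, bundled):
        """Mean per-base edit distance tracks the requested error rate."""
        pair, motifs = bundled
        hap = pair.gene_seq
        e, n = 0.10, 200
        reads = simulate_reads(hap, n, e, seed=21)
        dists = []
        for r in reads:
            seq = r.seq
            d_f = edlib.align(seq, hap, task="distance")["editDistance"]
            d_r = edlib.align(revcomp(seq), hap, task="distance")["editDistance"]
            dists.append(min(d_f, d_r))
        mean = np.mean(dists)
        expected = e * len(hap)
        se = np.sqrt(len(hap) * e * (1 - e) / n)
        # edit distance can fall slightly below the error count when nearby
        # indels coalesce into cheaper alignments
        assert 0.9 * expected <= mean <= expected + 3 * se

    def test_quality_encodes_error_rate(self, bundled):
        pair, motifs = bundled
        reads = simulate_reads(pair.gene_seq, 1, 0.10, seed=2)
        assert reads[0].qual[0] == chr(33 + 10)


class TestInjectArtifacts:
    def _normal_reads(self, bundled, n, error=0.02, seed=5):
        pair, motifs = bundled
        reads = simulate_reads(pair.gene_seq, n, error, seed=seed)
        truths = [
            TruthRecord(r.read_id, "normal", "deletion", (0,), None, None) for r in reads
        ]
        return pair, reads, truths

    def test_zero_fractions_identity(self, bundled):
        pair, reads, truths = self._normal_reads(bundled, 20)
        out_reads, out_truths = inject_artifacts(
            reads, truths, pair, 0.02, seed=1,
            palindrome_frac=0, pcr_chimera_frac=0, offtarget_frac=0,
        )
        assert [r.seq for r in out_reads] == [r.seq for r in reads]
        assert all(t.artifact is None for t in out_truths)

    def test_fractions_follow_binomial_expectation(self, bundled):
        pair, reads, truths = self._normal_reads(bundled, 2000)
        _, out_truths = inject_artifacts(
            reads, truths, pair, 0.02, seed=1,
            palindrome_frac=0.02, pcr_chimera_frac=0.05, offtarget_frac=0.01,
        )
        counts = {}
        for t in out_truths:
            counts[t.artifact] = counts.get(t.artifact, 0) + 1
        assert abs(counts["pcr_chimera"] - 100) < 40  # ~4.5 sd
        assert abs(counts["palindrome"] - 40) < 30
        assert abs(counts["off_target"] - 20) < 20

    def test_fractions_must_sum_below_one(self, bundled):
        pair, reads, truths = self._normal_reads(bundled, 5)
        with pytest.raises(ValueError):
            inject_artifacts(reads, truths, pair, 0.02, 1,
                             palindrome_frac=0.5, pcr_chimera_frac=0.5, offtarget_frac=0.1)


class TestMatchesTruth:
    SEGS = (("pseudo", 100, 2800), ("gene", 3100, 5900))

    def test_exact_signature(self):
        assert matches_truth([(100, 2800, "pseudo"), (3100, 5900, "gene")], self.SEGS)

    def test_fragmented_within_segments(self):
        t = [(100, 900, "pseudo"), (1500, 2800, "pseudo"), (3100, 5900, "gene")]
        assert matches_truth(t, self.SEGS)

    def test_shrunken_terminal_motifs(self):
        assert matches_truth([(500, 2600, "pseudo"), (3300, 5700, "gene")], self.SEGS)

    def test_missing_segment_fails(self):
        assert not matches_truth([(100, 2800, "pseudo")], self.SEGS)

    def test_wrong_region_order_fails(self):
        assert not matches_truth([(3100, 5900, "gene"), (100, 2800, "pseudo")], self.SEGS)

    def test_overshoot_beyond_slack_fails(self):
        t = [(100, 2800, "pseudo"), (2300, 5900, "gene")]  # gene starts 800 early
        assert not matches_truth(t, self.SEGS, slack=250)

    def test_reversed_group_fails(self):
        assert not matches_truth([(2800, 100, "pseudo"), (3100, 5900, "gene")], self.SEGS)

    def test_non_monotone_within_segment_fails(self):
        t = [(100, 1500, "pseudo"), (900, 2800, "pseudo"), (3100, 5900, "gene")]
        assert not matches_truth(t, self.SEGS)

    def test_empty_observation_fails(self):
        assert not matches_truth([], self.SEGS)


class TestScoring:
    def test_grid_enumerates_800_datasets(self):
        grid = paper_grid()
        assert len(grid) == 800
        assert len(set(grid)) == 800

    def test_all_correct_scores_one(self, bundled):
        res, *_ = run_dataset("pseudo_to_gene_chimera", 0.0, 30, seed=4)
        assert res.accuracy == 1.0

    def test_definition_of_accuracy(self, bundled):
        """Accuracy is exactly correct / non-artifact reads."""
        pair, motifs = bundled
        sc = scenario("deletion", n=20)
        reads, truths = simulate_dataset(sc, pair, motifs)
        profiles = [profile_read(r.read_id, r.seq, r.quals, motifs) for r in reads]
        cs = greedy_cluster(collapse_profiles(profiles))
        # corrupt truth for 5 reads: pretend they came from a different deletion
        bad_segments = (("gene", 55, 1000), ("gene", 5000, 5913))
        for i in range(5):
            truths[i] = TruthRecord(
                truths[i].read_id, "x", "deletion", (0,), None, bad_segments
            )
        res = score_accuracy(cs, truths)
        assert res.n_reads == 20 and res.n_correct == 15
        assert res.accuracy == 0.75

    def test_artifact_reads_excluded_from_denominator(self, bundled):
        pair, motifs = bundled
        sc = scenario("deletion", n=10)
        reads, truths = simulate_dataset(sc, pair, motifs)
        profiles = [profile_read(r.read_id, r.seq, r.quals, motifs) for r in reads]
        cs = greedy_cluster(collapse_profiles(profiles))
        truths[0] = TruthRecord(truths[0].read_id, "x", "deletion", (0,), "pcr_chimera", None)
        res = score_accuracy(cs, truths)
        assert res.n_reads == 9

    def test_run_dataset_deterministic(self):
        a, cs_a, *_ = run_dataset("gene_to_pseudo_chimera", 0.05, 40, seed=77)
        b, cs_b, *_ = run_dataset("gene_to_pseudo_chimera", 0.05, 40, seed=77)
        assert a.accuracy == b.accuracy
        assert len(cs_a.clusters) == len(cs_b.clusters)
        assert a.per_read == b.per_read
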