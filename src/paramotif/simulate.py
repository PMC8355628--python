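"""Ground-truthed simulation of gene/pseudogene rearrangements and long reads.

The generator emulates a targeted amplicon experiment over a highly
homologous gene/pseudogene pair: a bundled synthetic 6 kb reference pair
differing at 30 well-spaced sites (hence 30 discriminating motifs per region
at k = 11), five rearrangement classes, full-span amplicon reads with a
tunable i.i.d. per-base error rate (substitution/insertion/deletion mix),
and the three amplicon artifact types (palindromes, in-vitro PCR chimeras
with uniformly random breakpoints, off-target molecules).

Per-read detection accuracy is the proportion of non-artifact reads whose
assigned cluster calls the simulated rearrangement: the cluster's
representative group structure must be assignable, in order, to the truth
segments -- same regions, contained coordinates, increasing motif order
within each segment, and every truth junction witnessed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cluster import collapse_profiles, greedy_cluster
from .filters import apply_filters
from .refs import GENE, PSEUDO, MotifSet, ReferencePair, find_motifs, revcomp
from .scan import ScanParams, profile_read

CLASSES = (
    "deletion",
    "pseudo_to_gene_chimera",
    "gene_to_pseudo_chimera",
    "tandem_duplication",
    "dispersed_duplication",
)

ADAPTER_SEQ = "ATCTCTCTCTTTTCCTCCTC"  # stand-in SMRTbell-style adapter


# ---------------------------------------------------------------------------
# bundled synthetic reference pair


@lru_cache(maxsize=1)
def synthetic_reference_pair(length: int = 6000, n_sites: int = 30, k: int = 11):
    """Deterministic synthetic gene/pseudogene pair and its motif set.

    Two ``length`` bp sequences differing by single-base substitutions at
    ``n_sites`` evenly spaced positions (>= 150 bp apart, kept clear of the
    ends so every site carries a full k-mer context), sized to mimic the
    motif density of a ~6 kb homology with 30 discriminating sites per
    region.  Generation retries deterministically until the pair yields
    exactly ``n_sites`` motifs per region and no motif (or its reverse
    complement) collides elsewhere in either reference.

    Returns ``(ReferencePair, MotifSet)``.
    """
    margin = 60
    step = (length - 2 * margin) // (n_sites - 1)
    site_positions = [margin + i * step for i in range(n_sites)]
    bases = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
    for attempt in range(50):
        rng = np.random.default_rng(7021 + attempt)
        gene = "".join(bases[rng.integers(0, 4, size=length)])
        pseudo = list(gene)
        for pos in site_positions:
            old = "ACGT".index(pseudo[pos])
            pseudo[pos] = "ACGT"[(old + int(rng.integers(1, 4))) % 4]
        pair = ReferencePair("geneA", gene, "geneA_P", "".join(pseudo))
        motifs = find_motifs(pair, k=k)
        if len(motifs.gene) != n_sites or len(motifs.pseudo) != n_sites:
            continue
        both = pair.gene_seq + "#" + pair.pseudo_seq
        if any(revcomp(m.seq) in both for m in motifs):
            continue
        return pair, motifs
    raise RuntimeError("failed to construct a clean synthetic reference pair")


# ---------------------------------------------------------------------------
# scenarios and haplotypes


@dataclass(frozen=True)
class SimScenario:
    """One simulated rearrangement configuration.

    ``breakpoints`` are reference coordinates whose meaning depends on the
    class: (start, end) of the affected segment for deletions and tandem
    duplications, a single junction position for chimeras, and
    (start, end, insertion_point) for dispersed duplications.
    """

    name: str
    rearrangement_class: str
    breakpoints: Tuple[int, ...]
    error_rate: float
    n_reads: int
    seed: int
    error_mix: Tuple[float, float, float] = (0.4, 0.3, 0.3)

    def __post_init__(self):
        if self.rearrangement_class not in CLASSES:
            raise ValueError(f"unknown rearrangement class {self.rearrangement_class!r}")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if abs(sum(self.error_mix) - 1.0) > 1e-9:
            raise ValueError("error_mix fractions must sum to 1")


# default breakpoints used by the error sweep: each class affects a segment
# spanning many motif sites so its junction signature is unambiguous
DEFAULT_BREAKPOINTS: Dict[str, Tuple[int, ...]] = {
    "deletion": (2700, 3300),
    "pseudo_to_gene_chimera": (3000,),
    "gene_to_pseudo_chimera": (3000,),
    "tandem_duplication": (1800, 4200),
    "dispersed_duplication": (800, 3200, 3800),
}


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted read."""

    read_id: str
    scenario: str
    rearrangement_class: str
    breakpoints: Tuple[int, ...]
    artifact: Optional[str] = None  # None | palindrome | pcr_chimera | off_target
    segments: Optional[Tuple[Tuple[str, int, int], ...]] = None


@dataclass
class SimRead:
    read_id: str
    seq: str
    qual: str  # Phred+33

    @property
    def quals(self) -> List[int]:
        return [ord(c) - 33 for c in self.qual]


def _pieces(scenario: SimScenario, gene_len: int, pseudo_len: int) -> List[Tuple[str, int, int]]:
    """Molecule layout as (region, start, end) slices of the references."""
    cls, bp = scenario.rearrangement_class, scenario.breakpoints
    if cls == "deletion":
        s, e = bp
        return [(GENE, 0, s), (GENE, e, gene_len)]
    if cls == "pseudo_to_gene_chimera":
        (b,) = bp
        return [(PSEUDO, 0, b), (GENE, b, gene_len)]
    if cls == "gene_to_pseudo_chimera":
        (b,) = bp
        return [(GENE, 0, b), (PSEUDO, b, pseudo_len)]
    if cls == "tandem_duplication":
        s, e = bp
        return [(GENE, 0, e), (GENE, s, gene_len)]
    # dispersed duplication: copy [s, e) inserted at d
    s, e, d = bp
    return [(GENE, 0, d), (GENE, s, e), (GENE, d, gene_len)]


def build_haplotype(
    scenario: SimScenario, pair: ReferencePair, motif_set: MotifSet
) -> Tuple[str, Tuple[Tuple[str, int, int], ...]]:
    """Construct the rearranged molecule and its truth motif-segment signature.

    The signature lists, per molecule piece, the region and the reference
    coordinates of the first and last motif wholly contained in the piece --
    the group structure an error-free read scan recovers.  Junction positions
    for chimeras assume coordinate-commensurable references (the bundled
    pair is substitution-only, so a breakpoint maps to itself).
    """
    pieces = _pieces(scenario, len(pair.gene_seq), len(pair.pseudo_seq))
    for region, s, e in pieces:
        if not (0 <= s < e <= len(pair.seq(region))):
            raise ValueError(f"breakpoints out of range for {region}: [{s}, {e})")
    seq = "".join(pair.seq(region)[s:e] for region, s, e in pieces)
    segments = []
    for region, s, e in pieces:
        inside = [
            m for m in motif_set.by_region(region) if m.ref_pos >= s and m.ref_pos + motif_set.k <= e
        ]
        if len(inside) >= 2:
            segments.append((region, inside[0].ref_pos, inside[-1].ref_pos))
    return seq, tuple(segments)


# ---------------------------------------------------------------------------
# read simulation


def _mutate(seq: str, error_rate: float, mix: Tuple[float, float, float], rng) -> str:
    """Apply i.i.d. per-base errors (substitution / insertion / deletion)."""
    if error_rate <= 0:
        return seq
    L = len(seq)
    err = np.flatnonzero(rng.random(L) < error_rate)
    if err.size == 0:
        return seq
    kinds = rng.choice(3, size=err.size, p=list(mix))
    sub_off = rng.integers(1, 4, size=err.size)
    ins_base = rng.integers(0, 4, size=err.size)
    parts = []
    prev = 0
    for idx, kind, so, ib in zip(err, kinds, sub_off, ins_base):
        parts.append(seq[prev:idx])
        base = seq[idx]
        if kind == 0:  # substitution to a different base
            parts.append("ACGT"[("ACGT".index(base) + so) % 4] if base in "ACGT" else base)
        elif kind == 1:  # insertion after the base
            parts.append(base + "ACGT"[ib])
        # kind == 2: deletion, emit nothing
        prev = idx + 1
    parts.append(seq[prev:])
    return "".join(parts)


def _qual_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else int(round(-10 * math.log10(error_rate)))
    return chr(33 + max(2, min(q, 40)))


def simulate_reads(
    haplotype: str,
    n: int,
    error_rate: float,
    seed: int,
    error_mix: Tuple[float, float, float] = (0.4, 0.3, 0.3),
    read_prefix: str = "read",
) -> List[SimRead]:
    """Emit ``n`` full-span amplicon reads with i.i.d. errors.

    Strand is random; base qualities are set uniformly to the Phred score of
    the error rate (capped at Q40, floored at Q2), mirroring a run-level
    predicted accuracy.  Deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    qc = _qual_char(error_rate)
    reads = []
    for i in range(n):
        seq = _mutate(haplotype, error_rate, error_mix, rng)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append(SimRead(f"{read_prefix}_{i:05d}", seq, qc * len(seq)))
    return reads


def simulate_dataset(
    scenario: SimScenario, pair: ReferencePair, motif_set: MotifSet
) -> Tuple[List[SimRead], List[TruthRecord]]:
    """Reads plus per-read truth records for one scenario."""
    haplotype, segments = build_haplotype(scenario, pair, motif_set)
    reads = simulate_reads(
        haplotype,
        scenario.n_reads,
        scenario.error_rate,
        scenario.seed,
        scenario.error_mix,
        read_prefix=scenario.name,
    )
    truths = [
        TruthRecord(
            r.read_id,
            scenario.name,
            scenario.rearrangement_class,
            scenario.breakpoints,
            artifact=None,
            segments=segments,
        )
        for r in reads
    ]
    return reads, truths


def inject_artifacts(
    reads: List[SimRead],
    truths: List[TruthRecord],
    pair: ReferencePair,
    error_rate: float,
    seed: int,
    palindrome_frac: float = 0.02,
    pcr_chimera_frac: float = 0.05,
    offtarget_frac: float = 0.01,
    error_mix: Tuple[float, float, float] = (0.4, 0.3, 0.3),
) -> Tuple[List[SimRead], List[TruthRecord]]:
    """Replace random reads with amplicon artifacts (in place semantics: new lists).

    Palindromes append a short adapter plus the read's reverse complement;
    PCR chimeras are gene/pseudogene fusions at uniformly random breakpoints
    (either orientation) re-simulated at the dataset error rate; off-target
    reads are random-composition sequence of comparable length.
    """
    if palindrome_frac + pcr_chimera_frac + offtarget_frac >= 1:
        raise ValueError("artifact fractions must sum to < 1")
    rng = np.random.default_rng(seed)
    out_reads, out_truths = [], []
    qc = _qual_char(error_rate)
    b_max = min(len(pair.gene_seq), len(pair.pseudo_seq)) - 500
    for read, truth in zip(reads, truths):
        u = rng.random()
        if u < palindrome_frac:
            seq = read.seq + ADAPTER_SEQ + revcomp(read.seq)
            qual = read.qual + "I" * len(ADAPTER_SEQ) + read.qual[::-1]
            out_reads.append(SimRead(read.read_id, seq, qual))
            out_truths.append(
                TruthRecord(read.read_id, truth.scenario, truth.rearrangement_class,
                            truth.breakpoints, artifact="palindrome")
            )
        elif u < palindrome_frac + pcr_chimera_frac:
            b = int(rng.integers(500, b_max))
            if rng.random() < 0.5:
                seq = pair.gene_seq[:b] + pair.pseudo_seq[b:]
            else:
                seq = pair.pseudo_seq[:b] + pair.gene_seq[b:]
            seq = _mutate(seq, error_rate, error_mix, rng)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            out_reads.append(SimRead(read.read_id, seq, qc * len(seq)))
            out_truths.append(
                TruthRecord(read.read_id, truth.scenario, truth.rearrangement_class,
                            truth.breakpoints, artifact="pcr_chimera")
            )
        elif u < palindrome_frac + pcr_chimera_frac + offtarget_frac:
            L = len(pair.gene_seq)
            bases = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
            seq = "".join(bases[rng.integers(0, 4, size=L)])
            out_reads.append(SimRead(read.read_id, seq, qc * L))
            out_truths.append(
                TruthRecord(read.read_id, truth.scenario, truth.rearrangement_class,
                            truth.breakpoints, artifact="off_target")
            )
        else:
            out_reads.append(read)
            out_truths.append(truth)
    return out_reads, out_truths


# ---------------------------------------------------------------------------
# truth matching and accuracy


def matches_truth(
    t_obs: Sequence[Tuple[int, int, str]],
    segments: Sequence[Tuple[str, int, int]],
    slack: float = 250,
) -> bool:
    """Is an observed group structure consistent with a truth signature?

    True when the observed groups (in read order) can be partitioned into
    consecutive non-empty blocks, one per truth segment in order, such that
    every group matches its segment's region, lies within the segment's
    motif interval (with ``slack``), and groups within a block advance
    strictly along the reference.  Requiring every block to be non-empty
    means each truth junction is witnessed by an actual group boundary;
    error-induced group splits inside a segment are tolerated because the
    missing motifs keep the pieces inside the same truth interval.

    The default ``slack`` admits a boundary displaced by about one
    discriminating site: a single base-call error at a differing site can
    relabel that site's motif as the other region's, shifting the apparent
    junction one site outward while the read still supports the same
    rearrangement.
    """
    if not t_obs or not segments:
        return False
    if any(s > e for s, e, _ in t_obs):
        return False  # reversed-orientation group: never part of a clean call
    m, K = len(t_obs), len(segments)
    if m < K:
        return False

    def block_ok(block, segment) -> bool:
        region, lo, hi = segment
        prev_end = None
        for s, e, r in block:
            if r != region or s < lo - slack or e > hi + slack:
                return False
            if prev_end is not None and s <= prev_end:
                return False
            prev_end = e
        return True

    for cuts in combinations(range(1, m), K - 1):
        bounds = (0, *cuts, m)
        if all(
            block_ok(t_obs[bounds[i] : bounds[i + 1]], segments[i]) for i in range(K)
        ):
            return True
    return False


@dataclass
class AccuracyResult:
    n_reads: int
    n_correct: int
    per_read: Dict[str, bool] = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_reads if self.n_reads else float("nan")


def score_accuracy(cluster_set, truths: Sequence[TruthRecord], slack: float = 250) -> AccuracyResult:
    """Proportion of non-artifact reads supporting their true rearrangement.

    A read supports the truth when it survived filtering, was assigned to a
    cluster, and that cluster's representative group structure matches the
    read's truth signature.  Artifact reads are excluded from the
    denominator; discarded or unassigned reads count as incorrect.
    """
    assignments = cluster_set.read_assignments()
    rep = {c.id: cluster_set.representative_t(c) for c in cluster_set.clusters}
    result = AccuracyResult(0, 0)
    for truth in truths:
        if truth.artifact is not None:
            continue
        result.n_reads += 1
        cid = assignments.get(truth.read_id)
        ok = (
            cid is not None
            and truth.segments is not None
            and matches_truth(rep[cid], truth.segments, slack)
        )
        result.n_correct += ok
        result.per_read[truth.read_id] = ok
    return result


# ---------------------------------------------------------------------------
# the error-rate sweep


def paper_grid(
    classes: Sequence[str] = CLASSES,
    error_pcts: Sequence[int] = tuple(range(16)),
    replicates: int = 10,
) -> List[Tuple[str, int, int]]:
    """Enumerate the full sweep design: class x error rate x replicate."""
    return [(c, e, r) for c in classes for e in error_pcts for r in range(replicates)]


def _child_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def run_dataset(
    rearrangement_class: str,
    error_rate: float,
    n_reads: int,
    seed: int,
    scan_params: ScanParams = ScanParams(),
    alpha: float = 10,
    beta: float = 0.5,
    min_reads: int = 3,
    artifact_fracs: Tuple[float, float, float] = (0.0, 0.0, 0.0),
    breakpoints: Optional[Tuple[int, ...]] = None,
):
    """Simulate one dataset, run the detection pipeline, score against truth.

    Returns ``(AccuracyResult, ClusterSet, truths, filter_report)``.
    """
    pair, motifs = synthetic_reference_pair()
    scenario = SimScenario(
        name=f"{rearrangement_class}_e{error_rate:.2f}_s{seed}",
        rearrangement_class=rearrangement_class,
        breakpoints=breakpoints or DEFAULT_BREAKPOINTS[rearrangement_class],
        error_rate=error_rate,
        n_reads=n_reads,
        seed=seed,
    )
    reads, truths = simulate_dataset(scenario, pair, motifs)
    if any(f > 0 for f in artifact_fracs):
        reads, truths = inject_artifacts(
            reads, truths, pair, error_rate, _child_seed(seed, 911),
            palindrome_frac=artifact_fracs[0],
            pcr_chimera_frac=artifact_fracs[1],
            offtarget_frac=artifact_fracs[2],
        )
    profiles = [profile_read(r.read_id, r.seq, r.quals, motifs, scan_params) for r in reads]
    kept, report = apply_filters(profiles, motifs.k)
    table = collapse_profiles(kept)
    cluster_set = greedy_cluster(table, alpha=alpha, beta=beta, min_reads=min_reads)
    result = score_accuracy(cluster_set, truths)
    return result, cluster_set, truths, report


def run_sweep(
    classes: Sequence[str] = CLASSES,
    error_pcts: Sequence[int] = tuple(range(16)),
    replicates: int = 3,
    reads_per_dataset: int = 100,
    seed: int = 1,
    scan_params: ScanParams = ScanParams(),
):
    """Scaled error-rate sweep; returns a tidy DataFrame of accuracies."""
    import pandas as pd

    rows = []
    for cls_i, cls in enumerate(classes):
        for e_pct in error_pcts:
            for rep in range(replicates):
                ds_seed = _child_seed(seed, cls_i, e_pct, rep)
                result, *_ = run_dataset(
                    cls, e_pct / 100.0, reads_per_dataset, ds_seed, scan_params
                )
                rows.append(
                    {
                        "class": cls,
                        "error_pct": e_pct,
                        "replicate": rep,
                        "n_reads": result.n_reads,
                        "accuracy": result.accuracy,
                    }
                )
    return pd.DataFrame(rows)
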