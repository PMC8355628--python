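# Methods

`paramotif` detects structural rearrangements between a gene and a highly
homologous pseudogene from targeted long-read (amplicon) sequencing, then
estimates copy numbers and phases variants within each rearrangement. This
note records the model, the tunables and their defaults, the numerical
choices, what the synthetic-data generator does and does not emulate, and the
known limitations.

## The motif model

Two highly homologous references (a gene and its pseudogene) are aligned
end-to-end (affine gaps: match +1, mismatch −2, gap open −4, gap extend −1;
an identity below 80% aborts, since the model presumes near-identical
paralogs). Every substitution column whose flanking ⌊k/2⌋ columns are
gap-free yields two candidate *motifs*: the k-mer centered on the
differing base in each reference (default k = 11, forced odd so "centered"
is well defined). A candidate survives only if it occurs nowhere in the
other reference and exactly once in its own. Motifs are the only sequence
evidence the method uses: each exact motif match in a read is a
paralog-discriminating anchor with a known reference coordinate.
Uniqueness is checked only within the two target regions — appropriate for
amplicon data, where every molecule derives from the co-amplified loci.

## Scanning and grouping reads

Each read is scanned for exact occurrences of every motif and of its reverse
complement, requiring base quality ≥ `min_qual` (default 10) at all k
positions. The orientation (read vs. its reverse complement) with more
forward-strand hits becomes canonical; reverse-strand hits within the
canonical orientation are retained because they are the signature of
palindromic adapter artifacts.

Hits are assembled into *motif groups*: runs of same-region, same-strand
hits whose motif ids advance along the read and whose read spacing matches
the reference spacing. The spacing tolerance between two hits at reference
distance d is

    |Δread − Δref| ≤ D + drift_frac · d

with D = 10 and drift_frac = 0.05. The distance-proportional term absorbs
the indel drift a read accumulates between distant anchors (standard
deviation ≈ √(0.6·e·d) under an error rate e with 60% indels), while true
junctions displace spacing by the full rearranged length and always fail the
check. Because spacing consistency — not id adjacency — is what separates
junctions from error-induced motif losses, the id-gap cap M (`max_skip`) is
unbounded by default; a small M re-enables the stricter classic behavior
(e.g. `max_skip=2` recovers a group across one lost motif and nothing more)
but fragments reads badly above ~4% error.

Groups are selected by a highest-scoring-path dynamic program over the hits:
the path visits hits in read order, either chaining (extending a group under
the rules above) or breaking (starting a new group past the previous k-mer),
and maximizes the number of motifs in groups of size ≥ 2 — isolated hits
carry no structural evidence. Ties prefer fewer groups, then the smaller
summed spacing residual. The per-motif formulation matters in one important
case: a single base-call error at a differing site converts one region's
motif into the other's, and such a hit chains seamlessly into the other
region's group (the coordinates are commensurable); an all-or-nothing
arbitration between whole groups lets one such hit annihilate a legitimate
group, whereas the path search simply routes around it. A group-level
non-overlap arbiter (weighted interval scheduling maximizing total motif
count) runs afterwards as a guard and serves externally supplied groups.

A read's profile is its ordered group list, summarized as t(R): the
(start, end) reference coordinates of each group.

## Artifact filters

*Palindromes* (missed-adapter reads containing template + adapter + reverse
complement) are detected from the profile: a group mirrored later in the
read by an opposite-strand group with the same motif ids marks both spans;
the read is discarded when mirrored spans exceed 50% of its length.

*Off-target* reads are discarded when more than 30% of the read is
unexplained by motifs. The explained span runs from the first to the last
raw motif hit: sequence inside verified groups is vouched for by spacing
checks, and sequence between motif-anchored coordinates is either a junction
or error-destroyed motif sites — both on-target. Counting only group
footprints would discard genuine reads in proportion to their error rate
(interior holes where a run of motifs was destroyed), which is a property of
the sequencing error, not of the molecule's origin. Off-target molecules
essentially never assemble even one spacing-consistent group, which remains
required.

Both filters are pure predicates; discard tallies partition the input
(palindrome takes precedence in reporting).

## Clustering and classification

Reads with identical motif sequences collapse into weighted unique profiles.
The distance between two profiles is the position-wise L1 difference of
their t(R) tuple lists, infinite when group counts or group regions differ.
Greedy intermediate-linkage clustering visits profiles in descending weight;
a profile joins the best existing cluster for which at least β of the
cluster's weight (by supporting reads; a `--beta-basis seqs` switch counts
unique sequences instead) lies within distance α, with α = 10 and β = 0.5;
otherwise it founds a new cluster. Ties prefer the higher qualifying
fraction, then the lower weighted mean distance, then creation order.
Clusters below `min_reads` (default 3) are flagged weak rather than dropped.

Each cluster's representative (highest-weight member) is classified by its
region switches: none → normal gene / normal pseudogene; exactly one
pseudogene→gene switch → the unequal-crossover chimera; one gene→pseudogene
switch → the converse class; two or more switches → `other`, with a
`conversion_like` flag when the pattern returns to its starting region
(an internal tract of the other region).

Copy numbers are apportioned from supporting-read counts by largest
remainder so they always sum to `total_copies` (default 4: two copies of
each region per diploid genome). Because in-vitro PCR recombination creates
gene/pseudogene fusion molecules at a roughly constant background (~5% of
reads, with uniformly random breakpoints), that expected share is deducted
from chimeric clusters before apportionment. Supplied heterozygous variant
allele fractions arbitrate: at copy number c every het VAF must lie within
±0.08 of j/c for some integer 1 ≤ j < c, else the cluster is flagged
`cn_conflict`. Chimera junction labels come from a user-editable interval
table (the CH-naming convention is locus-specific literature knowledge and
is shipped only as an example).

## Phasing

Variant sites (supplied as VCF or TSV; discovery is out of scope) are typed
per read by local realignment: the read segment around the
motif-interpolated site position (read↔reference coordinates interpolated
from motif anchor pairs; window 25 bp per side) is aligned against the
reference-allele and alternate-allele contexts, and the smaller edit
distance wins; ties and non-spanning reads are missing. Reads are clustered
by Ward linkage over missing-aware normalized Hamming distances
(disagreements / columns observed in both; no shared columns → distance 1)
and the tree is cut into `n_haplotypes` groups (default 2, the diploid
expectation; `--cut-height` overrides). Per-group majority consensus alleles
(ties → reference) are written as phased genotypes to a VCF 4.2 file with a
PS tag carrying the cluster id.

## The synthetic-data generator

The generator emulates the method's validation design at desk scale: a 6 kb
gene/pseudogene pair differing at 30 single-base sites spaced ~200 bp apart
(kept ≥ 50 bp from the ends), deterministically constructed so that exactly
30 motifs per region survive at k = 11 and no motif or reverse complement
collides elsewhere. Five rearrangement classes are built from it, with
default breakpoints chosen so each junction-delimited piece spans at least
ten discriminating sites (the rearrangements this method targets, such as
the common ~30 kb gene/pseudogene deletion or multi-exon conversions, span
many sites):

| class                  | breakpoints (gene coords)       | molecule length |
|------------------------|---------------------------------|-----------------|
| deletion               | remove [2700, 3300)             | 5.4 kb          |
| pseudogene→gene chimera| junction 3000                   | 6.0 kb          |
| gene→pseudogene chimera| junction 3000                   | 6.0 kb          |
| tandem duplication     | repeat [1800, 4200)             | 8.4 kb          |
| dispersed duplication  | copy [800, 3200) inserted at 3800 | 8.4 kb        |

Reads are full-span amplicons on a random strand with i.i.d. per-base errors
(mix 0.4 substitution / 0.3 insertion / 0.3 deletion) and uniform base
qualities set to the Phred score of the error rate. Artifacts are injected
by replacement: palindromes (read + 20 bp adapter + reverse complement,
default 2%), PCR chimeras (gene/pseudogene fusions at uniform random
breakpoints, re-simulated at the dataset error rate, default 5%), and
off-target reads (random sequence, default 1%).

Per-read detection accuracy is the fraction of non-artifact reads assigned
to a cluster whose representative group structure matches the read's truth
signature: observed groups must partition, in read order, into one
non-empty block per truth segment with matching regions, coordinates
contained within the segment (slack 250 bp ≈ one site spacing, since a
single base error at a differing site can relabel that site's motif and
shift the apparent junction one site outward), and strictly advancing
coordinates within each block. Discarded or unassigned reads count as
incorrect; artifact reads are excluded from the denominator.

The full published design (5 classes × error 0–15% in 1% steps × 10
replicates) enumerates 800 datasets; the bundled sweep runs a scaled version
(3 replicates × 100 reads per dataset, ~1 minute on one CPU), which
reproduces the method's operating boundary: class-averaged accuracy stays
above 0.95 through 7% error and first drops below at 8%.

### What the generator does not emulate

* **Quality–error correlation.** Real base callers concentrate errors at
  low-quality positions; with i.i.d. errors and uniform qualities, motif
  survival at a nominal error rate is lower than for real reads (where
  Jensen's inequality makes heterogeneous per-base error rates *raise*
  expected k-mer survival), so the accuracy curve here is conservative.
  A side effect of uniform qualities: at ≥ 12% error the run-level quality
  falls below the Q10 scan threshold and accuracy drops to zero — a sharper
  floor than mixed-quality reads would show.
* **Sequence-context error profiles** (homopolymer indels), chimera
  formation mid-PCR with partial error history, length jitter in amplicons,
  and multi-copy mixtures with stoichiometry other than one haplotype per
  dataset.
* **Reference divergence structure.** The bundled pair differs by
  substitutions only, making gene and pseudogene coordinates identical;
  real pairs also differ by indels, which motif-anchored coordinates handle
  but the bundled conditions do not exercise.

Passing the bundled sweep therefore shows the detection machinery is correct
and robust to uniform random error up to the stated rates; it does not
certify performance under platform-specific error structure.

### Accuracy at the margins

Two irreducible effects bound per-class accuracy near 7% error: terminal
runs of destroyed motifs occasionally push leading/trailing unexplained
sequence over the 30% filter (~2–3% of chimera-class reads), and
*conversion mimicry* — an error at a differing site relabels the site's
motif while destroying the real one, which can displace a cluster's apparent
junction by two or more sites when the intervening real hits are also lost
(~2%). Both scale steeply with error rate, which is what produces the sharp
accuracy knee; at the 300-read scale of the bundled acceptance sweep the
chimera classes' 7% means (~0.955) fluctuate by ±0.012 and can dip below
0.95 for individual seeds.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere; motif `ref_pos` is the k-mer
  start; VCF output converts to 1-based.
* FASTA reads (no qualities) are treated as uniform quality 40.
* Reads shorter than k, or with no hits, yield empty profiles; the
  off-target filter discards profiles with no groups.
* Copy-number apportionment with zero total weight is an error; fractional
  ties go to the heavier cluster, then the earlier one.
* Phasing requires ≥ 2 reads and at least one observed matrix entry;
  consensus ties resolve to the reference allele.
* All randomness flows through seeded NumPy generators; dataset seeds are
  derived with `SeedSequence` so grids are reproducible and independent.

## Limitations

* Exactly two regions; multi-pseudogene families are out of scope.
* No inexact motif matching: sensitivity at high error comes only from motif
  redundancy along the molecule, so performance degrades for short
  homologies with few discriminating sites (junction segments spanning
  fewer than ~5 sites lose their witnesses at ≥ 5% error).
* Junction resolution is one inter-motif interval; breakpoints closer than
  one site spacing to each other are indistinguishable.
* Variant discovery (as opposed to typing/phasing of supplied sites) is not
  implemented.
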