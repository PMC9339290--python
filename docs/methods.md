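# Methods

This note documents the models, algorithms, numerical choices, and
known limitations of `dipscaffold`, and what the synthetic test bed
does and does not establish about real data.

## Coordinates and formats

All coordinates are 0-based half-open internally. AGP v2.1 (1-based
inclusive) and GFF3 are converted only at the serialization boundary.
Structure files use AGP component types `W` (sequence slice) and `U`/`N`
(gap; `U` with the conventional 100 bp placeholder length when the true
size is unknown). An internal BED-like dialect carries the same
information 0-based; conversion between the two is lossless. Genetic
map positions may be centimorgans or ordinals; only the dense per-LG
rank (ties broken by input order and flagged) is used downstream, so
map distances never enter any computation.

## Marker anchoring

A marker is *reliable* if it occurs at ≤2 locations in the assembly and
≤1 time per sequence: two locations are expected for an allelic pair,
three or more (or two in one sequence) indicate a repeat or a fused
allele, and such markers are excluded and reported.

The "longest sorted set of markers" of a sequence is formalized as the
longest strictly monotone subsequence of map ranks ordered by position
on the sequence. It is computed by dynamic programming with an
enumeration of all optimal chains (capped at 512) so that the declared
tie-break — increasing preferred over decreasing, then smallest rank
span, then lexicographically smallest marker ids, then linkage-group
name — is applied exactly. Hit lists per sequence are small (tens), so
the quadratic DP is never a bottleneck; the anchor aligner (below) uses
an O(n log n) patience-style LIS where n reaches 10^5. Chains from
different linkage groups compete directly; a sequence whose winning
chain accounts for under half of its reliable hits is flagged
`ambiguous-LG` (a chimera candidate) but still assigned.

Orientation is the chain direction. A single-marker sequence is
oriented by the majority strand (weighted by matching bases) of its
alignments to the alternative-haplotype sequence sharing the marker,
else defaults to `+` with an `unknown-defaulted` flag.

## Tiling paths

Nodes carry all the weight (markers covered, or matching bases in guide
mode); edges are unweighted adjacency between rank-disjoint, ordered
intervals. The best path maximizes total node weight by DP in
topological order; ties prefer larger total sequence length (contiguity
bias), then the lexicographically smallest id tuple, making output
fully deterministic. The second haplotype is the best path after
removing the first path's nodes — sequential, not joint, optimization,
so haplotype 1's total weight always ≥ haplotype 2's. Haplotype labels
are per-linkage-group and arbitrary; no cross-chromosome phasing is
attempted. Mutual-exclusion (allelic) constraints bind in the second
pass: a pair with one member already in haplotype 1 is automatically
satisfied; a pair with both members still free may not co-occur in
haplotype 2 (violations are resolved by dropping the lighter member and
re-solving). Inter-component gaps default to 100 bp (`--gap-size`).

A consequence of the max-marker objective worth knowing: if one
haplotype has a hole (a contig with no markers, or withheld), the best
path will legally *weave* through the other haplotype's contigs
covering the hole's ranks, because that covers more markers. This is a
property of the objective, not an implementation artifact; the remedy
on real data is allelic constraints, and the gap-filling experiment in
the validation suite therefore starts from the intact reconstruction
with contigs excised rather than from a re-run of the splitter.

## Guide and hybrid modes

The built-in anchor aligner finds k-mers (default k = 15) unique in
each sequence, matches them across sequences on both strands, chains
them by longest increasing subsequence on the target coordinate, and
splits chains where either coordinate jumps more than `slack` (default
2 kb). Identity is estimated as anchored bases over block span. It is a
test-scale stand-in for a production aligner; real runs consume PAF.
`stride` subsamples anchors (used at 10 for pseudomolecule-scale
comparisons, where ~200 bp anchor spacing times 10 still leaves block
boundaries resolved to well under a flank length).

Each draft sequence is assigned to the guide sequence with the most
matching bases after discarding fragments < 1 kb or < 80% identity
(defaults mirror the QC significance threshold; both configurable).
Adjacent projections may overlap by 5% of the shorter (alignment ends
are fuzzy); the tiling machinery then runs with matching-base weights.
Guide mode inherits the guide's structure by design — structural
variants of the guide will be imprinted on the result; no correction is
attempted. In hybrid mode the map is primary: map-placed components are
never dropped or reordered; unplaced sequences whose projections do not
significantly overlap (> the same 5% tolerance) any placed projection
are inserted into the projection gap they fall in, haplotype 1 served
first, each sequence inserted at most once.

## Breaking and making

A breakpoint coordinate resolves to the nearest structure junction
within the search limit (default 50 kb), else the nearest run of ≥
`min_gap` Ns (default 10), else stays unresolved (reported, not fatal).
A pair resolving to two junctions (sequence ends count as junctions)
flags the intervening piece "unwanted"; a gap resolution splits the
sequence with the N run removed — gap Ns are placeholders, not
sequence, and re-scaffolding reintroduces standard gaps. Pieces are
renamed `<id>_p1…` with an id map emitted; non-N residue content is
conserved exactly.

Structure application concatenates oriented slices and N gaps. Features
and marker hits wholly inside a slice are lifted strand-aware; anything
spanning a junction (or on unused sequence) is dropped and listed.
Junction-overlap trimming aligns each upstream slice end against the
next slice start (window 5 kb); a terminal match ≥ 90% identity shifts
the downstream slice start past the duplicated span — always the
downstream side, for determinism; content is conserved either way — and
removes the gap between them, unless a supplied feature overlaps the
trimmed span, in which case the trim is skipped and logged so
annotation is never invalidated.

## Coverage classification and gap filling

Depth is binned (default 1 kb, mean per bin). The expected haploid
depth E(x) is a Savitzky–Golay smooth (window 151 bins, order 3) of the
bin series after excluding annotated repeat bins *and* bins deviating
more than 50% from the global median; excluded bins are linearly
interpolated before smoothing. The median screen is a robustness
choice: a collapsed (2×) block longer than about half the filter window
would otherwise inflate its own baseline and classify itself haploid.
On a flat track the screen removes nothing and E equals the plain
smooth. Bins are labelled by r = depth/E: uncovered r < 0.1, haploid
0.1 ≤ r < 1.5, diploid 1.5 ≤ r < 2.5, repetitive r ≥ 2.5 — all
user-configurable.

For each gap, flanks (default 50 kb, capped at the neighbouring gap)
and the corresponding alternative-haplotype interval — obtained by
projecting the gap through the colinearity map between the two
pseudomolecules — define the supports. If the alternative region is
reliable (≤20% N, ≤50% repetitive bins), two supports are built: the
*hybrid* (own flanks around the alternative allele) and the
*alternative* (the allele with its own flanks). Otherwise two *gapped*
supports concatenate the flanks on each haplotype.

Candidate (filler, support) pairs are scored by aligned bases matching
non-repetitive support sequence (tie: whole-support matches, then
hybrid > alternative > gapped). Validation differs by support shape.
For supports with a gap-corresponding centre, the filler's alignment
must reach both flank junctions within 2 kb — the filler is the missing
allele's counterpart and cannot share literal flank sequence, so
"bridging" means spanning the centre end-to-end. For gapped supports
the filler must extend ≥1 kb into each flank **as a split bridge**: a
single alignment crossing the junction as one contiguous diagonal means
the filler's content is already present in the flanks (placing it would
duplicate the allele — the scenario where the other haplotype's
junction falls inside the filler's span) and is rejected; only a bridge
with an unaligned middle, i.e. novel sequence at the junction, counts.
Assignment is globally greedy by descending score under the one-to-one
filler↔gap constraint — deterministic and scalable; a maximum-weight
matching could in principle differ on adversarial score ties.

An unfilled gap whose alternative interval is majority-diploid (both
haplotypes' reads pile on the single assembled copy) is assumed
homozygous and receives a copy of the alternative allele. The copy is
materialized as its own source sequence (named `…_homofill`, flagged in
the AGP component note) rather than a pointer, deliberately duplicating
content — the alternative would leave the haplotype incomplete.
Iteration repeats assign-and-fill until a round makes no assignment or
the round budget is spent; the unplaced count and total length are
non-increasing by construction.

## Colinearity maps

Local alignments between two haplotypes are filtered against repeat
annotation (>20% overlap discards), then chained into the
maximum-weight chain monotone on both coordinates; plus- and
minus-strand chains are computed separately and the heavier one wins,
so locally inverted segments appear as holes rather than as mixed
chains. Adjacent blocks may overlap by 1% of the shorter; the overlap
is clipped from the downstream block. Sequences are never modified.

## The synthetic diploid test bed

The generator derives two haplotypes from a uniform-random ancestor via
SNPs (default 0.5%/bp — mid-range for outbred plant/animal diploids),
short indels (2×10⁻⁴/bp, 1–10 bp), and optional SVs (inversion,
deletion, duplication, tandem expansion; 2–8 kb). A configurable
fraction of each chromosome carries no variants at all (collapse
candidate). Contigs partition each haplotype; with collapsing on, the
homozygous block is emitted once (haplotype 1) and registered; a
fuse fraction builds chimeric opposite-haplotype scaffolds with a 100 N
junction. Coverage regimes: 1× phased, 2× collapsed, multiplicity ×
for expansions, 0 on gaps, truncated Gaussian noise. Markers are unique
21-mers of the ancestor avoiding all variants, so every marker occurs
intact on both haplotypes, and the exact-search and hit-table paths
agree. Everything is integer-seeded and byte-reproducible.

Two generator choices encode the *identifiability conditions* under
which map-based phasing has a unique answer, and were fixed as part of
the study design. First, the two haplotypes' cut points are staggered
(haplotype 2 breaks near the midpoints of haplotype 1's pieces), as in
real assemblies, where independent haplotype breakpoints rarely
coincide. Second, marker sampling guarantees at least one marker per
contig and per cross-haplotype stagger interval. If both haplotypes
broke inside the same inter-marker interval the max-marker objective
would tie exactly between weaving and not weaving, and no method using
marker counts alone could decide the phase there.

What the simulator does **not** emulate: sequencing errors and read
mosaicism (depth is drawn directly, not from reads), assembly base
errors, segmental duplications beyond the SV menu, translocations (off
by default), gene conversion, and real marker-map error structure
(order errors are injected as adjacent swaps). Passing tests therefore
establish algorithmic correctness under clean, identifiable conditions
— not robustness to every failure mode of real maps and assemblies.

## Validation problem sizes

The reference experiments run at two 500 kb chromosomes, ~40 contigs
per haplotype (N50 ≈ 12.5 kb), 1600 markers/Mb (~20 per contig),
haploid depth 30 with noise σ = 3 — large enough that every stage runs
at realistic relative scales, small enough to re-run in minutes. The
combinatorial cores (best/second tiling path, longest monotone chain,
colinear chaining) are additionally verified against exhaustive
enumeration on hundreds of random small instances.

## Known limitations

- Sequential best-then-second path extraction is not a joint optimum
  over both haplotypes; no k > 2 polyploid support.
- Greedy 1-to-1 filler assignment, not optimal matching.
- The toy anchor aligner requires unique exact k-mers; it is blind in
  high-identity repeats and at diverged (<~90% identity) homology, so
  production use should supply external PAF.
- Colinearity chains are single-strand; inversions are reported as
  gaps, not as signed blocks within one chain.
- The homozygous fallback duplicates sequence content by design.
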