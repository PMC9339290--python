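# dipscaffold

Build, quality-control, correct, and gap-fill **fully phased diploid
chromosome-scale pseudomolecules** from a draft diploid assembly
(primary contigs + haplotigs, or any diploid sequence set), guided by a
genetic map and/or a related guide genome.

Diploid-aware assemblers emit both haplotypes of a genome as a bag of
contigs. Turning that bag into two chromosome-scale haplotypes requires
(1) anchoring each contig to a chromosome and orienting it, (2) choosing
which contigs form which haplotype, (3) spotting misassemblies such as
fused alleles, (4) breaking them, and (5) recovering regions that ended
up as gaps in one haplotype. `dipscaffold` does all five, and ships a
synthetic diploid-genome simulator that provides ground truth for every
step.

## The model

**Anchoring.** Markers of a genetic map (sorted per linkage group, used
only through their dense rank order) are located on the draft
sequences. Markers seen at ≥3 assembly locations, or twice in one
sequence, are unreliable and removed. Each sequence is assigned the
linkage group and orientation of its *longest strictly monotone marker
chain* — the longest subsequence of hits whose map ranks increase (or
decrease) along the sequence — and occupies the closed rank interval
`[min rank, max rank]` of that chain.

**Tiling.** Per linkage group, a directed acyclic adjacency network is
built: node = assigned sequence with weight `w(v)` = number of covered
markers (or matching bases in guide mode); edge `u → v` iff the rank
intervals are disjoint with `max_rank(u) < min_rank(v)`, so sequences
that share markers (the two alleles of a region) can never share a
path. The first haplotype is the maximum-weight path

&nbsp;&nbsp;&nbsp;&nbsp;`Hap1 = argmax_P Σ_{v∈P} w(v)`,

computed by dynamic programming in topological order; its nodes are
removed and the second-best path over the remainder is the second
haplotype. User constraints (blacklists, forced linkage groups, allelic
pairs that must not share a haplotype) are honored.

**QC, breaking, filling.** Reports expose duplicated markers, per-gene
copy counts between haplotypes (significant = coverage and identity
both > 80%), dotplot tables, and unplaced-sequence conflicts. Breaks
snap to the nearest scaffolding junction within a search limit, else to
the nearest N run. Gap filling classifies each bin of a read-depth
track as uncovered / haploid / diploid / repetitive by the ratio of its
depth to a Savitzky–Golay expected haploid depth (default bands 0.1 /
1.5 / 2.5), builds support sequences around every gap from the flanks
and the corresponding region of the alternative haplotype, assigns
unplaced sequences to gaps one-to-one by aligned non-repetitive bases,
and — for gaps left unfilled whose alternative region shows diploid
depth — copies the alternative allele in (the region is inferred
homozygous and collapsed).

## Worked example

```python
from dipscaffold import simdip, split_by_map

bundle = simdip.simulate_diploid(n_chrom=1, chrom_len=100_000, snp_rate=0.005, seed=7)
draft = simdip.fragment_contigs(bundle, n50_target=12_500, seed=8)
gmap, hits = simdip.simulate_map(bundle, density_per_mb=1600, seed=9)
print(f"{len(draft)} draft contigs, {gmap.n_markers()} markers")

result = split_by_map(draft, gmap, hits)
for oid in result.structure.objects:
    print(oid, result.structure.object_length(oid), "bp")
score = simdip.score_reconstruction(result.structure, bundle)
print("assignment accuracy:", score["assignment_accuracy"])
print("orientation accuracy:", score["orientation_accuracy"])
print("switch errors:", score["switch_errors"])
print("completeness:", score["completeness"])
```

prints

```
16 draft contigs, 160 markers
chr01_Hap1 100701 bp
chr01_Hap2 100704 bp
assignment accuracy: 1.0
orientation accuracy: 1.0
switch errors: 0
completeness: {1: 1.0, 2: 1.0}
```

All 16 contigs land on their true chromosome with the right
orientation; the two pseudomolecules (each haplotype plus 100 bp
inter-contig gaps) carry zero phasing switch errors and 100% of each
haplotype's bases.

The same pipeline is available from the shell:

```sh
dipscaffold sim --seed 5 --out-dir sim/
dipscaffold split --fasta sim/draft.fasta --map sim/map.tsv \
    --hits sim/hits.tsv --out-prefix out
dipscaffold qc --hits out.hits.tsv --out-prefix qc
dipscaffold fill --fasta sim/draft.fasta --structure out.agp \
    --unplaced out.unplaced.fasta --bedgraph depth.bedgraph --out-prefix filled
```

`break`, `make` (structure application + annotation liftover) and `map`
(haplotype colinearity) complete the toolset.

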