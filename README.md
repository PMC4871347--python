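# introtrace

Forensic analysis of **unintended introgression** in selfing crop pedigrees.

Insertional mutant collections (T-DNA, transposon) in rice and other selfers
are screened by phenotype, but many striking phenotypes have nothing to do
with the tagged insertion. One well-documented failure mode is spontaneous
outcrossing in the field: pollen from a genetically distant variety (e.g. an
*indica* donor into a *japonica* recipient) introduces chromosome segments
that then segregate and fix over selfing generations, carrying their own
trait alleles. `introtrace` implements the post-variant-calling analysis
that untangles such a case from multi-sample SNP calls, plus a forward
simulator of the crossing/tissue-culture history so the whole pipeline is
testable at desk scale without any external data.

## What it computes

Given a multi-sample VCF (GT/AD/DP), a chromosome-length table and,
optionally, gene models:

- **Introgression detection** (`introgression`): sliding-window SNP density
  (reported as SNPs per 2 Mb; default window 2 Mb, step 5 kb), windows
  called *high* against control samples (fold change ≥ 10 over the
  strongest control plus an absolute floor), borders refined to 10 kb beyond
  the outermost sample-specific SNP, zygosity classified from the het/hom
  composition, and a donor-similarity score. A 100-kb heterozygosity profile
  separates clean genomes, segmental introgression and the genome-wide
  heterozygosity of a fresh outcross.
- **Lineage tracking** (`lineage`): introgressed genome fractions (any /
  het / hom), region trajectories across generations (het→hom fixation,
  loss), and generation-since-outcross inference from the heterozygosity
  decay law: material heterozygous at the F1 stays heterozygous with
  probability (½)^g after g selfing generations, so ĝ = round(log½ of the
  observed het fraction).
- **Bulk-segregant mapping** (`bsa`): the SNP index of a DNA pool at a
  marker is alt reads / total reads. An F2 pool fluctuates around 0.5 away
  from a causal locus; a pool of phenotypic recessives is fixed (index 1)
  at the causal locus, while the phenotypic wild-type pool (1 AA : 2 Aa)
  expects ⅓. Tracks are smoothed with a 20-SNP moving window stepped one
  SNP at a time, and peaks are called where the mutant pool stays ≥ 0.9
  while the wild-type pool stays ≤ 0.7.
- **Candidate SNPs** (`candidates`): the exact co-segregation predicate —
  homozygous-alternate in all affected plants, not homozygous-alternate in
  any unaffected plant — plus a minimal strand-aware coding-effect
  classifier (synonymous / nonsynonymous / stop_gained / splice_site /
  frameshift / noncoding).
- **Phylogeny check** (`phylo`): allele-sharing (dosage) distances and a
  neighbor-joining tree; restricted to an introgressed region the carrier
  clusters with the donor group, on the whole genome with the recipient.
- **Forward simulator** (`sim_cross`): recipient/donor/mapping-parent
  founders at configurable marker densities, Poisson crossovers without
  interference (λ = 1.25 per chromosome per meiosis), tissue-culture point
  mutations at 1.5 × 10⁻⁶ per site per diploid genome, a T-DNA
  presence/absence pseudo-marker, fully penetrant recessive causal loci,
  and Poisson/binomial read sampling for single plants and 20-plant pools.
  Every simulated plant exposes its true ancestry mosaic for scoring.

## Worked example

Run the whole pipeline on the built-in study-mimicking pedigree (one
spontaneous outcross, one selfing, tissue culture with T-DNA insertion and
a causal de-novo mutation, three selfing generations, and an F2 mapping
cross with two 20-plant pools):

```sh
introtrace run-all --seed 3 --out-dir out/
```

which prints, stage by stage:

```
simulate: 32959 markers, 11 samples -> out/sim
detect: T1a: 27 regions, genome state segmental_introgression
...
detect: T3b: 17 regions, genome state segmental_introgression
track: 7 plants -> out/track
bsa: 3 peak region(s) -> out/bsa
candidates: 2 SNP(s) co-segregate -> out/candidates
phylo: 11 samples -> out/phylo
```

Reading the outputs: each `out/detect/regions_*.tsv` lists the called donor
segments with zygosity and donor similarity (near 1.0 for genuine donor
segments); `out/track/lineage_summary.tsv` gives per-plant introgressed
fractions and their union; `out/bsa/peaks.bed` contains the mapping peak
spanning the planted grain-size locus; and `out/candidates/candidates.tsv`
ranks the SNPs that co-segregate with the dwarf phenotype — the planted
causal tissue-culture mutation appears with the diagnostic pattern
(hom-alt in all dwarf plants, het or absent in the others):

```
rank  chrom  pos      ref alt effect    pattern
1     chr04  1656904  G   A   noncoding T1c=hom-alt;...;T2a=het
2     chr04  1666666  G   A   noncoding T1c=hom-alt;...;T2a=het
```

(position 1666666 is the planted causal site; the other row is a tightly
linked donor marker, the expected ~1 hitchhiker per run).

## Layout

```
src/introtrace/
  sim_cross.py      forward simulator + pedigree runner + study preset
  variant_io.py     VCF / BED / gene-table / newick readers and writers
  introgression.py  windowed detector, borders, zygosity, genome state
  lineage.py        fractions, trajectories, generation inference
  bsa.py            SNP index, smoothing, peak calling
  candidates.py     co-segregation filter + effect classifier
  phylo.py          allele-sharing distances, neighbor joining, placement
  cli.py            `introtrace` subcommands (simulate ... run-all)
```

See `docs/methods.md` for the model assumptions, parameter choices and
limitations.
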