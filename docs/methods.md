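# Methods

This note records the models behind `introtrace`, the parameters that
matter, the design choices made where the design was genuinely open, and
what the simulation-based tests do and do not demonstrate about real data.

## The problem being modelled

A selfing crop line (recipient, *japonica*-like) receives pollen from a
genetically distant variety (donor, *indica*-like) one generation before a
seed is taken into tissue culture for transformation. The regenerated plant
and its selfed descendants then carry a mosaic of donor chromosome
segments — initially heterozygous, progressively fixing or disappearing —
together with a T-DNA insertion and a handful of tissue-culture point
mutations. Traits observed in the line can come from any of these three
sources, and the analysis has to attribute them.

## Forward simulator (`sim_cross`)

**Genome.** Desk scale by default: 12 chromosomes × 2.5 Mb. All sizes are
configurable; the statistical structure of every downstream method (window
counts, segregation ratios, index distributions) is unchanged by genome
size, only the number of segments per chromosome is.

**Markers.** Founders differ at Poisson-placed biallelic markers. The
donor-diagnostic class is dense (default 10⁻³/bp at desk scale) mirroring
the indica-vs-japonica contrast of millions of genome-wide SNPs; the
mapping-parent class is sparse (10⁻⁴/bp) mirroring the tens-of-thousands
contrast between two japonica varieties.

**Meiosis.** Crossovers per chromosome are Poisson(λ), λ = 1.25 by default
(≈ rice map length divided by 12 chromosomes), positions uniform, no
interference, starting copy by fair coin. This is the simplest model
consistent with the observed per-generation recombination of donor
segments; it slightly overdisperses crossover counts relative to real
interference but none of the statistics tested depend on interference.

**Tissue culture.** Point mutations arrive as Poisson(μ × genome bp) with
μ = 1.5 × 10⁻⁶ per site per diploid genome, inside the measured range for
rice tissue culture (0.89–2.10 × 10⁻⁶). Each mutation lands on one random
haplotype, hence is heterozygous in the regenerant — which is why a
culture-derived causal allele can sit heterozygous or absent in some
descendants while homozygous in all affected ones. The T-DNA is a
presence/absence pseudo-marker on one haplotype that segregates
Mendelianly; flanking-sequence mechanics are out of scope.

**Phenotype.** Causal loci are fully penetrant recessives: the label is
asserted iff both haplotypes carry the causal allele. No environmental
variance.

**Reads.** Per site, depth ~ Poisson(mean 15 — matching typical
re-sequencing depths of the setting modelled, where single plants and
20-plant pools were sequenced at ≈ 11–18×), alt reads ~ Binomial(depth, p′)
with p = dosage/2 and p′ = p(1−e) + (1−p)e for base error e = 0.005. Pools
are modelled at the dosage level (mean dosage of members), which is
equivalent to read-level mixing under binomial sampling. Genotypes are
called by count thresholds (missing below depth 4; homozygous beyond an
80% allele fraction; boundary fractions count as homozygous) — a
re-specification of what a variant caller's defaults do, made explicit and
configurable because caller defaults are not a reproducible contract.

**Pedigree preset.** The built-in study-mimicking pedigree conditions some
sibling draws on phenotype (e.g. a dwarf T1 plant must exist). This models
the selection that defines such a study: the line is analysed *because* its
offspring showed the traits. Unconditioned draws would make the roster's
phenotype composition a coin flip.

## Introgression detection (`introgression`)

Density windows: width 2 Mb stepped every 5 kb at full scale, with density
always expressed per 2 Mb (truncated trailing windows are rescaled). At
desk scale the presets use a 100-kb window — the same ~4–5% of a chromosome
that 2 Mb is of a real rice chromosome. A window is *high* iff its density
is ≥ 50 per 2 Mb and ≥ 10× the strongest control window (controls floored
at 1 per 2 Mb); these two thresholds are explicit stand-ins for a visual
genome-browser judgement and are logged with every run. Runs of high
windows separated by less than one window width merge.

Borders are then made exact: the region is trimmed/extended to 10 kb beyond
the outermost *sample-specific* SNP (non-reference in the sample, reference
or missing in every control; missing control calls are non-informative).
Regions with fewer than 10 sample-specific SNPs are dropped with a log
notice. Zygosity is the het fraction among the region's non-reference
calls (≥ 0.8 heterozygous, ≤ 0.2 homozygous, else mixed); mixed regions are
recursively split at the change point flanked by the longest het and hom
runs, provided both halves retain 10 sites, then each half is re-refined —
so adjacent fixed and segregating segments are reported separately, at the
cost of slightly overlapping borders where the pad spans the cut.

A deliberate fidelity choice: no HMM or IBD-likelihood segmentation. The
procedure implemented is the explicit windowed rule set, because the claim
being reproduced is about that procedure's output.

## Lineage dynamics (`lineage`)

Under neutral selfing, material heterozygous at the F1 remains heterozygous
with probability (½)^g after g generations; the remainder fixes equally to
both homozygous states. Generation inference inverts this:
ĝ = round(log½ f̂), where f̂ is the observed heterozygous fraction of the
*initially introgressed* (F1-heterozygous) material — in practice the het
fraction among donor-diagnostic markers. Two cautions, both verified in
simulation:

- Whole-genome donor *dosage* is a martingale under selfing (expectation
  stays ½ forever), so donor fraction carries no generation signal; only
  heterozygosity decays.
- A single plant's het fraction has few effective degrees of freedom (one
  per ancestry block, roughly 12 × (1 + gλ) blocks), so reliable rounding
  at g = 4 needs a small family of plants; the estimator is therefore fed
  the family mean. The package reports both the raw introgressed fraction
  and ĝ and does not treat any particular observed fraction as a target.

Region trajectories across generations are matched by reciprocal overlap
≥ 0.5 — simple, deterministic, and adequate for segments whose borders move
by at most the border pad between generations.

## Bulk-segregant SNP index (`bsa`)

Index = alt reads / total reads per marker, undefined below pooled depth 5.
Smoothing: arithmetic mean of 20 consecutive *defined* markers, stepping
one marker, per chromosome; chromosomes with fewer than 20 defined markers
yield nothing (logged). The window anchor is the midpoint of the window's
first and last marker positions; this choice is recorded in the output
metadata. Peaks: ≥ 5 consecutive windows with mutant pool ≥ 0.9 and
wild-type pool ≤ 0.7, converted to the interval between the first and last
window anchor; the two thresholds are explicit stand-ins for a visual call
of an extreme-contrast region.

Expected values at a fully penetrant recessive causal locus: mutant pool
exactly 1 at error 0; wild-type pool ⅓ (1 AA : 2 Aa among phenotypic wild
types) — at realistic pool depths the *observed* wild-type value scatters
around ⅓ by roughly ±0.1, so single-experiment readings near 0.4 are
unsurprising and the package asserts only the expectation.

One desk-scale artefact needs naming: with ~5,000 markers on a 30-Mb
genome, 20 consecutive markers span ~120 kb, while at a real
indica/japonica marker density (~1 SNP per 150 bp) they span ~3 kb. A
20-SNP window around a causal site is effectively recombination-free at
real density but not at sparse desk density. The simulator therefore
supports a dense marker cluster around the causal locus (default 100-bp
spacing) reproducing the real local density; the exactness property of the
causal window (smoothed index exactly 1 in an error-free homozygous pool)
is tested under that realistic local density.

## Candidates (`candidates`)

The co-segregation rule is the exact deterministic predicate, not an
association statistic: keep SNPs homozygous-alternate in all affected and
not homozygous-alternate in any unaffected sample, tolerating a configured
number of missing calls (default 0). Tight linkage means the causal site
typically brings ~1 hitchhiking marker per run at desk scale; ranking by
effect severity is what separates them when gene models are supplied.

Effect classification translates the reference and alternate codon
(standard code, strand-aware) for SNVs in the CDS; variants within 2
intronic bp of an exon boundary are splice_site (the canonical GT/AG
positions); length-changing CDS variants with |Δlen| mod 3 ≠ 0 are
frameshift; in-frame length changes are reported as nonsynonymous;
everything else is noncoding. UTR and regulatory classes are out of scope.

## Phylogeny (`phylo`)

Distance between two samples = mean over shared genotyped SNP sites of
|dosage difference|/2, pairwise deletion, with a minimum of 100 shared
sites per pair (errors otherwise). Neighbor joining is the standard
Q-criterion agglomeration with deterministic tie-breaking; negative branch
lengths are clamped to zero with the deficit logged; the final three nodes
are resolved by the three-point formulas into a trifurcating root.
Placement midpoint-roots the tree and assigns a focal leaf to the group
holding the majority of reference leaves in its smallest enclosing clade
that contains any.

The donor/recipient flip between region-restricted and whole-genome trees
holds for carriers with a minority donor genome — exactly the kind of line
the analysis targets. Because the expected donor fraction of an
unconditioned outcross descendant is ½ (see above), the flip test
conditions its simulated offspring on ≤ 35% donor genome.

## Numerical and testing notes

- All randomness flows through `numpy.random.Generator` seeded from a
  single integer; identical configuration + seed reproduce byte-identical
  VCF output.
- Internal coordinates are 1-based closed everywhere; BED conversion
  happens only at the file boundary. Indels are parsed but excluded from
  SNP-density and SNP-index statistics.
- Genotype-caller boundary fractions (exactly 0.8 / 0.2) count as
  homozygous, enforced with a 10⁻⁹ tolerance against float division noise.
- Simulation-based tests use desk-scale problem sizes chosen once: 1,000
  F2 plants and ~5,000 markers for the bulk-segregant checks, 100 seeds for
  detector recovery and false-positive screens, 40–50 seeds per condition
  for generation inference and the phylogeny flip.

## What passing tests do and do not show

The simulator produces clean biallelic SNPs with independent Poisson depth
and symmetric base error. It does not model alignment artefacts, indel
realignment noise, reference bias, segmental duplications, selection during
tissue culture, epigenetic somaclonal variation, or phenotyping error. The
tests therefore demonstrate that the *procedures* are implemented exactly
and behave correctly under their stated statistical assumptions — not that
those thresholds are optimal for any particular real data set. The
detector's fold/floor thresholds and the BSA peak thresholds, in
particular, are stand-ins for judgements made visually in the original
setting and should be tuned against controls in real applications.
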