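# Methods

## The comparative design

The pipeline detects early neo-Y degeneration without assembling the neo-Y.
Male and female short reads are mapped separately to a female-derived
reference.  Because the neo-Y never passes through females, every fixed
neo-X/neo-Y difference is present in the male read pool at an expected
allele ratio of 1:1 (one neo-X and one neo-Y complement per male), while
female reads carry only neo-X polymorphism.  Three signals follow:

1. **Excess male coding SNPs.**  Per-chromosome exonic/intronic SNP
   densities and their male/female ratio; on the neo element the male
   density folds in neo-X/neo-Y divergence.
2. **Pseudogenes.**  A neo-X allele (reference + near-fixed female
   alleles) and a neo-Y allele (neo-X + male-only alleles at
   heterozygous-like ratio) are rebuilt per gene and scanned for premature
   stops, frameshifts and start loss.  Genes already broken in the
   female-derived allele are ancestral pseudogenes and are removed — on
   every chromosome, so autosomal counts are comparable.  Enrichment of
   the surviving set on the neo element is a two-sided Fisher exact test
   with no multiple-testing correction.
3. **Tandem duplications.**  Mate pairs mapping reverse-forward instead of
   forward-reverse mark tandem-duplication breakpoints; pairs whose span
   deviates from the library insert by more than `sd_multiplier` (3)
   standard deviations mark long insertions/deletions.  Same-class
   anomalies within one cluster window are merged; calls need
   `min_support` (3) pairs.

B-chromosome candidates come from assembly subtraction: a male scaffold
with less than `cov_threshold` (20%) of its length alignable to the female
assembly is a candidate; candidates whose annotated proteins match known
sequences are removed; a B-derived probe ranks the rest by local alignment
score; per-sex fractions of reads aligning to subcentromeric sequence give
read-level corroboration.

## Synthetic study material

`simdata` generates the conditions this design assumes.

* **Reference**: random sequence at GC 0.42 with non-overlapping
  single-exon ORFs (ATG + stop-free codons + one stop) on random strands.
  Multi-exon structure is omitted: every downstream statistic operates on
  coding sequence, not splice structure.  Genes carry a `gene_flank`
  (300 bp) non-coding genic margin so the "intronic" partition is
  non-empty, and a random expression label used for the codon-bias
  reference set.
* **Female sample**: two reference-like haplotypes with residual
  heterozygosity `female_het_rate` (5×10⁻⁴/bp; the real inbreeding
  residual is unknown and the parameter is free).
* **Male sample**: `male_haplotype_pairs` (4) neo-X-side haplotypes plus as
  many **clonal** neo-Y-side haplotypes.  A two-haplotype male would put
  every male polymorphism at a 0.5 read ratio, indistinguishable from
  fixed differences; a male *pool* (as sequenced in this kind of study)
  shows segregating sites at many frequencies.  Polymorphic sites
  (`male_het_rate`, 3×10⁻³/bp, an outbred-pool level above the inbred
  female's) are placed on 1–3 haplotypes, i.e. pool frequencies ≤ 3/8.
* **Neo-Y lesions** (clonal, so at exactly 1:1 in the male pool):
  divergence SNPs at `snp_rate` (2×10⁻³/bp, a sensible magnitude for a
  very young neo-Y given the published male neo densities), 1–6 bp indels
  at `indel_rate` (2×10⁻⁴/bp), `tandem_dup_count` (10) duplications of
  500–2000 bp, and disruptions in `pseudogene_fraction` (0.2) of neo
  genes — a premature stop (a **single** nonsense substitution: one base
  turning an internal codon into a stop, as such mutations arise; a full
  codon rewrite would need up to 3 adjacent mismatches and make the mutant
  reads unmappable under the 2-mismatch contract, for this pipeline as for
  the original one) or a frameshift (one indel of length 1, 2, 4 or 5).
  `ancestral_disruption_count` (5) additional stops go into **all**
  haplotypes, making them homozygous differences from the reference that
  the female data reveals — the ancestral-pseudogene control.
* **B fragment**: subcentromeric chrX slice + B-private core + neo-end
  slice (2 kb + 20 kb + 2 kb) with a few diagnostic SNPs.  The private
  core reflects the finding that B chromosomes acquire unique sequence;
  without it a pure two-slice mosaic is >95% alignable to the female
  assembly and no 20% subtraction rule could ever recover it.  It is also
  where the probe is drawn from (260 bp at 5% divergence).
* **Reads**: uniform fragment starts per haplotype, insert ~
  Normal(500, 50) truncated at twice the 100 bp read length, inward-facing
  mates, uniform substitution errors at 0.2%/base, constant Q30 qualities
  (the caller uses counts, not qualities), origin-encoding read names.
  Pair counts follow round(C·G/2L) with largest-remainder allocation
  across haplotypes, so sample coverage is depth over the reference.

Planted events are recorded in a truth table (0-based reference
coordinates) with expected male-pool allele frequencies.

What the generator does **not** model: transposable elements and repeats,
recombination/coalescent structure, indel/quality error profiles,
GC-coverage bias, chromatin-driven coverage variation, male X hemizygosity
(the male carries two copies of every chromosome except the extra B).
Passing tests therefore demonstrate the correctness of the decision rules
and the recoverability of the planted signal classes under clean mapping
conditions, not performance on repeat-rich real libraries.

## Mapper

Seed-and-extend with k = 13 seeds at three disjoint read offsets, so any
placement of a ≥39 bp read with ≤2 mismatches retains one exact seed
(pigeonhole).  Orientation and span are recorded but never used to reject
a pair — anomalous geometry is exactly the SV evidence — hence the best
co-placement factorises into each mate's best placement.  Ties in best
mismatch count make a mate ambiguous and the pair is excluded from all
downstream evidence (multi-mapper policy; determinism demands it).  Reads
failing ungapped placement are realigned single-end with exactly one
1–6 bp gap, scored exhaustively over gap length and position from seeds
anchored at both read ends; the winning gap is left-aligned (VCF
convention).

## Caller

A count-threshold caller replaces a Bayesian genotyper: a site is called
in a sex when depth ≥ `min_depth` (8), alt reads ≥ `min_alt_reads` (3) and
alt fraction ≥ `f_min` (0.2).  Qualities are synthetic constants upstream,
and what the comparison needs — high recall of 1:1 divergence at 30–40x
and a negligible error floor (three independent same-base errors at one
site) — is a property of counts.  Partitions: `male_only` (called in
males, female alt below threshold), `female_segregating`, `shared`.
Short indels are kept iff supported by ≥1 read on each strand and 1–6 bp
long.  Densities divide by **callable** bp (depth ≥ min_depth in that sex,
per region class) rather than chromosome length, removing coverage
confounding; the "around 1:1" allele-ratio band is [0.4, 0.6]
(configurable; at 40x pool depth the binomial spread of a true 1:1 site
is ±0.08, so discrimination tests run the male pool deeper).
Ratios print at 2 decimals, switching to integers at ≥10, matching the
source table's style.

## Allele reconstruction and Ka/Ks

Female alleles are applied to the reference CDS only when near-fixed
(female alt fraction ≥ 0.75): residual heterozygous sites are population
variation, not the neo-X consensus.  Male-only alleles are applied on top
only when the male alt ratio lies in [0.25, 0.75] (heterozygous-like,
i.e. candidate fixed difference; the band is configurable).  Minus-strand
genes are reverse-complemented after editing.  Overlapping indels make a
gene unresolvable and it is excluded, with a log record.

Ka/Ks uses Nei–Gojobori (1986) pathway counting with the Jukes–Cantor
correction: per codon, site counts average the two alleles' synonymous
fractions (mutations to stops count as nonsynonymous); differences average
over minimal substitution paths, discarding paths through stops.  The
closed-form method was chosen over a maximum-likelihood counterpart
because every number it produces can be re-derived by hand enumeration in
the tests; on synthetic data the distinction is immaterial.  Frameshifted
or length-mismatched pairs and alleles containing N are excluded.

Codon-usage indices: ENC by Wright's formula (family homozygosity
F̂ = (nΣp² − 1)/(n − 1) averaged per degeneracy class, a missing 3-fold
class borrowing the 2-/4-fold mean, clamped to [20, 61]); CAI from
relative-adaptiveness weights of a reference set = the top 10% of genes by
the simulator's expression label; FOP = optimal/total codons in degenerate
families; CBI per Bennetzen–Hall with the uniform-usage expectation.

## Scaffolding and subtraction

Scaffold merging consumes tabular protein hits from any aligner (the
merging logic, not the alignment, is the method): per protein, overlapping
hits resolve greedily by score (ties by scaffold id) so that a region
freed by a dropped hit can still be represented; scaffolds hitting
successive parts of one protein concatenate in protein order with
orientations harmonised; scaffolds anchored (>50% of the query) to
conserved-adjacent proteins join with exactly 500 Ns.  All ambiguity
(a scaffold demanded twice, anchors to non-adjacent slots) conservatively
leaves scaffolds unmerged with a logged reason.  N50 is the largest length
L such that scaffolds ≥ L hold half the assembly.

Assembly subtraction measures alignable length by shared-k-mer coverage
with k = 21: on megabase assemblies, a random 13-mer collides with the
female k-mer set a few percent of the time, inflating coverage of genuinely
novel sequence by ~50%; at k = 21 spurious sharing is negligible while 1%
diverged homologous sequence still covers (0.99²¹ ≈ 0.81 of positions seed
an intact k-mer and each hit covers 21 bp).  The published E-value/span
criteria belong to a specific aligner; the decision rule that matters —
<20% alignable length — is preserved.  The probe ranking uses Biopython's
local alignment (match +1, mismatch −1, gap −2) after a shared-13-mer
prefilter, so unrelated probes yield an empty ranking.

## Orchestration, sizes and determinism

`run_all` executes simulate → map → call → scan → reconstruct → scaffold →
subtract → report, writing each stage's artifacts before the next starts.
Everything derives from one config seed; two runs of one config are
byte-identical.  Density windows scale with the genome (window = genome/10,
step = window/10) so the 2 Mb demo produces meaningful Fig-2-style tracks.
The default problem size — 2 Mb genome, 120 genes, 30x/40x, ~700k read
pairs per seed — was chosen so a full run evaluates in about a minute on
one CPU while every per-chromosome statistic still rests on hundreds to
thousands of events; the test-suite fixtures use a 500 kb genome for the
same reason.

## Known limitations

* Dispersed-duplication calling (clustered interlocus pairs anchoring a
  common locus) is a declared approximation; the original detection
  procedure is undescribed.  Same-strand (FF/RR) pairs are tallied as
  "other", not emitted as inversion calls.
* Male polymorphism at intermediate pool frequency is occasionally
  misattributed as a fixed difference (it enters the neo-Y allele and can
  create accidental "pseudogenes" on autosomes).  This is inherent to the
  published design, not an implementation artifact, and is why the
  ancestral filter is applied on every chromosome.
* The mapper is blind to placements needing >2 mismatches or more than one
  gap, so divergence hotspots lose coverage — faithful to the original
  contract, but a real caveat near clustered edits.
* Absolute mate-pair violation rates depend strongly on assembly quality;
  on the clean simulated reference they are far below the published ones,
  and only the male/female direction is meaningful.
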