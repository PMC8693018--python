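# Methods

`sexlinkscan` implements a read-depth-first strategy for locating a
paternally inherited, hemizygous (Y-linked) genomic region in a species
with male-heterogametic (XY) sex determination, together with the two
companion analyses that such a discovery calls for: a diagnosis of why
conventional SNV association scans mislocate the region when recently
duplicated sequence is left unmasked, and two validation assays (in-silico
PCR sex genotyping and a gonad expression test). Everything runs
end-to-end on synthetic data produced by the package's own generator.

## The copy-number model

A locus present on both chromosome sets of a diploid individual is
sequenced at the depth typical of its scaffold; a hemizygous locus at half
of it; an absent locus at zero. Dividing per-site depth by the per-scaffold
median depth therefore yields a relative copy number on the diploid scale
(diploid = 1), and a male-limited insertion shows the joint signature

    relative depth ~ 0.5 in every male,  ~ 0 in every female,

while unlinked regions sit at ~1 in everyone. The normalization median is
computed per scaffold, not genome-wide, which makes it robust to
scaffold-specific mappability but also means a hemizygous region that
occupies a large fraction of its scaffold depresses its own scaffold's
median: with the default geometry (60,750 bp of a 250,000 bp scaffold,
~24%), the male median falls from 30 to ~28 and the plateau reads ~0.54
rather than 0.50. This bias is inherent to the normalization (real
assemblies have it too) and is well inside the 0.15 grid tolerance; it
grows past that tolerance only when the region exceeds roughly a third of
its scaffold, which is why the bundled demo keeps the proportion near 25%.
Zero-depth sites are included in both the median and the mean — excluding
them would bias absent regions upward.

## Windowed CNV association scan

Depth is scanned in non-overlapping 500 bp windows. Each window's mean
depth over the scaffold median is snapped to the nearest point of the grid
{0, 0.5, 1, 1.5, 2} when within τ = 0.15, else marked unresolved.
Consecutive windows whose across-sample copy-number vectors are identical
are merged into regions; up to `max_gap` (default 2) interleaved unresolved
windows are tolerated inside a run, and runs of fewer than 3 resolved
windows are dropped. Merged regions are then tested two ways:

* **Mann–Whitney U** on the per-sample regional copy numbers between the
  sexes, two-sided.  Because the data are massively tied (values live on
  the half-integer grid), the test uses the *exact* permutation
  distribution of U with ties, computed by dynamic programming over
  midrank half-units; the DP is O(n₁ · n₁n₂ · distinct values) and is used
  for panels up to 40 samples (beyond that, the normal approximation with
  tie and continuity correction).  For the default 15-male/16-female panel
  the most extreme attainable two-sided p is 2/C(31,15) ≈ 6.65×10⁻⁹.
* **Quasigenotype contingency GWA**: regions whose copy numbers all lie in
  {0, 0.5, 1} are recoded 0→0/0, 0.5→0/1, 1→1/1 and tested with a Pearson
  chi-square on the 2×k sex-by-genotype table (all-zero genotype columns
  dropped, so a perfectly associated table collapses to 2×2 with
  chi-square = n).

Both scans are Bonferroni-corrected at α = 0.05 over the number of regions
each one tests. A region counts as *detected* when significant in both.
For plotting exports only, p-values are floored at 10⁻¹⁵ and the
Mann–Whitney track is signed (positive = copy number larger in males);
raw p-values are preserved in the result tables.

## SNV scan, cross-mapping, and masking

The SNV branch exists to demonstrate a failure mode: reads from a
male-specific cassette that is missing from the mapping reference land on
its closest paralog (92% identity by default), where their divergent
positions are called as male-only heterozygous SNVs with perfect sex
association. Site filters follow standard practice: biallelic sites only,
genotypes at depth < 20 set missing, sites with > 50% missing dropped,
minor allele frequency (allele-counted over called genotypes) required to
exceed 0.05, Bonferroni over the sites actually tested.

The remedy is duplication masking. Duplicated region pairs are detected by
seeded self-comparison of the assembly in which both copies are present:
shared k-mers (k = 15 by default; the trivial self-diagonal excluded) are
chained along co-diagonals and extended ungapped, keeping the
maximal-scoring segment through the seed with match +1 and mismatch
−min_ident/(1−min_ident), so any reported segment has identity ≥
min_ident (default 0.9; 0.85 in the pipeline to cover the 92% simulated
pair with margin). The detected duplicated *sequences* are then located in
the mapping reference by the same seed-and-extend machinery and every
matching interval hard-masked with N. Sequence-based carrying matters:
coordinates do not transfer between assemblies that differ by an
insertion. The in-repo mapper treats N as a universal mismatch, so masked
intervals attract no reads at all; reads anchored in unmasked flank may
still overlap a mask edge by at most `max_mismatch` bases.

## The mapper

A deliberately minimal, deterministic, ungapped mapper keeps the pipeline
self-contained. Candidate loci come from exact k-mer seeds (k = 15, eight
evenly spaced seed offsets per strand — at 92% identity the chance that no
seed survives is ≪ 1%), each candidate is scored by full-length mismatch
count, and the fewest-mismatch locus wins; ties are broken by scaffold
name, then leftmost coordinate, then strand, and flagged ambiguous.
Ambiguous reads are still assigned and counted — precisely the behaviour
that creates the cross-mapping artifact; the flag records the truth.
Unmapped means no locus within `max_mismatch` (default 12 on 100 bp reads:
mean 8, sd ≈ 2.7 for reads from a 92% paralog).

After placement the mapper computes an ungapped soft-clip: the
maximal-scoring subsegment of the read against its placement (match +1,
mismatch −2). Locus choice and the mismatch cutoff use the full read, but
the pileup counts only clipped bases. This emulates what gapped aligners
do to reads that run past a structural-variant breakpoint into unrelated
sequence: their mismatch-dense tails otherwise deposit spurious alleles
just outside the insertion junction. Uniformly diverged reads (mismatches
spread ~12 bp apart) lose at most a base or two at the ends, so the
paralog artifact is unaffected.

Pileup genotyping is intentionally simple: per site, candidate SNVs are
sites with exactly two pooled alleles; per sample, alt-allele fraction
f < 0.2 → 0/0, 0.2 ≤ f ≤ 0.8 → 0/1, f > 0.8 → 1/1, depth < 20 → missing.

## Cross-mapping audit

Each read mapped inside a focal region is re-scored (full-length ungapped
mismatch count, dense seeding) against a set of candidate origin loci that
includes the focal sequence itself. A read is *cross-mapped* when a
foreign locus scores strictly better, *ambiguous* on a tie, *concordant*
otherwise. The summary fraction counts cross-mapped reads plus ambiguous
reads whose tie involves a foreign locus. Classification is explicitly
relative to the candidate set — removing the foreign locus makes every
read concordant or ambiguous, and the tests assert this. The simulator
writes each read's true origin into its name (sample:haplotype:scaffold:
position:index); truth is used only by tests, never by the classifier.

## In-silico PCR and the expression test

Amplicon prediction finds every (forward site, reverse-complement site)
pair within the size cap (default 2,000 bp, exact primer matching by
default); product size runs from the forward primer's 5′ end to the
reverse primer's 5′ end inclusive. The sex call mirrors the classic
three-primer-set pattern: male iff both male-specific sets amplify and the
common set shows two product size classes; female iff neither
male-specific set amplifies and the common set shows a single class;
anything else is inconclusive.

Expression: FPKM[g,s] = counts × 10⁹ / (gene length × library size); a
gene is *expressed* in a sample iff FPKM > 0 — an intentionally
detection-based rule, since the biological claim is presence/absence, not
level. The testis/ovary expressed pattern is tested with a two-sided
Fisher's exact test (probability-mass summation convention); for the
10-vs-10 design with perfect separation, p = 2/C(20,10) ≈ 1.08×10⁻⁵.

## The synthetic-data generator

The generator emulates the study design, not sequencing physics:

* **Genomes.** Random scaffolds; a female (reference-like) genome carrying
  one autosomal paralog cassette; a male genome equal to the female plus a
  single hemizygous insertion (default 60,750 bp at offset 18,000 of a
  250,000 bp scaffold) whose cassette diverges from the paralog by i.i.d.
  substitutions at rate 1 − identity (default identity 0.92) plus a
  centred 7 bp deletion. The deletion is a deliberate addition: it gives
  the "common" primer pair two product sizes (male) versus one (female),
  the pattern the PCR assay reads out; substitution-only divergence cannot
  produce it.
* **Depth.** Site depth ~ Poisson(coverage × CN/2), CN = 2 everywhere
  except the male-specific region (1 in males, 0 in females). Default
  coverage 30 (a typical resequencing depth; the panel's true depth is a
  free parameter here). No GC bias, no mappability structure.
* **Reads.** Single-end, uniform over the sample's two genome copies
  (males: one female-like plus one insertion-bearing haplotype), per-base
  substitution errors at 0.001, constant qualities, origin recorded in the
  read name. Pairing is omitted because depth/CNV logic gains nothing
  from it.
* **Expression.** Negative-binomial counts (var = m + φm²); the
  male-specific gene is drawn positive in every testis sample and set to 0
  in every ovary sample; its autosomal paralog is low but mostly non-zero
  in both sexes; a high-expression control and 20 background genes fill
  out the matrix.
* Samples carry no individual genetic variation beyond the sex difference
  (an explicit non-goal), so the SNV scans' background site counts are far
  below genome-scale reality; consequences are discussed under
  limitations.

All generators fan the configured seed into independent named streams
(genome / depth / reads / expression, then per sample), so each stage is
reproducible standalone and outputs are byte-identical across reruns.

## Problem sizes

The depth-based analyses (relative depth, CNV scan, acceptance script) run
at the full desk scale: 2 scaffolds totalling ~1 Mb, 15 males + 16
females, coverage 30 — a few seconds of numpy. The read-mapping branch
(SNV scans, masking contrast, audit) runs on geometrically similar genomes
of 10–25 kb with the full 31-sample panel; the cross-mapping mechanism
depends on identity, read length and coverage, not genome size, and these
sizes keep the pure-Python mapper's suite runtime in minutes. The
20-seed masking-contrast property uses an 11 kb genome per replicate.

## What passing tests do and do not show

The simulation captures: the half-molarity depth signature and its
recovery by windowed scanning; cross-mapping between ~92%-identical
paralogs and its elimination by masking; breakpoint-overhang alignment
artifacts (handled by soft-clipping); the amplification-pattern logic of
the PCR assay; and presence/absence expression testing. It does not
capture: real population polymorphism (so Bonferroni denominators in the
SNV scans are unrealistically small and type-I behaviour on real data is
untested here), indels and repeat families beyond a single paralog pair,
GC/mappability bias, gapped alignment, or base-quality error structure.
A clean masked scan here therefore demonstrates the masking mechanism, not
that masking suffices on a real genome.

## Numerical and degenerate-case choices

* Exact MWU counts are held in float64; they are exact up to C(40, 20) <
  2⁵³.  Two-sided p = min(1, 2·min(P(U≤u), P(U≥u))).
* All samples identical in a region → p = 1 (no test).
* Contingency tables with one retained genotype column → monomorphic,
  p = 1; missing genotypes excluded pairwise.
* Fisher's test with a zero margin → p = 1.
* Scaffolds with zero median depth are skipped by the window scan (no
  normalization exists); a zero-median scaffold inside `relative_depth`
  raises instead, since the caller asked for a specific region.
* Window merging drops trailing partial windows; regions shorter than
  3 windows are discarded as unsupportable.
* Duplication-call extension is capped at 50 kb per side per seed chain;
  longer duplications are recovered piecewise from their other seeds.
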