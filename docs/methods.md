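# Methods

## Data model

Two marker classes are represented as dense loci × individuals int8
matrices: co-dominant SNP calls (hom-ref 0 / het 1 / hom-alt 2 /
missing −1) and dominant presence/absence calls (absent 0 / present 1 /
missing −1). Each individual carries a phenotypic sex (M/F/U); each
locus may carry a tag sequence (typically 69 bp, the DArTseq fragment).
Individuals of unknown sex are kept in the matrices but excluded from
every sex-conditional statistic, so all denominators below count only
known-sex individuals. Alignment coordinates are 1-based inclusive with
strand inferred from subject coordinate order, matching BLAST tabular
(`-outfmt 6`) conventions.

## Discovery

**Call-ratio filter.** A locus's call ratio is the fraction of
known-sex individuals with a non-missing call. Loci *below* the
threshold (default 0.8) are removed; the boundary passes. Filtering
precedes classification and preserves locus order.

**Concordance.** Under a hypothesized system, conforming individuals
are heterozygotes of the heterogametic sex plus homozygotes (either
class) of the homogametic sex for SNPs, or present-in-the-limited-sex
plus absent-in-the-other for PA loci. Concordance is conforming /
called, pooled over both sexes rather than computed per sex — the
pooled count is the natural quantity when sib-ship sizes are uneven and
keeps the statistic a single fraction. Because each called SNP
individual conforms to exactly one system, C_XY + C_ZW = 1; an exact
XY/ZW tie is therefore only reachable at C = 0.5 and such loci are
dropped as ambiguous.

A locus is classified when max(C_XY, C_ZW) ≥ the concordance threshold
(default 0.8, boundary inclusive) and each sex has at least
`min_called_per_sex` (default 3) called individuals — below 3 per sex
an 80% concordance is nearly unconstrained. Categories are
male-heterozygous SNP, female-heterozygous SNP, male-present PA and
female-present PA; they are mutually exclusive per locus.

**Sex-limited allele and false-positive screen.** For a SNP candidate,
the sex-limited allele b is the heterozygote allele *not* matching the
majority homozygote class of the homogametic sex (a tie between
homozygote classes leaves b undefined and flags the locus). The
false-positive statistic is the fraction of called known-sex
individuals (both sexes pooled) homozygous b/b; under true linkage b is
hemizygous on the Y (or W) and never homozygous, so a fraction above
`fp_threshold` (default 0.05) flags the locus. PA candidates are exempt
— homozygosity is undefined for a dominant marker. Flagged loci remain
in the candidate set; the bookkeeping summary reports, per category,
initial = members, false-positive = flagged, true = initial −
false-positive, plus the four-category total.

The concordance and false-positive formulas are explicit, configurable
definitions of the field's usual filtering expectations rather than a
transcription of any one prior script.

## Assignment

The built-in mapper indexes every `seed_k`-mer (default 21) of the
reference, extends each seed match without gaps over the full tag
(clipped at chromosome ends), and reports hits with identity ≥ 0.90
over ≥ 50 aligned bp, on both strands, at every qualifying position, in
deterministic (query, chromosome, start, strand) order. It is a
desk-scale stand-in for a gapped aligner with a deliberate escape
hatch: `read_alignment_tab` ingests standard 12-column BLAST tabular
output so BLASTn hits can be substituted unchanged. Like any
seed-and-extend aligner, a hit requires at least one exact `seed_k`-run
of matches; the brute-force oracle in the test suite encodes the same
rule.

A marker is uniquely assigned when all its hits fall on one chromosome
(several positions on that chromosome still count — the criterion names
the chromosome, not the position). The modal chromosome is the one with
the most uniquely assigned markers, ties broken toward the smaller
chromosome id (numeric-aware) and flagged; its percentage is computed
with exact decimal arithmetic and rounded half-up to one decimal, the
convention of the published count pairs (78/96 → 81.3, 57/64 → 89.1,
7/8 → 87.5, 3/5 → 60.0, 5/6 → 83.3). The call is translated to the
species karyotype via a correspondence map (default 9→7, 4→3, 13→13;
identity with a log note for unmapped chromosomes) and is confident
when the modal fraction ≥ 0.5 and the modal count ≥ 3.

## Synthetic data

The generator produces the marker-level signal the filters target, not
reads. Defaults describe one sib-ship-sized sample: 10 males and 10
females, XY, 13 chromosomes of 10 kb, 50 sex-linked and 2000 autosomal
SNPs, 10 sex-linked and 200 autosomal PA loci, minor-allele frequencies
uniform on (0.05, 0.5], 2% call error, 10% missingness, 10% of
sex-linked loci recombining, no sex reversal, 69 bp tags. Chromosomes
of 10 kb keep the mapper exhaustive at desk scale while leaving tag
placement effectively collision-free. PA counts are set an order of
magnitude below SNP counts, the usual proportion in DArT sexing
datasets.

Non-recombining sex-linked SNPs are fixed differences: homogametic a/a,
heterogametic a/b. Each carries a Y-haplotype label (b1/b2, equal
probability) that is invisible in the genotype calls; it exists so that
Y-haplotype sharing between populations is a measurable quantity.
Recombination is modeled as a per-locus "behaves autosomally"
indicator (count = round(r·n), membership random) rather than
genetic-map crossovers — it is exactly the disturbance the 80%
threshold is meant to absorb. Sex reversal flips phenotypic sex with
probability s per individual while genotypes follow genotypic sex.
Noise is applied last: each call is replaced by a uniformly chosen
different non-missing state with probability e, then set missing with
probability m. Every locus's tag is copied verbatim from its true
chromosome at a uniform position of a freshly simulated i.i.d.-uniform
reference.

The introgression scenario simulates donor, recipient and control on
one shared reference (one species complex): the recipient's Y-haplotype
labels are copied from the donor locus-for-locus, everything else is
drawn independently. The shared-Y-allele fraction between two datasets
is the fraction of positionally matched sex-linked SNP loci with equal
labels: 1.0 for the introgressed pair, Binomial(n, 0.5)/n for
independent Y chromosomes. On real data the analogous comparison would
use inferred sex-limited alleles; the function accepts externally
supplied label sequences for that purpose.

What the generator does **not** model: sib-ship pedigree structure
(individuals are independent draws, so Mendelian linkage between loci
is absent), polymorphic X haplotypes, locus dropout correlated with
genotype (allelic dropout), and read-level error processes. Passing
tests therefore demonstrate correctness of the filtering and assignment
logic under the stated noise model, not robustness to every artefact of
real DArT data.

## Verification design

Concordance statistics and the mapper are checked against brute-force
oracles (exhaustive per-individual counting on matrices up to 8 × 6;
exhaustive diagonal/strand scan on references up to a few kb). The
seeded recovery experiment uses 50 replicates of the default scenario
and requires the correct sex chromosome and ≥ 80% of non-recombining
sex-linked loci *classified into the candidate set* per replicate;
candidate-set membership measures the concordance screen's sensitivity,
while the null experiment (no simulated sex-linked loci, 10 replicates)
measures the pipeline's final output — markers surviving the
false-positive screen — and requires < 1% of autosomal loci reported.
The two metrics deliberately bracket the screen: it trades a little
sensitivity (each flag removes a candidate) for specificity, just as
the initial/false-positive/true bookkeeping separates those roles.
Replicate counts and problem sizes (2260 loci × 20 individuals per
replicate) keep the full suite in the tens of seconds.

## Limitations

* The mapper is ungapped; tags spanning indels against a diverged
  reference need an external aligner (supported via tabular import).
* The sex-limited allele is inferred from the majority homozygote class
  of the homogametic sex, which fails (and conservatively flags) loci
  where that sex is itself polymorphic with balanced homozygote classes.
* Confidence in the sex-chromosome call is a count/fraction rule, not a
  probability; with very few markers (< 3 assigned) no confident call
  is made.
* The simulator's independence assumptions understate linkage
  disequilibrium within sib-ships; real sib-ship data will show more
  correlated miscalls than the binomial noise model predicts.
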