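# Methods

## Scope and model

`tgintegrity` analyzes resequenced transgenic lines relative to their
progenitor reference on two axes: (i) the T-DNA integration event —
location, junction deletion, copy number, insert structure, and the gene
context of the site — and (ii) the genome-wide load of small variants
(SNP/MNP/INS/DEL/complex) established by a two-caller consensus. The
package does not align reads or call variants from pileups; it consumes
alignments (SAM/BAM) and two VCF callsets, and ships a generator that
emulates both so every stage is testable offline.

Internal coordinates are 0-based half-open throughout; emitted files follow
their format conventions (VCF/GFF3/SAM 1-based, BED 0-based). `SmallVariant.pos`
is VCF-style 1-based with indels anchored on the preceding base.

## Integration-site detection

Evidence comes from two sources over the combined reference (genome contigs
plus the vector as one extra contig):

* **Discordant pairs** — a genomic read whose mate maps to the vector. A
  forward-strand anchor points at a junction to its right ("left" evidence,
  junction candidate = anchor end); a reverse-strand anchor points left
  ("right" evidence, candidate = anchor start).
* **Split reads** — a genomic read soft-clipped by ≥ `min_clip` (default
  12) bases whose clipped tail exactly matches a 40-base T-DNA border
  window. Split positions are exact junction coordinates. Matching is
  exact-prefix/suffix only, no local alignment: at toy scale this is
  deterministic and sufficient; reads from inverted inserts (not simulated)
  would need the reverse-complement windows.

Evidence is clustered per side with a positional gap threshold
(`cluster_gap`, default 1000 bp ≈ 2–3 fragment lengths); clusters below
`min_support` (default 3) are dropped, which silences the no-insert negative
control. Each left cluster pairs with the nearest right cluster downstream;
the junction is the modal split-read coordinate when split reads exist,
otherwise the innermost anchor end, flagged approximate with a
±insert-size confidence interval (approximate junctions are excluded from
deletion-length exactness claims). Junction convention: `left_junction` is
the 1-based last retained base, `right_junction` the first retained base,
`deletion_len = right − left − 1`.

Copy number is `round(median depth over the T-DNA interval / median genomic
depth)`, floored at 1. The insert is called `TDNA_BACKBONE_TDNA` iff copies
= 2 and ≥ 50 % of backbone positions (vector minus T-DNA) have depth ≥ 3;
otherwise `TDNA_ONLY`. A double T-DNA with full backbone is modeled as
T-DNA + backbone (circular order) + T-DNA — two T-DNA copies and one
backbone copy in read depth; because the default construct linearizes the
circular vector with the T-DNA at the origin, this insert contains the
complete vector sequence as a contiguous substring.

Site classification uses the deleted interval plus the insertion point:
a gene is disrupting-hit when either falls inside its transcript span
(deleted CDS bases are reported per gene); otherwise a promoter hit when
within `promoter_len` (default 1500 bp) upstream of a TSS, strand-aware.
When several classes apply across overlapping genes the summary label uses
the precedence GENIC_DISRUPTING > PROMOTER > INTERGENIC, with every
qualifying gene listed.

## Dual-caller consensus

Normalization left-aligns and parsimony-trims indels (vt-style: trim equal
trailing bases, extending with the previous reference base when an allele
empties; then trim equal leading bases), decomposes MNPs into per-base SNPs
tagged with their source record, and keeps complex records atomic — they
match only exactly. Intersection retains a record of callset A iff **all**
primitives derived from it occur among B's primitives, and reports it in
A's original representation; an exact-record mode is also exposed.

The filter cascade is applied in a fixed order so removal tallies are
reproducible: low-complexity mask → QUAL ≥ 30 → depth > 10 → depth < 29 →
≥ 1 alt-supporting read per strand; records missing any required field are
tallied as malformed. The depth window's upper bound is a per-site
exclusive threshold (configurable, e.g. as mean coverage × factor); the
double-strand rule is interpreted as at least one alt-supporting read on
each strand (configurable).

The low-complexity masker scores windows of up to 64 bases with the
triplet statistic S = Σ cₜ(cₜ−1)/2 over the 64 triplet types (triplets
containing N are not counted) and masks the extent of every window whose
normalized score S/(L−2) exceeds the threshold (default 20), merging
overlapping windows. Under this normalization a long homopolymer is fully
masked while a perfect 4-periodic repeat like (ACGT)ₙ stays below the
default threshold; both behaviors are pinned by tests against an
independent brute-force scorer. Masked extents slightly overshoot the
low-complexity core (window-extent marking), which is conservative for
filtering.

## Effect annotation

Regions are assigned from the canonical transcript (longest CDS, ties
broken lexicographically) of every gene whose span or 1500-bp strand-aware
flank covers the variant's first changed base; the summary class follows
the precedence CDS exon > 5′UTR > 3′UTR > non-coding exon > intron >
upstream > downstream > intergenic, with all gene contexts retained.
Exonic positions of non-coding genes get their own class (`NC_EXON`,
MODIFIER tier) since they are neither CDS nor UTR.

Coding indels are frameshift when the net length change is not divisible
by 3, otherwise inframe (complex length-changing records follow the same
rule). Coding substitutions are evaluated codon-locally: affected codons
are mutated (complemented for minus-strand genes) and translated with the
standard nuclear codon table; priority is start_lost > stop_gained >
stop_lost > missense > synonymous. MNPs spanning the CDS boundary
contribute only their in-CDS bases; the non-CDS remainder could only add
MODIFIER-tier terms, so the coding call is the most severe by
construction. A canonical CDS that does not translate cleanly flags a
warning and the effect is computed on the raw frame. The test suite checks
this path against an independent oracle that rebuilds the entire mutated
CDS, translates it, and diffs the proteins.

Impact tiers are a pure function of the effect term: frameshift, start
lost, stop gained/lost → HIGH; missense, inframe indel → MODERATE;
synonymous → LOW; all non-coding terms → MODIFIER.

## Summary statistics

Variation rate is variants per base of total genome length, reported raw
and at 3 significant figures. Ts/Tv counts purine↔purine and
pyrimidine↔pyrimidine changes over all per-base substitutions, with MNPs
decomposed first; the substitution spectrum is reported both as 12 ordered
changes and collapsed to 6 unordered base pairs. Region densities divide
per-class counts by class lengths computed as a strict partition of the
genome under the region precedence (overlaps collapsed to the most
specific class). Binned distributions count variants in half-open bins
from base 1 (position 10 000 is in bin 1, 10 001 in bin 2), optionally
projected onto chromosomes via the contig→(chromosome, offset) map.
Hotspot contigs are those carrying ≥ 20 % (default) of a line's variants.
Percentage conventions are fixed per statistic: effect-table shares to 2
decimals, prose-style shares (verification precision, Venn percentages) to
the nearest integer.

## Synthetic data: what it emulates, and what it does not

The generator's defaults encode the study conditions: 100-bp paired-end
reads at 35× coverage; a planted variant spectrum of 62 % deletions, 27 %
SNPs, 7 % insertions, 2 % MNPs, 2 % complex; transition-weighted SNPs
(weight 0.63, Ts/Tv ≈ 1.7); 1-bp-dominant indels (97.5 % of deletions,
88.5 % of insertions); and three line fixtures mirroring the study lines —
junction deletions 1304/361/95 nt, copies 1/1/2, the two-copy line with
vector backbone, and the middle line inserted 361 bp before a TSS so that
the site deletion removes the first 142 coding bases of the overlapping
antisense gene. An optional hotspot contig receives a configurable share
(30 % in the acceptance runs) of all planted variants. Where the study
reports no value, defaults are chosen once at plausible scale: two 80-kb
contigs (GC 0.35, cucumber-like), ~0.8 genes per 10 kb with 1–3 exons,
a 6-kb vector with a 3.5-kb T-DNA (the real construct's size and border
coordinates are not published, so the construct is parameterized, not
reproduced), fragment length 350 ± 35 bp.

Reads carry substitution errors only (no indel errors, no quality decay,
no PCR duplicates): variant calling is emulated rather than performed from
pileups, so read-level error realism buys nothing downstream. The emulated
callers annotate records with a clipped-normal quality (mean 60), Poisson
depth (mean 20 — inside the default 10 < d < 29 window most of the time),
and a binomial strand split of full-depth alt support (homozygous line);
false positives are uniform SNPs outside truth loci, false negatives
independent drops. Truth alignments are computed from the piecewise
coordinate map of the transgenic contig onto the combined reference: a
read is aligned to the segment with the largest overlap and soft-clipped
at segment boundaries, which reproduces the junction-clip signature real
aligners produce. Consequently, passing tests demonstrate the detection
and consensus logic under clean mappability; they do not probe repetitive
mapping ambiguity, alignment artifacts, or caller-specific error modes of
real data.

## Numerical and degenerate-input choices

Generators use a single `numpy` PRNG per operation seeded explicitly, so
every output is byte-identical for a fixed (config, seed). Copy number
rounds half-up (⌊x + 0.5⌋) and is floored at 1; zero genomic depth leaves
copies undefined and the structure unresolved. Approximate junction pairs
that cross are clamped to a zero-length site deletion. Ratio statistics
(Ts/Tv, del/ins, NS/S) report an undefined sentinel (`None`/JSON null)
when their denominator is zero rather than raising. Variants at a contig's
first base cannot be left-aligned past the origin and are rejected
explicitly (the generator never plants there). Filter tallies attribute
each removal to the first failing filter in the fixed order. Problem sizes
in the test and acceptance runs — 20–80-kb contigs, 35× coverage,
n = 10 000 planted variants — were chosen as the smallest scales at which
the binomial 3-standard-error checks are meaningful.

## Known limitations

Only one insertion structure family is modeled (1–2 T-DNA copies, optional
single backbone copy, forward orientation); inverted or truncated inserts
and non-vector structural variants are out of scope. Complex records are
never decomposed, trading recall for determinism in the intersection.
Gene-level aggregation of affected genes follows the stated precedence
rules but cannot be anchored to any external annotation. Depth-based copy
number saturates in repetitive regions, and the scan assumes unique
mappability of the flanking genome.
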