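# Methods

## Scope and data model

The package analyzes targeted amplicon re-sequencing data at the level
of per-position pileup columns: strand-resolved base-call counts, counts
of reads with an insertion anchored after the position (`ins_anchor`),
counts of reads whose deletion spans the position (`del_span`), and
reference-skip marks. Columns are parsed from `samtools mpileup` text;
the parser supports the full symbol set samtools emits (`. ,` and cased
bases for strand, `^`+quality and `$` read boundaries, `+N<seq>` /
`-N<seq>` indel descriptors, `*`/`#` deletion spans, `></` reference
skips) and enforces the reconciliation *base calls + deletion spans +
skips = depth field* on every line. Columns beyond the sixth are
ignored. BED input is 0-based half-open; everything else in the package
is 1-based, and the conversion happens only in the I/O layer.

Pileup counts are authoritative for all statistics; the VCF writer is a
derived report format only.

### Denominator conventions

The source procedures leave denominators implicit, so each statistic is
normalized over its own event space:

* base-level frequencies (reference, major, minor, alternative allele)
  use A/C/G/T calls only — `N` calls, deletion spans and skips excluded;
* strand bias uses all base calls (strand information exists only for
  base calls, not for `*` marks);
* indel frequency uses the full read depth, since insertion and
  deletion are read-level events.

Undefined values (no qualifying events) are returned as `None`, never 0,
so downstream code can distinguish "quiet" from "no data".

## Per-position statistics

* **Normalized depth** = depth / sample mean depth, where the mean is
  over all targeted positions with absent positions counted as depth 0.
  By construction the normalized depths of a fully covered sample
  average exactly 1.
* **Major allele frequency** (hemizygous genes): most-called base over
  all base calls, ties broken by the fixed order A < C < G < T.
* **Minor allele fraction** (diploid genes): second-most-called base
  over all base calls; positions with MAF < 0.25 are eliminated as
  homozygous.
* **Alternative allele frequency**: 1 − (top base share). When this
  exceeds 0.25, a genuine second allele (heterozygote, or a hemizygous
  variant) is inflating it, and the noise figure is recalculated as the
  sum of the two *lowest* of the four base counts over the total. The
  recalculated value never exceeds the raw one. The rule keeps exactly
  the two lowest counts even if three alleles were substantial — a
  deliberately conservative reading.
* **Indel frequency**: (ins_anchor + del_span) / depth with the same
  0.25 guard. The source procedure states only that indels use "the
  same strategy"; with two event classes rather than four alleles, the
  residual-noise recalculation here returns the *smaller* of the
  insertion and deletion fractions, i.e. the event class that is not
  being called.
* **Cohort aggregation**: per-position mean and sample SD (ddof = 1;
  0.0 when only one sample covers a position) over samples with
  depth > 0; uncovered positions are omitted with a warning.
* **Cumulative bin tables**: counts of frequencies strictly above
  1/2/5/10 % plus the complement of the 1 % bin; the bins are
  cumulative, so the total is the sum of the `<1` and `>1` rows, and
  percentages are reported at 2 significant figures. This cumulative
  reading is the only one that reproduces the published percentage
  column of the mutated-position table (e.g. 20/553 = 3.6 %).

## Variant screening

A call is emitted per position and non-reference base whose fraction of
base calls is ≥ the threshold (default 0.25, inclusive), and per indel
event class whose fraction of depth reaches it; consecutive
deletion-span positions merge into a single deletion call. Frequencies
are reported pre-filter. Screening only ever *flags* calls:

* `pop_freq_fail` — population allele frequency > 1 %. A variant absent
  from the population table is "unknown" and passes: an allele never
  seen in a large population is rare by definition. The lookup
  deliberately returns an unknown sentinel rather than 0.
* `homopolymer_flag` — indel calls inside or adjacent to mononucleotide
  runs ≥ 6 (flow-chemistry run-length misestimation; manual review).
  Substitutions are unaffected.
* `strand_bias_flag` — forward share beyond 19:1 either way; advisory,
  since true variants sit near 0.5.

Annotation attaches mutation-database records by exact
(chrom, pos, ref, alt) match, falling back to position-only matches
with a lower confidence tag, and never alters quality fields. The
calling threshold is applied to the per-allele fraction before the
noise recalculation.

## Gross-deletion detection

Per sample and amplicon, the mean per-position depth is normalized by a
**median-of-ratios size factor** (the per-amplicon reference profile is
the cohort median; a sample's factor is the median of its ratios over
the amplicons it actually covers). This normalization — rather than
division by the sample's own mean depth — is robust both to
between-sample yield differences and to the carrier's own deletion: a
sample missing a whole gene would otherwise have a depressed mean,
inflating its remaining ratios and biasing a heterozygous deletion's
ratio away from 0.5. With size factors, an injected heterozygous
deletion at true ratio 0.5 is recovered at 0.50 even when it spans a
third of the panel. The approach assumes fewer than half of a sample's
covered amplicons are deleted.

Amplicons whose cohort reference is zero or below 5 % of the global mean
reference are *systematically low-yield* primer systems, not deletions,
and are excluded from run formation (like the designated low-efficiency
exon-15 amplicon of the diploid gene). Detection scans each gene's
analyzable amplicons in order: runs of ≥ `min_run` (default 2)
consecutive amplicons with ratio ≤ `hemi_max` (default 0.10) are
hemizygous calls; runs within `het_band` (default 0.30–0.70) on diploid
genes are heterozygous calls. The numeric thresholds are this package's
own choices — the source observations are only "decreased or absent"
depth and "approximately 50 %" — and all are configurable; the defaults
separate the three reference cases cleanly from between-amplicon
variation, and clean cohorts produce zero calls across seeds.
`min_run = 2` also makes single-amplicon dropouts uncallable by design.

## Synthetic cohort generator

The generator emulates the statistical structure of AmpliSeq/Ion
Torrent data by drawing each pileup column independently — no
read-level alignment is simulated, which is sufficient because every
downstream statistic is column-based. Defaults define the study
conditions:

* **Panel**: 3 genes (two hemizygous X-linked with 56 and 12 amplicons,
  one diploid autosomal with 55; 123 total), 88-bp inserts tiling 26/8/52
  exons with short intron gaps; one designated dropout amplicon (diploid
  gene, exon 15) at 3 % efficiency. Mononucleotide runs of lengths 6–9
  (including a 9-bp poly-T per gene) are embedded in exonic sequence;
  run lengths are recomputed from the final reference so natural runs
  count too.
* **Depth**: target 2000X; per-amplicon efficiency log-normal
  (σ = 0.5, mean-normalized — the between-amplicon spread is shown only
  graphically in the source, so σ is a free, exposed choice);
  per-sample factor log-normal (σ = 0.1, mean 1); per-position depth
  Poisson.
* **Substitution noise**: per-position systematic rate, bulk
  Beta(2, 398) (mean ≈ 0.5 %) with a 0.5 % fraction of noisy positions
  at Uniform(3–8 %), split over the three non-reference bases by a
  per-position Dirichlet. This reproduces the observed regime: ≈ 99 %
  of database positions below 1 % alternative-allele frequency,
  > 99 % of hemizygous cells with reference fraction > 0.95, and
  per-position mean alternative frequency < 10 % everywhere.
* **Indel noise**: per-position base rate Beta(2, 398) multiplied by
  2^(run length − 4) and capped at 8 %, so runs ≥ 6 show clearly
  elevated indel frequencies while every per-position mean stays below
  15 %. Insertion/deletion split uniform per position.
* **Strand bias**: 0.5 % of positions drawn at 97:3 either direction;
  all others 50:50 per base call.
* **Pseudogene-like contamination** (diploid gene only): in 2 regions a
  45 % fraction of reads carries the reference haplotype, pushing a
  heterozygote's minor allele toward the 25 % cut-off
  (0.5 × (1 − 0.45) ≈ 0.28); 2 further regions use 15 % for milder
  depression — 4 depressed regions in total.
* **Polymorphisms**: 40 diploid-gene SNP sites (some forced into the
  pseudogene regions), per-sample genotypes het/hom-alt/hom-ref at
  0.4/0.1/0.5, population AFs 2–40 % (all caught by the 1 % filter).
  A companion population table also carries rare decoy alleles below
  1 %, and the mutation-database table carries the injected lesions
  plus several hundred point/indel positional entries so database
  positions can be profiled independently of patient genotype.
* **Injections**: substitutions (het 50 %, hemizygous 100 % of the
  allele), small insertions/deletions (hemizygous carriers simulated at
  a 97 % event fraction, leaving a realistic residue of non-conforming
  reads), and gross deletions that zero (hemizygous) or halve
  (heterozygous) the expected depth of all involved amplicons;
  heterozygously deleted regions revert polymorphic genotypes to the
  retained haplotype.

Identical config + seed gives byte-identical pileups and truth; the
ground-truth manifest records every injection, genotype and per-position
noise parameter, and the emitted mpileup text re-parses to the truth
counts exactly.

The frozen 24-patient scenario mirrors a realistic validation cohort:
8 patients per disorder, 18 substitutions, 3 small indels (one a
single-base duplication inside the poly-T stretch), 3 gross deletions
(heterozygous diploid-gene exons 14–52; hemizygous whole second X-linked
gene; hemizygous exons 1–12 of the first), plus 3 incidental
heterozygous diploid-gene variants in X-linked-lesion carriers.

### What the simulator does not model

Flowgram/signal-level chemistry, base-quality scores, alignment and
mapping artifacts, GC-dependent amplification, real human sequence
context, and the recurrent intron-22 inversion of *F8* (not assayable by
an exonic amplicon panel). Passing tests therefore demonstrate the
*statistical* machinery — thresholding, normalization, run detection,
flag logic — under the documented error structure, not robustness to
alignment- or chemistry-level failure modes of real data.

## Numerical choices and edge cases

* Ties for top/second allele: fixed base order A < C < G < T.
* Undefined statistics return `None`; zero-depth positions are omitted
  from pileups (as samtools does) and counted as depth 0 where a
  denominator over targeted positions is needed.
* Percentages in bin tables: 2 significant figures (round-half-even).
* Depth reconciliation failures raise an integrity error; malformed or
  truncated indel descriptors raise a parse error — corruption never
  degrades to a silent miscount.
* Sample size factors fall back to 1.0 for a sample covering no
  amplicon with positive cohort median (its cells are all zero anyway).
* Detection of heterozygous deletions on a gene registered as
  hemizygous is a configuration error when requested explicitly, and
  the heterozygous band is simply not applied in the default combined
  mode.

## Problem sizes used in the test suite

The acceptance-level tests run the full-size panel (123 amplicons,
~10.8 kb of targeted sequence, 24 samples, 2000X): one clean cohort for
the noise-regime and parameter-recovery properties, ten seeded
replicates of the 24-patient scenario for detection completeness, and
10^4/10^3-draw oracle-equivalence checks for the parser and the binning.
Unit and property tests use a structurally identical scaled-down panel
(15 amplicons, 400X, 6 samples).
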