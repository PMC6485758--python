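# ampliscreen

Characterization and mutation screening of targeted multiplex-PCR
(AmpliSeq) / Ion Torrent re-sequencing data for the inherited
bleeding-disorder genes *F8*, *F9* (X-linked, analyzed as hemizygous in
males) and *VWF* (autosomal, diploid) — and, generically, for any small
amplicon panel whose per-position evidence comes as `samtools mpileup`
text.

The package is written for laboratories validating an amplicon panel:
it quantifies the panel's noise floor position by position, screens for
disease-causing variants at a frequency threshold, and detects gross
(multi-exon) deletions from amplicon read depth. A seeded synthetic
cohort generator with full ground truth makes every step testable end
to end.

## What it computes

For each sample and targeted position, from strand-resolved pileup
counts:

* **Mean read depth** per sample, and **normalized depth**
  `depth / mean depth` (dimensionless).
* **Coverage**: fraction of targeted positions with depth ≥ a minimum
  (default 100 reads).
* **Strand bias** `fwd / (fwd + rev)` over base calls; the complement is
  the reverse-strand share. Values beyond 19:1 (> 0.95 or < 0.05) are
  flagged as artifacts.
* **Reference / major allele frequency**: for hemizygous genes, the
  most-called base over all A/C/G/T calls (expected ≈ 1); for diploid
  heterozygotes, the **minor allele fraction** (second-most-called base,
  expected ≈ 0.5), with positions below the 0.25 cut-off eliminated as
  homozygous.
* **Alternative allele frequency** (the substitution noise measure):
  the calls differing from the most-called base divided by all base
  calls; if this exceeds 0.25 a true second allele is being observed,
  and the noise figure is recalculated from the two least-called of the
  four bases.
* **Indel frequency**: (insertions anchored at + deletions spanning the
  position) / depth, with the same > 0.25 guard.
* Cohort-level per-position mean and SD of the noise frequencies, and
  cumulative bin tables (counts above 1 / 2 / 5 / 10 %) of the
  frequencies observed at known mutation-database positions.

Screening then emits a call wherever a non-reference allele or indel
class reaches the 0.25 threshold, splits multi-allelic records, flags
(never deletes) calls with population allele frequency > 1 %, attaches
mutation-database annotation, and flags indel calls in mononucleotide
runs ≥ 6 — the homopolymer contexts where flow-based chemistry
misestimates run length. Gross deletions are detected from a samples ×
amplicons matrix of normalized mean depths: runs of ≥ 2 consecutive
amplicons at ≤ 0.10 of the cohort reference are hemizygous calls, runs
within 0.30–0.70 on a diploid gene are heterozygous calls.

## Worked example

Simulate the frozen 24-patient validation cohort (18 substitutions, 3
small indels, 3 gross deletions, plus 3 incidental heterozygous *VWF*
variants in hemophilia patients) and run the whole pipeline in memory:

```bash
ampliscreen all --scenario paper --seed 1 --out report/
```

The per-variant quality report (depth/strand-bias per call) ends:

```
sample_id gene       mutation    consequence   quality          filters
   HA_208   F8     c.3637dupA     Frameshift 1288/0.50 homopolymer_flag
   HA_365   F8      c.3640del     Frameshift  823/0.39             PASS
   HA_398   F8        c.67A>G       Missense 1410/0.49             PASS
   ...
   HA_420   F8 Gross deletion Gross deletion       0/0             PASS
   HB_129   F9 Gross deletion Gross deletion       0/0             PASS
   VWF_25  VWF Gross deletion Gross deletion       -/-             PASS
```

Every known lesion is recovered: the duplication inside the 9-bp poly-T
stretch is called but carries the homopolymer manual-review flag;
strand biases cluster around 0.5; the two hemizygous gross deletions
show the `0/0` (no reads) quality convention while the heterozygous
*VWF* exon 14–52 deletion shows `-/-` and a measured depth ratio of
0.501 over its 38 analyzable amplicons:

```
sample_id gene first_amplicon last_amplicon  n_amplicons  mean_ratio     zygosity
   HA_420   F8      F8_amp001     F8_amp028           28     0.00000   hemizygous
   HB_129   F9      F9_amp001     F9_amp012           12     0.00000   hemizygous
   VWF_25  VWF     VWF_amp017    VWF_amp055           38     0.50135 heterozygous
```

The same run writes `position_metrics.tsv` (per position × sample),
`cohort_summary.tsv`, the bin tables, `variants.tsv`/`variants.vcf`,
`deletions.tsv` and a `run.log` recording every threshold used. File-based
workflows are available through `ampliscreen simulate / stats / screen /
deletions / report` (see `--help`), driven by BED targets, an amplicon
TSV, mpileup files and TSV frequency/mutation tables.

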