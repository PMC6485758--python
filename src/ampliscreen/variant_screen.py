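"""Frequency-threshold variant screening with annotation and filters.

Candidate variants are emitted wherever a non-reference base — or an
insertion/deletion event class — reaches the calling threshold (default
0.25 of the relevant denominator).  Hemizygous true variants are
expected near fraction 1.0, diploid heterozygotes near 0.5; sequencing
noise sits well below the threshold at adequate depth.

Screening never deletes a call.  Population-frequency failures
(common polymorphisms), extreme strand bias and homopolymer context are
recorded as filter flags so a report can show *why* a candidate was
excluded or needs manual review.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .errors import ConfigError
from .io_formats import (
    MutationDatabase,
    PileupColumn,
    PopulationFrequencies,
    TargetRegion,
)
from .pileup_stats import NOISE_THRESHOLD, SampleLibrary, strand_bias

#: Filter flag names.
POP_FREQ_FAIL = "pop_freq_fail"
HOMOPOLYMER_FLAG = "homopolymer_flag"
STRAND_BIAS_FLAG = "strand_bias_flag"

#: Strand-bias advisory boundary: forward share beyond 19:1 in either
#: direction.
STRAND_BIAS_LIMIT = 0.95

#: Minimum mononucleotide-run length that makes indel calls suspect on
#: semiconductor sequencing chemistry.
MIN_HOMOPOLYMER_RUN = 6


@dataclass(frozen=True)
class VariantCall:
    """A candidate non-reference allele passing the calling threshold.

    ``alt`` is a base for substitutions, ``+<seq>`` for insertions
    anchored after ``pos`` and ``-<n>`` (or ``-<seq>`` when the deleted
    bases are known) for deletions starting at ``pos``.  ``freq`` is the
    allele fraction before any filtering; ``pop_af`` is ``None`` when
    the variant is absent from the population table ("unknown").
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    freq: float
    depth: int
    strand_bias: float | None
    gene: str = ""
    filters: frozenset = frozenset()
    annotations: tuple = ()
    annotation_confidence: str | None = None
    pop_af: float | None = None

    @property
    def is_indel(self) -> bool:
        return self.alt.startswith(("+", "-")) or self.alt in ("<INS>", "<DEL>")

    def with_flag(self, flag: str) -> "VariantCall":
        return replace(self, filters=self.filters | {flag})


def _gene_at(regions: Sequence[TargetRegion] | None, chrom: str, pos: int) -> str:
    if not regions:
        return ""
    for reg in regions:
        if reg.chrom == chrom and reg.start < pos <= reg.end:
            return reg.gene
    return ""


def call_variants(
    sample: SampleLibrary,
    threshold: float = NOISE_THRESHOLD,
    regions: Sequence[TargetRegion] | None = None,
) -> list[VariantCall]:
    """Screen every pileup column of a sample for candidate variants.

    A substitution call is emitted for each non-reference base whose
    fraction of A/C/G/T calls is >= ``threshold`` (inclusive).  An
    insertion call is emitted where the anchored-insertion fraction of
    the depth reaches the threshold, with the most frequent inserted
    sequence as the descriptor.  Positions whose deletion-span fraction
    reaches the threshold are grouped into runs of consecutive positions
    and reported as a single deletion call at the first spanned
    position.  Frequencies are reported before any filtering.
    """
    if not 0.0 < threshold <= 1.0:
        raise ConfigError(f"calling threshold {threshold} outside (0, 1]")
    calls: list[VariantCall] = []
    del_candidates: list[tuple[str, int, PileupColumn, float]] = []

    for (chrom, pos), col in sorted(sample.columns.items()):
        counts = col.acgt_counts()
        total = sum(counts.values())
        sb = strand_bias(col)
        if total > 0:
            for base, count in counts.items():
                if base == col.ref_base or count == 0:
                    continue
                frac = count / total
                if frac >= threshold:
                    calls.append(
                        VariantCall(
                            sample_id=sample.sample_id,
                            chrom=chrom,
                            pos=pos,
                            ref=col.ref_base,
                            alt=base,
                            freq=frac,
                            depth=col.depth,
                            strand_bias=sb,
                            gene=_gene_at(regions, chrom, pos),
                        )
                    )
        if col.depth > 0:
            ins_frac = col.ins_anchor / col.depth
            if ins_frac >= threshold:
                seq = (
                    col.ins_seqs.most_common(1)[0][0] if col.ins_seqs else "N"
                )
                calls.append(
                    VariantCall(
                        sample_id=sample.sample_id,
                        chrom=chrom,
                        pos=pos,
                        ref=col.ref_base,
                        alt=f"+{seq}",
                        freq=ins_frac,
                        depth=col.depth,
                        strand_bias=sb,
                        gene=_gene_at(regions, chrom, pos),
                    )
                )
            del_frac = col.del_span / col.depth
            if del_frac >= threshold:
                del_candidates.append((chrom, pos, col, del_frac))

    # merge consecutive deletion-span positions into single calls
    run: list[tuple[str, int, PileupColumn, float]] = []
    for item in del_candidates:
        if run and (item[0] != run[-1][0] or item[1] != run[-1][1] + 1):
            calls.append(_deletion_call(sample, run, regions))
            run = []
        run.append(item)
    if run:
        calls.append(_deletion_call(sample, run, regions))
    calls.sort(key=lambda c: (c.chrom, c.pos, c.alt))
    return calls


def _deletion_call(
    sample: SampleLibrary,
    run: list[tuple[str, int, PileupColumn, float]],
    regions: Sequence[TargetRegion] | None,
) -> VariantCall:
    chrom, first, col0, _ = run[0]
    seq = "".join(col.ref_base for _, _, col, _ in run)
    mean_frac = sum(frac for *_, frac in run) / len(run)
    mean_depth = round(sum(col.depth for _, _, col, _ in run) / len(run))
    sb = strand_bias(col0)
    return VariantCall(
        sample_id=sample.sample_id,
        chrom=chrom,
        pos=first,
        ref=col0.ref_base,
        alt=f"-{seq}",
        freq=mean_frac,
        depth=mean_depth,
        strand_bias=sb,
        gene=_gene_at(regions, chrom, first),
    )


def split_multiallelic(calls: Sequence[VariantCall]) -> list[VariantCall]:
    """Split records carrying comma-joined alternate alleles.

    One record with alts ``"A,G"`` becomes two records sharing the
    position; already-split input is returned unchanged (idempotent) and
    the total number of (pos, alt) pairs is preserved.
    """
    out: list[VariantCall] = []
    for call in calls:
        if "," in call.alt:
            out.extend(replace(call, alt=a) for a in call.alt.split(",") if a)
        else:
            out.append(call)
    return out


def population_filter(
    calls: Sequence[VariantCall],
    popfreqs: PopulationFrequencies,
    cutoff: float = 0.01,
) -> list[VariantCall]:
    """Flag calls whose population allele frequency exceeds ``cutoff``.

    Calls are flagged with ``pop_freq_fail``, never dropped.  A variant
    absent from the table has unknown AF and passes: an allele never
    observed in a large population is rare by definition.
    """
    out = []
    for call in calls:
        af = popfreqs.lookup(call.chrom, call.pos, call.ref, call.alt)
        call = replace(call, pop_af=af)
        if af is not None and af > cutoff:
            call = call.with_flag(POP_FREQ_FAIL)
        out.append(call)
    return out


def annotate_calls(
    calls: Sequence[VariantCall], mutation_db: MutationDatabase
) -> list[VariantCall]:
    """Attach mutation-database records to calls.

    Exact (chrom, pos, ref, alt) matches attach with confidence
    ``"exact"``; otherwise any record at the same position attaches with
    confidence ``"position-only"``.  Annotation never changes the
    call's frequency or quality fields.
    """
    out = []
    for call in calls:
        exact = mutation_db.by_allele.get(
            (call.chrom, call.pos, call.ref, call.alt), []
        )
        if exact:
            call = replace(
                call, annotations=tuple(exact), annotation_confidence="exact"
            )
        else:
            positional = mutation_db.by_position.get((call.chrom, call.pos), [])
            if positional:
                call = replace(
                    call,
                    annotations=tuple(positional),
                    annotation_confidence="position-only",
                )
        out.append(call)
    return out


def homopolymer_run_length(sequence: str, index0: int) -> int:
    """Length of the mononucleotide run covering 0-based ``index0``."""
    base = sequence[index0]
    left = index0
    while left > 0 and sequence[left - 1] == base:
        left -= 1
    right = index0
    n = len(sequence)
    while right + 1 < n and sequence[right + 1] == base:
        right += 1
    return right - left + 1


def flag_homopolymer(
    calls: Sequence[VariantCall],
    reference: Mapping[str, str],
    min_run: int = MIN_HOMOPOLYMER_RUN,
) -> list[VariantCall]:
    """Flag indel calls inside or immediately adjacent to mononucleotide
    runs of length >= ``min_run``.

    Flow-based chemistries misestimate run lengths in long homopolymers,
    so such indel calls are a manual-review signal.  Substitution calls
    are unaffected.  Raises :class:`ConfigError` when the reference does
    not cover the required window around a call.
    """
    out = []
    for call in calls:
        if not call.is_indel:
            out.append(call)
            continue
        seq = reference.get(call.chrom)
        if seq is None or call.pos > len(seq):
            raise ConfigError(
                f"reference does not cover {call.chrom}:{call.pos}"
            )
        idx = call.pos - 1
        window = [idx]
        if idx > 0:
            window.append(idx - 1)
        if idx + 1 < len(seq):
            window.append(idx + 1)
        if any(homopolymer_run_length(seq, i) >= min_run for i in window):
            call = call.with_flag(HOMOPOLYMER_FLAG)
        out.append(call)
    return out


def flag_strand_bias(
    calls: Sequence[VariantCall], limit: float = STRAND_BIAS_LIMIT
) -> list[VariantCall]:
    """Advisory flag for calls at positions with forward-strand share
    beyond ``limit`` in either direction (default 19:1)."""
    out = []
    for call in calls:
        sb = call.strand_bias
        if sb is not None and (sb > limit or sb < 1.0 - limit):
            call = call.with_flag(STRAND_BIAS_FLAG)
        out.append(call)
    return out
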