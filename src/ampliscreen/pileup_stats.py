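"""Per-position statistics for targeted amplicon panels.

Implements the descriptive statistics used to characterize an
AmpliSeq/Ion Torrent panel from strand-resolved pileup counts: sample
mean read depth and depth normalization, coverage at a minimum depth,
strand bias, reference/major/minor allele frequencies, alternative
allele frequency with the >0.25 two-lowest-alleles recalculation,
per-position indel frequency, cohort-level mean/SD aggregation, and
cumulative threshold binning of frequency vectors.

Denominator conventions (the counts a frequency is normalized over):

* base-level statistics (reference/major/minor/alternative allele
  frequencies) use A/C/G/T base calls only — 'N' calls, deletion-span
  marks and reference skips are excluded, so each statistic is
  normalized over its own event space;
* strand bias uses all base calls including 'N';
* indel frequency uses the full read depth, since both a spanning
  deletion and an anchored insertion are read-level events.

Positions with no qualifying events return ``None`` (an "undefined"
sentinel), never 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .io_formats import (
    BASES,
    PileupColumn,
    TargetRegion,
    read_pileup,
    region_positions,
)

#: Default noise threshold above which a second allele is treated as a
#: real allele rather than noise (used by the alternative-allele and
#: indel recalculation and by the minor-allele elimination rule).
NOISE_THRESHOLD = 0.25

#: Default minimum depth for coverage calculations (reads).
DEFAULT_MIN_DEPTH = 100


# ---------------------------------------------------------------------------
# sample container
# ---------------------------------------------------------------------------

@dataclass
class SampleLibrary:
    """One sample's pileup columns, keyed by (chrom, 1-based position).

    ``genes`` maps gene symbol -> ploidy (1 for hemizygous X-linked
    genes in males, 2 for autosomal genes).
    """

    sample_id: str
    columns: dict[tuple[str, int], PileupColumn]
    genes: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_pileup(
        cls,
        path: str | Path,
        sample_id: str | None = None,
        genes: Mapping[str, int] | None = None,
    ) -> "SampleLibrary":
        cols = read_pileup(path)
        return cls(
            sample_id=sample_id or Path(path).stem,
            columns={(c.chrom, c.pos): c for c in cols},
            genes=dict(genes or {}),
        )

    def depth_at(self, chrom: str, pos: int) -> int:
        col = self.columns.get((chrom, pos))
        return col.depth if col is not None else 0


# ---------------------------------------------------------------------------
# per-sample / per-position statistics
# ---------------------------------------------------------------------------

def mean_depth(
    sample: SampleLibrary, regions: Sequence[TargetRegion] | None = None
) -> float:
    """Arithmetic mean read depth over all targeted positions.

    With ``regions``, every targeted position enters the mean and
    positions absent from the pileup count as depth 0; without, the mean
    is over the positions present in the pileup.
    """
    if regions is not None:
        total = 0
        n = 0
        for chrom, pos in region_positions(regions):
            total += sample.depth_at(chrom, pos)
            n += 1
    else:
        n = len(sample.columns)
        total = sum(col.depth for col in sample.columns.values())
    if n == 0:
        raise ConfigError(f"sample {sample.sample_id}: no targeted positions")
    return total / n


def normalized_depth(column: PileupColumn, sample_mean: float) -> float:
    """Read depth divided by the sample mean depth (dimensionless)."""
    if sample_mean <= 0:
        raise ConfigError(f"sample mean depth must be > 0, got {sample_mean}")
    return column.depth / sample_mean


def coverage(
    sample: SampleLibrary,
    regions: Sequence[TargetRegion],
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> float:
    """Fraction of targeted positions with depth >= ``min_depth``.

    Positions absent from the pileup count as depth 0.
    """
    if min_depth < 0:
        raise ConfigError("min_depth must be >= 0")
    n = 0
    ok = 0
    for chrom, pos in region_positions(regions):
        n += 1
        if sample.depth_at(chrom, pos) >= min_depth:
            ok += 1
    if n == 0:
        raise ConfigError("coverage requires at least one targeted position")
    return ok / n


def strand_bias(column: PileupColumn) -> float | None:
    """Forward-strand share of base calls; ``None`` if no base calls.

    The complement is the reverse-strand share.  Deletion-span marks
    carry no strand information in the pileup dialect and are excluded.
    """
    fwd = sum(column.fwd_counts.values())
    rev = sum(column.rev_counts.values())
    total = fwd + rev
    if total == 0:
        return None
    return fwd / total


def major_allele_freq(column: PileupColumn) -> tuple[str, float] | None:
    """Most-called base and its fraction of A/C/G/T calls.

    Ties are broken by the fixed base order A < C < G < T.  Returns
    ``None`` when there are no base calls.  For hemizygous genes this is
    the reference-allele frequency estimator.
    """
    counts = column.acgt_counts()
    total = sum(counts.values())
    if total == 0:
        return None
    best = max(BASES, key=lambda b: (counts[b], -BASES.index(b)))
    return best, counts[best] / total


def minor_ref_freq(
    column: PileupColumn, cutoff: float = NOISE_THRESHOLD
) -> float | None:
    """Second-most-called base fraction at a diploid position (MAF).

    Positions where the minor fraction is below ``cutoff`` are
    eliminated (returned as ``None``): the position is treated as
    homozygous and the second allele as noise.  Fewer than two distinct
    observed bases also eliminates the position.
    """
    counts = column.acgt_counts()
    total = sum(counts.values())
    if total == 0:
        return None
    ordered = sorted(counts.values(), reverse=True)
    second = ordered[1]
    if second == 0:
        return None
    maf = second / total
    if maf < cutoff:
        return None
    return maf


def ref_allele_freq(column: PileupColumn) -> float | None:
    """Fraction of A/C/G/T calls matching the reference base."""
    counts = column.acgt_counts()
    total = sum(counts.values())
    if total == 0:
        return None
    return counts.get(column.ref_base, 0) / total


def alt_allele_freq(
    column: PileupColumn, recalc_threshold: float = NOISE_THRESHOLD
) -> float | None:
    """Alternative-allele (noise) frequency at a position.

    Sum of the base calls differing from the most-called base, divided
    by all A/C/G/T calls.  If this exceeds ``recalc_threshold`` the
    second allele is considered real (a heterozygote or hemizygous
    variant) and the frequency is recalculated from the two least-called
    of the four bases, so the returned value measures residual noise.
    The recalculated value is always <= the original.
    """
    counts = column.acgt_counts()
    total = sum(counts.values())
    if total == 0:
        return None
    ordered = sorted(counts.values())
    freq = (total - ordered[-1]) / total
    if freq > recalc_threshold:
        freq = (ordered[0] + ordered[1]) / total
    return freq


def indel_freq(
    column: PileupColumn, recalc_threshold: float = NOISE_THRESHOLD
) -> float | None:
    """Indel-event frequency: (insertions anchored + deletions spanning)
    divided by the full read depth.

    The same >0.25 guard as for alternative alleles applies: when the
    combined indel fraction exceeds the threshold a true indel allele is
    being called, and the residual noise figure excludes the dominant
    event class (returning the smaller of the insertion and deletion
    fractions).
    """
    if column.depth == 0:
        return None
    raw = (column.ins_anchor + column.del_span) / column.depth
    if raw > recalc_threshold:
        return min(column.ins_anchor, column.del_span) / column.depth
    return raw


# ---------------------------------------------------------------------------
# per-sample metrics table
# ---------------------------------------------------------------------------

METRIC_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "gene",
    "depth",
    "norm_depth",
    "strand_bias",
    "ref_freq",
    "alt_freq",
    "indel_freq",
    "maf",
]


def sample_metrics(
    sample: SampleLibrary,
    regions: Sequence[TargetRegion],
    sample_mean: float | None = None,
) -> pd.DataFrame:
    """Per-position metrics table for one sample (one row per targeted
    position; uncovered positions appear with depth 0 and NaN metrics).

    The ``maf`` column (minor allele fraction, with the <0.25
    elimination rule applied) is computed only for genes registered as
    diploid in ``sample.genes``.
    """
    if sample_mean is None:
        sample_mean = mean_depth(sample, regions)
    rows = []
    nan = float("nan")
    for reg in regions:
        diploid = sample.genes.get(reg.gene, 1) == 2
        for pos in reg.positions():
            col = sample.columns.get((reg.chrom, pos))
            if col is None:
                rows.append(
                    (sample.sample_id, reg.chrom, pos, reg.gene, 0, 0.0,
                     nan, nan, nan, nan, nan)
                )
                continue
            sb = strand_bias(col)
            rf = ref_allele_freq(col)
            af = alt_allele_freq(col)
            inf = indel_freq(col)
            maf = minor_ref_freq(col) if diploid else None
            rows.append(
                (
                    sample.sample_id,
                    reg.chrom,
                    pos,
                    reg.gene,
                    col.depth,
                    normalized_depth(col, sample_mean),
                    nan if sb is None else sb,
                    nan if rf is None else rf,
                    nan if af is None else af,
                    nan if inf is None else inf,
                    nan if maf is None else maf,
                )
            )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


# ---------------------------------------------------------------------------
# cohort aggregation
# ---------------------------------------------------------------------------

def cohort_summary(
    samples: Sequence[SampleLibrary], regions: Sequence[TargetRegion]
) -> pd.DataFrame:
    """Per-position mean and sample SD (ddof=1) of the alternative-allele
    and indel frequencies across samples.

    Only samples with depth > 0 at a position contribute to that
    position's summary; positions covered in no sample are omitted with
    a warning.  With a single contributing sample the SD is reported as
    0.0.
    """
    if len(samples) < 2:
        raise ConfigError("cohort_summary requires at least 2 samples")
    rows = []
    skipped = 0
    for reg in regions:
        for pos in reg.positions():
            alts = []
            indels = []
            for sample in samples:
                col = sample.columns.get((reg.chrom, pos))
                if col is None or col.depth == 0:
                    continue
                af = alt_allele_freq(col)
                inf = indel_freq(col)
                alts.append(0.0 if af is None else af)
                indels.append(0.0 if inf is None else inf)
            if not alts:
                skipped += 1
                continue
            n = len(alts)
            a = np.asarray(alts)
            d = np.asarray(indels)
            rows.append(
                {
                    "chrom": reg.chrom,
                    "pos": pos,
                    "gene": reg.gene,
                    "n": n,
                    "alt_mean": a.mean(),
                    "alt_sd": a.std(ddof=1) if n > 1 else 0.0,
                    "indel_mean": d.mean(),
                    "indel_sd": d.std(ddof=1) if n > 1 else 0.0,
                }
            )
    if skipped:
        warnings.warn(
            f"{skipped} targeted positions covered in no sample were omitted",
            stacklevel=2,
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "gene", "n", "alt_mean", "alt_sd",
                 "indel_mean", "indel_sd"],
    )


# ---------------------------------------------------------------------------
# cumulative frequency binning
# ---------------------------------------------------------------------------

def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class BinTable:
    """Cumulative binning of a frequency vector at percentage thresholds.

    ``counts_above[i]`` counts values strictly above ``thresholds[i]``
    percent, so the bins are cumulative (everything above 10% is also
    above 5%, 2% and 1%).  ``count_below`` is the complement of the
    lowest threshold, and the total is ``count_below +
    counts_above[0]``.  Percentages are rounded to 2 significant
    figures, matching the precision such summary tables are printed at.
    """

    thresholds: tuple[float, ...]
    counts_above: tuple[int, ...]
    count_below: int
    pct_above: tuple[float, ...]
    pct_below: float

    @property
    def total(self) -> int:
        return self.count_below + self.counts_above[0]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "bin": f"<{self.thresholds[0]:g}",
                "count": self.count_below,
                "percent": self.pct_below,
            }
        ]
        for t, c, p in zip(self.thresholds, self.counts_above, self.pct_above):
            rows.append({"bin": f">{t:g}", "count": c, "percent": p})
        return pd.DataFrame(rows, columns=["bin", "count", "percent"])


def bin_frequencies(
    freqs: Iterable[float], thresholds: Sequence[float] = (1.0, 2.0, 5.0, 10.0)
) -> BinTable:
    """Bin frequencies (fractions in [0, 1]) at percentage thresholds.

    Counts are cumulative strictly-above counts; percentages are of the
    total number of values, rounded to 2 significant figures.
    """
    thresholds = tuple(float(t) for t in thresholds)
    if list(thresholds) != sorted(thresholds) or len(set(thresholds)) != len(
        thresholds
    ):
        raise ConfigError("thresholds must be strictly increasing")
    values = [float(f) for f in freqs]
    for f in values:
        if not 0.0 <= f <= 1.0:
            raise ValidationError(f"frequency {f} outside [0, 1]")
    pct = [100.0 * f for f in values]
    counts_above = tuple(sum(1 for p in pct if p > t) for t in thresholds)
    count_below = len(values) - (counts_above[0] if counts_above else 0)
    total = len(values)
    if total:
        pct_above = tuple(round_sig(100.0 * c / total) for c in counts_above)
        pct_below = round_sig(100.0 * count_below / total)
    else:
        pct_above = tuple(0.0 for _ in thresholds)
        pct_below = 0.0
    return BinTable(
        thresholds=thresholds,
        counts_above=counts_above,
        count_below=count_below,
        pct_above=pct_above,
        pct_below=pct_below,
    )
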