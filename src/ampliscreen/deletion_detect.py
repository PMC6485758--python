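"""Gross-deletion detection from normalized per-amplicon read depth.

A gross (multi-amplicon) deletion shows as absent read depth across all
involved amplicons in a hemizygous carrier, or roughly half depth in a
heterozygous carrier of a diploid gene.  Detection works on a
samples-by-amplicons matrix of normalized mean depths compared, per
amplicon, against a cohort reference level.

Normalization uses median-of-ratios sample size factors (the reference
profile per amplicon is the cohort median), which is robust both to
between-sample library-yield differences and to the deletion carrier's
own missing amplicons — a carrier's non-deleted amplicons are not
inflated by its reduced total yield.  Amplicons whose cohort reference
is zero, or below 5% of the global mean reference (systematically
low-yield primer systems rather than deletions), are marked
unanalyzable and skipped when forming runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import Amplicon
from .pileup_stats import SampleLibrary

HEMI_MAX_RATIO = 0.10
HET_BAND = (0.30, 0.70)
MIN_RUN = 2
LOW_YIELD_FRACTION = 0.05


@dataclass(frozen=True)
class DeletionCall:
    """A run of consecutive analyzable amplicons with depressed depth."""

    sample_id: str
    gene: str
    amplicon_ids: tuple[str, ...]
    mean_ratio: float
    zygosity: str  # "hemizygous" | "heterozygous"

    @property
    def first(self) -> str:
        return self.amplicon_ids[0]

    @property
    def last(self) -> str:
        return self.amplicon_ids[-1]

    def __len__(self) -> int:
        return len(self.amplicon_ids)


@dataclass
class AmpliconDepthMatrix:
    """Samples x amplicons normalized mean-depth matrix.

    ``values[s, a]`` is the amplicon mean per-position depth divided by
    the sample size factor; ``reference[a]`` is the per-amplicon cohort
    median of those cells; ``analyzable[a]`` excludes zero-reference and
    systematically low-yield amplicons.
    """

    sample_ids: list[str]
    amplicons: list[Amplicon]
    values: np.ndarray
    reference: np.ndarray
    analyzable: np.ndarray
    gene_ploidy: dict[str, int]

    def ratios(self, sample_id: str) -> np.ndarray:
        """Per-amplicon depth ratio of one sample to the cohort reference
        (NaN for unanalyzable amplicons)."""
        s = self.sample_ids.index(sample_id)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.values[s] / self.reference
        r[~self.analyzable] = np.nan
        return r

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[a.id for a in self.amplicons],
        )


def _amplicon_mean_depth(sample: SampleLibrary, amp: Amplicon) -> float:
    depths = [sample.depth_at(amp.chrom, pos) for pos in amp.positions()]
    return float(np.mean(depths)) if depths else 0.0


def build_depth_matrix(
    samples: Sequence[SampleLibrary],
    amplicons: Sequence[Amplicon],
    gene_ploidy: Mapping[str, int] | None = None,
) -> AmpliconDepthMatrix:
    """Build the normalized depth matrix for a cohort (>= 3 samples).

    Positions absent from a sample's pileup count as depth 0.  Gene
    ploidies default to the union of the samples' ``genes`` maps.
    """
    if len(samples) < 3:
        raise ConfigError("a stable cohort reference requires >= 3 samples")
    amps = sorted(amplicons, key=lambda a: (a.gene, a.chrom, a.start))
    raw = np.array(
        [[_amplicon_mean_depth(s, a) for a in amps] for s in samples],
        dtype=float,
    )
    # median-of-ratios size factors, robust to a carrier's own deletions
    ref_raw = np.median(raw, axis=0)
    usable = ref_raw > 0
    if not usable.any():
        raise ConfigError("no amplicon has nonzero cohort median depth")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = raw[:, usable] / ref_raw[usable]
    # a sample's own dropped-out amplicons must not drag its size factor
    # down, so the median is over amplicons the sample actually covers
    size_factors = np.ones(len(samples))
    for s in range(len(samples)):
        covered = ratios[s][raw[s, usable] > 0]
        if covered.size:
            size_factors[s] = np.median(covered)
    if (size_factors <= 0).any():
        bad = [samples[i].sample_id for i in np.where(size_factors <= 0)[0]]
        raise ConfigError(f"samples with zero size factor: {bad}")
    values = raw / size_factors[:, None]
    reference = np.median(values, axis=0)
    analyzable = reference > 0
    global_mean = reference[analyzable].mean() if analyzable.any() else 0.0
    analyzable &= reference >= LOW_YIELD_FRACTION * global_mean

    if gene_ploidy is None:
        gene_ploidy = {}
        for s in samples:
            gene_ploidy.update(s.genes)
    return AmpliconDepthMatrix(
        sample_ids=[s.sample_id for s in samples],
        amplicons=amps,
        values=values,
        reference=reference,
        analyzable=analyzable,
        gene_ploidy=dict(gene_ploidy),
    )


def detect_deletions(
    matrix: AmpliconDepthMatrix,
    sample_id: str,
    hemi_max: float = HEMI_MAX_RATIO,
    het_band: tuple[float, float] = HET_BAND,
    min_run: int = MIN_RUN,
    zygosity: str = "both",
) -> list[DeletionCall]:
    """Scan one sample's amplicon depth ratios for gross deletions.

    Runs of >= ``min_run`` consecutive analyzable amplicons of one gene
    with ratio <= ``hemi_max`` are hemizygous calls; runs within
    ``het_band`` are heterozygous calls and are only meaningful for
    diploid genes — requesting heterozygous detection when every
    considered gene is hemizygous is a configuration error.
    """
    if not 0 <= hemi_max < het_band[0] < het_band[1] <= 1.0:
        raise ConfigError("require 0 <= hemi_max < het_band[0] < het_band[1] <= 1")
    if zygosity not in ("both", "hemizygous", "heterozygous"):
        raise ConfigError(f"unknown zygosity mode {zygosity!r}")
    ratios = matrix.ratios(sample_id)
    genes = sorted({a.gene for a in matrix.amplicons})
    if zygosity == "heterozygous" and all(
        matrix.gene_ploidy.get(g, 1) != 2 for g in genes
    ):
        raise ConfigError(
            "heterozygous deletion detection requested but no diploid gene present"
        )
    calls: list[DeletionCall] = []
    for gene in genes:
        diploid = matrix.gene_ploidy.get(gene, 1) == 2
        run_ids: list[str] = []
        run_ratios: list[float] = []
        run_class: str | None = None

        def flush() -> None:
            nonlocal run_ids, run_ratios, run_class
            if run_class is not None and len(run_ids) >= min_run:
                if zygosity in ("both", run_class):
                    calls.append(
                        DeletionCall(
                            sample_id=sample_id,
                            gene=gene,
                            amplicon_ids=tuple(run_ids),
                            mean_ratio=float(np.mean(run_ratios)),
                            zygosity=run_class,
                        )
                    )
            run_ids, run_ratios, run_class = [], [], None

        for idx, amp in enumerate(matrix.amplicons):
            if amp.gene != gene or not matrix.analyzable[idx]:
                continue
            r = ratios[idx]
            if r <= hemi_max:
                cls: str | None = "hemizygous"
            elif diploid and het_band[0] <= r <= het_band[1]:
                cls = "heterozygous"
            else:
                cls = None
            if cls != run_class:
                flush()
                run_class = cls
            if cls is not None:
                run_ids.append(amp.id)
                run_ratios.append(float(r))
        flush()
    return calls


def deletions_to_frame(calls: Sequence[DeletionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "gene": c.gene,
                "first_amplicon": c.first,
                "last_amplicon": c.last,
                "n_amplicons": len(c),
                "mean_ratio": c.mean_ratio,
                "zygosity": c.zygosity,
            }
            for c in calls
        ],
        columns=[
            "sample_id",
            "gene",
            "first_amplicon",
            "last_amplicon",
            "n_amplicons",
            "mean_ratio",
            "zygosity",
        ],
    )
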