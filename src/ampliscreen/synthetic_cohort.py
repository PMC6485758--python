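"""Seeded synthetic-cohort generator for targeted amplicon panels.

Emulates the data a multiplex-PCR (AmpliSeq) + semiconductor (Ion
Torrent) workflow produces over a three-gene bleeding-disorder panel:
two X-linked genes analyzed as hemizygous in males (F8, F9) and one
diploid autosomal gene (VWF), ~123 amplicons, ~2000X mean depth.

Reads are simulated as independent per-column draws rather than via
read-level alignment — every downstream statistic in this package is
column-based, so the column counts are a sufficient statistic.  The
error structure emulated:

* per-amplicon amplification efficiency (log-normal spread) and a
  designated low-yield dropout amplicon;
* per-position substitution noise, mostly sub-1% with a small fraction
  of systematically noisy positions;
* per-position indel noise, elevated geometrically with mononucleotide
  run length (flow-chemistry homopolymer errors) and capped;
* occasional positions with extreme (>95:5) strand bias;
* pseudogene-like regions of the diploid gene where co-mapping reads
  from a highly similar locus depress the apparent minor allele toward
  the 25% calling cut-off;
* injected substitutions, small indels, heterozygous polymorphisms and
  single/multi-amplicon gross deletions, all recorded in a ground-truth
  manifest.

Identical config + seed reproduces byte-identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .io_formats import (
    Amplicon,
    MutationRecord,
    PileupColumn,
    PopulationFrequencyRecord,
    TargetRegion,
    write_amplicons,
    write_fasta,
    write_mutation_db,
    write_pileup,
    write_population_freqs,
)
from .pileup_stats import SampleLibrary

_BASES = "ACGT"
#: Transition map used when choosing alternate alleles deterministically.
_ALT_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSpec:
    """Panel gene: name, chromosome, ploidy and amplicon layout."""

    name: str
    chrom: str
    ploidy: int
    n_exons: int
    n_amplicons: int
    offset: int  # chromosome coordinate where the gene starts


DEFAULT_GENES: tuple[GeneSpec, ...] = (
    GeneSpec("F8", "chrX", 1, 26, 56, 10_000),
    GeneSpec("F9", "chrX", 1, 8, 12, 40_000),
    GeneSpec("VWF", "chr12", 2, 52, 55, 10_000),
)


@dataclass(frozen=True)
class VariantSpec:
    """An injected small lesion, positioned relative to its gene.

    ``locus`` is a fraction in [0, 1) mapped onto the gene's targeted
    positions (adjusted off homopolymer runs and collisions), or the
    string ``"polyT"`` to target the gene's embedded poly-T stretch.
    """

    sample_id: str
    gene: str
    kind: str  # "substitution" | "insertion" | "deletion"
    zygosity: str  # "hemizygous" | "heterozygous"
    locus: float | str
    length: int = 1
    hgvs_c: str = ""
    consequence: str = ""
    phenotype: str = ""
    n_reports: int = 0


@dataclass(frozen=True)
class DeletionSpec:
    """An injected gross deletion covering an inclusive exon range."""

    sample_id: str
    gene: str
    first_exon: int  # 1-based
    last_exon: int
    zygosity: str


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator, with the study-condition defaults.

    The noise defaults put the bulk of positions below 1% substitution
    and indel noise with a small systematically-noisy tail, keep
    per-position average alternative/indel frequencies below 10%/15%,
    give ~0.5% of positions extreme strand bias, and push the apparent
    minor allele in the pseudogene-like regions toward the 25% cut-off.
    """

    n_samples: int = 24
    genes: tuple[GeneSpec, ...] = DEFAULT_GENES
    amplicon_len: int = 88
    target_depth: float = 2000.0
    efficiency_sigma: float = 0.5
    sample_sigma: float = 0.1
    dropout_efficiency: float = 0.03
    dropout_gene: str = "VWF"
    dropout_exon: int = 15
    # substitution noise: bulk Beta plus a noisy tail
    sub_noise_a: float = 2.0
    sub_noise_b: float = 398.0
    noisy_fraction: float = 0.005
    noisy_range: tuple[float, float] = (0.03, 0.08)
    # indel noise with homopolymer elevation
    indel_noise_a: float = 2.0
    indel_noise_b: float = 398.0
    homopolymer_factor: float = 2.0
    homopolymer_onset: int = 4
    indel_cap: float = 0.08
    # strand bias
    strand_bias_fraction: float = 0.005
    strand_bias_level: float = 0.97
    # depressed / pseudogene-contaminated regions (diploid gene only)
    pseudogene_fraction: float = 0.45
    mild_depression_fraction: float = 0.15
    n_pseudogene_regions: int = 2
    n_mild_regions: int = 2
    # polymorphisms on the diploid gene
    n_polymorphic: int = 40
    het_prob: float = 0.4
    hom_alt_prob: float = 0.1
    # companion tables
    extra_db_points: int = 300
    extra_db_indels: int = 120
    n_rare_popfreq: int = 20
    # injections
    variants: tuple[VariantSpec, ...] = ()
    deletions: tuple[DeletionSpec, ...] = ()
    sample_ids: tuple[str, ...] | None = None
    seed: int = 0

    def resolve_sample_ids(self) -> list[str]:
        if self.sample_ids is not None:
            if len(self.sample_ids) != self.n_samples:
                raise ConfigError("sample_ids length != n_samples")
            return list(self.sample_ids)
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    def gene_map(self) -> dict[str, GeneSpec]:
        return {g.name: g for g in self.genes}

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["genes"] = [asdict(g) for g in self.genes]
        data["variants"] = [asdict(v) for v in self.variants]
        data["deletions"] = [asdict(d) for d in self.deletions]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["genes"] = tuple(GeneSpec(**g) for g in data.get("genes", []))
        data["variants"] = tuple(VariantSpec(**v) for v in data.get("variants", []))
        data["deletions"] = tuple(DeletionSpec(**d) for d in data.get("deletions", []))
        for key in ("noisy_range",):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        if data.get("sample_ids") is not None:
            data["sample_ids"] = tuple(data["sample_ids"])
        return cls(**data)


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

@dataclass
class Panel:
    """A simulated panel: reference, regions, amplicons and per-position
    annotation arrays (parallel to the targeted-position layout, which
    is per gene, left to right)."""

    reference: dict[str, str]
    regions: list[TargetRegion]
    amplicons: list[Amplicon]
    amp_exon: list[int]  # 1-based exon index per amplicon
    chrom_arr: np.ndarray  # object: chromosome per targeted position
    pos_arr: np.ndarray  # int: 1-based position
    gene_arr: np.ndarray  # object: gene symbol
    amp_idx: np.ndarray  # int: index into amplicons
    ref_idx: np.ndarray  # int: 0..3 reference base index
    run_len: np.ndarray  # int: mononucleotide run length at the position
    gene_slices: dict[str, slice]
    homopolymers: list[tuple[str, str, int, int]]  # (gene, chrom, start0, length)
    polyT: dict[str, tuple[str, int, int]]  # gene -> (chrom, start0, length)
    dropout_amplicons: set[str]

    @property
    def n_positions(self) -> int:
        return len(self.pos_arr)

    def gene_ploidy(self, config: SimulationConfig) -> dict[str, int]:
        return {g.name: g.ploidy for g in config.genes}

    def amplicons_for_exons(
        self, gene: str, first_exon: int, last_exon: int
    ) -> list[int]:
        """Indices of the amplicons covering an inclusive exon range."""
        return [
            i
            for i, (a, ex) in enumerate(zip(self.amplicons, self.amp_exon))
            if a.gene == gene and first_exon <= ex <= last_exon
        ]


def _distribute(n: int, k: int) -> list[int]:
    base, rem = divmod(n, k)
    return [base + 1] * rem + [base] * (k - rem)


def _run_lengths(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int32)
    i = 0
    for _, group in itertools.groupby(seq):
        n = len(list(group))
        out[i : i + n] = n
        i += n
    return out


def simulate_panel(config: SimulationConfig, rng: np.random.Generator) -> Panel:
    """Generate reference, exon regions and tiling amplicons.

    Exons of each gene are laid out left to right with short intron
    gaps; each exon is tiled exactly by 1-3 non-overlapping amplicon
    inserts assigned to alternating pools.  Mononucleotide runs of
    lengths 6-9 are embedded in exonic sequence of every gene (including
    a guaranteed poly-T stretch of 9 in each gene), emulating the
    homopolymer contexts that dominate flow-chemistry indel errors.  One
    designated amplicon (by default the diploid gene's exon 15) is a
    low-yield dropout.
    """
    regions: list[TargetRegion] = []
    amplicons: list[Amplicon] = []
    amp_exon: list[int] = []
    dropout: set[str] = set()
    chrom_len: dict[str, int] = {}
    gene_layouts: dict[str, list[tuple[int, int, int]]] = {}  # gene -> (exon, start, end)

    for gene in config.genes:
        if gene.n_amplicons < gene.n_exons:
            raise ConfigError(
                f"{gene.name}: cannot tile {gene.n_exons} exons with "
                f"{gene.n_amplicons} amplicons"
            )
        per_exon = _distribute(gene.n_amplicons, gene.n_exons)
        cursor = gene.offset
        layout = []
        amp_counter = 0
        for exon_i, n_amp in enumerate(per_exon, start=1):
            exon_start = cursor
            for _ in range(n_amp):
                amp_counter += 1
                amp_id = f"{gene.name}_amp{amp_counter:03d}"
                amplicons.append(
                    Amplicon(
                        id=amp_id,
                        chrom=gene.chrom,
                        start=cursor,
                        end=cursor + config.amplicon_len,
                        pool=amp_counter % 2,
                        gene=gene.name,
                    )
                )
                amp_exon.append(exon_i)
                if (
                    gene.name == config.dropout_gene
                    and exon_i == config.dropout_exon
                ):
                    dropout.add(amp_id)
                cursor += config.amplicon_len
            regions.append(
                TargetRegion(
                    gene.chrom,
                    exon_start,
                    cursor,
                    gene.name,
                    f"{gene.name}_ex{exon_i}",
                )
            )
            layout.append((exon_i, exon_start, cursor))
            cursor += 150 + int(rng.integers(0, 101))  # intron gap
        gene_layouts[gene.name] = layout
        chrom_len[gene.chrom] = max(chrom_len.get(gene.chrom, 0), cursor + 100)

    # reference sequences
    reference = {
        chrom: "".join(
            _BASES[i] for i in rng.integers(0, 4, size=length)
        )
        for chrom, length in sorted(chrom_len.items())
    }

    # embed homopolymer runs inside exons (guaranteed lengths 6-9, with a
    # 9-long poly-T per gene)
    homopolymers: list[tuple[str, str, int, int]] = []
    polyT: dict[str, tuple[str, int, int]] = {}
    seq_mut = {chrom: list(seq) for chrom, seq in reference.items()}
    for gene in config.genes:
        layout = gene_layouts[gene.name]
        runs = [("T", 9), ("A", 6), ("C", 7), ("G", 8)]
        occupied: list[tuple[int, int]] = []
        for base, length in runs:
            run_start = None
            for _attempt in range(200):
                _, start, end = layout[int(rng.integers(0, len(layout)))]
                margin = 10
                lo, hi = start + margin, end - margin - length
                if hi <= lo:
                    continue
                cand = int(rng.integers(lo, hi))
                if all(
                    cand + length + 2 <= s or cand >= e + 2
                    for s, e in occupied
                ):
                    run_start = cand
                    break
            if run_start is None:
                raise ConfigError("exons too short to embed homopolymer runs")
            occupied.append((run_start, run_start + length))
            # pad neighbours so the embedded run has its exact length
            if run_start > 0:
                seq_mut[gene.chrom][run_start - 1] = _ALT_OF[base]
            if run_start + length < len(seq_mut[gene.chrom]):
                seq_mut[gene.chrom][run_start + length] = _ALT_OF[base]
            for k in range(length):
                seq_mut[gene.chrom][run_start + k] = base
            homopolymers.append((gene.name, gene.chrom, run_start, length))
            if base == "T" and length == 9:
                polyT[gene.name] = (gene.chrom, run_start, length)
    reference = {chrom: "".join(chars) for chrom, chars in seq_mut.items()}
    run_by_chrom = {chrom: _run_lengths(seq) for chrom, seq in reference.items()}

    # per-position arrays (gene by gene, left to right)
    chroms: list[str] = []
    poss: list[int] = []
    genes: list[str] = []
    amps: list[int] = []
    gene_slices: dict[str, slice] = {}
    amp_of: dict[tuple[str, int], int] = {}
    for i, a in enumerate(amplicons):
        for pos in a.positions():
            amp_of[(a.chrom, pos)] = i
    cursor = 0
    for gene in config.genes:
        start_idx = cursor
        for _, ex_start, ex_end in gene_layouts[gene.name]:
            for pos in range(ex_start + 1, ex_end + 1):
                chroms.append(gene.chrom)
                poss.append(pos)
                genes.append(gene.name)
                amps.append(amp_of[(gene.chrom, pos)])
                cursor += 1
        gene_slices[gene.name] = slice(start_idx, cursor)

    pos_arr = np.asarray(poss, dtype=np.int64)
    chrom_arr = np.asarray(chroms, dtype=object)
    gene_arr = np.asarray(genes, dtype=object)
    amp_idx = np.asarray(amps, dtype=np.int64)
    ref_idx = np.asarray(
        [_BASES.index(reference[c][p - 1]) for c, p in zip(chroms, poss)],
        dtype=np.int64,
    )
    run_len = np.asarray(
        [run_by_chrom[c][p - 1] for c, p in zip(chroms, poss)], dtype=np.int64
    )
    return Panel(
        reference=reference,
        regions=regions,
        amplicons=amplicons,
        amp_exon=amp_exon,
        chrom_arr=chrom_arr,
        pos_arr=pos_arr,
        gene_arr=gene_arr,
        amp_idx=amp_idx,
        ref_idx=ref_idx,
        run_len=run_len,
        gene_slices=gene_slices,
        homopolymers=homopolymers,
        polyT=polyT,
        dropout_amplicons=dropout,
    )


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResolvedVariant:
    sample_id: str
    gene: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str  # base, "+<seq>" or "-<seq>"
    kind: str
    zygosity: str
    index: int  # position index into the panel arrays
    length: int = 1
    hgvs_c: str = ""
    consequence: str = ""
    phenotype: str = ""
    n_reports: int = 0


@dataclass(frozen=True)
class ResolvedDeletion:
    sample_id: str
    gene: str
    zygosity: str
    amplicon_ids: tuple[str, ...]
    first_exon: int
    last_exon: int


@dataclass
class CohortTruth:
    """Everything a downstream test needs to score the pipeline."""

    config: SimulationConfig
    variants: list[ResolvedVariant]
    deletions: list[ResolvedDeletion]
    polymorphic: list[dict]  # chrom, pos, index, ref, alt, af
    genotypes: dict[str, dict[tuple[str, int], tuple[str, str]]]
    noise: dict[str, np.ndarray]  # e_sub, p_indel, p_strand, f_cont
    efficiencies: np.ndarray  # per amplicon
    sample_factors: dict[str, float]

    def expected_positions(self, sample_id: str) -> set[tuple[str, int]]:
        """Positions where a >= 25% non-reference allele is expected for
        a sample: injected small lesions plus non-hom-ref polymorphic
        genotypes (including the depressed pseudogene heterozygotes,
        whose minor allele sits near the cut-off)."""
        expected = {
            (v.chrom, v.pos)
            for v in self.variants
            if v.sample_id == sample_id
        }
        for (chrom, pos), (a1, a2) in self.genotypes.get(sample_id, {}).items():
            expected.add((chrom, pos))
        return expected


@dataclass
class Cohort:
    panel: Panel
    samples: list[SampleLibrary]
    truth: CohortTruth

    def sample(self, sample_id: str) -> SampleLibrary:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


# ---------------------------------------------------------------------------
# injection resolution
# ---------------------------------------------------------------------------

def _resolve_variants(
    config: SimulationConfig,
    panel: Panel,
    taken: set[int],
) -> list[ResolvedVariant]:
    resolved: list[ResolvedVariant] = []
    sample_ids = set(config.resolve_sample_ids())
    for spec in config.variants:
        if spec.sample_id not in sample_ids:
            raise ConfigError(f"injected variant for unknown sample {spec.sample_id}")
        if spec.gene not in panel.gene_slices:
            raise ConfigError(f"injected variant outside panel: gene {spec.gene}")
        sl = panel.gene_slices[spec.gene]
        if spec.locus == "polyT":
            chrom, start0, length = panel.polyT[spec.gene]
            target_pos = start0 + 1 + length // 2  # inside the run, 1-based
            idx = int(
                np.nonzero(
                    (panel.chrom_arr == chrom) & (panel.pos_arr == target_pos)
                )[0][0]
            )
        else:
            gene_len = sl.stop - sl.start
            idx = sl.start + int(float(spec.locus) * (gene_len - 1))
            # shift off homopolymer context and collisions
            guard = 0
            while (
                idx in taken
                or panel.run_len[idx] >= 4
                or (spec.kind == "deletion" and spec.length > 1
                    and idx + spec.length - 1 >= sl.stop)
            ):
                idx += 1
                guard += 1
                if idx >= sl.stop or guard > gene_len:
                    raise ConfigError(
                        f"could not place injected variant for {spec.sample_id}"
                    )
        chrom = str(panel.chrom_arr[idx])
        pos = int(panel.pos_arr[idx])
        ref = _BASES[panel.ref_idx[idx]]
        if spec.kind == "substitution":
            alt = _ALT_OF[ref]
        elif spec.kind == "insertion":
            base = panel.reference[chrom][pos - 1]
            alt = "+" + base * spec.length
        elif spec.kind == "deletion":
            seq = panel.reference[chrom][pos - 1 : pos - 1 + spec.length]
            alt = "-" + seq
        else:
            raise ConfigError(f"unknown variant kind {spec.kind!r}")
        for k in range(spec.length if spec.kind == "deletion" else 1):
            taken.add(idx + k)
        resolved.append(
            ResolvedVariant(
                sample_id=spec.sample_id,
                gene=spec.gene,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                kind=spec.kind,
                zygosity=spec.zygosity,
                index=idx,
                length=spec.length,
                hgvs_c=spec.hgvs_c,
                consequence=spec.consequence,
                phenotype=spec.phenotype,
                n_reports=spec.n_reports,
            )
        )
    return resolved


def _resolve_deletions(
    config: SimulationConfig, panel: Panel
) -> list[ResolvedDeletion]:
    resolved = []
    for spec in config.deletions:
        amp_indices = panel.amplicons_for_exons(
            spec.gene, spec.first_exon, spec.last_exon
        )
        if not amp_indices:
            raise ConfigError(
                f"gross deletion outside panel: {spec.gene} exons "
                f"{spec.first_exon}-{spec.last_exon}"
            )
        resolved.append(
            ResolvedDeletion(
                sample_id=spec.sample_id,
                gene=spec.gene,
                zygosity=spec.zygosity,
                amplicon_ids=tuple(panel.amplicons[i].id for i in amp_indices),
                first_exon=spec.first_exon,
                last_exon=spec.last_exon,
            )
        )
    return resolved


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate a full cohort: panel, per-sample pileup columns, truth."""
    rng = np.random.default_rng(config.seed)
    panel = simulate_panel(config, rng)
    n = panel.n_positions
    gene_map = config.gene_map()
    sample_ids = config.resolve_sample_ids()

    # --- systematic per-position noise profile (shared across samples)
    e_sub = rng.beta(config.sub_noise_a, config.sub_noise_b, size=n)
    noisy = rng.random(n) < config.noisy_fraction
    e_sub[noisy] = rng.uniform(*config.noisy_range, size=int(noisy.sum()))
    # error split over the three non-reference bases
    w_raw = rng.gamma(2.0, size=(n, 3))
    w_raw /= w_raw.sum(axis=1, keepdims=True)
    err_w = np.zeros((n, 4))
    for b in range(4):
        mask = panel.ref_idx == b
        others = [x for x in range(4) if x != b]
        for k, o in enumerate(others):
            err_w[mask, o] = w_raw[mask, k]

    mult = config.homopolymer_factor ** np.clip(
        panel.run_len - config.homopolymer_onset, 0, None
    )
    p_indel = np.minimum(
        rng.beta(config.indel_noise_a, config.indel_noise_b, size=n) * mult,
        config.indel_cap,
    )
    ins_share = rng.uniform(0.3, 0.7, size=n)

    p_strand = np.full(n, 0.5)
    biased = rng.random(n) < config.strand_bias_fraction
    direction = rng.random(int(biased.sum())) < 0.5
    levels = np.where(
        direction, config.strand_bias_level, 1.0 - config.strand_bias_level
    )
    p_strand[biased] = levels

    # --- depressed/pseudogene regions on the diploid gene(s)
    f_cont = np.zeros(n)
    diploid_genes = [g for g in config.genes if g.ploidy == 2]
    pseudo_indices: list[np.ndarray] = []
    for g in diploid_genes:
        exons = [
            (reg, i)
            for i, reg in enumerate(panel.regions)
            if reg.gene == g.name
        ]
        candidates = [
            reg
            for reg, _ in exons
            if not (g.name == config.dropout_gene
                    and reg.label.endswith(f"_ex{config.dropout_exon}"))
        ]
        k = config.n_pseudogene_regions + config.n_mild_regions
        if k and len(candidates) > k:
            chosen = rng.choice(len(candidates), size=k, replace=False)
            for j, reg_k in enumerate(chosen):
                reg = candidates[int(reg_k)]
                frac = (
                    config.pseudogene_fraction
                    if j < config.n_pseudogene_regions
                    else config.mild_depression_fraction
                )
                mask = (
                    (panel.chrom_arr == reg.chrom)
                    & (panel.pos_arr > reg.start)
                    & (panel.pos_arr <= reg.end)
                )
                f_cont[mask] = frac
                if j < config.n_pseudogene_regions:
                    pseudo_indices.append(np.nonzero(mask)[0])

    # --- amplicon efficiencies (normalized to mean 1, dropout overridden)
    eff = np.exp(
        rng.normal(0.0, config.efficiency_sigma, size=len(panel.amplicons))
    )
    eff /= eff.mean()
    for i, a in enumerate(panel.amplicons):
        if a.id in panel.dropout_amplicons:
            eff[i] = config.dropout_efficiency

    # --- sample factors (mean-1 log-normal)
    z = rng.normal(0.0, 1.0, size=len(sample_ids))
    factors = np.exp(config.sample_sigma * z - config.sample_sigma**2 / 2)
    sample_factors = dict(zip(sample_ids, factors.tolist()))

    # --- polymorphic sites on diploid genes (some inside pseudogene regions)
    taken: set[int] = set()
    polymorphic: list[dict] = []
    if diploid_genes and config.n_polymorphic > 0:
        pool: list[int] = []
        for g in diploid_genes:
            sl = panel.gene_slices[g.name]
            pool.extend(
                i
                for i in range(sl.start, sl.stop)
                if panel.run_len[i] < 4
            )
        forced: list[int] = []
        for idx_arr in pseudo_indices:
            clean = [int(i) for i in idx_arr if panel.run_len[i] < 4]
            if len(clean) >= 2:
                picks = rng.choice(len(clean), size=2, replace=False)
                forced.extend(clean[int(p)] for p in picks)
        remaining = [i for i in pool if i not in set(forced)]
        k = max(config.n_polymorphic - len(forced), 0)
        chosen = list(forced)
        if k and remaining:
            picks = rng.choice(len(remaining), size=min(k, len(remaining)),
                               replace=False)
            chosen.extend(remaining[int(p)] for p in picks)
        for idx in sorted(set(chosen)):
            taken.add(idx)
            ref = _BASES[panel.ref_idx[idx]]
            polymorphic.append(
                {
                    "chrom": str(panel.chrom_arr[idx]),
                    "pos": int(panel.pos_arr[idx]),
                    "index": idx,
                    "ref": ref,
                    "alt": _ALT_OF[ref],
                    "af": float(rng.uniform(0.02, 0.4)),
                }
            )

    # --- resolve injections
    variants = _resolve_variants(config, panel, taken)
    deletions = _resolve_deletions(config, panel)
    del_by_sample: dict[str, list[ResolvedDeletion]] = {}
    for d in deletions:
        del_by_sample.setdefault(d.sample_id, []).append(d)
    var_by_sample: dict[str, list[ResolvedVariant]] = {}
    for v in variants:
        var_by_sample.setdefault(v.sample_id, []).append(v)

    amp_index = {a.id: i for i, a in enumerate(panel.amplicons)}

    # --- per-sample genotypes at polymorphic sites
    genotypes: dict[str, dict[tuple[str, int], tuple[str, str]]] = {}
    geno_code: dict[str, np.ndarray] = {}  # 0 hom-ref, 1 het, 2 hom-alt
    for sid in sample_ids:
        u = rng.random(len(polymorphic))
        code = np.zeros(len(polymorphic), dtype=np.int8)
        code[u < config.het_prob] = 1
        code[(u >= config.het_prob)
             & (u < config.het_prob + config.hom_alt_prob)] = 2
        # positions inside this sample's gross deletions revert to hom-ref
        deleted_amp = {
            amp_index[aid]
            for d in del_by_sample.get(sid, [])
            for aid in d.amplicon_ids
        }
        for k, site in enumerate(polymorphic):
            if code[k] and panel.amp_idx[site["index"]] in deleted_amp:
                code[k] = 0
        geno_code[sid] = code
        genotypes[sid] = {
            (site["chrom"], site["pos"]): (
                (site["ref"], site["alt"]) if code[k] == 1
                else (site["alt"], site["alt"])
            )
            for k, site in enumerate(polymorphic)
            if code[k]
        }

    truth = CohortTruth(
        config=config,
        variants=variants,
        deletions=deletions,
        polymorphic=polymorphic,
        genotypes=genotypes,
        noise={
            "e_sub": e_sub,
            "p_indel": p_indel,
            "ins_share": ins_share,
            "p_strand": p_strand,
            "f_cont": f_cont,
            "run_len": panel.run_len.astype(float),
        },
        efficiencies=eff,
        sample_factors=sample_factors,
    )

    # --- simulate each sample
    gene_ploidy = {g.name: g.ploidy for g in config.genes}
    ref_onehot = np.zeros((n, 4))
    ref_onehot[np.arange(n), panel.ref_idx] = 1.0
    samples: list[SampleLibrary] = []
    for sid in sample_ids:
        lib = _simulate_sample(
            sid,
            panel,
            config,
            rng,
            e_sub=e_sub,
            err_w=err_w,
            p_indel=p_indel,
            ins_share=ins_share,
            p_strand=p_strand,
            f_cont=f_cont,
            eff=eff,
            factor=sample_factors[sid],
            ref_onehot=ref_onehot,
            polymorphic=polymorphic,
            geno_code=geno_code[sid],
            inj_variants=var_by_sample.get(sid, []),
            inj_deletions=del_by_sample.get(sid, []),
            amp_index=amp_index,
            gene_ploidy=gene_ploidy,
        )
        samples.append(lib)
    return Cohort(panel=panel, samples=samples, truth=truth)


def _simulate_sample(
    sample_id: str,
    panel: Panel,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    e_sub: np.ndarray,
    err_w: np.ndarray,
    p_indel: np.ndarray,
    ins_share: np.ndarray,
    p_strand: np.ndarray,
    f_cont: np.ndarray,
    eff: np.ndarray,
    factor: float,
    ref_onehot: np.ndarray,
    polymorphic: list[dict],
    geno_code: np.ndarray,
    inj_variants: list[ResolvedVariant],
    inj_deletions: list[ResolvedDeletion],
    amp_index: dict[str, int],
    gene_ploidy: dict[str, int],
) -> SampleLibrary:
    n = panel.n_positions
    # genotype allele probabilities
    g = ref_onehot.copy()
    for k, site in enumerate(polymorphic):
        if geno_code[k] == 0:
            continue
        idx = site["index"]
        alt_i = _BASES.index(site["alt"])
        g[idx] = 0.0
        if geno_code[k] == 1:
            g[idx, panel.ref_idx[idx]] = 0.5
            g[idx, alt_i] = 0.5
        else:
            g[idx, alt_i] = 1.0

    p_ins = p_indel * ins_share
    p_del = p_indel * (1.0 - ins_share)
    ins_seq_at: dict[int, str] = {}

    for v in inj_variants:
        idx = v.index
        if v.kind == "substitution":
            alt_i = _BASES.index(v.alt)
            g[idx] = 0.0
            if v.zygosity == "heterozygous":
                g[idx, panel.ref_idx[idx]] = 0.5
                g[idx, alt_i] = 0.5
            else:
                g[idx, alt_i] = 1.0
        elif v.kind == "insertion":
            frac = 0.5 if v.zygosity == "heterozygous" else 0.97
            p_ins[idx] = frac
            ins_seq_at[idx] = v.alt[1:]
        elif v.kind == "deletion":
            frac = 0.5 if v.zygosity == "heterozygous" else 0.97
            for k in range(v.length):
                p_del[idx + k] = frac

    # gross deletions scale expected depth
    depth_scale = np.ones(n)
    for d in inj_deletions:
        amp_ids = {amp_index[aid] for aid in d.amplicon_ids}
        mask = np.isin(panel.amp_idx, list(amp_ids))
        depth_scale[mask] = 0.0 if d.zygosity == "hemizygous" else 0.5

    # contamination from a pseudogene-like locus carrying the reference
    # haplotype: dilutes true alleles toward the reference
    p = (1.0 - e_sub)[:, None] * g + e_sub[:, None] * err_w
    p = f_cont[:, None] * ref_onehot + (1.0 - f_cont)[:, None] * p
    p /= p.sum(axis=1, keepdims=True)

    depth = rng.poisson(config.target_depth * eff[panel.amp_idx] * factor
                        * depth_scale)
    del_span = rng.binomial(depth, np.minimum(p_del, 1.0))
    base_n = depth - del_span
    counts = rng.multinomial(base_n, p)
    fwd = rng.binomial(counts, p_strand[:, None])
    ins = rng.binomial(base_n, np.minimum(p_ins, 1.0))

    columns: dict[tuple[str, int], PileupColumn] = {}
    chrom_arr = panel.chrom_arr
    pos_arr = panel.pos_arr
    ref_idx = panel.ref_idx
    run_len = panel.run_len
    from collections import Counter

    for i in range(n):
        d = int(depth[i])
        if d == 0:
            continue
        fwd_counts = {}
        rev_counts = {}
        for b in range(4):
            c = int(counts[i, b])
            if c == 0:
                continue
            f = int(fwd[i, b])
            if f:
                fwd_counts[_BASES[b]] = f
            if c - f:
                rev_counts[_BASES[b]] = c - f
        ins_i = int(ins[i])
        ins_seqs: Counter = Counter()
        if ins_i:
            seq = ins_seq_at.get(
                i,
                panel.reference[chrom_arr[i]][pos_arr[i] - 1]
                if run_len[i] >= 4
                else "A",
            )
            ins_seqs[seq] = ins_i
        columns[(chrom_arr[i], int(pos_arr[i]))] = PileupColumn(
            chrom=chrom_arr[i],
            pos=int(pos_arr[i]),
            ref_base=_BASES[ref_idx[i]],
            fwd_counts=fwd_counts,
            rev_counts=rev_counts,
            del_span=int(del_span[i]),
            ins_anchor=ins_i,
            depth=d,
            ins_seqs=ins_seqs,
        )
    return SampleLibrary(
        sample_id=sample_id, columns=columns, genes=dict(gene_ploidy)
    )


# ---------------------------------------------------------------------------
# companion tables (population frequencies, mutation database)
# ---------------------------------------------------------------------------

def population_table(cohort: Cohort) -> list[PopulationFrequencyRecord]:
    """ExAC-NFE-style records: the panel's common polymorphisms (AF as
    simulated) plus a few rare decoy alleles below the 1% filter."""
    records = [
        PopulationFrequencyRecord(
            chrom=s["chrom"], pos=s["pos"], ref=s["ref"], alt=s["alt"],
            af=s["af"],
        )
        for s in cohort.truth.polymorphic
    ]
    seen = {(r.chrom, r.pos, r.ref, r.alt) for r in records}
    rng = np.random.default_rng(cohort.truth.config.seed + 104729)
    panel = cohort.panel
    guard = 0
    while (
        len(records) - len(cohort.truth.polymorphic)
        < cohort.truth.config.n_rare_popfreq
        and guard < 10_000
    ):
        guard += 1
        idx = int(rng.integers(0, panel.n_positions))
        ref = _BASES[panel.ref_idx[idx]]
        alt = _ALT_OF[ref]
        key = (str(panel.chrom_arr[idx]), int(panel.pos_arr[idx]), ref, alt)
        if key in seen:
            continue
        seen.add(key)
        records.append(
            PopulationFrequencyRecord(
                chrom=key[0], pos=key[1], ref=ref, alt=alt,
                af=float(rng.uniform(0.001, 0.009)),
            )
        )
    return sorted(records, key=lambda r: (r.chrom, r.pos, r.alt))


def mutation_table(cohort: Cohort) -> list[MutationRecord]:
    """Locus-database-style records: one per injected small lesion, plus
    extra point/indel positional entries so the database covers many
    positions no patient is mutated at (as real locus databases do)."""
    records = [
        MutationRecord(
            chrom=v.chrom,
            pos=v.pos,
            ref=v.ref,
            alt=v.alt,
            hgvs_c=v.hgvs_c,
            consequence=v.consequence
            or {"substitution": "Missense", "insertion": "Frameshift",
                "deletion": "Frameshift"}[v.kind],
            phenotype=v.phenotype,
            n_reports=v.n_reports,
        )
        for v in cohort.truth.variants
    ]
    cfg = cohort.truth.config
    panel = cohort.panel
    rng = np.random.default_rng(cfg.seed + 224737)
    used = {(r.chrom, r.pos) for r in records}
    for kind, count in (("point", cfg.extra_db_points),
                        ("indel", cfg.extra_db_indels)):
        added = 0
        guard = 0
        while added < count and guard < 50 * max(count, 1):
            guard += 1
            idx = int(rng.integers(0, panel.n_positions))
            key = (str(panel.chrom_arr[idx]), int(panel.pos_arr[idx]))
            if key in used:
                continue
            used.add(key)
            ref = _BASES[panel.ref_idx[idx]]
            if kind == "point":
                alt = _ALT_OF[ref]
                consequence = "Missense"
            else:
                alt = ""  # purely positional indel entry
                consequence = "Frameshift"
            records.append(
                MutationRecord(
                    chrom=key[0],
                    pos=key[1],
                    ref=ref,
                    alt=alt,
                    hgvs_c="",
                    consequence=consequence,
                    phenotype="",
                    n_reports=int(rng.integers(1, 11)),
                )
            )
            added += 1
    return sorted(records, key=lambda r: (r.chrom, r.pos, r.alt))


# ---------------------------------------------------------------------------
# the reference patient scenario
# ---------------------------------------------------------------------------

def paper_scenario(seed: int = 0) -> SimulationConfig:
    """The frozen 24-patient validation cohort configuration.

    Eight patients per disorder (hemophilia A: F8, hemizygous;
    hemophilia B: F9, hemizygous; VWD: VWF, diploid): 18 substitutions,
    3 small indels — one a single-base duplication inside the poly-T
    homopolymer stretch — and 3 gross deletions (a heterozygous
    multi-exon VWF deletion, a hemizygous whole-F9 deletion and a
    hemizygous F8 exon 1-12 deletion).  Three of the hemophilia patients
    additionally carry a heterozygous VWF missense variant.
    """
    v = VariantSpec
    variants = (
        # hemophilia A: F8, hemizygous
        v("HA_208", "F8", "insertion", "hemizygous", "polyT", 1,
          "c.3637dupA", "Frameshift", "Mild-Severe", 32),
        v("HA_365", "F8", "deletion", "hemizygous", 0.43, 1,
          "c.3640del", "Frameshift", "-", 0),
        v("HA_398", "F8", "substitution", "hemizygous", 0.05, 1,
          "c.67A>G", "Missense", "Mild", 2),
        v("HA_408", "F8", "substitution", "hemizygous", 0.62, 1,
          "c.5381T>A", "Missense", "-", 0),
        v("HA_432", "F8", "substitution", "hemizygous", 0.12, 1,
          "c.923C>T", "Missense", "Severe", 28),
        v("HA_448", "F8", "deletion", "hemizygous", 0.35, 1,
          "c.3134delC", "Frameshift", "-", 0),
        v("HA_459", "F8", "substitution", "hemizygous", 0.75, 1,
          "c.5393C>T", "Missense", "Moderate", 1),
        # hemophilia B: F9, hemizygous
        v("HB_130", "F9", "substitution", "hemizygous", 0.40, 1,
          "c.572G>A", "Missense", "Mild-Severe", 85),
        v("HB_132", "F9", "substitution", "hemizygous", 0.06, 1,
          "c.82T>C", "Missense", "Mild-Moderate", 5),
        v("HB_135", "F9", "substitution", "hemizygous", 0.55, 1,
          "c.785T>C", "Missense", "Mild-Moderate", 6),
        v("HB_136", "F9", "substitution", "hemizygous", 0.32, 1,
          "c.459G>A", "Silent", "Mild", 6),
        v("HB_138", "F9", "substitution", "hemizygous", 0.79, 1,
          "c.1135C>T", "Nonsense", "Mild-Severe", 65),
        v("HB_139", "F9", "substitution", "hemizygous", 0.90, 1,
          "c.1289G>T", "Missense", "Moderate", 1),
        v("HB_140", "F9", "substitution", "hemizygous", 0.07, 1,
          "c.83G>A", "Missense", "Moderate-Severe", 9),
        # von Willebrand disease: VWF, heterozygous
        v("VWF_140", "VWF", "substitution", "heterozygous", 0.60, 1,
          "c.5014G>A", "Missense", "Type 2A", 1),
        v("VWF_159", "VWF", "substitution", "heterozygous", 0.49, 1,
          "c.4120C>T", "Missense", "Type 1, 2A, 2M", 7),
        v("VWF_166", "VWF", "substitution", "heterozygous", 0.90, 1,
          "c.7603C>T", "Nonsense", "Type 3", 4),
        v("VWF_172", "VWF", "substitution", "heterozygous", 0.59, 1,
          "c.4975C>T", "Nonsense", "Type 3", 10),
        v("VWF_189", "VWF", "substitution", "heterozygous", 0.54, 1,
          "c.4517C>T", "Missense", "Type 2A", 14),
        v("VWF_238", "VWF", "substitution", "heterozygous", 0.27, 1,
          "c.2278C>T", "Missense", "Type 2N", 1),
        v("VWF_280", "VWF", "substitution", "heterozygous", 0.88, 1,
          "c.7430G>C", "Missense", "Type 1", 1),
        # additional heterozygous VWF variants in hemophilia patients
        v("HA_459", "VWF", "substitution", "heterozygous", 0.65, 1,
          "c.5453A>G", "Missense", "Type 1", 1),
        v("HB_135", "VWF", "substitution", "heterozygous", 0.96, 1,
          "c.8084C>G", "Missense", "Unclassified", 1),
        v("HB_138", "VWF", "substitution", "heterozygous", 0.94, 1,
          "c.7940C>T", "Missense", "Type 1", 2),
    )
    deletions = (
        DeletionSpec("HA_420", "F8", 1, 12, "hemizygous"),
        DeletionSpec("HB_129", "F9", 1, 8, "hemizygous"),
        DeletionSpec("VWF_25", "VWF", 14, 52, "heterozygous"),
    )
    sample_ids = tuple(
        ["HA_208", "HA_365", "HA_398", "HA_408", "HA_420", "HA_432",
         "HA_448", "HA_459",
         "HB_129", "HB_130", "HB_132", "HB_135", "HB_136", "HB_138",
         "HB_139", "HB_140",
         "VWF_25", "VWF_140", "VWF_159", "VWF_166", "VWF_172", "VWF_189",
         "VWF_238", "VWF_280"]
    )
    return SimulationConfig(
        n_samples=24,
        sample_ids=sample_ids,
        variants=variants,
        deletions=deletions,
        seed=seed,
    )


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A scaled-down panel (same structure, ~15 amplicons, shallower
    depth) for quick exploration and fast tests."""
    genes = (
        GeneSpec("F8", "chrX", 1, 4, 7, 2_000),
        GeneSpec("F9", "chrX", 1, 2, 3, 8_000),
        GeneSpec("VWF", "chr12", 2, 4, 5, 2_000),
    )
    defaults = dict(
        n_samples=6,
        genes=genes,
        amplicon_len=60,
        target_depth=400.0,
        dropout_exon=3,
        n_polymorphic=8,
        extra_db_points=30,
        extra_db_indels=12,
        n_rare_popfreq=5,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_cohort(
    cohort: Cohort, outdir: str | Path, write_pileups: bool = True
) -> dict[str, Path]:
    """Write the cohort to disk: reference FASTA, targets BED, amplicon
    TSV, per-sample mpileup text, population-frequency and mutation
    tables, ground-truth TSVs and the config (with seed) as YAML."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["reference"] = out / "reference.fa"
    write_fasta(cohort.panel.reference, paths["reference"])

    paths["targets"] = out / "targets.bed"
    with open(paths["targets"], "w") as fh:
        for reg in cohort.panel.regions:
            fh.write(f"{reg.chrom}\t{reg.start}\t{reg.end}\t{reg.label}\n")

    paths["amplicons"] = out / "amplicons.tsv"
    write_amplicons(cohort.panel.amplicons, paths["amplicons"])

    paths["popfreq"] = out / "popfreq.tsv"
    write_population_freqs(population_table(cohort), paths["popfreq"])

    paths["mutation_db"] = out / "mutation_db.tsv"
    write_mutation_db(mutation_table(cohort), paths["mutation_db"])

    if write_pileups:
        pdir = out / "pileups"
        pdir.mkdir(exist_ok=True)
        for sample in cohort.samples:
            p = pdir / f"{sample.sample_id}.mpileup"
            cols = [sample.columns[k] for k in sorted(sample.columns)]
            write_pileup(cols, p)
        paths["pileups"] = pdir

    tdir = out / "truth"
    tdir.mkdir(exist_ok=True)
    import pandas as pd

    pd.DataFrame(
        [
            {
                "sample_id": v.sample_id, "gene": v.gene, "chrom": v.chrom,
                "pos": v.pos, "ref": v.ref, "alt": v.alt, "kind": v.kind,
                "zygosity": v.zygosity, "hgvs_c": v.hgvs_c,
            }
            for v in cohort.truth.variants
        ]
    ).to_csv(tdir / "variants.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "sample_id": d.sample_id, "gene": d.gene,
                "zygosity": d.zygosity,
                "first_exon": d.first_exon, "last_exon": d.last_exon,
                "amplicons": ",".join(d.amplicon_ids),
            }
            for d in cohort.truth.deletions
        ]
    ).to_csv(tdir / "deletions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"sample_id": sid, "chrom": c, "pos": p,
             "allele1": a1, "allele2": a2}
            for sid, sites in sorted(cohort.truth.genotypes.items())
            for (c, p), (a1, a2) in sorted(sites.items())
        ]
    ).to_csv(tdir / "genotypes.tsv", sep="\t", index=False)
    noise_df = pd.DataFrame(
        {
            "chrom": cohort.panel.chrom_arr,
            "pos": cohort.panel.pos_arr,
            "gene": cohort.panel.gene_arr,
            **{k: v for k, v in cohort.truth.noise.items()},
        }
    )
    noise_df.to_csv(tdir / "noise.tsv", sep="\t", index=False)
    paths["truth"] = tdir

    paths["config"] = out / "config.yaml"
    cohort.truth.config.to_yaml(paths["config"])
    return paths
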