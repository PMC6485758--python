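"""Readers and writers for the external formats touched by the pipeline.

Formats handled here:

* BED files describing the targeted exonic regions (0-based, half-open).
* ``samtools mpileup`` text, one column per targeted position, with
  strand-resolved base calls, insertion/deletion descriptors, read
  start/end marks and reference skips.
* TSV tables with a header row for population allele frequencies
  (ExAC-NFE style: chrom, pos, ref, alt, af) and for locus-specific
  mutation databases (chrom, pos, ref, alt, hgvs_c, consequence,
  phenotype, n_reports).
* Variant report output as TSV and as a minimal VCF 4.2.

Coordinate conventions: BED input is 0-based half-open; every other
format in the package (pileup, reports, VCF) is 1-based.  Conversions
happen only in this module.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import IntegrityError, ParseError, ValidationError

#: Canonical nucleotide alphabet used for allele-level statistics.
BASES = ("A", "C", "G", "T")
#: Alphabet accepted in pileup base columns ('N' is a valid call but is
#: excluded from allele-frequency denominators downstream).
BASES_N = ("A", "C", "G", "T", "N")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetRegion:
    """One targeted interval (typically an exon plus flanking bases).

    ``start``/``end`` are 0-based half-open, as in the BED source.
    ``gene`` is the gene symbol, ``label`` the free-text name column
    (e.g. ``"F8_ex1"``).
    """

    chrom: str
    start: int
    end: int
    gene: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("TargetRegion requires a chromosome name")
        if self.start >= self.end:
            raise ValidationError(
                f"TargetRegion {self.chrom}:{self.start}-{self.end}: start >= end"
            )

    def positions(self) -> range:
        """1-based positions covered by this region."""
        return range(self.start + 1, self.end + 1)


@dataclass(frozen=True)
class Amplicon:
    """One multiplex-PCR amplicon insert (0-based half-open coordinates)."""

    id: str
    chrom: str
    start: int
    end: int
    pool: int = 0
    gene: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"Amplicon {self.id}: start >= end")

    def positions(self) -> range:
        return range(self.start + 1, self.end + 1)


@dataclass(slots=True)
class PileupColumn:
    """Strand-resolved base and indel counts at one position of one sample.

    ``fwd_counts``/``rev_counts`` map base -> count on the forward and
    reverse strand.  ``del_span`` counts reads whose deletion spans this
    position ('*' / '#' marks); ``ins_anchor`` counts reads with an
    insertion anchored immediately after this position.  ``ref_skips``
    counts '>'/'<' reference-skip marks, which contribute to the depth
    field but are neither base calls nor indel events.

    Invariant: ``sum(fwd) + sum(rev) + del_span + ref_skips == depth``.
    """

    chrom: str
    pos: int  # 1-based
    ref_base: str
    fwd_counts: dict
    rev_counts: dict
    del_span: int = 0
    ins_anchor: int = 0
    ref_skips: int = 0
    depth: int = 0
    ins_seqs: Counter = field(default_factory=Counter)
    del_seqs: Counter = field(default_factory=Counter)

    def base_calls(self) -> int:
        """Number of base calls (both strands, any base, excluding '*')."""
        return sum(self.fwd_counts.values()) + sum(self.rev_counts.values())

    def acgt_counts(self) -> dict:
        """Strand-summed A/C/G/T counts ('N' excluded)."""
        return {
            b: self.fwd_counts.get(b, 0) + self.rev_counts.get(b, 0)
            for b in BASES
        }

    def validate(self) -> None:
        for counts in (self.fwd_counts, self.rev_counts):
            for base, c in counts.items():
                if base not in BASES_N:
                    raise ValidationError(f"unexpected base {base!r} at {self.pos}")
                if c < 0:
                    raise ValidationError(f"negative count at {self.pos}")
        if min(self.del_span, self.ins_anchor, self.ref_skips, self.depth) < 0:
            raise ValidationError(f"negative field at {self.pos}")
        got = self.base_calls() + self.del_span + self.ref_skips
        if got != self.depth:
            raise IntegrityError(
                f"{self.chrom}:{self.pos}: depth field {self.depth} does not "
                f"reconcile with parsed symbols ({got})"
            )


@dataclass(frozen=True)
class PopulationFrequencyRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    af: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.af <= 1.0:
            raise ValidationError(
                f"population AF {self.af} at {self.chrom}:{self.pos} outside [0, 1]"
            )


@dataclass(frozen=True)
class MutationRecord:
    """One entry of a locus-specific mutation database.

    ``alt`` may be empty for purely positional entries (e.g. a database
    row describing an indel by coordinate only).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    hgvs_c: str = ""
    consequence: str = ""
    phenotype: str = ""
    n_reports: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 0:
            raise ValidationError(
                f"mutation record at {self.chrom}:{self.pos}: negative n_reports"
            )


# ---------------------------------------------------------------------------
# BED targets
# ---------------------------------------------------------------------------

def _merge_regions(regions: list[TargetRegion]) -> list[TargetRegion]:
    """Merge overlapping/adjacent regions of the same (chrom, gene)."""
    out: list[TargetRegion] = []
    for reg in sorted(regions, key=lambda r: (r.chrom, r.gene, r.start, r.end)):
        if (
            out
            and out[-1].chrom == reg.chrom
            and out[-1].gene == reg.gene
            and reg.start <= out[-1].end
        ):
            prev = out.pop()
            label = prev.label if prev.label == reg.label else f"{prev.label};{reg.label}"
            reg = TargetRegion(
                prev.chrom, prev.start, max(prev.end, reg.end), prev.gene, label
            )
        out.append(reg)
    return sorted(out, key=lambda r: (r.chrom, r.start))


def read_bed(path: str | Path) -> list[TargetRegion]:
    """Read a BED file of targeted regions.

    Requires >= 3 tab/whitespace-separated columns per line; comment
    (``#``), ``track`` and ``browser`` lines are skipped.  The gene
    symbol is taken as the part of the name column before the first
    underscore (``F8_ex1`` -> gene ``F8``).  Returns regions sorted by
    (chrom, start), with overlapping same-gene regions merged.
    """
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ParseError(f"{path}: line {lineno}: start >= end")
            name = fields[3] if len(fields) > 3 else ""
            gene = name.split("_")[0] if name else ""
            regions.append(TargetRegion(chrom, start, end, gene, name))
    return _merge_regions(regions)


def region_positions(regions: Iterable[TargetRegion]) -> Iterator[tuple[str, int]]:
    """Iterate (chrom, 1-based position) over all targeted bases."""
    for reg in regions:
        for pos in reg.positions():
            yield reg.chrom, pos


# ---------------------------------------------------------------------------
# amplicon table
# ---------------------------------------------------------------------------

def read_amplicons(path: str | Path) -> list[Amplicon]:
    """Read the per-amplicon TSV (id, chrom, start, end, pool[, gene])."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"id", "chrom", "start", "end", "pool"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValidationError(f"{path}: duplicate amplicon id {dup!r}")
    amps = [
        Amplicon(
            id=str(row.id),
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            pool=int(row.pool),
            gene=str(getattr(row, "gene", "") or ""),
        )
        for row in df.itertuples(index=False)
    ]
    return amps


def write_amplicons(amplicons: Sequence[Amplicon], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "id": a.id,
                "chrom": a.chrom,
                "start": a.start,
                "end": a.end,
                "pool": a.pool,
                "gene": a.gene,
            }
            for a in amplicons
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mpileup parsing
# ---------------------------------------------------------------------------

def parse_pileup_column(line: str, check_depth: bool = True) -> PileupColumn:
    """Parse one ``samtools mpileup`` row into a :class:`PileupColumn`.

    The supported read-base symbols are the ones samtools emits:

    * ``.`` / ``,``: reference base call on the forward/reverse strand;
    * ``A C G T N`` / ``a c g t n``: mismatching call, case = strand;
    * ``^`` + one mapping-quality character: read start (both stripped);
    * ``$``: read end (stripped);
    * ``+N<seq>``: insertion of N bases anchored after this position,
      counted once in ``ins_anchor`` and the sequence recorded;
    * ``-N<seq>``: deletion descriptor at the anchor; consumed without
      incrementing counts at this position (the deleted positions carry
      the ``*`` marks), the sequence recorded;
    * ``*`` / ``#``: a read whose deletion spans this position
      (``del_span``);
    * ``>`` / ``<``: reference skip; counted in depth reconciliation
      only.

    Columns beyond the 6th (e.g. mapping qualities) are ignored.  With
    ``check_depth`` the reconciliation ``base calls + del_span +
    ref_skips == depth`` is enforced and an :class:`IntegrityError`
    raised on mismatch.  A truncated indel descriptor or an unexpected
    character raises :class:`ParseError`.
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 5:
        raise ParseError(f"pileup line has {len(fields)} fields, expected >= 5")
    chrom, pos_s, ref_s, depth_s, bases = fields[:5]
    try:
        pos = int(pos_s)
        depth = int(depth_s)
    except ValueError as exc:
        raise ParseError(f"non-integer pos/depth in pileup line at {chrom}") from exc
    ref_base = ref_s.upper()
    fwd: dict = {}
    rev: dict = {}
    del_span = 0
    ins_anchor = 0
    ref_skips = 0
    ins_seqs: Counter = Counter()
    del_seqs: Counter = Counter()

    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise ParseError(f"{chrom}:{pos}: truncated '^' mark")
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise ParseError(f"{chrom}:{pos}: indel descriptor without length")
            length = int(bases[i + 1 : j])
            seq = bases[j : j + length]
            if len(seq) < length or any(
                ch.upper() not in "ACGTN*" for ch in seq
            ):
                raise ParseError(f"{chrom}:{pos}: truncated indel descriptor")
            if c == "+":
                ins_anchor += 1
                ins_seqs[seq.upper()] += 1
            else:
                del_seqs[seq.upper()] += 1
            i = j + length
            continue
        if c == ".":
            fwd[ref_base] = fwd.get(ref_base, 0) + 1
        elif c == ",":
            rev[ref_base] = rev.get(ref_base, 0) + 1
        elif c in "*#":
            del_span += 1
        elif c in "><":
            ref_skips += 1
        elif c.upper() in BASES_N:
            target = fwd if c.isupper() else rev
            base = c.upper()
            target[base] = target.get(base, 0) + 1
        else:
            raise ParseError(f"{chrom}:{pos}: unexpected pileup symbol {c!r}")
        i += 1

    col = PileupColumn(
        chrom=chrom,
        pos=pos,
        ref_base=ref_base,
        fwd_counts=fwd,
        rev_counts=rev,
        del_span=del_span,
        ins_anchor=ins_anchor,
        ref_skips=ref_skips,
        depth=depth,
        ins_seqs=ins_seqs,
        del_seqs=del_seqs,
    )
    if check_depth:
        col.validate()
    return col


def read_pileup(path: str | Path, check_depth: bool = True) -> list[PileupColumn]:
    """Parse a whole mpileup file into a list of columns."""
    cols: list[PileupColumn] = []
    with open(path) as fh:
        for raw in fh:
            if raw.strip():
                cols.append(parse_pileup_column(raw, check_depth=check_depth))
    return cols


def format_pileup_column(col: PileupColumn, qual_char: str = "F") -> str:
    """Render a column back into a canonical mpileup line.

    Inverse of :func:`parse_pileup_column` up to symbol ordering: base
    calls are emitted reference-first then alternates in A<C<G<T<N
    order, insertion/deletion descriptors are attached to the leading
    base characters, deletion spans come last.  No '^'/'$' marks are
    emitted.  The quality string is ``qual_char`` repeated ``depth``
    times.
    """
    tokens: list[str] = []
    order = [col.ref_base] + [b for b in BASES_N if b != col.ref_base]
    for base in order:
        sym = "." if base == col.ref_base else base
        tokens.extend([sym] * col.fwd_counts.get(base, 0))
    for base in order:
        sym = "," if base == col.ref_base else base.lower()
        tokens.extend([sym] * col.rev_counts.get(base, 0))
    descriptors: list[str] = []
    for seq, count in sorted(col.ins_seqs.items()):
        descriptors.extend([f"+{len(seq)}{seq}"] * count)
    for seq, count in sorted(col.del_seqs.items()):
        descriptors.extend([f"-{len(seq)}{seq}"] * count)
    if len(descriptors) > len(tokens):
        raise IntegrityError(
            f"{col.chrom}:{col.pos}: more indel descriptors than base calls"
        )
    for k, desc in enumerate(descriptors):
        tokens[k] = tokens[k] + desc
    tokens.extend(["*"] * col.del_span)
    tokens.extend([">"] * col.ref_skips)
    bases = "".join(tokens)
    quals = qual_char * col.depth
    return "\t".join(
        [col.chrom, str(col.pos), col.ref_base, str(col.depth), bases, quals]
    )


def write_pileup(columns: Iterable[PileupColumn], path: str | Path) -> None:
    with open(path, "w") as fh:
        for col in columns:
            fh.write(format_pileup_column(col) + "\n")


# ---------------------------------------------------------------------------
# population frequencies
# ---------------------------------------------------------------------------

class PopulationFrequencies:
    """Lookup table (chrom, pos, ref, alt) -> allele frequency.

    Absent keys return ``None`` ("unknown"), never 0: the downstream
    population filter must be able to distinguish a variant observed at
    a rare frequency from one never observed at all.
    """

    def __init__(self, records: Iterable[PopulationFrequencyRecord]):
        self._table: dict[tuple[str, int, str, str], float] = {}
        for rec in records:
            key = (rec.chrom, rec.pos, rec.ref, rec.alt)
            if key in self._table:
                raise ValidationError(
                    f"duplicate population-frequency key {key}"
                )
            self._table[key] = rec.af

    def lookup(self, chrom: str, pos: int, ref: str, alt: str) -> float | None:
        """Return the AF, or ``None`` if the variant is unknown."""
        return self._table.get((chrom, pos, ref, alt))

    def __len__(self) -> int:
        return len(self._table)


def read_population_freqs(path: str | Path) -> PopulationFrequencies:
    """Read an ExAC-NFE-style TSV (header: chrom, pos, ref, alt, af)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt", "af"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    records = [
        PopulationFrequencyRecord(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            af=float(row.af),
        )
        for row in df.itertuples(index=False)
    ]
    return PopulationFrequencies(records)


def write_population_freqs(
    records: Sequence[PopulationFrequencyRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {"chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt, "af": r.af}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mutation database
# ---------------------------------------------------------------------------

class MutationDatabase:
    """Locus-specific mutation records indexed by position and by exact allele."""

    def __init__(self, records: Iterable[MutationRecord]):
        self.records: list[MutationRecord] = list(records)
        self.by_position: dict[tuple[str, int], list[MutationRecord]] = {}
        self.by_allele: dict[tuple[str, int, str, str], list[MutationRecord]] = {}
        for rec in self.records:
            self.by_position.setdefault((rec.chrom, rec.pos), []).append(rec)
            if rec.alt:
                self.by_allele.setdefault(
                    (rec.chrom, rec.pos, rec.ref, rec.alt), []
                ).append(rec)

    def __len__(self) -> int:
        return len(self.records)


_MUTDB_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "hgvs_c",
    "consequence",
    "phenotype",
    "n_reports",
]


def read_mutation_db(path: str | Path) -> MutationDatabase:
    """Read a mutation-database TSV with header columns
    chrom, pos, ref, alt, hgvs_c, consequence, phenotype, n_reports."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_MUTDB_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        try:
            n_reports = int(row.n_reports) if row.n_reports != "" else 0
        except ValueError as exc:
            raise ValidationError(
                f"{path}: non-integer n_reports {row.n_reports!r}"
            ) from exc
        records.append(
            MutationRecord(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                hgvs_c=str(row.hgvs_c),
                consequence=str(row.consequence),
                phenotype=str(row.phenotype),
                n_reports=n_reports,
            )
        )
    return MutationDatabase(records)


def write_mutation_db(records: Sequence[MutationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "hgvs_c": r.hgvs_c,
                "consequence": r.consequence,
                "phenotype": r.phenotype,
                "n_reports": r.n_reports,
            }
            for r in records
        ],
        columns=_MUTDB_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA (reference emission / loading for homopolymer context)
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


# ---------------------------------------------------------------------------
# variant report writers
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=AF,Number=1,Type=Float,Description="Within-sample allele fraction">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at the position">
##INFO=<ID=SB,Number=1,Type=Float,Description="Forward-strand share of base calls">
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Library the call was made in">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variants_vcf(calls: Sequence, path: str | Path) -> None:
    """Write calls as a minimal VCF 4.2 (derived output; pileup counts
    remain the authoritative source for all statistics)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for call in calls:
            if call.alt.startswith("+"):
                ref, alt = call.ref, call.ref + call.alt[1:]
            elif call.alt.startswith("-") or call.alt == "<DEL>":
                ref, alt = call.ref, "<DEL>"
            else:
                ref, alt = call.ref, call.alt
            filt = ";".join(sorted(call.filters)) if call.filters else "PASS"
            sb = "." if call.strand_bias is None else f"{call.strand_bias:.4f}"
            info = f"AF={call.freq:.4f};DP={call.depth};SB={sb};SAMPLE={call.sample_id}"
            fh.write(
                f"{call.chrom}\t{call.pos}\t.\t{ref}\t{alt}\t.\t{filt}\t{info}\n"
            )


def variants_to_frame(calls: Sequence) -> pd.DataFrame:
    """Tabulate variant calls (one row per call) for TSV export."""
    rows = []
    for call in calls:
        ann = call.annotations[0] if call.annotations else None
        rows.append(
            {
                "sample_id": call.sample_id,
                "gene": call.gene,
                "chrom": call.chrom,
                "pos": call.pos,
                "ref": call.ref,
                "alt": call.alt,
                "freq": call.freq,
                "depth": call.depth,
                "strand_bias": call.strand_bias,
                "filters": ";".join(sorted(call.filters)) if call.filters else "PASS",
                "pop_af": "unknown" if call.pop_af is None else call.pop_af,
                "annotation": ann.hgvs_c if ann else "",
                "consequence": ann.consequence if ann else "",
                "n_reports": ann.n_reports if ann else "",
                "annotation_confidence": call.annotation_confidence or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "gene",
            "chrom",
            "pos",
            "ref",
            "alt",
            "freq",
            "depth",
            "strand_bias",
            "filters",
            "pop_af",
            "annotation",
            "consequence",
            "n_reports",
            "annotation_confidence",
        ],
    )


def write_variants_tsv(calls: Sequence, path: str | Path) -> None:
    variants_to_frame(calls).to_csv(path, sep="\t", index=False)
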