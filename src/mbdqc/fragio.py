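"""Alignment, reference and methylation-table I/O plus fragment reconstruction.

A "mapped fragment" is the reference interval spanning both sequenced mate
ends and the unsequenced region between them.  Pairs are kept only when both
mates map uniquely, on the same chromosome, in proper (inward) orientation,
and within a configurable maximum span (default 400 bp, consistent with a
~200 bp shearing target).  Fragments sharing exact coordinates are presumed
PCR copies of one molecule and are collapsed to a single fragment carrying a
multiplicity.
"""

from __future__ import annotations

import logging
from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

logger = logging.getLogger("mbdqc")

#: sentinel coverage for sources without read counts (array betas, true degrees)
UNLIMITED_COVERAGE = np.iinfo(np.int64).max

DEFAULT_MAX_SPAN = 400
DEFAULT_MAPQ_THRESHOLD = 20
DEFAULT_MIN_COVERAGE = 20


class ParseError(ValueError):
    """Malformed record in an input stream; the message names the line."""


@dataclass(frozen=True)
class AlignedPair:
    """One read pair, as mapped: mate positions/lengths and mapping flags.

    Positions are 0-based leftmost reference coordinates; lengths are aligned
    reference lengths in bp.  ``chrom`` is the chromosome of mate 1; a pair
    whose mates map to different chromosomes has ``same_chrom=False`` and is
    never properly oriented.
    """

    chrom: str
    pos1: int
    pos2: int
    len1: int
    len2: int
    unique1: bool
    unique2: bool
    proper_orientation: bool
    same_chrom: bool = True

    def __post_init__(self) -> None:
        if self.pos1 < 0 or self.pos2 < 0:
            raise ValueError("mate positions must be >= 0")
        if self.len1 <= 0 or self.len2 <= 0:
            raise ValueError("mate lengths must be > 0")


@dataclass(frozen=True)
class MappedFragment:
    """Reference interval [start, end) covering both mates and the gap.

    ``multiplicity`` counts identical copies observed before duplicate
    collapse; it is 1 for freshly reconstructed fragments.
    """

    chrom: str
    start: int
    end: int
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")

    def __len__(self) -> int:
        return self.end - self.start


class ReferenceGenome:
    """Named sequences over {A,C,G,T,N}, case preserved, held in memory.

    Soft-masked (lowercase) bases are retained; interval extraction is
    bounds-checked so downstream CpG counting can never silently truncate.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seqs = dict(sequences)

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown sequence {chrom!r}")
        n = len(self._seqs[chrom])
        if start < 0 or end > n or start >= end:
            raise IndexError(
                f"interval [{start}, {end}) out of bounds for {chrom!r} (length {n})"
            )
        return self._seqs[chrom][start:end]


def read_reference(path: str | Path) -> ReferenceGenome:
    """Load a FASTA file into a :class:`ReferenceGenome`.

    Raises on duplicate sequence names.  A sidecar ``.fai`` index may be
    created by pyfaidx next to the input.
    """
    fasta = Fasta(str(path), duplicate_action="stop", as_raw=True, rebuild=True)
    try:
        seqs = {name: str(fasta[name][:]) for name in fasta.keys()}
    finally:
        fasta.close()
    return ReferenceGenome(seqs)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.names:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# alignment reading


def read_alignment_pairs(
    source: str | Path,
    dialect: str = "sam",
    mapq_threshold: int = DEFAULT_MAPQ_THRESHOLD,
) -> list[AlignedPair]:
    """Read paired-end alignments into :class:`AlignedPair` records.

    ``dialect`` is ``"sam"`` (text SAM, read via pysam) or ``"bedpe"``.
    "Unique" mapping is operationalized as mapped, primary, and mapping
    quality >= ``mapq_threshold``.  Unmapped mates are flagged non-unique.
    Pair order (first appearance) is preserved.
    """
    if dialect == "sam":
        return _read_sam_pairs(source, mapq_threshold)
    if dialect == "bedpe":
        return _read_bedpe_pairs(source, mapq_threshold)
    raise ValueError(f"unknown alignment dialect {dialect!r} (expected 'sam' or 'bedpe')")


def _sam_unique(read: pysam.AlignedSegment, mapq_threshold: int) -> bool:
    return (
        not read.is_unmapped
        and not read.is_secondary
        and not read.is_supplementary
        and read.mapping_quality >= mapq_threshold
    )


def _read_sam_pairs(source: str | Path, mapq_threshold: int) -> list[AlignedPair]:
    mates: "OrderedDict[str, list[pysam.AlignedSegment]]" = OrderedDict()
    with pysam.AlignmentFile(str(source), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_secondary or read.is_supplementary:
                continue
            mates.setdefault(read.query_name, []).append(read)

    pairs: list[AlignedPair] = []
    for qname, reads in mates.items():
        if len(reads) > 2:
            raise ParseError(f"more than two primary records for read pair {qname!r}")
        r1 = next((r for r in reads if r.is_read1), reads[0])
        r2 = next((r for r in reads if r.is_read2 and r is not r1), None)
        if r2 is None:
            r2 = reads[1] if len(reads) == 2 and reads[1] is not r1 else None
        pairs.append(_pair_from_sam(r1, r2, mapq_threshold))
    return pairs


def _pair_from_sam(
    r1: pysam.AlignedSegment,
    r2: pysam.AlignedSegment | None,
    mapq_threshold: int,
) -> AlignedPair:
    def coords(r: pysam.AlignedSegment | None) -> tuple[str, int, int, bool, bool]:
        if r is None or r.is_unmapped:
            return "*", 0, 1, False, False
        length = r.reference_length or r.query_length or 1
        return (
            r.reference_name,
            r.reference_start,
            max(length, 1),
            _sam_unique(r, mapq_threshold),
            not r.is_reverse,
        )

    chrom1, pos1, len1, uniq1, fwd1 = coords(r1)
    chrom2, pos2, len2, uniq2, fwd2 = coords(r2)
    same_chrom = chrom1 != "*" and chrom1 == chrom2
    proper = _inward(pos1, fwd1, pos2, fwd2) if same_chrom else False
    return AlignedPair(
        chrom=chrom1 if chrom1 != "*" else chrom2,
        pos1=pos1,
        pos2=pos2,
        len1=len1,
        len2=len2,
        unique1=uniq1,
        unique2=uniq2,
        proper_orientation=proper,
        same_chrom=same_chrom,
    )


def _inward(pos1: int, fwd1: bool, pos2: int, fwd2: bool) -> bool:
    """Mates on opposite strands with the leftmost mate on the forward strand."""
    if fwd1 == fwd2:
        return False
    left_fwd = fwd1 if pos1 <= pos2 else fwd2
    return left_fwd


def _read_bedpe_pairs(source: str | Path, mapq_threshold: int) -> list[AlignedPair]:
    pairs: list[AlignedPair] = []
    with open(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ParseError(f"line {lineno}: BEDPE record has fewer than 6 fields")
            try:
                c1, s1, e1, c2, s2, e2 = (
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    fields[3],
                    int(fields[4]),
                    int(fields[5]),
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinate ({exc})") from None
            score = fields[7] if len(fields) > 7 else "."
            strand1 = fields[8] if len(fields) > 8 else "+"
            strand2 = fields[9] if len(fields) > 9 else "-"

            mapped1 = c1 != "." and s1 >= 0
            mapped2 = c2 != "." and s2 >= 0
            try:
                unique = score == "." or float(score) >= mapq_threshold
            except ValueError:
                unique = True
            same_chrom = mapped1 and mapped2 and c1 == c2
            proper = (
                _inward(s1, strand1 == "+", s2, strand2 == "+") if same_chrom else False
            )
            pairs.append(
                AlignedPair(
                    chrom=c1 if mapped1 else c2,
                    pos1=max(s1, 0),
                    pos2=max(s2, 0),
                    len1=max(e1 - s1, 1),
                    len2=max(e2 - s2, 1),
                    unique1=mapped1 and unique,
                    unique2=mapped2 and unique,
                    proper_orientation=proper,
                    same_chrom=same_chrom,
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# fragment reconstruction and deduplication


@dataclass
class FilterTally:
    """Per-filter rejection counts for the pair -> fragment step."""

    non_unique: int = 0
    cross_chromosome: int = 0
    improper_orientation: int = 0
    over_span: int = 0
    kept: int = 0

    def total_in(self) -> int:
        return (
            self.non_unique
            + self.cross_chromosome
            + self.improper_orientation
            + self.over_span
            + self.kept
        )


def reconstruct_fragments(
    pairs: Sequence[AlignedPair],
    max_span: int = DEFAULT_MAX_SPAN,
    span_metric: str = "outer",
    tally: FilterTally | None = None,
) -> list[MappedFragment]:
    """Turn properly mapped pairs into mapped fragments.

    Retains pairs with both mates unique, same chromosome, proper inward
    orientation, and span <= ``max_span``.  ``span_metric`` selects the span
    reading: ``"outer"`` (leftmost start to rightmost end, default) or
    ``"start_distance"`` (|pos1 - pos2|).  Filtering is not an error; pass a
    :class:`FilterTally` to audit per-filter rejections (also logged).
    """
    if max_span <= 0:
        raise ValueError("max_span must be > 0")
    if span_metric not in ("outer", "start_distance"):
        raise ValueError(f"unknown span_metric {span_metric!r}")
    t = tally if tally is not None else FilterTally()
    fragments: list[MappedFragment] = []
    for p in pairs:
        if not (p.unique1 and p.unique2):
            t.non_unique += 1
            continue
        if not p.same_chrom:
            t.cross_chromosome += 1
            continue
        if not p.proper_orientation:
            t.improper_orientation += 1
            continue
        start = min(p.pos1, p.pos2)
        end = max(p.pos1 + p.len1, p.pos2 + p.len2)
        span = end - start if span_metric == "outer" else abs(p.pos1 - p.pos2)
        if span > max_span:
            t.over_span += 1
            continue
        t.kept += 1
        fragments.append(MappedFragment(p.chrom, start, end, multiplicity=1))
    logger.info(
        "reconstruct_fragments: kept %d of %d pairs (non_unique=%d, "
        "cross_chromosome=%d, improper_orientation=%d, over_span=%d)",
        t.kept,
        len(pairs),
        t.non_unique,
        t.cross_chromosome,
        t.improper_orientation,
        t.over_span,
    )
    return fragments


def deduplicate_fragments(fragments: Iterable[MappedFragment]) -> list[MappedFragment]:
    """Collapse fragments sharing exact (chrom, start, end) into one.

    The surviving fragment carries the summed multiplicity, so the total
    multiplicity after collapse equals the input fragment count.  First-seen
    order is preserved.
    """
    counts: Counter[tuple[str, int, int]] = Counter()
    order: list[tuple[str, int, int]] = []
    for f in fragments:
        key = (f.chrom, f.start, f.end)
        if key not in counts:
            order.append(key)
        counts[key] += f.multiplicity
    return [
        MappedFragment(chrom, start, end, multiplicity=counts[(chrom, start, end)])
        for chrom, start, end in order
    ]


# ---------------------------------------------------------------------------
# yield accounting


@dataclass(frozen=True)
class YieldSummary:
    """Sequencing-yield accounting: raw, uniquely mapped and non-duplicate counts.

    Percentages follow the convention of one-decimal rounding (half away
    from zero); a zero denominator yields a missing percentage (``None``).
    """

    n_sequenced_fragments: int
    n_unique_mapped: int
    n_nonduplicate: int
    pct_unique_of_sequenced: float | None = field(init=False)
    pct_nondup_of_unique: float | None = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.n_nonduplicate <= self.n_unique_mapped <= self.n_sequenced_fragments:
            raise ValueError(
                "counts must satisfy nonduplicate <= unique <= sequenced, all >= 0"
            )
        object.__setattr__(
            self,
            "pct_unique_of_sequenced",
            _percentage(self.n_unique_mapped, self.n_sequenced_fragments),
        )
        object.__setattr__(
            self,
            "pct_nondup_of_unique",
            _percentage(self.n_nonduplicate, self.n_unique_mapped),
        )


def _percentage(numerator: int, denominator: int) -> float | None:
    if denominator == 0:
        return None
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def yield_summary(
    n_sequenced: int,
    unique_fragments: int | Sequence[MappedFragment],
    dedup_fragments: int | Sequence[MappedFragment],
) -> YieldSummary:
    """Build a :class:`YieldSummary` from counts or fragment collections."""
    n_unique = unique_fragments if isinstance(unique_fragments, int) else len(unique_fragments)
    n_dedup = dedup_fragments if isinstance(dedup_fragments, int) else len(dedup_fragments)
    return YieldSummary(n_sequenced, n_unique, n_dedup)


def write_yield_summary(summary: YieldSummary, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "n_sequenced_fragments": summary.n_sequenced_fragments,
                "n_unique_mapped": summary.n_unique_mapped,
                "n_nonduplicate": summary.n_nonduplicate,
                "pct_unique_of_sequenced": summary.pct_unique_of_sequenced,
                "pct_nondup_of_unique": summary.pct_nondup_of_unique,
            }
        ]
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# fragments as BED


def write_fragments_bed(fragments: Iterable[MappedFragment], path: str | Path) -> None:
    """Write fragments as BED with the multiplicity in the score column."""
    with open(path, "w") as fh:
        for i, f in enumerate(fragments):
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\tfrag{i}\t{f.multiplicity}\t+\n")


def read_fragments_bed(path: str | Path) -> list[MappedFragment]:
    fragments: list[MappedFragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: BED record has fewer than 3 fields")
            mult = int(float(fields[4])) if len(fields) > 4 and fields[4] != "." else 1
            fragments.append(
                MappedFragment(fields[0], int(fields[1]), int(fields[2]), multiplicity=mult)
            )
    return fragments


def write_pairs_bedpe(
    fragments: Iterable[MappedFragment], path: str | Path, read_len: int = 45
) -> None:
    """Emit fragments as inward-pointing mate pairs (first/last ``read_len`` bp)."""
    with open(path, "w") as fh:
        for i, f in enumerate(fragments):
            half = min(read_len, len(f))
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.start + half}"
                f"\t{f.chrom}\t{f.end - half}\t{f.end}"
                f"\tfrag{i}\t60\t+\t-\n"
            )


# ---------------------------------------------------------------------------
# methylation tables


@dataclass
class MethylationTable:
    """Per-CpG methylation degrees with coverage.

    ``df`` holds columns (chrom, pos, degree, coverage) with ``pos`` the
    0-based position of the C on the forward strand, one row per CpG.
    ``source_kind`` is ``"rrbs"`` (read counts), ``"array"`` (beta values) or
    ``"true"`` (simulator ground truth); non-rrbs coverage is the
    :data:`UNLIMITED_COVERAGE` sentinel.
    """

    df: pd.DataFrame
    source_kind: str

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "degree", "coverage"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"methylation table missing columns: {sorted(missing)}")
        deg = self.df["degree"].to_numpy()
        if len(deg) and ((deg < 0) | (deg > 1)).any():
            raise ValueError("methylation degrees must lie in [0, 1]")
        if self.df.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) records after strand merging")

    def __len__(self) -> int:
        return len(self.df)


def read_methylation_table(
    path: str | Path,
    source_kind: str,
    strand_mode: str = "merge",
) -> MethylationTable:
    """Read a per-CpG methylation TSV.

    ``rrbs`` dialect: header columns (chrom, pos, strand, meth_count,
    total_count); with ``strand_mode="merge"`` the forward-C and reverse-G
    records of one CpG are combined by summing counts, keyed to the
    forward-strand C position (reverse records sit one base right of the C).
    ``array`` dialect: (chrom, pos, beta), treated as already strand-combined
    with unlimited coverage.
    """
    if source_kind == "rrbs":
        return _read_rrbs(path, strand_mode)
    if source_kind == "array":
        return _read_array(path)
    raise ValueError(f"unknown methylation source kind {source_kind!r}")


def _read_rrbs(path: str | Path, strand_mode: str) -> MethylationTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "strand", "meth_count", "total_count"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"rrbs table missing columns: {sorted(missing)}")
    if strand_mode == "merge":
        reverse = df["strand"] == "-"
        key = df["pos"].where(~reverse, df["pos"] - 1)
        df = df.assign(pos=key)
        fwd_keys = set(map(tuple, df.loc[~reverse, ["chrom", "pos"]].itertuples(index=False)))
        orphan = sum(
            1
            for row in df.loc[reverse, ["chrom", "pos"]].itertuples(index=False)
            if tuple(row) not in fwd_keys
        )
        if orphan:
            logger.warning(
                "%d reverse-strand record(s) had no forward-strand CpG partner; "
                "kept as singletons keyed to the inferred C position",
                orphan,
            )
        df = (
            df.groupby(["chrom", "pos"], as_index=False, sort=True)[
                ["meth_count", "total_count"]
            ].sum()
        )
    elif strand_mode != "keep":
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    zero = df["total_count"] == 0
    if zero.any():
        logger.warning("dropping %d CpG record(s) with zero total count", int(zero.sum()))
        df = df.loc[~zero]
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "pos": df["pos"].to_numpy(dtype=np.int64),
            "degree": df["meth_count"].to_numpy(dtype=float)
            / df["total_count"].to_numpy(dtype=float),
            "coverage": df["total_count"].to_numpy(dtype=np.int64),
            "meth_count": df["meth_count"].to_numpy(dtype=np.int64),
        }
    )
    return MethylationTable(out.reset_index(drop=True), source_kind="rrbs")


def _read_array(path: str | Path) -> MethylationTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos", "beta"} - set(df.columns)
    if missing:
        raise ParseError(f"array table missing columns: {sorted(missing)}")
    beta = df["beta"].to_numpy(dtype=float)
    if ((beta < 0) | (beta > 1)).any():
        raise ValueError("beta values must lie in [0, 1]")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "pos": df["pos"].to_numpy(dtype=np.int64),
            "degree": beta,
            "coverage": np.full(len(df), UNLIMITED_COVERAGE, dtype=np.int64),
        }
    )
    return MethylationTable(out, source_kind="array")


def write_methylation_table(table: MethylationTable, path: str | Path) -> None:
    """Write a table in its native dialect (rrbs counts or array betas)."""
    if table.source_kind == "rrbs":
        meth = (
            table.df["meth_count"]
            if "meth_count" in table.df.columns
            else (table.df["degree"] * table.df["coverage"]).round().astype(np.int64)
        )
        out = pd.DataFrame(
            {
                "chrom": table.df["chrom"],
                "pos": table.df["pos"],
                "strand": "+",
                "meth_count": meth,
                "total_count": table.df["coverage"],
            }
        )
    else:
        out = pd.DataFrame(
            {"chrom": table.df["chrom"], "pos": table.df["pos"], "beta": table.df["degree"]}
        )
    out.to_csv(path, sep="\t", index=False)
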