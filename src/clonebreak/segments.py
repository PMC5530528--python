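"""Observed inputs of the model: segments, breakpoints and their preparation.

Coordinates are 0-based half-open throughout.  The genome is partitioned
into regular bins, with bins containing breakends split so that every
breakend coincides exactly with a segment boundary.  Total read counts are
the number of uniquely aligned, concordant read pairs fully contained in a
segment; allele counts are aggregated from pre-phased heterozygous-SNP
haplotype blocks assigned to segments by block midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import pysam

DEFAULT_BIN_SIZE = 500_000

SEGMENT_COLUMNS = [
    "chromosome", "start", "end", "length", "effective_length",
    "readcount", "allele_a_readcount", "allele_b_readcount",
]

BREAKPOINT_COLUMNS = [
    "breakpoint_id", "chrom_1", "position_1", "orientation_1",
    "chrom_2", "position_2", "orientation_2",
]

__all__ = [
    "Breakend", "Breakpoint", "HaplotypeBlock",
    "partition_genome", "count_reads", "aggregate_allele_counts",
    "effective_length", "effective_lengths", "raw_copy_numbers",
    "UniformBias", "ArrayBias", "GCQuantileBias",
    "read_segments", "write_segments",
    "read_breakpoints", "write_breakpoints",
    "breakpoints_from_table", "breakpoints_to_table",
    "SEGMENT_COLUMNS", "BREAKPOINT_COLUMNS", "DEFAULT_BIN_SIZE",
]


@dataclass(frozen=True)
class Breakend:
    """One oriented side of a rearrangement junction.

    ``orientation`` +1 means the junction connects the sequence to the left
    of ``position`` (it consumes right-extremities of the preceding
    segment); -1 connects the sequence to the right.
    """

    chromosome: str
    position: int
    orientation: int

    def __post_init__(self):
        if self.orientation not in (-1, 1):
            raise ValueError("orientation must be -1 or +1")


@dataclass(frozen=True)
class Breakpoint:
    """A pair of breakends defining a tumour-specific adjacency."""

    id: str
    breakend_1: Breakend
    breakend_2: Breakend

    def __post_init__(self):
        if (self.breakend_1.chromosome, self.breakend_1.position) == (
            self.breakend_2.chromosome, self.breakend_2.position,
        ):
            raise ValueError(f"breakpoint {self.id}: breakends must be distinct loci")


@dataclass(frozen=True)
class HaplotypeBlock:
    chromosome: str
    start: int
    end: int
    allele_1_readcount: int
    allele_2_readcount: int


def _empty_segment_frame(chroms, starts, ends) -> pd.DataFrame:
    lengths = np.asarray(ends) - np.asarray(starts)
    return pd.DataFrame({
        "chromosome": chroms,
        "start": starts,
        "end": ends,
        "length": lengths,
        "effective_length": lengths.astype(float),
        "readcount": 0,
        "allele_a_readcount": 0,
        "allele_b_readcount": 0,
    })


def partition_genome(
    chrom_lengths: Mapping[str, int],
    breakpoints: Sequence[Breakpoint] = (),
    bin_size: int = DEFAULT_BIN_SIZE,
) -> pd.DataFrame:
    """Tile each chromosome with ``bin_size`` bins, splitting bins so that
    every breakend falls exactly on a segment boundary.

    Returns a segment table sorted by (chromosome order as given, start)
    with counts zeroed and ``effective_length`` initialised to ``length``.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    extra: dict[str, set] = {chrom: set() for chrom in chrom_lengths}
    for bp in breakpoints:
        for be in (bp.breakend_1, bp.breakend_2):
            if be.chromosome not in chrom_lengths:
                raise ValueError(f"breakend chromosome {be.chromosome!r} unknown")
            if not 0 <= be.position <= chrom_lengths[be.chromosome]:
                raise ValueError(
                    f"breakend position {be.position} outside chromosome "
                    f"{be.chromosome} of length {chrom_lengths[be.chromosome]}"
                )
            extra[be.chromosome].add(int(be.position))

    chroms, starts, ends = [], [], []
    for chrom, length in chrom_lengths.items():
        bounds = set(range(0, int(length), bin_size))
        bounds.add(int(length))
        bounds.update(extra[chrom])
        bounds = sorted(b for b in bounds if 0 <= b <= length)
        for s, e in zip(bounds[:-1], bounds[1:]):
            chroms.append(chrom)
            starts.append(s)
            ends.append(e)
    return _empty_segment_frame(chroms, starts, ends)


def count_reads(
    alignments: Union[str, pysam.AlignmentFile],
    segments: pd.DataFrame,
    min_mapq: int = 1,
) -> pd.DataFrame:
    """Fill ``readcount`` with uniquely aligned, concordant read pairs fully
    contained within each segment.

    Each pair is counted once, at its leftmost read, using the template
    length to locate the fragment's right end; pairs straddling a segment
    boundary are counted nowhere.  Input must be coordinate sorted.
    """
    close = False
    if isinstance(alignments, (str,)):
        alignments = pysam.AlignmentFile(alignments, check_sq=False)
        close = True
    try:
        seg = segments.reset_index(drop=True)
        counts = np.zeros(len(seg), dtype=np.int64)
        by_chrom = {}
        for chrom, grp in seg.groupby("chromosome", sort=False):
            by_chrom[chrom] = (
                grp["start"].to_numpy(), grp["end"].to_numpy(),
                grp.index.to_numpy(),
            )
        last = {}
        for read in alignments:
            if (read.is_unmapped or read.mate_is_unmapped or read.is_secondary
                    or read.is_supplementary or read.is_duplicate):
                continue
            chrom = read.reference_name
            if read.reference_start < last.get(chrom, -1):
                raise ValueError("alignments must be coordinate sorted")
            last[chrom] = read.reference_start
            if not read.is_proper_pair or read.mapping_quality < min_mapq:
                continue
            if read.template_length <= 0:
                continue  # count each pair once, at its leftmost read
            if chrom not in by_chrom:
                continue
            frag_start = read.reference_start
            frag_end = frag_start + read.template_length
            starts, ends, idx = by_chrom[chrom]
            i = np.searchsorted(starts, frag_start, side="right") - 1
            if i >= 0 and frag_start >= starts[i] and frag_end <= ends[i]:
                counts[idx[i]] += 1
        out = seg.copy()
        out["readcount"] = counts
        return out
    finally:
        if close:
            alignments.close()


def aggregate_allele_counts(
    blocks: Iterable[HaplotypeBlock], segments: pd.DataFrame
) -> pd.DataFrame:
    """Aggregate haplotype-block allele counts into per-segment allele
    counts; a block contributes all its counts to the segment containing its
    midpoint."""
    seg = segments.reset_index(drop=True)
    xa = np.zeros(len(seg), dtype=np.int64)
    xb = np.zeros(len(seg), dtype=np.int64)
    by_chrom = {}
    for chrom, grp in seg.groupby("chromosome", sort=False):
        by_chrom[chrom] = (grp["start"].to_numpy(), grp["end"].to_numpy(),
                           grp.index.to_numpy())
    for block in blocks:
        if block.chromosome not in by_chrom:
            continue
        starts, ends, idx = by_chrom[block.chromosome]
        mid = (block.start + block.end) // 2
        i = np.searchsorted(starts, mid, side="right") - 1
        if i >= 0 and starts[i] <= mid < ends[i]:
            xa[idx[i]] += block.allele_1_readcount
            xb[idx[i]] += block.allele_2_readcount
    out = seg.copy()
    out["allele_a_readcount"] = xa
    out["allele_b_readcount"] = xb
    return out


# -- bias models and effective length --------------------------------------


class UniformBias:
    """Constant per-position weight."""

    def __init__(self, weight: float = 1.0):
        if weight < 0:
            raise ValueError("bias weight must be non-negative")
        self.weight = weight

    def weights(self, chromosome: str, start: int, end: int) -> np.ndarray:
        return np.full(end - start, self.weight)


class ArrayBias:
    """Per-position weights taken from pre-computed per-chromosome arrays."""

    def __init__(self, weights_by_chrom: Mapping[str, np.ndarray]):
        self.weights_by_chrom = {
            c: np.asarray(w, dtype=float) for c, w in weights_by_chrom.items()
        }
        for c, w in self.weights_by_chrom.items():
            if np.any(w < 0):
                raise ValueError(
                    f"bias weights must be non-negative (chromosome {c})")

    def weights(self, chromosome: str, start: int, end: int) -> np.ndarray:
        return self.weights_by_chrom[chromosome][start:end]


class GCQuantileBias:
    """GC-content bias: per-position weight looked up from a quantile table.

    The local GC fraction in a centred window indexes into ``table`` (a
    sequence of weights for equal-width GC bins).  A stand-in for fitted
    position-specific bias models; adequate for declaring relative
    representation of GC-extreme segments.
    """

    def __init__(self, sequences: Mapping[str, str], table: Sequence[float],
                 window: int = 200):
        self.sequences = sequences
        self.table = np.asarray(table, dtype=float)
        if np.any(self.table < 0):
            raise ValueError("bias table weights must be non-negative")
        self.window = window

    def weights(self, chromosome: str, start: int, end: int) -> np.ndarray:
        seq = str(self.sequences[chromosome]).upper()
        is_gc = np.frompyfunc(lambda ch: ch in "GC", 1, 1)(
            np.array(list(seq))
        ).astype(float)
        kernel = np.ones(self.window) / self.window
        gc = np.convolve(is_gc, kernel, mode="same")
        bins = np.minimum((gc * len(self.table)).astype(int), len(self.table) - 1)
        return self.table[bins][start:end]


def effective_length(segment, bias_model) -> float:
    """Bias-adjusted effective length: the sum of per-position weights over
    the segment.  Equals ``length`` when all weights are one."""
    w = np.asarray(
        bias_model.weights(segment["chromosome"], segment["start"], segment["end"]),
        dtype=float,
    )
    if np.any(w < 0):
        raise ValueError("bias weights must be non-negative")
    return float(w.sum())


def effective_lengths(segments: pd.DataFrame, bias_model) -> pd.DataFrame:
    out = segments.copy()
    out["effective_length"] = [
        effective_length(row, bias_model) for _, row in segments.iterrows()
    ]
    return out


def raw_copy_numbers(
    segments: pd.DataFrame, h: Sequence[float], normal_depth: float
) -> pd.DataFrame:
    """Continuous per-segment copy estimates for visualisation.

    ``raw_total`` removes the normal-diploid contribution from observed
    depth and scales by the summed tumour haploid depth ``h_T``; the
    major/minor split follows the observed allele-read ratio (A labelled as
    the higher-count allele).  Values may be negative or fractional and are
    not used in inference.
    """
    h_t = float(np.sum(h))
    if h_t <= 0:
        raise ValueError("summed tumour haploid depth must be positive")
    seg = segments.copy()
    depth = seg["readcount"] / seg["effective_length"]
    raw_total = (depth - 2.0 * normal_depth) / h_t
    n_allele = seg["allele_a_readcount"] + seg["allele_b_readcount"]
    major_count = np.maximum(seg["allele_a_readcount"], seg["allele_b_readcount"])
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_allele > 0, major_count / n_allele, np.nan)
    seg["raw_total"] = raw_total
    seg["raw_major"] = raw_total * frac
    seg["raw_minor"] = raw_total - seg["raw_major"]
    return seg


# -- tabular I/O ------------------------------------------------------------


def read_segments(path) -> pd.DataFrame:
    seg = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in SEGMENT_COLUMNS if c not in seg.columns]
    if missing:
        raise ValueError(f"segment table missing columns: {missing}")
    return seg


def write_segments(segments: pd.DataFrame, path) -> None:
    segments.to_csv(path, sep="\t", index=False)


def read_breakpoints(path) -> pd.DataFrame:
    bp = pd.read_csv(path, sep="\t", dtype={"chrom_1": str, "chrom_2": str})
    missing = [c for c in BREAKPOINT_COLUMNS if c not in bp.columns]
    if missing:
        raise ValueError(f"breakpoint table missing columns: {missing}")
    return bp


def write_breakpoints(breakpoints: pd.DataFrame, path) -> None:
    breakpoints.to_csv(path, sep="\t", index=False)


_STRAND = {"+": 1, "-": -1, 1: 1, -1: -1}
_STRAND_STR = {1: "+", -1: "-"}


def breakpoints_from_table(table: pd.DataFrame) -> list:
    """Convert a breakpoint table (orientations as +/-) to objects."""
    out = []
    for row in table.itertuples(index=False):
        out.append(Breakpoint(
            id=str(row.breakpoint_id),
            breakend_1=Breakend(str(row.chrom_1), int(row.position_1),
                                _STRAND[row.orientation_1]),
            breakend_2=Breakend(str(row.chrom_2), int(row.position_2),
                                _STRAND[row.orientation_2]),
        ))
    return out


def breakpoints_to_table(breakpoints: Sequence[Breakpoint]) -> pd.DataFrame:
    rows = []
    for bp in breakpoints:
        rows.append({
            "breakpoint_id": bp.id,
            "chrom_1": bp.breakend_1.chromosome,
            "position_1": bp.breakend_1.position,
            "orientation_1": _STRAND_STR[bp.breakend_1.orientation],
            "chrom_2": bp.breakend_2.chromosome,
            "position_2": bp.breakend_2.position,
            "orientation_2": _STRAND_STR[bp.breakend_2.orientation],
        })
    return pd.DataFrame(rows, columns=BREAKPOINT_COLUMNS)


def resample_reads(source_alignments, truth, out_path):  # pragma: no cover
    """Interface stub for aligned read re-sampling from a very high depth
    source normal genome dataset.

    Generating read-level data with realistic GC/mappability bias requires a
    deeply sequenced source alignment set (hundreds of gigabytes); this
    pathway is documented but not implemented.  Use segment-count simulation
    (`clonebreak.simulate.simulate_counts`) instead.
    """
    raise NotImplementedError(
        "aligned read re-sampling requires an external high-depth source "
        "dataset; use segment-count simulation instead"
    )
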