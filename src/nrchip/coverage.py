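"""Depth-normalized fragment coverage from weighted single-end alignments.

The pipeline consumes alignments (it does not align reads itself) and turns
each library into a coverage track in three steps:

1. every alignment of a read is weighted ``1 / n_hits``, so a read mapping
   equally well to n loci contributes total mass 1;
2. each alignment is extended to a fixed fragment length (default 500 bp)
   downstream of its sequenced 5' end, replacing the read span;
3. per-base weighted depth is averaged within fixed bins and scaled by
   ``1e6 / depth`` (reads per million aligned reads), where depth is the
   number of distinct aligned reads in the library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeLayout

DEFAULT_EXTENSION = 500


class AlignmentRecord(NamedTuple):
    """One reported alignment of a read.

    ``n_hits`` is the read's total number of equally good alignments; a
    multimapper appears once per hit locus, each record carrying the same
    ``read_id`` and ``n_hits``.
    """

    read_id: str
    chrom: str
    start: int  # 0-based leftmost aligned base
    strand: str  # '+' or '-'
    read_length: int
    n_hits: int = 1

    @property
    def weight(self) -> float:
        return 1.0 / self.n_hits


@dataclass
class LibraryMeta:
    sample: str = "sample"
    mark: str = ""
    genotype: str = ""
    role: str = "chip"  # 'chip' or 'input'
    replicate: int = 1
    generation: int = 0


@dataclass
class Library:
    """A collection of alignment records plus sample metadata.

    ``depth`` is the number of distinct read ids, which by the 1/n weighting
    equals the summed weight of all records (up to rounding).
    """

    records: list[AlignmentRecord]
    meta: LibraryMeta = field(default_factory=LibraryMeta)

    @property
    def depth(self) -> int:
        return len({r.read_id for r in self.records})

    def total_weight(self) -> float:
        return float(sum(r.weight for r in self.records))

    def validate(self, layout: GenomeLayout) -> None:
        """Check bounds and the per-read multimapper invariant."""
        counts: dict[str, int] = {}
        hits: dict[str, int] = {}
        for r in self.records:
            if r.strand not in "+-":
                raise ValueError(f"bad strand {r.strand!r} on read {r.read_id}")
            if not layout.contains(r.chrom, r.start, r.start + r.read_length):
                raise ValueError(
                    f"read {r.read_id} at {r.chrom}:{r.start} exceeds chromosome bounds"
                )
            counts[r.read_id] = counts.get(r.read_id, 0) + 1
            if hits.setdefault(r.read_id, r.n_hits) != r.n_hits:
                raise ValueError(f"read {r.read_id} has inconsistent n_hits")
        bad = [rid for rid, c in counts.items() if c != hits[rid]]
        if bad:
            raise ValueError(
                f"{len(bad)} reads violate the n_hits record-count invariant: "
                + ", ".join(sorted(bad)[:10])
            )


@dataclass
class CoverageTrack:
    """Binned, depth-normalized coverage.

    Each bin value is the mean per-base weighted depth within the bin,
    multiplied by ``normalization_factor = 1e6 / depth``. Values are
    therefore independent of bin size and of sequencing depth.
    """

    layout: GenomeLayout
    bin_size: int
    values: dict[str, np.ndarray]
    normalization_factor: float
    extension: int = DEFAULT_EXTENSION

    def __post_init__(self) -> None:
        for chrom, vec in self.values.items():
            expect = -(-self.layout.chrom_lengths[chrom] // self.bin_size)
            if len(vec) != expect:
                raise ValueError(
                    f"{chrom}: {len(vec)} bins, expected {expect} at bin_size {self.bin_size}"
                )

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(len(self.values[chrom])) * self.bin_size

    def span_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean normalized per-base depth over [start, end), overlap-weighted.

        Exact when per-base depth is constant within bins (always true at
        bin_size 1); otherwise a bin-resolution approximation.
        """
        if start >= end:
            raise ValueError("empty span")
        vec = self.values[chrom]
        lo = start // self.bin_size
        hi = -(-end // self.bin_size)
        total = 0.0
        for b in range(lo, hi):
            b0, b1 = b * self.bin_size, min((b + 1) * self.bin_size, self.layout.chrom_lengths[chrom])
            ov = min(end, b1) - max(start, b0)
            total += vec[b] * ov
        return total / (end - start)


def extend_alignment(
    record: AlignmentRecord,
    layout: GenomeLayout,
    extension: int = DEFAULT_EXTENSION,
) -> tuple[str, int, int, float]:
    """Extend one alignment to the fragment interval it represents.

    The fragment occupies ``extension`` bp downstream (3' direction) of the
    read's 5' mapping position, replacing the read span, and is clipped to
    the chromosome. Returns ``(chrom, start, end, weight)``.
    """
    if extension <= 0:
        raise ValueError("extension must be positive")
    length = layout.chrom_lengths[record.chrom]
    if record.strand == "+":
        start, end = record.start, record.start + extension
    else:
        read_end = record.start + record.read_length
        start, end = read_end - extension, read_end
    return record.chrom, max(0, start), min(length, end), record.weight


def per_base_depth(
    library: Library,
    layout: GenomeLayout,
    extension: int = DEFAULT_EXTENSION,
) -> dict[str, np.ndarray]:
    """Unnormalized per-base weighted fragment depth for every chromosome.

    Accumulated with a difference array: +w at each extended-fragment start,
    -w past its end, then a cumulative sum.
    """
    diffs = {
        chrom: np.zeros(length + 1) for chrom, length in layout.chrom_lengths.items()
    }
    for rec in library.records:
        chrom, start, end, w = extend_alignment(rec, layout, extension)
        if end > start:
            diffs[chrom][start] += w
            diffs[chrom][end] -= w
    return {chrom: np.cumsum(d[:-1]) for chrom, d in diffs.items()}


def _bin_means(depth: np.ndarray, bin_size: int) -> np.ndarray:
    n = len(depth)
    nbins = -(-n // bin_size)
    sums = np.add.reduceat(depth, np.arange(0, n, bin_size))
    lens = np.full(nbins, bin_size, dtype=float)
    if n % bin_size:
        lens[-1] = n % bin_size
    return sums / lens


def compute_coverage(
    library: Library,
    layout: GenomeLayout,
    bin_size: int = 25,
    extension: int = DEFAULT_EXTENSION,
) -> CoverageTrack:
    """Build the depth-normalized coverage track of one library."""
    depth = library.depth
    if depth == 0:
        raise ValueError("cannot normalize an empty library (depth 0)")
    factor = 1e6 / depth
    base = per_base_depth(library, layout, extension)
    values = {c: _bin_means(d, bin_size) * factor for c, d in base.items()}
    return CoverageTrack(layout, bin_size, values, factor, extension)


def locus_profile(
    tracks: Sequence[CoverageTrack] | CoverageTrack,
    interval: tuple[str, int, int],
    labels: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-bin signal of one or more tracks over a genomic interval.

    Rows are the track bins intersecting the interval; one value column per
    track, in input order. This is the export behind per-locus coverage
    plots (e.g. signal along a silenced gene).
    """
    if isinstance(tracks, CoverageTrack):
        tracks = [tracks]
    chrom, start, end = interval
    first = tracks[0]
    if not first.layout.contains(chrom, start, end) or start >= end:
        raise ValueError(f"interval {interval} outside layout")
    labels = list(labels) if labels is not None else [f"track{i+1}" for i in range(len(tracks))]
    lo = start // first.bin_size
    hi = -(-end // first.bin_size)
    out = pd.DataFrame(
        {
            "chrom": chrom,
            "bin_start": np.arange(lo, hi) * first.bin_size,
        }
    )
    out["bin_end"] = np.minimum(out["bin_start"] + first.bin_size, first.layout.chrom_lengths[chrom])
    for label, track in zip(labels, tracks):
        if track.bin_size != first.bin_size:
            raise ValueError("all tracks must share a bin size for a joint profile")
        out[label] = track.values[chrom][lo:hi]
    return out
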