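"""Fixed-window GC profiling and greedy merging into homogeneous segments.

Chromosomes are partitioned into non-overlapping windows of fixed size
(default 25 kb, a size small enough for compact unicellular chromosomes) and
window GC values are merged left to right into compositionally nearly
homogeneous segments: a window joins the running segment while its GC differs
from the running segment mean by at most a fixed threshold, otherwise it
opens a new segment. Gap-rich (invalid) windows always terminate the running
segment so that segments never bridge assembly gaps.

The merge rule deliberately favours long homogeneous segments; window-size
comparison utilities quantify how much apparent heterogeneity depends on the
window size (the standard deviation of window GC shrinks as windows grow).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import SequenceRecord

__all__ = [
    "Window",
    "SegmentationParams",
    "Segment",
    "partition_windows",
    "segment_gc_values",
    "segment_chromosome",
    "name_segment",
    "heterogeneity",
    "compare_window_sizes",
]


@dataclass(frozen=True)
class Window:
    """One fixed-size window with its GC level.

    ``valid`` is False when too few unambiguous bases were available to
    estimate GC (assembly gaps); invalid windows are excluded from
    segmentation and from heterogeneity estimates.
    """

    chrom_id: str
    start: int
    end: int
    gc_percent: float
    valid: bool = True


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the window/segment step.

    window_size
        Non-overlapping window length in bases (default 25,000).
    merge_threshold
        Maximum |window GC - running segment mean GC| in %-GC units for a
        window to join the current segment (default 1.5).
    min_valid_fraction
        Minimum fraction of unambiguous (ACGT) bases for a window to be
        considered valid (default 0.5).
    """

    window_size: int = 25_000
    merge_threshold: float = 1.5
    min_valid_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.window_size < 1_000:
            raise ValueError("window_size must be >= 1000 bases")
        if self.merge_threshold <= 0:
            raise ValueError("merge_threshold must be positive")
        if not 0.0 <= self.min_valid_fraction <= 1.0:
            raise ValueError("min_valid_fraction must be in [0, 1]")


@dataclass
class Segment:
    """A compositionally nearly homogeneous stretch of one chromosome."""

    chrom_id: str
    start: int
    end: int
    gc_percent: float
    name: str = ""

    @property
    def size(self) -> int:
        return self.end - self.start


_GC_BYTES = (ord("G"), ord("C"), ord("g"), ord("c"))
_AT_BYTES = (ord("A"), ord("T"), ord("a"), ord("t"))


def _window_gc_arrays(sequence: str, window_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-window (GC count, unambiguous count) via one pass over the byte array."""
    n = len(sequence) // window_size
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)[: n * window_size]
    arr = arr.reshape(n, window_size)
    gc_mask = np.zeros(arr.shape, dtype=bool)
    acgt_mask = np.zeros(arr.shape, dtype=bool)
    for b in _GC_BYTES:
        gc_mask |= arr == b
    acgt_mask |= gc_mask
    for b in _AT_BYTES:
        acgt_mask |= arr == b
    return gc_mask.sum(axis=1), acgt_mask.sum(axis=1)


def partition_windows(
    record: SequenceRecord, params: SegmentationParams = SegmentationParams()
) -> list[Window]:
    """Cut a record into non-overlapping fixed-size windows with GC levels.

    The trailing remainder shorter than one window is discarded so every
    window has identical length (segment GC is then an unweighted mean of its
    windows). A record shorter than one window yields an empty list with a
    warning. Windows whose unambiguous-base fraction falls below
    ``params.min_valid_fraction`` are flagged invalid.
    """
    w = params.window_size
    if record.length < w:
        warnings.warn(
            f"record {record.id!r} ({record.length} bp) shorter than one "
            f"{w}-bp window; no windows produced",
            stacklevel=2,
        )
        return []
    gc_counts, acgt_counts = _window_gc_arrays(record.sequence, w)
    windows = []
    for i, (gc, acgt) in enumerate(zip(gc_counts, acgt_counts)):
        valid = acgt >= params.min_valid_fraction * w and acgt > 0
        gc_pct = 100.0 * gc / acgt if acgt else float("nan")
        windows.append(
            Window(
                chrom_id=record.id,
                start=i * w,
                end=(i + 1) * w,
                gc_percent=gc_pct,
                valid=bool(valid),
            )
        )
    return windows


def segment_gc_values(
    values: Sequence[float],
    merge_threshold: float,
    valid: Optional[Sequence[bool]] = None,
) -> list[tuple[int, int]]:
    """Greedy left-to-right segmentation of a series of window GC values.

    Returns half-open index ranges ``(i0, i1)`` over ``values``. The first
    valid window opens a segment; each subsequent valid window joins the
    current segment iff its GC differs from the running segment mean by at
    most ``merge_threshold``, else it opens a new segment. Invalid entries
    close the current segment and are excluded from all segments.

    This is the computational core of :func:`segment_chromosome`, exposed on
    raw values so it can be applied to any numeric series.
    """
    segs: list[tuple[int, int]] = []
    append = segs.append
    t = merge_threshold
    total = 0.0
    count = 0
    start = -1
    if valid is None:
        for i, v in enumerate(values):
            if count:
                d = v - total / count
                if -t <= d <= t:
                    total += v
                    count += 1
                    continue
                append((start, i))
            start = i
            total = v
            count = 1
    else:
        for i, (v, ok) in enumerate(zip(values, valid)):
            if not ok:
                if count:
                    append((start, i))
                    count = 0
                continue
            if count:
                d = v - total / count
                if -t <= d <= t:
                    total += v
                    count += 1
                    continue
                append((start, i))
            start = i
            total = v
            count = 1
    if count:
        append((start, len(values)))
    return segs


def segment_chromosome(
    windows: Sequence[Window], params: SegmentationParams = SegmentationParams()
) -> list[Segment]:
    """Merge one chromosome's ordered windows into homogeneous segments.

    Segment GC is the (unweighted, since windows are equal-length) mean of
    member-window GC values. Segments are non-overlapping, ordered, and
    jointly cover exactly the valid windows. Returns an empty list for an
    empty or all-invalid window list.
    """
    if not windows:
        return []
    chroms = {w.chrom_id for w in windows}
    if len(chroms) != 1:
        raise ValueError(f"windows from multiple chromosomes: {sorted(chroms)}")
    gc = [w.gc_percent for w in windows]
    valid = [w.valid for w in windows]
    ranges = segment_gc_values(gc, params.merge_threshold, valid)
    segments = []
    for i0, i1 in ranges:
        member_gc = gc[i0:i1]
        segments.append(
            Segment(
                chrom_id=windows[0].chrom_id,
                start=windows[i0].start,
                end=windows[i1 - 1].end,
                gc_percent=float(np.mean(member_gc)),
            )
        )
    return segments


def name_segment(chromosome_number: int, species_name: str, index: int) -> str:
    """Conventional segment name: chromosome number, species initials, segment index.

    The genus initial is upper-case and the species epithet initial is
    lower-case, concatenated without separators: ``name_segment(3,
    "Saccharomyces cerevisiae", 2) == "3Sc2"``.
    """
    if chromosome_number < 1 or index < 1:
        raise ValueError("chromosome_number and index must be positive")
    words = species_name.split()
    if len(words) < 2:
        raise ValueError(
            f"species name {species_name!r} must contain at least genus and species"
        )
    return f"{chromosome_number}{words[0][0].upper()}{words[1][0].lower()}{index}"


def name_segments(
    segments: Sequence[Segment],
    species_name: str,
    chromosome_numbers: dict[str, int],
) -> None:
    """Assign conventional names in place, numbering segments per chromosome."""
    counters: dict[str, int] = {}
    for seg in segments:
        counters[seg.chrom_id] = counters.get(seg.chrom_id, 0) + 1
        chrom_no = chromosome_numbers[seg.chrom_id]
        seg.name = name_segment(chrom_no, species_name, counters[seg.chrom_id])


def heterogeneity(windows: Iterable[Window]) -> float:
    """Sample standard deviation of valid-window GC values (% GC).

    The classical scale-dependent heterogeneity measure: it decreases as the
    window size grows, so comparisons are only meaningful at a fixed size.
    Raises for fewer than two valid windows.
    """
    gc = [w.gc_percent for w in windows if w.valid]
    if len(gc) < 2:
        raise ValueError("heterogeneity requires at least 2 valid windows")
    return float(np.std(gc, ddof=1))


def compare_window_sizes(
    records: SequenceRecord | Sequence[SequenceRecord],
    sizes: Sequence[int],
    params: SegmentationParams = SegmentationParams(),
    bin_width: float = 0.5,
) -> dict[int, tuple["object", float]]:
    """Run the full windows->segments->binned-profile pipeline at several window sizes.

    Returns ``{window_size: (BinnedProfile, heterogeneity)}`` with all other
    parameters held fixed, for checking that the compositional pattern is not
    an artifact of the window size.
    """
    from dataclasses import replace as _replace

    from .families import bin_segments

    if isinstance(records, SequenceRecord):
        records = [records]
    out: dict[int, tuple[object, float]] = {}
    for size in sizes:
        p = _replace(params, window_size=size)
        all_windows: list[Window] = []
        all_segments: list[Segment] = []
        for rec in records:
            wins = partition_windows(rec, p)
            all_windows.extend(wins)
            all_segments.extend(segment_chromosome(wins, p))
        profile = bin_segments(all_segments, bin_width=bin_width)
        out[size] = (profile, heterogeneity(all_windows))
    return out
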