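"""Independent brute-force reference implementations used only by the tests.

These deliberately avoid the package's code paths: means are recomputed from
scratch over explicit slices, codon counts are tallied character by
character, and binning is a dict tally. They pin the semantics the package
implements efficiently.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np


def brute_force_segments(
    values: Sequence[float], threshold: float, valid: Optional[Sequence[bool]] = None
) -> list[tuple[int, int]]:
    """Greedy mean-tracking segmentation, recomputing every mean from a slice."""
    n = len(values)
    segs = []
    i = 0
    while i < n:
        if valid is not None and not valid[i]:
            i += 1
            continue
        j = i + 1
        while j < n and (valid is None or valid[j]):
            mean_so_far = sum(values[i:j]) / (j - i)
            if abs(values[j] - mean_so_far) > threshold:
                break
            j += 1
        segs.append((i, j))
        i = j
    return segs


def rowwise_greedy_start_masks(matrix: np.ndarray, threshold: float) -> np.ndarray:
    """Segment-start bitmasks of the greedy rule, computed row-parallel in numpy.

    Bit j of row i is set iff a new segment starts at column j for row i.
    Written as an array recurrence over columns, structurally unlike the
    package's sequential per-sequence loop.
    """
    m, n = matrix.shape
    sums = matrix[:, 0].astype(float).copy()
    counts = np.ones(m)
    masks = np.ones(m, dtype=np.int64)  # bit 0: first column always starts
    for j in range(1, n):
        col = matrix[:, j]
        merge = np.abs(col - sums / counts) <= threshold
        sums = np.where(merge, sums + col, col)
        counts = np.where(merge, counts + 1.0, 1.0)
        masks |= (~merge).astype(np.int64) << j
    return masks


def brute_force_codon_counts(sequence: str) -> dict[str, float]:
    """Per-position GC percentages by explicit codon-by-codon tally."""
    seq = sequence.upper()
    assert len(seq) % 3 == 0
    counted = 0
    gc_at_pos = [0, 0, 0]
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if any(b not in "ACGT" for b in codon):
            continue
        counted += 1
        for k, b in enumerate(codon):
            if b in "GC":
                gc_at_pos[k] += 1
    pos = [100.0 * g / counted for g in gc_at_pos]
    return {
        "gc1": pos[0],
        "gc2": pos[1],
        "gc3": pos[2],
        "gc": sum(pos) / 3.0,
    }


def brute_force_bin_tally(
    gc_values: Sequence[float], sizes: Sequence[float], bin_width: float
) -> dict[int, float]:
    """bp per bin index (floor(gc / width)) by explicit dict accumulation."""
    tally: dict[int, float] = {}
    for gc, size in zip(gc_values, sizes):
        idx = math.floor(gc / bin_width)
        tally[idx] = tally.get(idx, 0.0) + size
    return tally
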