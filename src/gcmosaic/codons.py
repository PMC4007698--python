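"""Codon-position GC statistics and orthogonal (major-axis) regression.

For a coding sequence, GC1/GC2/GC3 are the GC percentages at the first,
second and third codon positions; their mean equals the overall GC of the
CDS. Relationships between positions (within a species) and between
orthologs (across species) are summarized with major-axis regression — the
line minimizing summed squared *perpendicular* distances — which is the
appropriate symmetric fit when both variables are GC percentages measured
with comparable error, unlike ordinary least squares which designates a
response variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import CdsRecord

__all__ = [
    "CodonGC",
    "OrthologPair",
    "RegressionFit",
    "ZeroVarianceError",
    "codon_gc",
    "build_ortholog_pairs",
    "read_pairing_table",
    "gc_distributions",
    "histogram_overlap",
    "orthogonal_regression",
    "pairwise_position_fits",
    "POSITION_STATS",
]

POSITION_STATS = ("gc", "gc1", "gc2", "gc3")


class ZeroVarianceError(ValueError):
    """Raised when a regression variable has no variance (fit undefined)."""


@dataclass(frozen=True)
class CodonGC:
    """GC percentages of a CDS overall and at each codon position."""

    gc: float
    gc1: float
    gc2: float
    gc3: float

    def __getitem__(self, stat: str) -> float:
        return getattr(self, stat)


@dataclass(frozen=True)
class OrthologPair:
    """A pair of orthologous CDS with their codon-position GC statistics."""

    gene_id_a: str
    gene_id_b: str
    codon_gc_a: CodonGC
    codon_gc_b: CodonGC


@dataclass(frozen=True)
class RegressionFit:
    """Major-axis fit summary: y = slope*x + intercept, Pearson R, gene count N."""

    slope: float
    intercept: float
    r: float
    n: int


def codon_gc(cds: CdsRecord | str, include_stop: bool = True) -> CodonGC:
    """Per-codon-position GC of an in-frame CDS.

    ``gc_k = 100 * (G+C at position k) / (number of codons counted)``. Any
    codon containing an ambiguity code is skipped at *all* positions, so the
    identity ``gc == (gc1 + gc2 + gc3) / 3`` holds exactly. By default the
    terminal stop codon is included (the CDS runs through the stop); pass
    ``include_stop=False`` to drop the last codon.

    Raises for a length not divisible by 3 or when no unambiguous codon
    remains.
    """
    seq = (cds.sequence if isinstance(cds, CdsRecord) else cds).upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    if not include_stop:
        seq = seq[:-3]
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).reshape(-1, 3)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_at = (arr == ord("A")) | (arr == ord("T"))
    clean = (is_gc | is_at).all(axis=1)
    n = int(clean.sum())
    if n == 0:
        raise ValueError("no unambiguous codons in CDS")
    counts = is_gc[clean].sum(axis=0)  # per-position GC counts
    gc1, gc2, gc3 = (100.0 * c / n for c in counts)
    return CodonGC(gc=(gc1 + gc2 + gc3) / 3.0, gc1=gc1, gc2=gc2, gc3=gc3)


def read_pairing_table(path: str | Path) -> pd.DataFrame:
    """Read a two-column ortholog pairing table (id_a, id_b), TSV, header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: pairing table needs two columns")
    df = df.iloc[:, :2]
    df.columns = ["id_a", "id_b"]
    if list(df.iloc[0]) == ["id_a", "id_b"]:
        df = df.iloc[1:].reset_index(drop=True)
    return df


def build_ortholog_pairs(
    cds_a: Iterable[CdsRecord],
    cds_b: Iterable[CdsRecord],
    pairing: pd.DataFrame,
    include_stop: bool = True,
) -> tuple[list[OrthologPair], list[tuple[str, str]]]:
    """Join two accepted CDS sets on a pairing table and compute codon GC.

    Pairs referencing ids missing from either set are dropped and returned
    separately so the caller can log them.
    """
    by_a = {r.id: r for r in cds_a}
    by_b = {r.id: r for r in cds_b}
    pairs: list[OrthologPair] = []
    dropped: list[tuple[str, str]] = []
    for id_a, id_b in pairing[["id_a", "id_b"]].itertuples(index=False):
        ra = by_a.get(id_a)
        rb = by_b.get(id_b)
        if ra is None or rb is None:
            dropped.append((id_a, id_b))
            continue
        pairs.append(
            OrthologPair(
                gene_id_a=id_a,
                gene_id_b=id_b,
                codon_gc_a=codon_gc(ra, include_stop=include_stop),
                codon_gc_b=codon_gc(rb, include_stop=include_stop),
            )
        )
    return pairs, dropped


def _stat_values(pairs: Sequence[OrthologPair], species: str, stat: str) -> np.ndarray:
    attr = "codon_gc_a" if species == "a" else "codon_gc_b"
    return np.array([getattr(p, attr)[stat] for p in pairs], dtype=float)


def histogram_overlap(x: np.ndarray, y: np.ndarray, bin_width: float = 2.5) -> float:
    """Shared area of two normalized histograms on a common [0, 100] GC axis.

    Computed as the per-bin sum of the minimum of the two normalized
    histograms; 1.0 for identical samples, ~0 for disjoint distributions.
    """
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    hx, _ = np.histogram(np.clip(x, 0, 100 - 1e-9), bins=edges)
    hy, _ = np.histogram(np.clip(y, 0, 100 - 1e-9), bins=edges)
    return float(np.minimum(hx / hx.sum(), hy / hy.sum()).sum())


def gc_distributions(
    pairs: Sequence[OrthologPair], bin_width: float = 2.5
) -> dict[str, object]:
    """Histograms of gc/gc1/gc2/gc3 for both species of an ortholog set.

    Returns a dict with ``edges`` (shared [0, 100] axis), per-species
    ``counts[(species, stat)]``, per-statistic species ``means`` and the
    between-species histogram ``overlap`` per statistic.
    """
    if not pairs:
        raise ValueError("no ortholog pairs")
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    counts: dict[tuple[str, str], np.ndarray] = {}
    means: dict[tuple[str, str], float] = {}
    overlap: dict[str, float] = {}
    for stat in POSITION_STATS:
        va = _stat_values(pairs, "a", stat)
        vb = _stat_values(pairs, "b", stat)
        for sp, v in (("a", va), ("b", vb)):
            counts[(sp, stat)], _ = np.histogram(np.clip(v, 0, 100 - 1e-9), bins=edges)
            means[(sp, stat)] = float(v.mean())
        overlap[stat] = histogram_overlap(va, vb, bin_width)
    return {"edges": edges, "counts": counts, "means": means, "overlap": overlap}


def orthogonal_regression(
    x: Sequence[float], y: Sequence[float], method: str = "major_axis"
) -> RegressionFit:
    """Fit the orthogonal-regression line through (x, y).

    ``method="major_axis"`` (default): the first principal axis of the raw
    2x2 covariance matrix, i.e. the line minimizing summed squared
    perpendicular distances. Appropriate when both variables share units (as
    %-GC values do). ``method="rma"``: reduced major axis, slope =
    sign(cov) * sd(y)/sd(x).

    Swapping x and y maps the major-axis slope to its reciprocal and leaves
    R unchanged. Raises :class:`ZeroVarianceError` when either variable is
    constant, and ``ValueError`` for n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    sxx = float(np.var(x, ddof=1))
    syy = float(np.var(y, ddof=1))
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if sxx == 0.0 or syy == 0.0:
        raise ZeroVarianceError("a variable with zero variance has no regression line")
    if method == "rma":
        slope = math.copysign(math.sqrt(syy / sxx), sxy if sxy != 0 else 1.0)
    elif method == "major_axis":
        if sxy == 0.0:
            raise ZeroVarianceError(
                "zero covariance: the major axis is parallel to a coordinate axis "
                "or undefined"
            )
        # Largest eigenvalue of [[sxx, sxy], [sxy, syy]].
        lam = 0.5 * (sxx + syy + math.hypot(sxx - syy, 2.0 * sxy))
        slope = (lam - sxx) / sxy
    else:
        raise ValueError(f"unknown method {method!r}")
    intercept = float(y.mean() - slope * x.mean())
    r = sxy / math.sqrt(sxx * syy)
    return RegressionFit(slope=float(slope), intercept=intercept, r=float(r), n=n)


def pairwise_position_fits(
    pairs: Sequence[OrthologPair], method: str = "major_axis"
) -> pd.DataFrame:
    """All within-species position-vs-position fits plus between-species fits.

    Within each species: every ordered pair of distinct statistics among
    gc/gc1/gc2/gc3 (x_stat vs y_stat). Between species: the same statistic in
    species A (x) vs species B (y). Fits that are undefined because one
    variable is constant are reported with NaN slope/intercept/r. Returns a
    tidy frame with columns scope, x_stat, y_stat, slope, intercept, r, n.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 ortholog pairs")
    rows = []

    def add(scope: str, x_stat: str, y_stat: str, xv: np.ndarray, yv: np.ndarray) -> None:
        try:
            fit = orthogonal_regression(xv, yv, method=method)
            rows.append((scope, x_stat, y_stat, fit.slope, fit.intercept, fit.r, fit.n))
        except ZeroVarianceError:
            rows.append((scope, x_stat, y_stat, np.nan, np.nan, np.nan, len(xv)))

    for sp, scope in (("a", "species_a"), ("b", "species_b")):
        values = {s: _stat_values(pairs, sp, s) for s in POSITION_STATS}
        for i, xs in enumerate(POSITION_STATS):
            for ys in POSITION_STATS[i + 1 :]:
                add(scope, xs, ys, values[xs], values[ys])
    for stat in POSITION_STATS:
        add("between", stat, stat, _stat_values(pairs, "a", stat), _stat_values(pairs, "b", stat))

    return pd.DataFrame(
        rows, columns=["scope", "x_stat", "y_stat", "slope", "intercept", "r", "n"]
    )
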