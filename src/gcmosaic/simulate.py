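"""Synthetic compartmentalized genomes and ortholog CDS sets with known truth.

The genome generator emulates the compositional mosaic the analysis assumes:
each chromosome is a concatenation of segments drawn from a small number of
GC families (distinct mean GC, given genome proportions, segment lengths of
tens of kb), with window-level Gaussian jitter around the family mean and
bases drawn i.i.d. at the window's target GC. Segment lengths are rounded to
whole windows so that true boundaries sit exactly on the analysis grid and
boundary recovery can be scored exactly.

The ortholog generator draws per-gene (GC1, GC2, GC3) targets from a
trivariate Gaussian with configurable means, spreads and a common
between-position correlation, shifts one species' GC3 by a fixed offset, and
realizes each gene as a CDS whose per-position base draws hit the targets in
expectation (start codon forced first, stop codon forced last).

Everything is reproducible from the spec seed. The base-level model is
i.i.d. given the window target (no dinucleotide structure, no repeats, no
coding/noncoding mosaic): adequate because the analysis under test uses only
mononucleotide GC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import CdsRecord, GenomeAssembly, SequenceRecord

__all__ = [
    "FamilySpec",
    "GenomeSpec",
    "OrthologSetSpec",
    "simulate_genome",
    "simulate_orthologs",
    "realized_family_weights",
]


@dataclass(frozen=True)
class FamilySpec:
    """One compositional family of the synthetic genome."""

    mean_gc: float
    proportion: float
    segment_length_mean: float = 75_000.0
    segment_length_sd: float = 40_000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.mean_gc < 100.0:
            raise ValueError("mean_gc must be in (0, 100)")
        if self.proportion <= 0:
            raise ValueError("proportion must be positive")


@dataclass(frozen=True)
class GenomeSpec:
    """Specification of a synthetic compartmentalized genome.

    ``window_noise_sd`` is the %-GC jitter applied to each 25-kb window's
    target around its segment's family mean (1.0 by default, the order of
    within-isochore variation at that scale). Chromosome sizes default to a
    compact unicellular-like genome.
    """

    families: tuple[FamilySpec, ...]
    n_chromosomes: int = 4
    chromosome_length: int = 1_500_000
    window_noise_sd: float = 1.0
    seed: int = 0
    window_size: int = 25_000
    gc_skew: float = 0.0  # (G-C)/(G+C) asymmetry; 0 = even split

    def __post_init__(self) -> None:
        object.__setattr__(self, "families", tuple(self.families))
        total = sum(f.proportion for f in self.families)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"family proportions must sum to 1, got {total}")
        if self.chromosome_length < 10 * self.window_size:
            raise ValueError("chromosome_length must be >= 10 windows")
        if self.window_noise_sd < 0:
            raise ValueError("window_noise_sd must be >= 0")


@dataclass(frozen=True)
class OrthologSetSpec:
    """Specification of a synthetic two-species ortholog CDS set.

    Means/sds are %-GC at each codon position for species A;
    ``between_position_correlation`` is the common pairwise correlation of
    the latent (GC1, GC2, GC3) targets; species B receives the same targets
    with GC3 shifted by ``gc3_shift_b``. ``codons_per_gene`` defaults to 400
    codons (a typical ~1.2-kb CDS).
    """

    n_genes: int = 4000
    means: tuple[float, float, float] = (50.0, 40.0, 45.0)
    sds: tuple[float, float, float] = (10.0, 10.0, 10.0)
    between_position_correlation: float = 0.5
    gc3_shift_b: float = -25.0
    codons_per_gene: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("n_genes must be >= 3")
        if self.codons_per_gene < 3:
            raise ValueError("codons_per_gene must be >= 3")
        if not -1.0 <= self.between_position_correlation <= 1.0:
            raise ValueError("correlation must be in [-1, 1]")
        for m, s in zip(self.means, self.sds):
            if not 0.0 < m < 100.0:
                raise ValueError("means must lie in (0, 100)")
            if s < 0:
                raise ValueError("sds must be >= 0")


def _draw_bases(rng: np.random.Generator, p_gc: np.ndarray, gc_skew: float) -> np.ndarray:
    """i.i.d. bases as uint8 codes given per-base GC probability."""
    u = rng.random(p_gc.shape)
    gc = u < p_gc
    half = rng.random(p_gc.shape) < 0.5 * (1.0 + gc_skew)
    out = np.empty(p_gc.shape, dtype=np.uint8)
    out[gc & half] = ord("G")
    out[gc & ~half] = ord("C")
    out[~gc & half] = ord("A")
    out[~gc & ~half] = ord("T")
    return out


def simulate_genome(spec: GenomeSpec) -> tuple[GenomeAssembly, pd.DataFrame]:
    """Generate a mosaic genome; return the assembly and its ground truth.

    The truth table has one row per generated segment: chrom, start, end
    (0-based half-open, aligned to the window grid), family index, family
    mean GC and the realized mean of the segment's window targets.
    """
    rng = np.random.default_rng(spec.seed)
    w = spec.window_size
    n_win = spec.chromosome_length // w
    props = np.array([f.proportion for f in spec.families])
    records = []
    truth_rows = []
    for c in range(spec.n_chromosomes):
        chrom_id = f"chr{c + 1}"
        filled = 0
        targets = np.empty(n_win)
        while filled < n_win:
            fam_idx = int(rng.choice(len(props), p=props))
            fam = spec.families[fam_idx]
            length = rng.normal(fam.segment_length_mean, fam.segment_length_sd)
            seg_win = max(1, int(round(length / w)))
            seg_win = min(seg_win, n_win - filled)
            seg_targets = np.clip(
                fam.mean_gc + rng.normal(0.0, spec.window_noise_sd, seg_win), 0.5, 99.5
            )
            targets[filled : filled + seg_win] = seg_targets
            truth_rows.append(
                {
                    "chrom": chrom_id,
                    "start": filled * w,
                    "end": (filled + seg_win) * w,
                    "family": fam_idx,
                    "family_mean_gc": fam.mean_gc,
                    "target_mean_gc": float(seg_targets.mean()),
                }
            )
            filled += seg_win
        p_gc = np.repeat(targets / 100.0, w)
        bases = _draw_bases(rng, p_gc, spec.gc_skew)
        records.append(
            SequenceRecord(
                id=chrom_id, description=f"{chrom_id} synthetic", sequence=bases.tobytes().decode("ascii")
            )
        )
    assembly = GenomeAssembly(
        records=records,
        chromosome_numbers={r.id: i + 1 for i, r in enumerate(records)},
    )
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "family", "family_mean_gc", "target_mean_gc"]
    )
    return assembly, truth


def realized_family_weights(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-family realized weight of a truth table: bp, fraction, mean target GC."""
    sizes = truth["end"] - truth["start"]
    df = pd.DataFrame(
        {
            "family": truth["family"],
            "bp": sizes,
            "wgc": sizes * truth["target_mean_gc"],
        }
    )
    agg = df.groupby("family").sum()
    out = pd.DataFrame(
        {
            "bp": agg["bp"],
            "fraction": agg["bp"] / agg["bp"].sum(),
            "mean_target_gc": agg["wgc"] / agg["bp"],
        }
    )
    return out.reset_index()


_STOPS = ("TAA", "TAG", "TGA")


def simulate_orthologs(
    spec: OrthologSetSpec,
) -> tuple[list[CdsRecord], list[CdsRecord], pd.DataFrame, pd.DataFrame]:
    """Generate paired CDS sets for two species; return (cds_a, cds_b, pairing, truth).

    Per gene, latent (gc1, gc2, gc3) targets for species A come from a
    trivariate Gaussian (equicorrelated, clipped to (1, 99)); species B uses
    the same targets with gc3 shifted. Sequences realize the targets in
    expectation, with codon 1 forced to ATG and the final codon to a stop
    chosen reproducibly per gene. The truth table carries the latent targets.
    """
    rng = np.random.default_rng(spec.seed)
    n, c = spec.n_genes, spec.codons_per_gene
    rho = spec.between_position_correlation
    sds = np.asarray(spec.sds)
    corr = np.full((3, 3), rho)
    np.fill_diagonal(corr, 1.0)
    cov = corr * np.outer(sds, sds)
    latent_a = rng.multivariate_normal(np.asarray(spec.means), cov, size=n)
    latent_a = np.clip(latent_a, 1.0, 99.0)
    latent_b = latent_a.copy()
    latent_b[:, 2] = np.clip(latent_b[:, 2] + spec.gc3_shift_b, 1.0, 99.0)

    stops = np.array([list(s.encode("ascii")) for s in _STOPS], dtype=np.uint8)
    stop_choice = rng.integers(0, len(_STOPS), size=n)
    # Shared per-base uniforms: the two species realize their (possibly
    # shifted) targets from the same draws, so a zero shift yields identical
    # sequences and a pure-GC3 shift perturbs only third positions.
    u_gc = rng.random((n, c, 3))
    u_half = rng.random((n, c, 3))

    def realize(latent: np.ndarray) -> list[np.ndarray]:
        seqs = np.empty((n, c, 3), dtype=np.uint8)
        for k in range(3):
            p = np.repeat(latent[:, k] / 100.0, c).reshape(n, c)
            gc = u_gc[:, :, k] < p
            half = u_half[:, :, k] < 0.5
            pos = seqs[:, :, k]
            pos[gc & half] = ord("G")
            pos[gc & ~half] = ord("C")
            pos[~gc & half] = ord("A")
            pos[~gc & ~half] = ord("T")
        seqs[:, 0, :] = np.frombuffer(b"ATG", dtype=np.uint8)
        seqs[:, -1, :] = stops[stop_choice]
        # Internal stop codons would be rejected downstream. Rewrite the
        # third base GC-neutrally (A->T, G->C): TAA->TAT, TAG->TAC,
        # TGA->TGT, none of which is a stop, leaving GC3 exactly unchanged.
        flat = seqs.reshape(n, c * 3)
        codons = seqs[:, 1:-1, :]
        bad = _is_stop_matrix(codons)
        third = codons[..., 2]
        third[bad & (third == ord("A"))] = ord("T")
        third[bad & (third == ord("G"))] = ord("C")
        return [flat[row] for row in range(n)]

    seqs_a = realize(latent_a)
    seqs_b = realize(latent_b)
    width = len(str(n))
    cds_a = [
        CdsRecord(
            id=f"geneA{idx + 1:0{width}d}",
            description=f"geneA{idx + 1:0{width}d} synthetic coding sequence",
            sequence=s.tobytes().decode("ascii"),
        )
        for idx, s in enumerate(seqs_a)
    ]
    cds_b = [
        CdsRecord(
            id=f"geneB{idx + 1:0{width}d}",
            description=f"geneB{idx + 1:0{width}d} synthetic coding sequence",
            sequence=s.tobytes().decode("ascii"),
        )
        for idx, s in enumerate(seqs_b)
    ]
    pairing = pd.DataFrame({"id_a": [r.id for r in cds_a], "id_b": [r.id for r in cds_b]})
    truth = pd.DataFrame(
        {
            "id_a": pairing["id_a"],
            "id_b": pairing["id_b"],
            "gc1_a": latent_a[:, 0],
            "gc2_a": latent_a[:, 1],
            "gc3_a": latent_a[:, 2],
            "gc1_b": latent_b[:, 0],
            "gc2_b": latent_b[:, 1],
            "gc3_b": latent_b[:, 2],
        }
    )
    return cds_a, cds_b, pairing, truth


def _is_stop_matrix(codons: np.ndarray) -> np.ndarray:
    """Boolean stop-codon mask for an (..., 3) array of base codes."""
    t, a, g = ord("T"), ord("A"), ord("G")
    first_t = codons[..., 0] == t
    return first_t & (
        ((codons[..., 1] == a) & ((codons[..., 2] == a) | (codons[..., 2] == g)))
        | ((codons[..., 1] == g) & (codons[..., 2] == a))
    )
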