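"""Conservation profiles, alignment-fraction triangles and matched controls.

The alignment-fraction triangle summarizes, per element, how many genomes
align nearly all (N1) or nearly none (N2) of its sequence.  Elements are
then partitioned into conservation groups (strongly conserved / actively
evolving / primate-specific), into density-balanced triangle slices, and
by inferred evolutionary origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tracks import ElementSet, GenomicInterval, SignalTrack

__all__ = [
    "TriangleCoords",
    "ConservationGroup",
    "GroupParams",
    "aggregate_signal_profile",
    "triangle_coordinates",
    "assign_conservation_groups",
    "triangle_slices",
    "evolutionary_origin",
    "matched_controls",
    "gc_cpg_counts",
]

HI_FRACTION = 0.90
LO_FRACTION = 0.10


@dataclass(frozen=True)
class TriangleCoords:
    """Counts of species aligning >= hi (N1) and <= lo (N2) of an element."""

    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.n2 < 0:
            raise ValueError("N1 and N2 must be >= 0")


class ConservationGroup(str, Enum):
    G1 = "G1"
    G2 = "G2"
    G3 = "G3"
    OTHER = "other"


@dataclass(frozen=True)
class GroupParams:
    """Thresholds for conservation-group assignment (all configurable)."""

    g1_majority_frac: float = 0.5
    g2_min_each_frac: float = 0.1
    g3_nonprimate_majority_frac: float = 0.5


def aggregate_signal_profile(
    track: SignalTrack,
    centers: Sequence[tuple[str, int]],
    flank: int,
    smooth_window: int = 1,
) -> np.ndarray:
    """Positionwise mean of a track around centers, then rolling-mean smoothed.

    The profile covers [center - flank, center + flank], length 2*flank + 1.
    Smoothing uses a centered window; edge positions use the truncated
    window.  ``smooth_window`` must be odd and <= flank.
    """
    if not centers:
        raise ValueError("empty center list")
    if smooth_window % 2 != 1:
        raise ValueError("smooth_window must be odd")
    if flank < smooth_window:
        raise ValueError("flank must be >= smooth_window")
    width = 2 * flank + 1
    acc = np.zeros(width, dtype=np.float64)
    for chrom, pos in centers:
        start = pos - flank
        if start < 0:
            # pad with zeros on the left, consistent with gap semantics
            vals = np.zeros(width)
            vals[-start:] = track.dense(chrom, 0, pos + flank + 1)
        else:
            vals = track.dense(chrom, start, pos + flank + 1)
        acc += vals
    profile = acc / len(centers)
    if smooth_window == 1:
        return profile
    half = smooth_window // 2
    csum = np.concatenate(([0.0], np.cumsum(profile)))
    out = np.empty(width)
    for i in range(width):
        lo = max(0, i - half)
        hi = min(width, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def triangle_coordinates(
    fractions: np.ndarray, hi: float = HI_FRACTION, lo: float = LO_FRACTION
) -> TriangleCoords:
    """N1 = #{f >= hi}, N2 = #{f <= lo} over a per-element species vector."""
    fractions = np.asarray(fractions, dtype=np.float64)
    if np.any(fractions < 0) or np.any(fractions > 1):
        raise ValueError("alignment fractions must be in [0, 1]")
    return TriangleCoords(int(np.sum(fractions >= hi)), int(np.sum(fractions <= lo)))


def assign_conservation_groups(
    coords: TriangleCoords,
    n_species: int,
    params: GroupParams = GroupParams(),
    nonprimate_n2: int | None = None,
    n_nonprimates: int | None = None,
) -> ConservationGroup:
    """Assign a conservation group from triangle coordinates.

    G1: N1 exceeds a majority of species.  G2 (else): both N1 and N2 reach
    a minimum fraction of species.  G3 (else): N2 restricted to
    non-primate species exceeds a majority of non-primates.  Otherwise
    "other".  When non-primate counts are not supplied, all species are
    treated as non-primate for the G3 test.
    """
    if coords.n1 + coords.n2 > n_species:
        raise ValueError("N1 + N2 exceeds species count")
    if coords.n1 > params.g1_majority_frac * n_species:
        return ConservationGroup.G1
    g2_min = params.g2_min_each_frac * n_species
    if coords.n1 >= g2_min and coords.n2 >= g2_min:
        return ConservationGroup.G2
    np_n2 = coords.n2 if nonprimate_n2 is None else nonprimate_n2
    np_total = n_species if n_nonprimates is None else n_nonprimates
    if np_n2 > params.g3_nonprimate_majority_frac * np_total:
        return ConservationGroup.G3
    return ConservationGroup.OTHER


def triangle_slices(
    all_coords: Sequence[TriangleCoords], rows: int = 4, cols: int = 4
) -> np.ndarray:
    """Density-balanced slice label (1..rows*cols) per element.

    Column boundaries are empirical quantiles of N2, row boundaries
    quantiles of N1, computed over all supplied elements.  Labels run
    row-major from (low N1, low N2); boundary values fall in the lower
    bin, so maximal coordinates land in the top row / rightmost column.
    """
    if len(all_coords) < rows * cols:
        raise ValueError("need at least rows*cols elements")
    n1 = np.array([c.n1 for c in all_coords], dtype=np.float64)
    n2 = np.array([c.n2 for c in all_coords], dtype=np.float64)
    qs = np.linspace(0, 1, rows + 1)[1:-1]
    row_bounds = np.quantile(n1, qs)
    col_bounds = np.quantile(n2, np.linspace(0, 1, cols + 1)[1:-1])
    for name, bounds in (("row", row_bounds), ("column", col_bounds)):
        if len(np.unique(bounds)) < len(bounds):
            warnings.warn(
                f"degenerate {name} quantile boundaries: fewer effective slices",
                stacklevel=2,
            )
    r = np.digitize(n1, row_bounds, right=True)
    c = np.digitize(n2, col_bounds, right=True)
    return (r * cols + c + 1).astype(np.int64)


def evolutionary_origin(
    fractions: np.ndarray,
    species_clades: Sequence[str],
    clades_near_to_far: Sequence[str],
    min_align_frac: float = 0.5,
) -> str:
    """Clade of the most distant species in which the element aligns.

    A species "aligns" when its fraction is >= ``min_align_frac``; with no
    aligning species the label is "human-specific".
    """
    fractions = np.asarray(fractions, dtype=np.float64)
    if len(fractions) != len(species_clades):
        raise ValueError("fractions and species_clades must be aligned")
    rank = {clade: i for i, clade in enumerate(clades_near_to_far)}
    unknown = set(species_clades) - set(rank)
    if unknown:
        raise ValueError(f"species clades not in declared order: {sorted(unknown)}")
    best = -1
    for f, clade in zip(fractions, species_clades):
        if f >= min_align_frac:
            best = max(best, rank[clade])
    return "human-specific" if best < 0 else clades_near_to_far[best]


def triangle_table(
    fraction_matrix: pd.DataFrame,
    hi: float = HI_FRACTION,
    lo: float = LO_FRACTION,
) -> pd.DataFrame:
    """(N1, N2) per element from an elements x species fraction matrix."""
    vals = fraction_matrix.to_numpy(dtype=np.float64)
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError("alignment fractions must be in [0, 1]")
    return pd.DataFrame(
        {"n1": (vals >= hi).sum(axis=1), "n2": (vals <= lo).sum(axis=1)},
        index=fraction_matrix.index,
    )


def gc_cpg_counts(seq: str) -> tuple[int, int]:
    """C+G mononucleotide count and CpG dinucleotide count of a sequence."""
    s = seq.upper()
    gc = s.count("C") + s.count("G")
    cpg = s.count("CG")
    return gc, cpg


def matched_controls(
    elements: ElementSet,
    genome: Mapping[str, str],
    seed: int,
    max_attempts: int = 1000,
) -> tuple[ElementSet, list[str]]:
    """Random same-length control regions with exactly matched composition.

    For each element, same-length windows are proposed uniformly across
    the genome (any chrom, weighted by placeable length) until one has
    exactly the element's C+G count and CpG count.  Windows containing N
    bases are rejected.  Returns the controls and the ids of elements for
    which ``max_attempts`` was exhausted (skipped, with a warning).
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(genome.keys())
    seqs = {c: str(genome[c]).upper() for c in chroms}
    lens = np.array([len(seqs[c]) for c in chroms], dtype=np.float64)
    controls: list[GenomicInterval] = []
    failed: list[str] = []
    for e in elements:
        target = gc_cpg_counts(seqs[e.chrom][e.start : e.end])
        length = len(e)
        placeable = np.maximum(lens - length + 1, 0)
        if placeable.sum() <= 0:
            raise ValueError(f"genome too short to place element {e.id}")
        probs = placeable / placeable.sum()
        found = False
        for _ in range(max_attempts):
            ci = int(rng.choice(len(chroms), p=probs))
            chrom = chroms[ci]
            start = int(rng.integers(0, int(placeable[ci])))
            window = seqs[chrom][start : start + length]
            if "N" in window:
                continue
            if gc_cpg_counts(window) == target:
                controls.append(
                    GenomicInterval(chrom, start, start + length, f"ctrl_{e.id}")
                )
                found = True
                break
        if not found:
            failed.append(e.id)
    if failed:
        warnings.warn(
            f"no matched control within {max_attempts} attempts for "
            f"{len(failed)} element(s); skipped",
            stacklevel=2,
        )
    return ElementSet(controls), failed
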