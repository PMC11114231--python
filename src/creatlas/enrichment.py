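"""Validation-region weighting, shuffle-null enrichment and trait selection."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tracks import ElementSet, GenomicInterval, count_overlapping, overlap_fractions

__all__ = [
    "ValidationRegion",
    "TissueClass",
    "EnrichmentResult",
    "BRAIN_TISSUES",
    "NERVOUS_NONBRAIN_TISSUES",
    "vista_weighted_validation",
    "classify_validation_tissue",
    "shuffle_enrichment",
    "window_targets_from_tss",
    "priority_assign",
    "select_independent_traits",
]

BRAIN_TISSUES = frozenset({"forebrain", "midbrain", "hindbrain"})
NERVOUS_NONBRAIN_TISSUES = frozenset(
    {"cranial nerve", "eye", "neural tube", "dorsal root ganglion", "trigeminal V"}
)
#: Common tissue names recognized as ordinary (non-nervous) activity.
KNOWN_NON_NERVOUS_TISSUES = frozenset(
    {
        "limb",
        "heart",
        "somite",
        "branchial arch",
        "nose",
        "ear",
        "tail",
        "facial mesenchyme",
        "genital tubercle",
        "melanocytes",
        "liver",
        "pancreas",
        "blood vessels",
    }
)

#: Label used for validation regions not touching any classified element.
NON_ELEMENT_CLASS = "non-cCRE"


class TissueClass(str, Enum):
    BRAIN = "brain"
    NERVOUS_NONBRAIN = "nervous-nonbrain"
    NON_NERVOUS = "non-nervous"
    INACTIVE = "inactive"


@dataclass(frozen=True)
class ValidationRegion:
    """A tested genomic region annotated with the tissues it is active in."""

    interval: GenomicInterval
    active_tissues: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class EnrichmentResult:
    observed: int
    null_mean: float
    null_sd: float
    enrichment: float
    #: observed / mean simulated count (secondary definition, for transparency)
    enrichment_vs_mean: float
    n_undefined: int = 0


def classify_validation_tissue(active_tissues: Iterable[str]) -> TissueClass:
    """Tissue class of a validation region from its active-tissue set.

    Brain beats nervous-nonbrain beats non-nervous; no activity at all is
    inactive.  Unknown tissue strings are treated as non-nervous evidence
    with a warning.
    """
    tissues = set(active_tissues)
    known = BRAIN_TISSUES | NERVOUS_NONBRAIN_TISSUES | KNOWN_NON_NERVOUS_TISSUES
    unknown = tissues - known
    if unknown:
        warnings.warn(
            f"unknown tissue strings treated as non-nervous: {sorted(unknown)}",
            stacklevel=2,
        )
    if tissues & BRAIN_TISSUES:
        return TissueClass.BRAIN
    if tissues & NERVOUS_NONBRAIN_TISSUES:
        return TissueClass.NERVOUS_NONBRAIN
    if tissues:
        return TissueClass.NON_NERVOUS
    return TissueClass.INACTIVE


def region_class_weights(
    region: ValidationRegion, classified: ElementSet
) -> dict[str, float]:
    """Fractional class weights contributed by one validation region.

    No overlapping element: weight 1 to the non-element class.  A single
    overlap: weight 1 to that element's class.  Multiple overlaps: each
    element contributes its overlap fraction (overlap bp / element
    length), normalized so the region's weights sum to 1.
    """
    if len(region.interval) <= 0:
        raise ValueError("zero-length validation region")
    q = ElementSet([region.interval])
    hits = overlap_fractions(q, classified).get(region.interval.id, [])
    if not hits:
        return {NON_ELEMENT_CLASS: 1.0}
    if len(hits) == 1:
        label = classified.label_of(hits[0][0], NON_ELEMENT_CLASS)
        return {label: 1.0}
    total = sum(f for _, f in hits)
    weights: dict[str, float] = {}
    for eid, frac in hits:
        label = classified.label_of(eid, NON_ELEMENT_CLASS)
        weights[label] = weights.get(label, 0.0) + frac / total
    return weights


def vista_weighted_validation(
    regions: Sequence[ValidationRegion], classified: ElementSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weighted class counts and rates per (tissue class x element class).

    Returns (counts, rates): counts sum to the number of regions; rates
    are per element class, i.e. each column of counts normalized by its
    column sum, giving the fraction of each class's weight attributable
    to each tissue class.
    """
    rows: dict[TissueClass, dict[str, float]] = {t: {} for t in TissueClass}
    for region in regions:
        tissue = classify_validation_tissue(region.active_tissues)
        for label, w in region_class_weights(region, classified).items():
            rows[tissue][label] = rows[tissue].get(label, 0.0) + w
    counts = pd.DataFrame(
        {t.value: rows[t] for t in TissueClass}
    ).T.fillna(0.0)
    col_sums = counts.sum(axis=0)
    rates = counts.divide(col_sums.where(col_sums > 0, np.nan), axis=1)
    return counts, rates


def shuffle_enrichment(
    query: ElementSet,
    targets: ElementSet,
    genome_sizes: Mapping[str, int],
    n_shuffles: int = 100,
    seed: int = 0,
    genome_wide: bool = False,
    exclude: ElementSet | None = None,
    max_place_attempts: int = 100,
) -> EnrichmentResult:
    """Permutation enrichment of query intervals against target intervals.

    The observed statistic is the number of query intervals overlapping
    >= 1 bp of any target.  Each shuffle replaces every query interval
    with a length-preserving uniform random placement (same chromosome by
    default; any chromosome weighted by length with ``genome_wide``),
    optionally rejecting placements overlapping ``exclude``.  The
    enrichment is the mean over shuffles of observed/simulated; shuffles
    with zero simulated intersections are excluded and counted.
    """
    if len(query) == 0:
        raise ValueError("empty query set")
    rng = np.random.default_rng(seed)
    merged = targets.merged()
    excl = exclude.merged() if exclude is not None else None
    observed = count_overlapping(
        ((e.chrom, e.start, e.end) for e in query), merged
    )
    chroms = sorted(genome_sizes)
    sizes = np.array([genome_sizes[c] for c in chroms], dtype=np.float64)

    def place(length: int, chrom: str) -> tuple[str, int]:
        for _ in range(max_place_attempts):
            if genome_wide:
                placeable = np.maximum(sizes - length, 0)
                c = chroms[int(rng.choice(len(chroms), p=placeable / placeable.sum()))]
            else:
                c = chrom
            limit = genome_sizes[c] - length
            if limit < 0:
                raise ValueError(f"interval of length {length} does not fit on {c}")
            s = int(rng.integers(0, limit + 1))
            if excl is not None and count_overlapping([(c, s, s + length)], excl):
                continue
            return c, s
        return c, s  # give up on exclusion after max attempts

    ratios: list[float] = []
    sim_counts: list[int] = []
    n_undefined = 0
    lengths = [(len(e), e.chrom) for e in query]
    for _ in range(n_shuffles):
        placed = []
        for length, chrom in lengths:
            c, s = place(length, chrom)
            placed.append((c, s, s + length))
        sim = count_overlapping(placed, merged)
        sim_counts.append(sim)
        if sim == 0:
            n_undefined += 1
        else:
            ratios.append(observed / sim)
    if not ratios:
        raise ValueError("all shuffles had zero simulated intersections")
    mean_sim = float(np.mean(sim_counts))
    return EnrichmentResult(
        observed=observed,
        null_mean=mean_sim,
        null_sd=float(np.std(ratios)),
        enrichment=float(np.mean(ratios)),
        enrichment_vs_mean=observed / mean_sim if mean_sim > 0 else float("nan"),
        n_undefined=n_undefined,
    )


def window_targets_from_tss(
    tss: Sequence[tuple[str, int]],
    window: int = 100_000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> ElementSet:
    """Symmetric windows around TSS positions, clipped to chromosome ends.

    Overlapping windows are kept separate (membership, not bp, drives the
    downstream overlap counting).
    """
    elems = []
    for i, (chrom, pos) in enumerate(tss):
        if pos < 0:
            raise ValueError("TSS positions must be >= 0")
        start = max(0, pos - window)
        end = pos + window
        if chrom_sizes is not None and chrom in chrom_sizes:
            end = min(end, chrom_sizes[chrom])
        elems.append(GenomicInterval(chrom, start, end, f"tss_{i}_{chrom}:{pos}"))
    return ElementSet(elems)


def priority_assign(
    catalog_regions: ElementSet,
    class_sets: Sequence[tuple[str, ElementSet]],
    no_overlap_label: str = NON_ELEMENT_CLASS,
) -> dict[str, str]:
    """Assign each region the label of the first class set it intersects.

    ``class_sets`` is ordered by priority; regions intersecting none of
    them get ``no_overlap_label``.
    """
    merged = [(label, es.merged()) for label, es in class_sets]
    out: dict[str, str] = {}
    for region in catalog_regions:
        key = (region.chrom, region.start, region.end)
        assigned = no_overlap_label
        for label, m in merged:
            if count_overlapping([key], m):
                assigned = label
                break
        out[region.id] = assigned
    return out


def select_independent_traits(
    rg: pd.DataFrame, threshold_sq: float = 0.1, seed: int = 0
) -> list[str]:
    """Greedy selection of mutually independent traits.

    Traits are visited in seeded-shuffle order and kept only if the
    squared genetic correlation with every previously kept trait does not
    exceed ``threshold_sq``.  Missing correlations count as 0.
    """
    if rg.shape[0] != rg.shape[1] or list(rg.index) != list(rg.columns):
        raise ValueError("rg must be square with matching index and columns")
    rng = np.random.default_rng(seed)
    traits = list(rg.index)
    order = rng.permutation(len(traits))
    kept: list[str] = []
    vals = rg.to_numpy(dtype=np.float64)
    vals = np.nan_to_num(vals, nan=0.0)
    idx = {t: i for i, t in enumerate(traits)}
    for i in order:
        t = traits[i]
        if all(vals[idx[t], idx[k]] ** 2 <= threshold_sq for k in kept):
            kept.append(t)
    return kept
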