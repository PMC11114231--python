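"""Cell-type classification and pseudo-bulk coverage metrics.

Aggregate accessibility tracks for groups of experiments (e.g. sorted
neuronal vs non-neuronal nuclei) are summed before re-calling activity;
classification then uses the 2x2 activity pattern of the two aggregates.
"""

from __future__ import annotations

import warnings
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .atlas import ACTIVE_Z, DEFAULT_PSEUDOCOUNT, lognorm_zscores
from .tracks import ElementSet, SignalTrack, mean_signal_over_elements, sum_tracks

__all__ = [
    "CellTypeLabel",
    "aggregate_group_zscores",
    "classify_neuron_glia",
    "celltype_activity_coverage",
    "overlap_coefficient_matrix",
]


class CellTypeLabel(str, Enum):
    NEURON_SPECIFIC = "neuron-specific"
    GLIA_SPECIFIC = "glia-specific"
    NEURON_GLIA_SHARED = "neuron-glia-shared"
    LOW_SIGNAL = "low-signal"


def aggregate_group_zscores(
    tracks: list[SignalTrack],
    elements: ElementSet,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Sum a group's tracks, then z-score the aggregate signal at elements."""
    agg = sum_tracks(tracks)
    return lognorm_zscores(mean_signal_over_elements(agg, elements), pseudocount)


def classify_neuron_glia(
    z_neuron: np.ndarray,
    z_glia: np.ndarray,
    element_ids: Iterable[str],
    threshold: float = ACTIVE_Z,
) -> dict[str, CellTypeLabel]:
    """Label elements by the 2x2 aggregate-activity pattern."""
    z_neuron = np.asarray(z_neuron, dtype=np.float64)
    z_glia = np.asarray(z_glia, dtype=np.float64)
    ids = list(element_ids)
    if len(z_neuron) != len(z_glia) or len(ids) != len(z_neuron):
        raise ValueError("z vectors and ids must be aligned and equal-length")
    out: dict[str, CellTypeLabel] = {}
    for eid, zn, zg in zip(ids, z_neuron, z_glia):
        n_act, g_act = zn > threshold, zg > threshold
        if n_act and g_act:
            out[eid] = CellTypeLabel.NEURON_GLIA_SHARED
        elif n_act:
            out[eid] = CellTypeLabel.NEURON_SPECIFIC
        elif g_act:
            out[eid] = CellTypeLabel.GLIA_SPECIFIC
        else:
            out[eid] = CellTypeLabel.LOW_SIGNAL
    return out


def celltype_activity_coverage(
    z: np.ndarray,
    element_ids: Iterable[str],
    reference_set: set[str],
    top_k: int = 50_000,
    min_active: int = 10_000,
    threshold: float = ACTIVE_Z,
) -> tuple[list[str], float] | None:
    """Coverage of a reference set by a dataset's top active elements.

    Elements with z above ``threshold`` are active; datasets calling
    fewer than ``min_active`` are dropped (``None``).  Otherwise the
    ``top_k`` highest-z active elements (or all of them if fewer) are
    taken and the fraction belonging to ``reference_set`` is returned.
    Ties are broken by a stable sort on (-z, element id).
    """
    z = np.asarray(z, dtype=np.float64)
    ids = list(element_ids)
    if len(ids) != len(z):
        raise ValueError("z vector and ids must be aligned")
    active = [(float(zi), eid) for zi, eid in zip(z, ids) if zi > threshold]
    if len(active) < min_active:
        return None
    active.sort(key=lambda t: (-t[0], t[1]))
    top = [eid for _, eid in active[: min(top_k, len(active))]]
    coverage = sum(1 for eid in top if eid in reference_set) / len(top)
    return top, coverage


def overlap_coefficient_matrix(sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Pairwise overlap coefficients |A&B| / min(|A|, |B|).

    Rows/columns involving an empty set are 0 (with a warning); the
    diagonal is 1 for non-empty sets.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = list(sets)
    empty = [n for n in names if not sets[n]]
    if empty:
        warnings.warn(f"empty sets get overlap coefficient 0: {empty}", stacklevel=2)
    n = len(names)
    mat = np.zeros((n, n), dtype=np.float64)
    for i, a in enumerate(names):
        for j, b in enumerate(names[i:], start=i):
            sa, sb = sets[a], sets[b]
            if not sa or not sb:
                val = 0.0
            else:
                val = len(sa & sb) / min(len(sa), len(sb))
            mat[i, j] = mat[j, i] = val
    return pd.DataFrame(mat, index=names, columns=names)
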