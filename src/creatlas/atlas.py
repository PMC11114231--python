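"""Consensus calling of brain-active elements from accessibility z-scores.

Phase 1 scores each experiment independently: per-element mean signal is
log-transformed and normalized to z-scores over the element universe, and
elements exceeding an activity threshold are called active.  Phase 2 takes
the consensus across experiments, with an optional high-z rescue path for
sparsely supported elements, and classifies elements by life stage.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .tracks import ElementSet, SignalTrack, mean_signal_over_elements

__all__ = [
    "LifeStageLabel",
    "DEFAULT_PSEUDOCOUNT",
    "ACTIVE_Z",
    "RESCUE_Z",
    "MIN_SUPPORT",
    "lognorm_zscores",
    "call_active_elements",
    "zscore_matrix",
    "activity_matrix",
    "consensus_bccres",
    "classify_life_stage",
]

#: One-tailed 95th-percentile standard-normal point, two decimals.
ACTIVE_Z = 1.64
#: 99th-percentile standard-normal point, truncated to two decimals.
RESCUE_Z = 2.32
#: Minimum number of supporting experiments for consensus membership.
MIN_SUPPORT = 5
DEFAULT_PSEUDOCOUNT = 1e-3


class DegenerateInputError(ValueError):
    """Raised when an input is constant where variation is required."""


class LifeStageLabel(str, Enum):
    ADULT_SPECIFIC = "adult-specific"
    FETAL_SPECIFIC = "fetal-specific"
    ADULT_FETAL_SHARED = "adult-fetal-shared"
    NON_BRAIN = "non-brain"


def lognorm_zscores(
    signal: np.ndarray, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> np.ndarray:
    """z-scores of natural-log-transformed signal.

    z = (ln(x + pseudocount) - mean) / SD with the population SD taken
    over the full input vector (the normalization universe).
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1 or signal.size < 2:
        raise ValueError("signal must be a 1-D vector of length >= 2")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if np.any(signal < 0) or not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite and >= 0")
    logx = np.log(signal + pseudocount)
    sd = float(np.std(logx))  # population SD
    if sd == 0.0:
        raise DegenerateInputError("constant signal vector: SD is zero")
    return (logx - logx.mean()) / sd


def call_active_elements(z: np.ndarray, threshold: float = ACTIVE_Z) -> np.ndarray:
    """Boolean activity calls: active iff z strictly exceeds the threshold."""
    z = np.asarray(z, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    return z > threshold


def zscore_matrix(
    tracks: Mapping[str, SignalTrack],
    elements: ElementSet,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Elements x experiments z-score matrix from per-experiment tracks."""
    cols = {}
    for exp_id, track in tracks.items():
        signal = mean_signal_over_elements(track, elements)
        cols[exp_id] = lognorm_zscores(signal, pseudocount)
    return pd.DataFrame(cols, index=elements.ids)


def activity_matrix(z: pd.DataFrame, threshold: float = ACTIVE_Z) -> pd.DataFrame:
    """Boolean activity matrix, same shape as the z-score matrix."""
    return pd.DataFrame(
        call_active_elements(z.to_numpy(), threshold),
        index=z.index,
        columns=z.columns,
    )


def consensus_bccres(
    activity: pd.DataFrame,
    z: pd.DataFrame,
    min_support: int = MIN_SUPPORT,
    rescue_threshold: float | None = RESCUE_Z,
) -> set[str]:
    """Consensus set of active elements across experiments.

    An element enters the consensus when it is active in >= ``min_support``
    experiments.  When ``rescue_threshold`` is set, elements active in at
    least one but fewer than ``min_support`` experiments are rescued if
    their maximum z-score exceeds the threshold.  Elements active in no
    experiment are never rescued.
    """
    if activity.shape != z.shape or list(activity.index) != list(z.index):
        raise ValueError("activity and z matrices must share shape and index")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    support = activity.to_numpy().sum(axis=1)
    keep = support >= min_support
    if rescue_threshold is not None:
        max_z = z.to_numpy().max(axis=1)
        keep |= (support >= 1) & (support < min_support) & (max_z > rescue_threshold)
    return set(np.asarray(activity.index)[keep])


def classify_life_stage(
    adult_set: Iterable[str],
    fetal_set: Iterable[str],
    universe: Iterable[str],
) -> dict[str, LifeStageLabel]:
    """Partition the universe into the four life-stage labels."""
    adult = set(adult_set)
    fetal = set(fetal_set)
    universe = set(universe)
    outside = (adult | fetal) - universe
    if outside:
        raise ValueError(f"ids outside universe: {sorted(outside)[:5]}")
    out: dict[str, LifeStageLabel] = {}
    for eid in universe:
        in_a, in_f = eid in adult, eid in fetal
        if in_a and in_f:
            out[eid] = LifeStageLabel.ADULT_FETAL_SHARED
        elif in_a:
            out[eid] = LifeStageLabel.ADULT_SPECIFIC
        elif in_f:
            out[eid] = LifeStageLabel.FETAL_SPECIFIC
        else:
            out[eid] = LifeStageLabel.NON_BRAIN
    return out
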