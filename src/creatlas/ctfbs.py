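"""HMM segmentation of base-resolution importance scores into candidate
TF binding sites, with motif assignment by padded PWM similarity.

Per-base importance scores are z-normalized over the whole dataset,
discretized into {-1, 0, +1} symbols, and segmented with a 3-state HMM
whose states are intended to emit predominantly -1s, 0s and +1s.  Decoded
direction-state runs become candidate sites after long zero runs are
excised; each site is then assigned its most similar catalog motif.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from hmmlearn.hmm import CategoricalHMM
from scipy.stats import chi2_contingency

from .pwm import PWM, encode_sequence, reverse_complement
from .tracks import ElementSet, GenomicInterval, SignalTrack

__all__ = [
    "IMPORTANCE_Z",
    "MIN_ZERO_RUN",
    "MIN_INSTANCES",
    "Direction",
    "HmmModel",
    "CtfbsRecord",
    "importance_zscores",
    "discretize_importance",
    "fit_importance_hmm",
    "decode_states",
    "segment_ctfbs",
    "motif_similarity",
    "assign_best_motif",
    "motif_set_chi2",
    "site_specificity_classes",
    "site_importance_profiles",
]

#: Two-decimal 97.5th-percentile standard-normal point (+/- discretization).
IMPORTANCE_Z = 1.96
#: Zero runs at least this long split decoded segments.
MIN_ZERO_RUN = 4
#: Fragments shorter than this are discarded (guards against calling
#: chance runs of extreme noise symbols as sites).
MIN_SITE_LEN = 4
#: Minimum per-set motif instances for the chi-square comparison.
MIN_INSTANCES = 25

# symbol -> categorical index
_SYM_TO_CAT = {-1: 0, 0: 1, 1: 2}


class Direction(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class HmmModel:
    """3-state HMM over {-1, 0, +1} symbols (categorical indices 0, 1, 2).

    After fitting, states are relabeled so state 0 best emits -1, state 1
    best emits 0 and state 2 best emits +1.
    """

    startprob: np.ndarray
    transmat: np.ndarray
    emissionprob: np.ndarray
    log_likelihoods: tuple[float, ...] = ()
    degenerate: bool = False

    def __post_init__(self) -> None:
        for name, arr, shape in (
            ("startprob", self.startprob, (3,)),
            ("transmat", self.transmat, (3, 3)),
            ("emissionprob", self.emissionprob, (3, 3)),
        ):
            a = np.asarray(arr, dtype=np.float64)
            if a.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
            if np.any(a < 0) or np.any(a > 1):
                raise ValueError(f"{name} entries must be in [0, 1]")
            sums = a.sum(axis=-1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise ValueError(f"{name} rows must sum to 1 (tolerance 1e-9)")
            object.__setattr__(self, name, a)


@dataclass(frozen=True)
class CtfbsRecord:
    """An HMM-called importance segment with its assigned motif."""

    interval: GenomicInterval
    direction: Direction
    mean_importance: float
    motif_id: str | None = None
    similarity: float = float("nan")

    def __post_init__(self) -> None:
        if self.mean_importance > 0 and self.direction is not Direction.POSITIVE:
            raise ValueError("positive mean importance requires positive direction")
        if self.mean_importance < 0 and self.direction is not Direction.NEGATIVE:
            raise ValueError("negative mean importance requires negative direction")


def importance_zscores(windows: Sequence[np.ndarray]) -> list[np.ndarray]:
    """z-scores of importance values, normalized over the whole dataset.

    The mean and population SD are taken over all positions of all
    windows, not per window.
    """
    if not windows:
        raise ValueError("no importance windows supplied")
    flat = np.concatenate([np.asarray(w, dtype=np.float64) for w in windows])
    if not np.all(np.isfinite(flat)):
        raise ValueError("importance scores must be finite")
    mu, sd = float(flat.mean()), float(flat.std())
    if sd == 0.0:
        raise ValueError("degenerate importance dataset: SD is zero")
    return [(np.asarray(w, dtype=np.float64) - mu) / sd for w in windows]


def discretize_importance(z: np.ndarray, z_hi: float = IMPORTANCE_Z) -> np.ndarray:
    """Symbols per base: +1 for z > z_hi, -1 for z < -z_hi, else 0."""
    z = np.asarray(z, dtype=np.float64)
    out = np.zeros(len(z), dtype=np.int64)
    out[z > z_hi] = 1
    out[z < -z_hi] = -1
    return out


def _to_hmmlearn(model: HmmModel) -> CategoricalHMM:
    hm = CategoricalHMM(n_components=3, init_params="", params="")
    hm.n_features = 3
    hm.startprob_ = model.startprob.copy()
    hm.transmat_ = model.transmat.copy()
    hm.emissionprob_ = model.emissionprob.copy()
    return hm


def _encode(sequences: Sequence[np.ndarray]) -> tuple[np.ndarray, list[int]]:
    lengths = [len(s) for s in sequences]
    cat = np.concatenate(
        [np.vectorize(_SYM_TO_CAT.__getitem__)(np.asarray(s)) for s in sequences]
    ).reshape(-1, 1)
    return cat.astype(np.int64), lengths


def fit_importance_hmm(
    sequences: Sequence[np.ndarray],
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> HmmModel:
    """Baum-Welch fit of the 3-state symbol HMM.

    Initialization is informed (sticky transitions, emissions biased
    toward the intended -1/0/+1 state semantics, with seeded jitter).
    States are relabeled post hoc so the permutation maximizes the summed
    probability of each state emitting its namesake symbol.  A fit on
    symbol-constant input is flagged as degenerate.
    """
    sequences = [np.asarray(s, dtype=np.int64) for s in sequences]
    if not sequences or any(len(s) == 0 for s in sequences):
        raise ValueError("need >= 1 non-empty symbol sequence")
    X, lengths = _encode(sequences)
    degenerate = len(np.unique(X)) == 1
    rng = np.random.default_rng(seed)

    hm = CategoricalHMM(
        n_components=3,
        n_iter=max_iter,
        tol=tol,
        init_params="",
        params="ste",
        random_state=int(rng.integers(2**31 - 1)),
    )
    hm.n_features = 3
    jitter = rng.uniform(0, 0.02, size=(3, 3))
    emission = np.array(
        [[0.70, 0.25, 0.05], [0.05, 0.90, 0.05], [0.05, 0.25, 0.70]]
    )
    emission = emission + jitter
    hm.emissionprob_ = emission / emission.sum(axis=1, keepdims=True)
    trans = np.full((3, 3), 0.05) + np.eye(3) * 0.85
    hm.transmat_ = trans / trans.sum(axis=1, keepdims=True)
    hm.startprob_ = np.array([0.05, 0.90, 0.05])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hm.fit(X, lengths)

    # relabel states: permutation maximizing sum_c P(emit c | state perm[c])
    em = hm.emissionprob_
    best_perm = max(
        itertools.permutations(range(3)),
        key=lambda p: sum(em[p[c], c] for c in range(3)),
    )
    perm = np.array(best_perm)
    start = hm.startprob_[perm]
    trans = hm.transmat_[np.ix_(perm, perm)]
    em = em[perm]

    def _renorm(a: np.ndarray) -> np.ndarray:
        a = np.clip(a, 0.0, 1.0)
        return a / a.sum(axis=-1, keepdims=True)

    return HmmModel(
        startprob=_renorm(start),
        transmat=_renorm(trans),
        emissionprob=_renorm(em),
        log_likelihoods=tuple(float(x) for x in hm.monitor_.history),
        degenerate=degenerate,
    )


def decode_states(
    model: HmmModel, sequence: np.ndarray, method: str = "viterbi"
) -> np.ndarray:
    """Hidden-state path for a symbol sequence ("viterbi" or "map")."""
    hm = _to_hmmlearn(model)
    X, _ = _encode([np.asarray(sequence, dtype=np.int64)])
    if method == "viterbi":
        _, states = hm.decode(X, algorithm="viterbi")
    elif method == "map":
        states = hm.predict_proba(X).argmax(axis=1)
    else:
        raise ValueError(f"unknown decoding method: {method}")
    return np.asarray(states, dtype=np.int64)


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs where mask is True."""
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _split_on_zero_runs(
    symbols: np.ndarray, start: int, end: int, min_zero_run: int
) -> list[tuple[int, int]]:
    """Excise runs of >= min_zero_run zeros inside [start, end)."""
    fragments = []
    frag_start = start
    i = start
    while i < end:
        if symbols[i] == 0:
            j = i
            while j < end and symbols[j] == 0:
                j += 1
            if j - i >= min_zero_run:
                if i > frag_start:
                    fragments.append((frag_start, i))
                frag_start = j
            i = j
        else:
            i += 1
    if end > frag_start:
        fragments.append((frag_start, end))
    return fragments


def segment_ctfbs(
    model: HmmModel,
    symbols: np.ndarray,
    window: GenomicInterval | None = None,
    importance: np.ndarray | None = None,
    min_zero_run: int = MIN_ZERO_RUN,
    min_site_len: int = MIN_SITE_LEN,
    method: str = "viterbi",
) -> list[CtfbsRecord]:
    """Candidate sites from one decoded symbol window.

    Maximal runs of the +1-state and -1-state become candidate segments;
    a direction state is only trusted when its most likely emission is
    its namesake symbol (a degenerate fit where every state mostly emits
    0 yields no sites).  Runs of >= ``min_zero_run`` consecutive zeros
    inside a segment are excised, splitting it; fragments whose mean raw
    importance contradicts the segment direction are dropped.

    Coordinates are relative to the window, lifted to the genome when
    ``window`` is given.
    """
    symbols = np.asarray(symbols, dtype=np.int64)
    states = decode_states(model, symbols, method=method)
    records: list[CtfbsRecord] = []
    for state, direction, sym in (
        (2, Direction.POSITIVE, 1),
        (0, Direction.NEGATIVE, -1),
    ):
        cat = _SYM_TO_CAT[sym]
        if int(model.emissionprob[state].argmax()) != cat:
            continue  # state does not predominantly emit its symbol
        for seg_start, seg_end in _runs_of(states == state):
            for s, e in _split_on_zero_runs(symbols, seg_start, seg_end, min_zero_run):
                if e - s < min_site_len:
                    continue
                if importance is not None:
                    mean_imp = float(np.mean(importance[s:e]))
                else:
                    mean_imp = float(np.mean(symbols[s:e]))
                if (direction is Direction.POSITIVE) != (mean_imp > 0):
                    continue
                if window is not None:
                    iv = GenomicInterval(
                        window.chrom,
                        window.start + s,
                        window.start + e,
                        f"{window.id}:{s}-{e}:{direction.value[:3]}",
                    )
                else:
                    iv = GenomicInterval("window", s, e, f"{s}-{e}:{direction.value[:3]}")
                records.append(CtfbsRecord(iv, direction, mean_imp))
    records.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return records


def _similarity_one_strand(seq_idx: np.ndarray, pwm: PWM) -> float:
    n, L = len(seq_idx), len(pwm)
    # append an N column so index 4 contributes 0.25
    mat = np.hstack([pwm.matrix, np.full((L, 1), 0.25)])
    if n >= L:
        best = -np.inf
        for off in range(n - L + 1):
            score = mat[np.arange(L), seq_idx[off : off + L]].sum() + 0.25 * (n - L)
            best = max(best, float(score))
        return best
    best = -np.inf
    for off in range(L - n + 1):
        score = mat[np.arange(off, off + n), seq_idx].sum() + 0.25 * (L - n)
        best = max(best, float(score))
    return best


def motif_similarity(seq: str, pwm: PWM, both_strands: bool = True) -> float:
    """Padded alignment similarity between a sequence and a PWM.

    Every offset of the shorter object fully inside the longer is
    scored as the sum of the PWM probabilities at aligned positions plus
    0.25 per unaligned position of the longer object; the maximum over
    offsets (and both strands by default) is returned.  N bases
    contribute 0.25.
    """
    if not seq:
        raise ValueError("empty sequence")
    fwd = _similarity_one_strand(encode_sequence(seq), pwm)
    if not both_strands:
        return fwd
    rev = _similarity_one_strand(encode_sequence(reverse_complement(seq)), pwm)
    return max(fwd, rev)


def assign_best_motif(
    seq: str, catalog: Mapping[str, PWM], both_strands: bool = True
) -> tuple[str, float]:
    """Most similar catalog motif; ties go to the smallest motif id."""
    if not catalog:
        raise ValueError("empty motif catalog")
    best_id, best_score = None, -np.inf
    for motif_id in sorted(catalog):
        score = motif_similarity(seq, catalog[motif_id], both_strands)
        if score > best_score:
            best_id, best_score = motif_id, score
    return best_id, float(best_score)


def motif_set_chi2(
    counts_a: Mapping[str, int],
    total_a: int,
    counts_b: Mapping[str, int],
    total_b: int,
    min_instances: int = MIN_INSTANCES,
) -> dict[str, tuple[float, float]]:
    """Per-motif chi-square comparison of instance fractions in two sets.

    Motifs with fewer than ``min_instances`` in either set are excluded.
    Each remaining motif is tested on the 2x2 table
    [[a, total_a - a], [b, total_b - b]] with Yates continuity
    correction.  Zero-margin tables are excluded with a warning.
    """
    out: dict[str, tuple[float, float]] = {}
    for motif in sorted(set(counts_a) | set(counts_b)):
        a = counts_a.get(motif, 0)
        b = counts_b.get(motif, 0)
        if a > total_a or b > total_b:
            raise ValueError(f"count exceeds total for motif {motif}")
        if a < min_instances or b < min_instances:
            continue
        table = np.array([[a, total_a - a], [b, total_b - b]], dtype=np.float64)
        if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            warnings.warn(f"zero-margin table for motif {motif}; excluded", stacklevel=2)
            continue
        res = chi2_contingency(table, correction=True)
        out[motif] = (float(res.statistic), float(res.pvalue))
    return out


def site_specificity_classes(
    sites_a: ElementSet, sites_b: ElementSet
) -> dict[str, str]:
    """Label each site a-only / b-only / shared by >= 1 bp cross-overlap."""
    merged_a = sites_a.merged()
    merged_b = sites_b.merged()
    out: dict[str, str] = {}
    from .tracks import count_overlapping

    for s in sites_a:
        hit = count_overlapping([(s.chrom, s.start, s.end)], merged_b)
        out[s.id] = "shared" if hit else "a-only"
    for s in sites_b:
        hit = count_overlapping([(s.chrom, s.start, s.end)], merged_a)
        out[s.id] = "shared" if hit else "b-only"
    return out


def site_importance_profiles(
    sites: ElementSet,
    tracks: Mapping[str, SignalTrack],
    window: int = 101,
) -> dict[str, np.ndarray]:
    """Per cell type, positionwise mean importance over aligned site windows.

    Windows of fixed length are centered on each site midpoint; sites
    whose window would run off the chromosome start are skipped with a
    warning.
    """
    if len(sites) == 0:
        raise ValueError("empty site list")
    half = window // 2
    usable: list[GenomicInterval] = []
    skipped = 0
    for s in sites:
        if s.midpoint - half < 0:
            skipped += 1
            continue
        usable.append(s)
    if skipped:
        warnings.warn(f"{skipped} site(s) exceeded track bounds; skipped", stacklevel=2)
    if not usable:
        raise ValueError("no usable sites within track bounds")
    out: dict[str, np.ndarray] = {}
    for ct, track in tracks.items():
        acc = np.zeros(window, dtype=np.float64)
        for s in usable:
            start = s.midpoint - half
            acc += track.dense(s.chrom, start, start + window)
        out[ct] = acc / len(usable)
    return out
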