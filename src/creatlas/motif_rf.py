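"""Motif-enrichment machine learning.

Sequences are featurized by max PWM log-odds scores, negatives come from
dinucleotide shuffling, and motif importances are averaged over an
ensemble of random-forest classifiers, optionally combined with external
enrichment scores and differential-expression statistics.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .pwm import PWM, encode_sequence, reverse_complement

__all__ = [
    "N_MODELS",
    "pwm_max_scores",
    "dinucleotide_shuffle",
    "rf_motif_importance",
    "combine_importance_expression",
]

N_MODELS = 10
LOGODDS_FLOOR = 1e-3
BACKGROUND = 0.25


def _logodds(pwm: PWM, background: float, floor: float) -> np.ndarray:
    """L x 5 log2 odds matrix; the 5th column (N) scores 0."""
    lo = np.log2(np.maximum(pwm.matrix, floor) / background)
    return np.hstack([lo, np.zeros((len(pwm), 1))])


def _max_score_one(seq_idx: np.ndarray, lo: np.ndarray) -> float:
    L = lo.shape[0]
    n = len(seq_idx)
    if n < L:
        return -np.inf
    scores = np.zeros(n - L + 1)
    for j in range(L):
        scores += lo[j, seq_idx[j : j + n - L + 1]]
    return float(scores.max())


def pwm_max_scores(
    sequences: Sequence[str],
    catalog: Mapping[str, PWM],
    background: float = BACKGROUND,
    floor: float = LOGODDS_FLOOR,
    log_odds: bool = True,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Sequences x motifs matrix of max PWM scores.

    The score is the maximum over positions (and both strands by default)
    of the summed per-position log2 odds against a uniform background,
    with probabilities floored at ``floor``.  With ``log_odds=False`` the
    raw probability sum is used instead.  Sequences shorter than a motif
    get that motif's dataset minimum, with a warning.
    """
    if not catalog:
        raise ValueError("empty motif catalog")
    motif_ids = sorted(catalog)
    enc_f = [encode_sequence(s) for s in sequences]
    enc_r = [encode_sequence(reverse_complement(s)) for s in sequences] if both_strands else None
    mat = np.empty((len(sequences), len(motif_ids)))
    short_warned = False
    for j, mid in enumerate(motif_ids):
        pwm = catalog[mid]
        if log_odds:
            lo = _logodds(pwm, background, floor)
        else:
            lo = np.hstack([pwm.matrix, np.full((len(pwm), 1), 0.25)])
        for i in range(len(sequences)):
            best = _max_score_one(enc_f[i], lo)
            if both_strands:
                best = max(best, _max_score_one(enc_r[i], lo))
            mat[i, j] = best
        col = mat[:, j]
        if np.any(np.isneginf(col)):
            finite = col[np.isfinite(col)]
            fill = float(finite.min()) if len(finite) else 0.0
            mat[np.isneginf(col), j] = fill
            if not short_warned:
                warnings.warn(
                    "sequences shorter than a motif scored at the dataset minimum",
                    stacklevel=2,
                )
                short_warned = True
    return pd.DataFrame(mat, columns=motif_ids)


def dinucleotide_shuffle(seq: str, seed: int) -> str:
    """Dinucleotide-preserving shuffle (Euler-path construction).

    The output has exactly the input's dinucleotide count multiset and
    the same first and last base; it is deterministic for a given seed.
    N (or any non-ACGT symbol) is treated as an ordinary 5th symbol.
    """
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    rng = np.random.default_rng(seed)
    s = seq.upper()
    vertices = sorted(set(s))
    # adjacency: multiset of successors for each vertex
    adj: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(s[:-1], s[1:]):
        adj[a].append(b)
    last = s[-1]

    # Altschul-Erickson: pick a random last edge from each non-terminal
    # vertex such that the chosen edges form a tree pointing toward the
    # terminal vertex; then permute the remaining edges.
    for _ in range(10_000):
        last_edge: dict[str, str] = {}
        for v in vertices:
            if v != last and adj[v]:
                last_edge[v] = adj[v][int(rng.integers(len(adj[v])))]
        # connectivity check: every non-terminal vertex with out-edges
        # must reach `last` via chosen last edges
        ok = True
        for v in last_edge:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - practically unreachable
        raise RuntimeError("failed to construct an Eulerian arrangement")

    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        edges = list(adj[v])
        if v in last_edge:
            edges.remove(last_edge[v])
        rng.shuffle(edges)
        if v in last_edge:
            edges.append(last_edge[v])
        shuffled[v] = edges

    out = [s[0]]
    counters = {v: 0 for v in vertices}
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = shuffled[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def rf_motif_importance(
    pos_features: pd.DataFrame,
    neg_features: pd.DataFrame,
    n_models: int = N_MODELS,
    seed: int = 0,
    n_estimators: int = 100,
) -> pd.Series:
    """Ensemble-averaged, normalized random-forest motif importances.

    ``n_models`` forests are trained with distinct derived seeds on the
    positive-vs-negative classification task; each model's impurity-based
    importances are normalized to sum to 1 and the final importance is
    the mean across models (which again sums to 1).
    """
    if list(pos_features.columns) != list(neg_features.columns):
        raise ValueError("positive and negative feature columns must match")
    if len(pos_features) == 0 or len(neg_features) == 0:
        raise ValueError("both classes must be non-empty")
    X = np.vstack([pos_features.to_numpy(), neg_features.to_numpy()])
    y = np.concatenate([np.ones(len(pos_features)), np.zeros(len(neg_features))])
    rng = np.random.default_rng(seed)
    model_seeds = rng.integers(0, 2**31 - 1, size=n_models)
    acc = np.zeros(X.shape[1])
    for ms in model_seeds:
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=int(ms), n_jobs=1
        )
        clf.fit(X, y)
        imp = clf.feature_importances_
        total = imp.sum()
        if total > 0:
            imp = imp / total
        acc += imp
    acc /= n_models
    if acc.sum() > 0:
        acc = acc / acc.sum()
    return pd.Series(acc, index=pos_features.columns, name="importance")


def _minmax(values: pd.Series) -> pd.Series:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        warnings.warn("constant score vector scaled to all zeros", stacklevel=2)
        return pd.Series(np.zeros(len(values)), index=values.index)
    return (values - lo) / (hi - lo)


def combine_importance_expression(
    importance: Mapping[str, float],
    enrichment_scores: Mapping[str, float],
    tf_expression: Mapping[str, float],
    motif_to_tf: Mapping[str, str],
) -> pd.DataFrame:
    """Combine scaled importances and enrichment scores, joined to TFs.

    Both score vectors are min-max scaled to [0, 1] over the motifs they
    share; the combined score (in [0, 2]) is their sum.  Motifs missing
    from either input are excluded with a warning.  The result is joined
    to a TF differential-expression statistic through ``motif_to_tf``.
    """
    imp = pd.Series(dict(importance), dtype=float)
    enr = pd.Series(dict(enrichment_scores), dtype=float)
    shared = imp.index.intersection(enr.index)
    dropped = set(imp.index).symmetric_difference(enr.index)
    if dropped:
        warnings.warn(
            f"motifs missing from one score map excluded: {sorted(dropped)[:5]}",
            stacklevel=2,
        )
    if len(shared) == 0:
        raise ValueError("no shared motifs between importance and enrichment")
    combined = _minmax(imp.loc[shared]) + _minmax(enr.loc[shared])
    rows = []
    for motif in shared:
        tf = motif_to_tf.get(motif)
        rows.append(
            {
                "motif": motif,
                "tf": tf,
                "combined_score": float(combined.loc[motif]),
                "diff_expression": tf_expression.get(tf, np.nan) if tf else np.nan,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("combined_score", ascending=False)
        .reset_index(drop=True)
    )
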