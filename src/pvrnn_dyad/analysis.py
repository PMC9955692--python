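"""Behavioral statistics for dyadic interactions.

All measures operate on per-step primitive label sequences (ints 0/1/2 for
A/B/C, as produced by the ESN classifier): movement frequencies,
synchronization rates and their chance level, turn-taking counts,
plug-in transfer entropy on the 3-symbol alphabet, and the partition of a
meta-prior grid into ignoring / leading / turn-taking regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .movement import Primitive

__all__ = ["SyncReport", "TEResult", "movement_frequency",
           "synchronization_rate", "chance_level_sync", "per_label_chance",
           "count_turn_taking", "transfer_entropy",
           "sliding_transfer_entropy", "classify_phase_regions"]


@dataclass(frozen=True)
class SyncReport:
    """Synchronization of two label sequences.

    ``overall``: fraction of steps with equal labels.  ``per_label[M]``:
    steps where both show M over steps where either shows M.
    """

    overall: float
    per_label: tuple[float, float, float]

    def __post_init__(self) -> None:
        assert 0.0 <= self.overall <= 1.0


def _as_labels(seq) -> np.ndarray:
    arr = np.asarray(seq, dtype=int)
    if arr.ndim != 1:
        raise ValueError("label sequence must be 1-D")
    return arr


def movement_frequency(labels) -> np.ndarray:
    """Fractions of A, B, C in a label sequence (sums to 1)."""
    arr = _as_labels(labels)
    if arr.size == 0:
        raise ValueError("label sequence must be non-empty")
    counts = np.bincount(arr, minlength=3)
    return counts / counts.sum()


def synchronization_rate(labels1, labels2) -> SyncReport:
    """Step-wise label agreement of two equally long sequences."""
    a, b = _as_labels(labels1), _as_labels(labels2)
    if a.shape != b.shape:
        raise ValueError("label sequences must have equal length")
    if a.size == 0:
        raise ValueError("label sequences must be non-empty")
    overall = float(np.mean(a == b))
    per = []
    for m in range(3):
        either = (a == m) | (b == m)
        both = (a == m) & (b == m)
        per.append(float(both.sum() / either.sum()) if either.any() else 0.0)
    return SyncReport(overall=overall, per_label=tuple(per))


def chance_level_sync(p1, p2) -> float:
    """Chance-level overall synchronization of two independent label
    distributions: sum_M p1(M) p2(M)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    for p in (p1, p2):
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("label distributions must sum to 1")
    return float(np.dot(p1, p2))


def per_label_chance(p1, p2) -> np.ndarray:
    """Chance level of the per-label sync rate (both-show-M over
    either-shows-M) for independent marginals:
    p1 p2 / (p1 + p2 - p1 p2), per label."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    both = p1 * p2
    either = p1 + p2 - both
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(either > 0, both / either, 0.0)
    return out


def _sync_segments(a: np.ndarray, b: np.ndarray, min_run: int) -> list[int]:
    """Labels of maximal synchronized B/C runs of length >= min_run."""
    sync = (a == b) & ((a == Primitive.B) | (a == Primitive.C))
    segs: list[int] = []
    t = 0
    n = a.size
    while t < n:
        if sync[t]:
            lab = a[t]
            start = t
            while t < n and sync[t] and a[t] == lab:
                t += 1
            if t - start >= min_run:
                segs.append(int(lab))
        else:
            t += 1
    return segs


def count_turn_taking(labels1, labels2, min_run: int = 20) -> int:
    """Number of turn exchanges between synchronized B and C episodes.

    A turn is a transition from a synchronized-B segment to the next
    synchronized-C segment (or vice versa); intervening A steps or
    unsynchronized stretches do not reset the detector.  Segments shorter
    than ``min_run`` steps (default: one primitive duration) are ignored as
    label flicker.
    """
    a, b = _as_labels(labels1), _as_labels(labels2)
    if a.shape != b.shape:
        raise ValueError("label sequences must have equal length")
    segs = _sync_segments(a, b, min_run)
    return int(sum(1 for prev, cur in zip(segs, segs[1:]) if prev != cur))


def transfer_entropy(source, target, k: int = 1, l: int = 1) -> float:
    """Plug-in transfer entropy (bits) from source to target labels.

    TE_{X->Y} = sum p(y_{t+1}, y_t^(k), x_t^(l))
                log2 [ p(y_{t+1} | y_t^(k), x_t^(l)) / p(y_{t+1} | y_t^(k)) ]
    over the 3-symbol alphabet, estimated from joint counts with no bias
    correction.
    """
    x, y = _as_labels(source), _as_labels(target)
    if x.shape != y.shape:
        raise ValueError("sequences must have equal length")
    m = max(k, l)
    n = y.size - m
    if n < 1:
        raise ValueError("sequences too short for the given history lengths")

    def embed(seq: np.ndarray, order: int) -> np.ndarray:
        """Code each length-``order`` history ending at t (t = m-1 .. n+m-2)."""
        code = np.zeros(n, dtype=np.int64)
        for j in range(order):
            code = code * 3 + seq[m - 1 - j: m - 1 - j + n]
        return code

    yk = embed(y, k)
    xl = embed(x, l)
    y1 = y[m:].astype(np.int64)

    def probs(codes: np.ndarray) -> dict[int, float]:
        vals, counts = np.unique(codes, return_counts=True)
        return dict(zip(vals.tolist(), (counts / n).tolist()))

    nx = 3 ** l
    j_y1_yk_xl = probs((y1 * (3 ** k) + yk) * nx + xl)
    j_yk_xl = probs(yk * nx + xl)
    j_y1_yk = probs(y1 * (3 ** k) + yk)
    j_yk = probs(yk)

    te = 0.0
    for code, p in j_y1_yk_xl.items():
        xl_c = code % nx
        rest = code // nx
        yk_c = rest % (3 ** k)
        y1_c = rest // (3 ** k)
        p_cond_full = p / j_yk_xl[yk_c * nx + xl_c]
        p_cond_self = j_y1_yk[y1_c * (3 ** k) + yk_c] / j_yk[yk_c]
        te += p * np.log2(p_cond_full / p_cond_self)
    return max(float(te), 0.0)


def sliding_transfer_entropy(source, target, window: int = 320,
                             k: int = 1, l: int = 1) -> np.ndarray:
    """Transfer entropy over every length-``window`` suffix [t-window+1, t].

    Returns an array of length T - window + 1 (one value per valid t).
    """
    x, y = _as_labels(source), _as_labels(target)
    T = x.size
    if T < window:
        raise ValueError("sequences shorter than the sliding window")
    return np.array([
        transfer_entropy(x[s:s + window], y[s:s + window], k=k, l=l)
        for s in range(T - window + 1)
    ])


def classify_phase_regions(
    sync_b: np.ndarray,
    sync_c: np.ndarray,
    chance_b: float,
    chance_c: float,
) -> np.ndarray:
    """Partition a meta-prior grid into behavior-coordination regions.

    ``sync_b`` / ``sync_c`` are per-cell per-label synchronization rates.
    Both above their chance level -> 'turn_taking'; neither -> 'ignoring';
    only C (agent 1's preferred movement) -> 'robot1_leads'; only B ->
    'robot2_leads'.
    """
    sync_b = np.asarray(sync_b, dtype=float)
    sync_c = np.asarray(sync_c, dtype=float)
    above_b = sync_b > chance_b
    above_c = sync_c > chance_c
    out = np.full(sync_b.shape, "ignoring", dtype=object)
    out[above_b & above_c] = "turn_taking"
    out[~above_b & above_c] = "robot1_leads"
    out[above_b & ~above_c] = "robot2_leads"
    return out


@dataclass(frozen=True)
class TEResult:
    """Directed transfer entropy between two agents (bits)."""

    te_12: float
    te_21: float
    k: int = 1
    l: int = 1

    def __post_init__(self) -> None:
        assert self.te_12 >= 0 and self.te_21 >= 0
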