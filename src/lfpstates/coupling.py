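"""Pairwise coupling of channel states: transition synchrony, NMI, CCA.

Three complementary measures, all symmetric and bounded in [0, 1]:

* **Transition synchrony** (SPIKE-synchronization applied to state-transition
  trains): each transition r gets an adaptive coincidence window tau(r) equal
  to half the smaller of its flanking inter-transition intervals; two
  transitions count as coincident when they are mutually nearest and closer
  than min(tau_i, tau_j). The pairwise score is the mean coincidence
  indicator over all transitions of both trains.
* **NMI** (symmetric uncertainty): U(X, Y) = 2 I(X; Y) / (H(X) + H(Y)) with
  plug-in entropies in bits over the label contingency table. Invariant to
  relabeling, so channel-local state indices compare cleanly.
* **CCA similarity**: mean of the canonical correlations between the two
  channels' NMF score matrices — a soft state-similarity measure invariant
  to invertible linear maps of either channel's state space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "TransitionTrain",
    "transition_train",
    "transition_synchrony",
    "global_synchrony",
    "nmi_labels",
    "state_nmi",
    "cca_similarity",
    "pairwise_matrix",
]


@dataclass
class TransitionTrain:
    """Sorted transition times with their adaptive coincidence windows."""

    times_s: np.ndarray
    tau_s: np.ndarray

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("transition times must be strictly increasing")
        self.tau_s = np.asarray(self.tau_s, dtype=float)


def transition_train(times_s) -> TransitionTrain:
    """Build a TransitionTrain, deriving tau(r) from flanking intervals.

    tau(r) is half the smaller of the inter-transition intervals directly
    before and after r. The first/last transition has a single flanking
    interval and uses half of it; a singleton train gets tau = inf.
    """
    t = np.asarray(times_s, dtype=float)
    n = t.size
    if n == 0:
        return TransitionTrain(times_s=t, tau_s=np.empty(0))
    if n == 1:
        return TransitionTrain(times_s=t, tau_s=np.array([np.inf]))
    gaps = np.diff(t)
    prev_gap = np.concatenate([[np.inf], gaps])
    next_gap = np.concatenate([gaps, [np.inf]])
    tau = np.minimum(prev_gap, next_gap) / 2.0
    return TransitionTrain(times_s=t, tau_s=tau)


def _nearest(times_a: np.ndarray, times_b: np.ndarray) -> np.ndarray:
    """Index in b of the nearest neighbor of each time in a; ties -> earlier."""
    idx = np.searchsorted(times_b, times_a)
    left = np.clip(idx - 1, 0, times_b.size - 1)
    right = np.clip(idx, 0, times_b.size - 1)
    d_left = np.abs(times_a - times_b[left])
    d_right = np.abs(times_a - times_b[right])
    # strict < favors the earlier (left) neighbor on exact ties
    return np.where(d_right < d_left, right, left)


def transition_synchrony(train_i, train_j):
    """Pairwise SPIKE-synchronization of two transition trains.

    Returns (indicators_i, indicators_j, mean_score): per-transition 0/1
    coincidence indicators for each train and their mean over all
    transitions of both trains. Empty trains score 0.
    """
    if not isinstance(train_i, TransitionTrain):
        train_i = transition_train(train_i)
    if not isinstance(train_j, TransitionTrain):
        train_j = transition_train(train_j)
    ti, tj = train_i.times_s, train_j.times_s
    ind_i = np.zeros(ti.size)
    ind_j = np.zeros(tj.size)
    if ti.size == 0 or tj.size == 0:
        return ind_i, ind_j, 0.0
    ni = _nearest(ti, tj)
    nj = _nearest(tj, ti)
    for a, b in enumerate(ni):
        if nj[b] != a:
            continue
        delta = abs(ti[a] - tj[b])
        lim = min(train_i.tau_s[a], train_j.tau_s[b])
        if delta < lim or delta == 0.0:
            ind_i[a] = 1.0
            ind_j[b] = 1.0
    total = ti.size + tj.size
    mean = float((ind_i.sum() + ind_j.sum()) / total)
    return ind_i, ind_j, mean


def global_synchrony(trains):
    """Per-transition global synchrony scores across all channels.

    For each channel's transitions, the global score is the mean of its
    pairwise coincidence indicators with every other channel. Returns a list
    of arrays, one per channel.
    """
    trains = [t if isinstance(t, TransitionTrain) else transition_train(t)
              for t in trains]
    n = len(trains)
    if n < 2:
        raise ValueError("need at least 2 channels")
    sums = [np.zeros(t.times_s.size) for t in trains]
    for i in range(n):
        for j in range(i + 1, n):
            ind_i, ind_j, _ = transition_synchrony(trains[i], trains[j])
            sums[i] += ind_i
            sums[j] += ind_j
    return [s / (n - 1) for s in sums]


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def nmi_labels(x, y) -> float:
    """Symmetric uncertainty U(X, Y) = 2 I / (H(X) + H(Y)) of two label arrays.

    Plug-in entropies in bits from the joint contingency table; defined as 0
    when both marginal entropies are 0 (both sequences constant).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size or x.size == 0:
        raise ValueError("label arrays must be nonempty and aligned")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1)
    hx = _entropy_bits(joint.sum(axis=1))
    hy = _entropy_bits(joint.sum(axis=0))
    hxy = _entropy_bits(joint.ravel())
    if hx + hy == 0:
        return 0.0
    mi = hx + hy - hxy
    return float(2.0 * mi / (hx + hy))


def state_nmi(seq_x, seq_y) -> float:
    """NMI of two StateSequences on their shared window grid.

    Only windows present (unmasked) in both sequences are used; a NaN-free
    label array is expected per sequence.
    """
    lx, ly = seq_x.labels, seq_y.labels
    if lx.size != ly.size:
        raise ValueError("sequences must be aligned to the same window grid")
    return nmi_labels(lx, ly)


def cca_similarity(V: np.ndarray, W: np.ndarray, reg: float = 1e-10):
    """Mean canonical correlation between two score matrices (N x L, N x M).

    Columns are mean-centered; canonical correlations come from the SVD of
    Q_V^T Q_W after thin QR of each centered matrix (the standard canoncorr
    algorithm). Rank-deficient inputs are handled by truncating to the
    effective rank (diagonal-R threshold scaled by ``reg``); the mean is
    taken over K = min(L, M) correlations with truncated directions
    contributing 0.
    """
    V = np.asarray(V, dtype=float)
    W = np.asarray(W, dtype=float)
    n = V.shape[0]
    if W.shape[0] != n:
        raise ValueError("score matrices must share the sample axis")
    k_full = min(V.shape[1], W.shape[1])
    if n <= max(V.shape[1], W.shape[1]) + 1:
        raise ValueError("too few samples for CCA")
    Vc = V - V.mean(axis=0)
    Wc = W - W.mean(axis=0)

    def _qr_trunc(X):
        Q, R, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = max(n, X.shape[1]) * np.finfo(float).eps * (diag[0] if diag.size else 0)
        tol = max(tol, reg)
        rank = int(np.sum(diag > tol))
        return Q[:, :max(rank, 1)], rank

    Qv, rv = _qr_trunc(Vc)
    Qw, rw = _qr_trunc(Wc)
    rho = linalg.svd(Qv.T @ Qw, compute_uv=False)
    rho = np.clip(rho, 0.0, 1.0)[: k_full]
    if rho.size < k_full:
        rho = np.concatenate([rho, np.zeros(k_full - rho.size)])
    return float(rho.mean())


def pairwise_matrix(items, measure) -> np.ndarray:
    """Symmetric channel-pair matrix of a coupling measure; NaN diagonal."""
    n = len(items)
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = measure(items[i], items[j])
    return out
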