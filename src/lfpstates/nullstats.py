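"""Markov-shuffled surrogates and significance testing of coupling measures.

A discrete-time Markov chain is fit to each channel's window-resolution state
sequence (self-transitions included, which preserves dwell-time statistics)
and used to simulate surrogate state sequences of the same length. The
surrogates preserve each channel's state occupancy and transition statistics
while destroying all cross-channel coordination, so they provide the null
distribution for every pairwise coupling measure. Score-matrix surrogates for
CCA draw, at each surrogate window, a random row of the channel's original
score matrix from windows where the original state matched.

Group comparisons respect the dependency structure of pairwise matrices:
permutation tests shuffle whole channels (rows and columns together), and
between-recording comparisons bootstrap rows and columns of rectangular
cross-probe matrices with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .states import StateSequence

__all__ = [
    "MarkovNull",
    "PairTestResult",
    "fit_markov",
    "simulate_null",
    "simulate_null_scores",
    "pair_significance",
    "group_permutation_test",
    "between_recording_bootstrap",
    "pairs_from_attributes",
]


@dataclass
class MarkovNull:
    """Per-channel fitted chain and its surrogate sequences."""

    transition_probs: np.ndarray  # (K, K), rows sum to 1
    initial_dist: np.ndarray  # empirical occupancy
    n_windows: int
    surrogates: np.ndarray = None  # (n_surrogates, n_windows) int

    @property
    def n_states(self) -> int:
        return self.transition_probs.shape[0]


@dataclass
class PairTestResult:
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    significant: bool
    n_pairs: int
    alpha: float


def fit_markov(seq, dwell_aware: bool = True) -> MarkovNull:
    """Maximum-likelihood window-resolution Markov chain for a state sequence.

    Counts window-to-window label adjacencies including self-transitions
    (``dwell_aware=True``), so surrogate dwell times match the data. The
    initial distribution is the empirical occupancy. A single-state sequence
    yields the degenerate identity chain with a warning.
    """
    labels = seq.labels if isinstance(seq, StateSequence) else np.asarray(seq, dtype=int)
    if labels.size < 2:
        raise ValueError("need at least 2 windows")
    k = int(labels.max()) + 1
    counts = np.zeros((k, k))
    a, b = labels[:-1], labels[1:]
    if not dwell_aware:
        keep = a != b
        a, b = a[keep], b[keep]
    np.add.at(counts, (a, b), 1)
    rows = counts.sum(axis=1)
    probs = np.eye(k)
    nz = rows > 0
    probs[nz] = counts[nz] / rows[nz, None]
    if k == 1:
        warnings.warn("single-state sequence: degenerate identity chain")
    occ = np.bincount(labels, minlength=k).astype(float)
    return MarkovNull(transition_probs=probs, initial_dist=occ / occ.sum(),
                      n_windows=labels.size)


def simulate_null(null_model: MarkovNull, n: int = 1000, seed: int = 0) -> np.ndarray:
    """Simulate ``n`` surrogate state sequences of the original length.

    Vectorized over surrogates: all chains advance one window per step.
    Deterministic given the seed. The result is also stored on the model.
    """
    rng = np.random.default_rng(seed)
    k = null_model.n_states
    T = null_model.n_windows
    cum = np.cumsum(null_model.transition_probs, axis=1)
    cum[:, -1] = 1.0
    out = np.empty((n, T), dtype=int)
    state = np.searchsorted(np.cumsum(null_model.initial_dist), rng.random(n))
    state = np.clip(state, 0, k - 1)
    out[:, 0] = state
    for t in range(1, T):
        u = rng.random(n)
        nxt = np.empty(n, dtype=int)
        for s in range(k):
            idx = np.flatnonzero(state == s)
            if idx.size:
                nxt[idx] = np.searchsorted(cum[s], u[idx], side="right")
        state = np.clip(nxt, 0, k - 1)
        out[:, t] = state
    null_model.surrogates = out
    return out


def simulate_null_scores(surrogate_labels: np.ndarray, original_labels: np.ndarray,
                         V_original: np.ndarray, seed: int = 0) -> np.ndarray:
    """State-conditioned score-matrix surrogates for CCA nulls.

    For each surrogate window with state k, a row of the original score
    matrix is drawn (with replacement) from the original windows whose state
    was k. Raises if a surrogate state never occurs in the original data.
    Input of shape (n_surr, T) yields output (n_surr, T, K_components).
    """
    rng = np.random.default_rng(seed)
    surr = np.atleast_2d(surrogate_labels)
    pools = {}
    for s in np.unique(surr):
        pool = np.flatnonzero(original_labels == s)
        if pool.size == 0:
            raise ValueError(f"state {s} has no windows in the original data")
        pools[int(s)] = pool
    out = np.empty(surr.shape + (V_original.shape[1],))
    for s, pool in pools.items():
        where = surr == s
        draws = pool[rng.integers(pool.size, size=int(where.sum()))]
        out[where] = V_original[draws]
    return out if surrogate_labels.ndim > 1 else out[0]


def pair_significance(observed: float, null_values, alpha: float = 0.05,
                      n_pairs: int = 1) -> PairTestResult:
    """One-tailed z test of an observed coupling value against its null.

    Fits a normal to the surrogate values, computes z = (obs - mean)/sd and
    the upper-tail p, and flags significance at the Bonferroni-corrected
    level alpha / n_pairs.
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size < 30:
        raise ValueError("need at least 30 null values for a stable normal fit")
    mu = float(null_values.mean())
    sd = float(null_values.std(ddof=1))
    if sd == 0:
        warnings.warn("zero null SD; p set by sign of the deviation")
        p = 0.0 if observed > mu else 1.0
        z = np.inf if observed > mu else (-np.inf if observed < mu else 0.0)
    else:
        z = (observed - mu) / sd
        p = float(norm.sf(z))
    return PairTestResult(observed=float(observed), null_mean=mu, null_sd=sd,
                          z=float(z), p=p, significant=bool(p < alpha / n_pairs),
                          n_pairs=n_pairs, alpha=alpha)


def pairs_from_attributes(attributes, predicate):
    """Unordered channel pairs (i, j), i < j, whose attributes satisfy a predicate.

    ``predicate(attr_i, attr_j)`` decides membership; e.g. same-region pairs
    via ``lambda a, b: a == b``.
    """
    n = len(attributes)
    return [(i, j) for i in range(n) for j in range(i + 1, n)
            if predicate(attributes[i], attributes[j])]


def group_permutation_test(pair_matrix: np.ndarray, group_a, group_b,
                           n_perm: int = 100_000, seed: int = 0) -> float:
    """Row/column-preserving permutation test of mean(group_a) - mean(group_b).

    Each permutation applies one random permutation to the labels of the
    channels involved in either group (rows and columns move together, which
    preserves the dependency structure of the pairwise matrix), then
    recomputes the group-mean difference. One-tailed p with +1 smoothing:
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    M = np.asarray(pair_matrix, dtype=float)
    group_a = [tuple(p) for p in group_a]
    group_b = [tuple(p) for p in group_b]
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint pair sets")
    channels = sorted({c for p in group_a + group_b for c in p})
    ch_index = {c: i for i, c in enumerate(channels)}
    if any(not np.isfinite(M[i, j]) for i, j in group_a + group_b):
        raise ValueError("groups reference missing matrix entries")

    a_idx = np.array([(ch_index[i], ch_index[j]) for i, j in group_a])
    b_idx = np.array([(ch_index[i], ch_index[j]) for i, j in group_b])
    sub = M[np.ix_(channels, channels)]

    def diff(perm):
        pa = sub[perm[a_idx[:, 0]], perm[a_idx[:, 1]]]
        pb = sub[perm[b_idx[:, 0]], perm[b_idx[:, 1]]]
        return pa.mean() - pb.mean()

    ident = np.arange(len(channels))
    observed = diff(ident)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(channels))
        if diff(perm) >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


def between_recording_bootstrap(matrices_a, matrices_b, n_boot: int = 10_000,
                                seed: int = 0) -> float:
    """Bootstrap test for mean(a) > mean(b) over rectangular pair matrices.

    Each matrix holds a coupling measure for channels of one probe (rows)
    against channels of another (columns). Per replicate, row and column
    indices are resampled with replacement in every matrix; the replicate
    statistic is the difference of pooled group means. p is the fraction of
    replicates with difference <= 0.
    """
    for mats in (matrices_a, matrices_b):
        for m in mats:
            if np.asarray(m).size == 0:
                raise ValueError("empty matrix in bootstrap input")
    rng = np.random.default_rng(seed)

    def resampled_mean(mats):
        vals = []
        for m in mats:
            m = np.asarray(m, dtype=float)
            r = rng.integers(m.shape[0], size=m.shape[0])
            c = rng.integers(m.shape[1], size=m.shape[1])
            vals.append(m[np.ix_(r, c)].ravel())
        return np.concatenate(vals).mean()

    count = 0
    for _ in range(n_boot):
        if resampled_mean(matrices_a) - resampled_mean(matrices_b) <= 0:
            count += 1
    return count / n_boot
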