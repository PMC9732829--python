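"""Per-channel NMF state extraction: rank selection, fitting, discrete states.

Each channel's rank-normalized spectrogram A (frequencies x windows) is
factorized individually as A ~ U V^T with non-negative loadings U (F x K) and
scores V (N x K). The component with the highest rescaled score in each
window defines the channel's discrete state; short, ambiguous segments are
merged away, and the remaining label changes are the channel's state
transitions. Labels are channel-local: the same index on two channels does
not mean the same spectral state.

Rank selection uses bi-cross-validation: hold out a random block of rows and
columns, fit on the remainder, refit scores on the row-held-out data with
loadings fixed and loadings on the column-held-out data with scores fixed,
and score the reconstruction of the held-out block. K is the smallest value
where adding one more component improves mean held-out error by less than
one percentage point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import non_negative_factorization
from sklearn.exceptions import ConvergenceWarning

from .spectral import Spectrogram

__all__ = [
    "NMFModel",
    "StateSequence",
    "TransitionMatrix",
    "bicv_select_k",
    "fit_nmf_rescaled",
    "assign_states",
    "transition_matrix",
    "prototypical_windows",
    "transition_triggered_spectrogram",
    "mixed_state_consistency",
]

_NMF_KW = dict(solver="mu", beta_loss="frobenius", max_iter=500, tol=1e-5)


@dataclass
class NMFModel:
    """Rescaled NMF factorization of one channel's normalized spectrogram.

    ``U`` (F x K) holds unit-L2-norm loading columns; ``V`` (N x K) holds the
    counter-scaled scores so that U @ V.T reproduces the unrescaled product.
    ``D`` records the per-component rescaling (the original loading norms).
    ``E`` is the relative Frobenius reconstruction error on the fitted data.
    """

    U: np.ndarray
    V: np.ndarray
    D: np.ndarray
    K: int
    E: float
    seed: int = 0
    n_restarts: int = 5
    window_times_s: np.ndarray = None  # type: ignore[assignment]
    step_s: float = None  # type: ignore[assignment]


@dataclass
class StateSequence:
    """Discrete state labels on a uniform window grid, after merging.

    ``segments`` is a list of (start_window, end_window, state) with
    half-open window index ranges; ``transition_times_s`` are the midpoints
    between the window centers flanking each label change.
    """

    labels: np.ndarray
    window_times_s: np.ndarray
    step_s: float
    segments: list = field(default_factory=list)
    transition_times_s: np.ndarray = None  # type: ignore[assignment]
    channel: int = -1

    def n_states(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class TransitionMatrix:
    counts: np.ndarray
    probabilities: np.ndarray


def sequence_to_json(seq: "StateSequence") -> str:
    """Serialize a StateSequence (segments, transitions, parameters) to JSON."""
    import json

    return json.dumps({
        "channel": seq.channel,
        "step_s": seq.step_s,
        "labels": seq.labels.tolist(),
        "window_times_s": np.asarray(seq.window_times_s).tolist(),
        "segments": [list(s) for s in seq.segments],
        "transition_times_s": np.asarray(seq.transition_times_s).tolist(),
    })


def sequence_from_json(blob: str) -> "StateSequence":
    import json

    d = json.loads(blob)
    return StateSequence(labels=np.asarray(d["labels"], dtype=int),
                         window_times_s=np.asarray(d["window_times_s"]),
                         step_s=d["step_s"],
                         segments=[tuple(s) for s in d["segments"]],
                         transition_times_s=np.asarray(d["transition_times_s"]),
                         channel=d["channel"])


def _nmf(A, K, seed, W=None, H=None, update_H=True, init=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        return non_negative_factorization(
            A, W=W, H=H, n_components=K, init=init or "random",
            update_H=update_H, random_state=seed, **_NMF_KW,
        )


def _relative_error(A, Ahat):
    denom = np.linalg.norm(A)
    return float(np.linalg.norm(A - Ahat) / denom) if denom > 0 else 0.0


def bicv_select_k(A: np.ndarray, k_range=range(1, 16), holdout_frac: float = 0.2,
                  downsample: int = 20, n_reps: int = 5,
                  improvement_cut: float = 0.01, seed: int = 0):
    """Bi-cross-validated NMF rank for a non-negative matrix A (F x N).

    Columns are first downsampled by strided selection (every
    ``downsample``-th window). Returns (K, mean_errors dict K -> error).
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("A must be non-negative")
    ks = sorted(k_range)
    if not ks:
        raise ValueError("k_range must be nonempty")
    Ad = A[:, ::downsample] if downsample > 1 else A
    F, N = Ad.shape
    n_hold_r = max(1, int(round(holdout_frac * F)))
    n_hold_c = max(1, int(round(holdout_frac * N)))
    rng = np.random.default_rng(seed)
    # fixed per-replicate holdouts and seeds, shared across K so the error
    # curve is comparable
    reps = []
    for r in range(n_reps):
        rows = rng.choice(F, n_hold_r, replace=False)
        cols = rng.choice(N, n_hold_c, replace=False)
        reps.append((np.isin(np.arange(F), rows), np.isin(np.arange(N), cols),
                     int(rng.integers(2 ** 31))))

    mean_err = {}

    def err_for(K):
        errs = []
        for hold_r, hold_c, rseed in reps:
            A11 = Ad[~hold_r][:, ~hold_c]
            U1, V1t, _ = _nmf(A11, K, rseed)
            # refit scores on row-held-out data with loadings fixed
            V2, _, _ = _nmf(Ad[~hold_r].T, K, rseed, H=np.ascontiguousarray(U1.T),
                            update_H=False, init="custom")
            # refit loadings on column-held-out data with scores fixed
            U3, _, _ = _nmf(Ad[:, ~hold_c], K, rseed, H=np.ascontiguousarray(V1t),
                            update_H=False, init="custom")
            block = Ad[hold_r][:, hold_c]
            est = U3[hold_r] @ V2[hold_c].T
            errs.append(_relative_error(block, est))
        return float(np.mean(errs))

    selected = ks[-1]
    for i, K in enumerate(ks):
        if K not in mean_err:
            mean_err[K] = err_for(K)
        if i + 1 < len(ks):
            nxt = ks[i + 1]
            mean_err[nxt] = err_for(nxt)
            if mean_err[K] - mean_err[nxt] < improvement_cut:
                selected = K
                break
    return selected, mean_err


def fit_nmf_rescaled(A: np.ndarray, K: int, seed: int = 0, n_restarts: int = 5,
                     window_times_s=None, step_s=None,
                     warm_start=None) -> NMFModel:
    """Fit NMF to A (F x N) and rescale loadings to unit L2 norm.

    Multiplicative updates, Frobenius objective, best of ``n_restarts``
    seeded random restarts. ``warm_start=(U0, V0)`` adds one restart seeded
    from a previous factorization (columns are padded/truncated to K), which
    makes the error curve over nested K fits monotone. The diagonal
    rescaling D (original loading norms) moves scale from U into V, leaving
    U @ V.T unchanged.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("A must be non-negative")
    best = None
    for r in range(n_restarts):
        U, Vt, _ = _nmf(A, K, seed + r)
        e = _relative_error(A, U @ Vt)
        if best is None or e < best[0]:
            best = (e, U, Vt)
    if warm_start is not None:
        U0, V0 = warm_start
        rng = np.random.default_rng(seed)
        W = np.abs(U0[:, :K])
        H = np.abs(V0[:, :K]).T
        scale = max(A.mean(), 1e-6)
        if W.shape[1] < K:
            W = np.hstack([W, scale * rng.random((W.shape[0], K - W.shape[1]))])
            H = np.vstack([H, scale * rng.random((K - H.shape[0], H.shape[1]))])
        U, Vt, _ = _nmf(A, K, seed, W=np.ascontiguousarray(W + 1e-9),
                        H=np.ascontiguousarray(H + 1e-9), init="custom")
        e = _relative_error(A, U @ Vt)
        if e < best[0]:
            best = (e, U, Vt)
    e, U, Vt = best
    V = Vt.T
    d = np.linalg.norm(U, axis=0)
    d = np.where(d > 0, d, 1.0)
    return NMFModel(U=U / d, V=V * d, D=d, K=K, E=e, seed=seed,
                    n_restarts=n_restarts,
                    window_times_s=None if window_times_s is None else np.asarray(window_times_s),
                    step_s=step_s)


def _segments_from_labels(labels: np.ndarray):
    """Half-open (start, end, state) runs of equal labels."""
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [(int(s), int(e), int(labels[s])) for s, e in zip(starts, ends)]


def _transition_magnitude(V: np.ndarray, boundary: int, flank_win: int) -> float:
    """Euclidean jump of the mean score vector across a segment boundary."""
    lo = max(0, boundary - flank_win)
    hi = min(V.shape[0], boundary + flank_win)
    if boundary - lo == 0 or hi - boundary == 0:
        return 0.0
    before = V[lo:boundary].mean(axis=0)
    after = V[boundary:hi].mean(axis=0)
    return float(np.linalg.norm(after - before))


def assign_states(model: NMFModel, min_segment_s: float = 100.0,
                  ambiguity_ratio: float = 1.1, flank_s: float = 3.0,
                  step_s: float = None, window_times_s=None,
                  channel: int = -1) -> StateSequence:
    """Argmax state labels with iterative short/ambiguous segment merging.

    A segment shorter than ``min_segment_s`` whose own mean score (within the
    segment) is less than ``ambiguity_ratio`` times a flanking segment's
    component mean score (also within the segment) is absorbed into that
    flank. When both flanks qualify, the boundary with the *smaller* score
    jump (mean score vector over ``flank_s`` after minus before, Euclidean
    magnitude) is the one ignored, so the segment joins that neighbor. The
    scan repeats until no merge fires.
    """
    V = model.V
    step = step_s if step_s is not None else model.step_s
    if step is None:
        raise ValueError("window step must be provided (step_s)")
    times = window_times_s if window_times_s is not None else model.window_times_s
    if times is None:
        times = (np.arange(V.shape[0]) + 0.5) * step
    labels = np.argmax(V, axis=1).astype(int)
    min_win = min_segment_s / step
    flank_win = max(1, int(round(flank_s / step)))

    while True:
        segments = _segments_from_labels(labels)
        merged = False
        for si, (s, e, st) in enumerate(segments):
            if e - s >= min_win:
                continue
            own_mean = V[s:e, st].mean()
            candidates = []  # (neighbor index, neighbor state, boundary window)
            if si > 0:
                b_state = segments[si - 1][2]
                if own_mean < ambiguity_ratio * V[s:e, b_state].mean():
                    candidates.append((si - 1, b_state, s))
            if si + 1 < len(segments):
                b_state = segments[si + 1][2]
                if own_mean < ambiguity_ratio * V[s:e, b_state].mean():
                    candidates.append((si + 1, b_state, e))
            if not candidates:
                continue
            if len(candidates) == 2:
                mags = [_transition_magnitude(V, c[2], flank_win) for c in candidates]
                # ignore the transition with the smaller jump -> merge there
                pick = candidates[int(np.argmin(mags))]
            else:
                pick = candidates[0]
            labels[s:e] = pick[1]
            merged = True
            break
        if not merged:
            break

    segments = _segments_from_labels(labels)
    boundaries = [seg[0] for seg in segments[1:]]
    trans_times = np.array([(times[b - 1] + times[b]) / 2.0 for b in boundaries])
    return StateSequence(labels=labels, window_times_s=np.asarray(times),
                         step_s=float(step), segments=segments,
                         transition_times_s=trans_times, channel=channel)


def transition_matrix(seq: StateSequence) -> TransitionMatrix:
    """Tally how often each discrete state follows each other state."""
    if not seq.segments:
        raise ValueError("sequence has no segments")
    k = max(seq.n_states(), max(st for _, _, st in seq.segments) + 1)
    counts = np.zeros((k, k), dtype=int)
    for (_, _, a), (_, _, b) in zip(seq.segments[:-1], seq.segments[1:]):
        counts[a, b] += 1
    probs = np.zeros_like(counts, dtype=float)
    rows = counts.sum(axis=1)
    nz = rows > 0
    probs[nz] = counts[nz] / rows[nz, None]
    return TransitionMatrix(counts=counts, probabilities=probs)


def prototypical_windows(model: NMFModel, seq: StateSequence, state: int,
                         n: int = 5) -> np.ndarray:
    """Windows of a state ranked by top-score dominance.

    Ranks windows assigned to ``state`` by the ratio of the assigned
    component's score to the sum of all scores, descending; returns the top
    ``n`` window indices.
    """
    in_state = np.flatnonzero(seq.labels == state)
    if in_state.size == 0:
        raise ValueError(f"state {state} does not occur in the sequence")
    V = model.V[in_state]
    totals = V.sum(axis=1)
    ratio = np.where(totals > 0, V[:, state] / np.where(totals > 0, totals, 1.0), 0.0)
    order = np.argsort(-ratio, kind="stable")
    return in_state[order[:n]]


def transition_triggered_spectrogram(spec: Spectrogram, seq: StateSequence,
                                     pre_s: float = 30.0, post_s: float = 30.0):
    """Mean normalized spectrogram around the most frequent transition type.

    Returns (mean_matrix, rel_times_s, n_occurrences, (from_state, to_state)).
    Occurrences whose window would exceed the recording bounds are skipped.
    """
    tm = transition_matrix(seq)
    if tm.counts.sum() == 0:
        raise ValueError("sequence has no transitions")
    modal = np.unravel_index(np.argmax(tm.counts), tm.counts.shape)
    pre_win = int(round(pre_s / seq.step_s))
    post_win = int(round(post_s / seq.step_s))
    snippets = []
    for (s0, e0, a), (s1, e1, b) in zip(seq.segments[:-1], seq.segments[1:]):
        if (a, b) != tuple(modal):
            continue
        if s1 - pre_win < 0 or s1 + post_win > spec.power.shape[0]:
            continue
        snippets.append(spec.power[s1 - pre_win: s1 + post_win])
    if not snippets:
        raise ValueError("no full-window occurrence of the modal transition")
    mean = np.nanmean(snippets, axis=0)
    rel = (np.arange(-pre_win, post_win) + 0.5) * seq.step_s
    return mean, rel, len(snippets), tuple(int(m) for m in modal)


def mixed_state_consistency(channels, n_per_state: int = 600, n_reps: int = 500,
                            seed: int = 0, k_mixed: int = None):
    """Cross-recording state consistency via mixed-state reclassification.

    ``channels`` is a list of (normalized Spectrogram, StateSequence), one
    per recording, all at a matched depth/region. Per replicate, spectra are
    sampled per state from every recording (without replacement when
    possible), concatenated, refactorized with NMF, and labeled by argmax
    score ("mixed states"). The NMI of mixed labels with recording IDs and
    with the source-local state labels (mean over recordings) is recorded.

    Returns (nmi_id array, nmi_local array, p) where p is the paired
    percentile probability that NMI with IDs is at least NMI with local
    states — small p means mixed states track local states, not animals.
    """
    from .coupling import nmi_labels

    if len(channels) < 2:
        raise ValueError("need at least 2 recordings")
    if k_mixed is None:
        k_mixed = int(np.median([seq.n_states() for _, seq in channels]))
        k_mixed = max(k_mixed, 2)
    rng = np.random.default_rng(seed)

    nmi_id = np.empty(n_reps)
    nmi_local = np.empty(n_reps)
    for rep in range(n_reps):
        rows, rec_ids, local = [], [], []
        for rid, (spec, seq) in enumerate(channels):
            good = ~np.isnan(spec.power).any(axis=1)
            for st in np.unique(seq.labels):
                pool = np.flatnonzero((seq.labels == st) & good)
                if pool.size == 0:
                    continue
                replace_draw = pool.size < n_per_state
                take = rng.choice(pool, size=n_per_state, replace=replace_draw)
                rows.append(spec.power[take])
                rec_ids.extend([rid] * n_per_state)
                local.extend((seq.labels[take] + 1000 * rid).tolist())
        X = np.vstack(rows)  # samples x freqs
        model = fit_nmf_rescaled(X.T, k_mixed, seed=int(rng.integers(2 ** 31)),
                                 n_restarts=2)
        mixed = np.argmax(model.V, axis=1)
        rec_ids = np.asarray(rec_ids)
        local = np.asarray(local)
        nmi_id[rep] = nmi_labels(mixed, rec_ids)
        per_rec = [nmi_labels(mixed[rec_ids == rid], local[rec_ids == rid])
                   for rid in np.unique(rec_ids)]
        nmi_local[rep] = float(np.mean(per_rec))
    p = (1 + int(np.sum(nmi_id >= nmi_local))) / (n_reps + 1)
    return nmi_id, nmi_local, float(p)
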