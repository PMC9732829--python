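"""Coupling measures vs independent brute-force oracles and their invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import linalg
from sklearn.metrics import mutual_info_score

from lfpstates import coupling as cp
from lfpstates.states import StateSequence


# --- independent oracles ---------------------------------------------------

def brute_synchrony(ti, tj):
    """Direct per-definition evaluation of SPIKE-synchronization."""
    ti, tj = np.asarray(ti, float), np.asarray(tj, float)

    def taus(t):
        out = []
        for i in range(t.size):
            gaps = []
            if i > 0:
                gaps.append(t[i] - t[i - 1])
            if i < t.size - 1:
                gaps.append(t[i + 1] - t[i])
            out.append(min(gaps) / 2 if gaps else np.inf)
        return out

    tau_i, tau_j = taus(ti), taus(tj)
    ind_i, ind_j = np.zeros(ti.size), np.zeros(tj.size)
    for a in range(ti.size):
        dists = np.abs(tj - ti[a])
        b = int(np.argmin(dists))  # argmin takes the earliest on ties
        if int(np.argmin(np.abs(ti - tj[b]))) != a:
            continue
        d = abs(ti[a] - tj[b])
        if d < min(tau_i[a], tau_j[b]) or d == 0:
            ind_i[a] = ind_j[b] = 1
    return (ind_i.sum() + ind_j.sum()) / (ti.size + tj.size)


def brute_nmi(x, y):
    """Symmetric uncertainty from sklearn's MI (nats) converted to bits."""
    mi = mutual_info_score(x, y) / np.log(2)

    def H(v):
        _, counts = np.unique(v, return_counts=True)
        p = counts / counts.sum()
        return -(p * np.log2(p)).sum()

    denom = H(x) + H(y)
    return 0.0 if denom == 0 else 2 * mi / denom


def brute_cca_mean(V, W):
    """Canonical correlations via the generalized eigenproblem on covariances."""
    Vc = V - V.mean(axis=0)
    Wc = W - W.mean(axis=0)
    Svv = Vc.T @ Vc
    Sww = Wc.T @ Wc
    Svw = Vc.T @ Wc
    M = np.linalg.solve(Svv, Svw) @ np.linalg.solve(Sww, Svw.T)
    eig = np.sort(np.real(linalg.eigvals(M)))[::-1]
    k = min(V.shape[1], W.shape[1])
    rho = np.sqrt(np.clip(eig[:k], 0, 1))
    return rho.mean()


# --- transition synchrony --------------------------------------------------

class TestSynchrony:
    def test_hand_example(self):
        _, _, mean = cp.transition_synchrony([10.0, 20.0, 40.0], [21.0, 60.0])
        assert mean == pytest.approx(0.4)

    def test_identical_trains_score_one(self):
        t = [3.0, 17.0, 40.0, 41.0]
        ind_i, ind_j, mean = cp.transition_synchrony(t, t)
        assert mean == 1.0 and ind_i.all() and ind_j.all()

    def test_distant_trains_score_zero(self):
        _, _, mean = cp.transition_synchrony([1.0, 2.0, 3.0], [500.0, 501.0])
        assert mean == 0.0

    def test_empty_train_scores_zero(self):
        _, _, mean = cp.transition_synchrony([], [1.0, 2.0])
        assert mean == 0.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 25), st.integers(1, 25))
    def test_matches_brute_force_oracle(self, seed, na, nb):
        rng = np.random.default_rng(seed)
        ti = np.unique(np.round(rng.uniform(0, 300, na), 2))
        tj = np.unique(np.round(rng.uniform(0, 300, nb), 2))
        _, _, mean = cp.transition_synchrony(ti, tj)
        assert mean == pytest.approx(brute_synchrony(ti, tj))
        _, _, rev = cp.transition_synchrony(tj, ti)
        assert mean == pytest.approx(rev)

    def test_invariant_to_common_shift_and_rescale(self):
        rng = np.random.default_rng(1)
        ti = np.sort(rng.uniform(0, 200, 12))
        tj = np.sort(rng.uniform(0, 200, 9))
        _, _, base = cp.transition_synchrony(ti, tj)
        _, _, shifted = cp.transition_synchrony(ti + 55.0, tj + 55.0)
        _, _, scaled = cp.transition_synchrony(ti * 3.0, tj * 3.0)
        assert base == pytest.approx(shifted) == pytest.approx(scaled)

    def test_global_scores_match_pairwise_average(self):
        rng = np.random.default_rng(2)
        trains = [np.sort(rng.uniform(0, 100, rng.integers(3, 8)))
                  for _ in range(3)]
        glob = cp.global_synchrony(trains)
        for i in range(3):
            inds = []
            for j in range(3):
                if j == i:
                    continue
                a, b, _ = cp.transition_synchrony(trains[i], trains[j])
                inds.append(a)
            assert np.allclose(glob[i], np.mean(inds, axis=0))

    def test_identical_channels_global_one_lone_channel_zero(self):
        t = [5.0, 20.0, 60.0]
        glob = cp.global_synchrony([t, t, [400.0, 450.0]])
        # each transition of channel 0 coincides with its twin (1) but not
        # the distant loner (0) -> global score 0.5
        assert np.allclose(glob[0], 0.5)
        assert np.allclose(glob[2], 0.0)
        glob2 = cp.global_synchrony([t, t, t])
        assert all(np.allclose(g, 1.0) for g in glob2)


# --- NMI --------------------------------------------------------------------

class TestNmi:
    def test_identical_sequences_give_one(self):
        x = np.array([0, 0, 1, 1, 2, 2])
        assert cp.nmi_labels(x, x) == pytest.approx(1.0)

    def test_independent_by_construction_gives_zero(self):
        assert cp.nmi_labels([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_hand_computed_contingency(self):
        u = cp.nmi_labels([0, 0, 1, 1], [0, 0, 1, 0])
        assert u == pytest.approx(0.3437, abs=2e-4)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 5), st.integers(10, 200))
    def test_matches_sklearn_oracle(self, seed, k, n):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, k, n)
        y = rng.integers(0, k, n)
        assert cp.nmi_labels(x, y) == pytest.approx(brute_nmi(x, y), abs=1e-12)
        assert cp.nmi_labels(x, y) == pytest.approx(cp.nmi_labels(y, x))

    def test_invariant_to_relabeling(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 4, 300)
        y = rng.integers(0, 3, 300)
        perm = np.array([2, 0, 3, 1])
        assert cp.nmi_labels(perm[x], y) == pytest.approx(cp.nmi_labels(x, y))

    def test_redundancy_identity(self):
        # (H(X)+H(Y)-H(X,Y)) / (H(X)+H(Y)) == U/2
        rng = np.random.default_rng(4)
        x = rng.integers(0, 3, 500)
        y = (x + (rng.random(500) < 0.3).astype(int)) % 3
        u = cp.nmi_labels(x, y)

        def H(labels):
            _, c = np.unique(labels, return_counts=True)
            p = c / c.sum()
            return -(p * np.log2(p)).sum()

        joint = [f"{a}-{b}" for a, b in zip(x, y)]
        red = (H(x) + H(y) - H(joint)) / (H(x) + H(y))
        assert red == pytest.approx(u / 2)

    def test_state_nmi_requires_aligned_grids(self):
        a = StateSequence(labels=np.zeros(5, int), window_times_s=np.arange(5.0),
                          step_s=1.0)
        b = StateSequence(labels=np.zeros(6, int), window_times_s=np.arange(6.0),
                          step_s=1.0)
        with pytest.raises(ValueError):
            cp.state_nmi(a, b)


# --- CCA --------------------------------------------------------------------

class TestCca:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(5)
        V = rng.standard_normal((200, 4))
        assert cp.cca_similarity(V, V) == pytest.approx(1.0, abs=1e-9)

    def test_invariance_to_invertible_linear_map(self):
        rng = np.random.default_rng(6)
        V = rng.standard_normal((300, 5))
        B = rng.standard_normal((5, 5)) + 0.5 * np.eye(5)
        assert cp.cca_similarity(V, V @ B) == pytest.approx(1.0, abs=1e-8)

    def test_independent_noise_low_and_matches_eigen_oracle(self):
        rng = np.random.default_rng(7)
        V = rng.standard_normal((5000, 6))
        W = rng.standard_normal((5000, 6))
        got = cp.cca_similarity(V, W)
        assert got < 0.1
        assert got == pytest.approx(brute_cca_mean(V, W), abs=1e-6)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 6), st.integers(2, 6))
    def test_matches_eigen_oracle_and_symmetry(self, seed, l, m):
        rng = np.random.default_rng(seed)
        n = 80
        V = rng.standard_normal((n, l))
        W = 0.5 * rng.standard_normal((n, m))
        # plant shared structure in one column
        shared = rng.standard_normal(n)
        V[:, 0] += shared
        W[:, 0] += shared
        got = cp.cca_similarity(V, W)
        assert got == pytest.approx(brute_cca_mean(V, W), abs=1e-6)
        assert got == pytest.approx(cp.cca_similarity(W, V), abs=1e-9)
        assert 0.0 <= got <= 1.0

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            cp.cca_similarity(np.zeros((4, 3)), np.zeros((4, 3)))


class TestCouplingMonotonicity:
    def test_all_three_measures_nondecreasing_in_c(self):
        """Median coupling over seeds rises with the generator's c."""
        from lfpstates import synth

        cs = [0.0, 0.25, 0.5, 0.75, 1.0]
        med = {m: [] for m in ("sync", "nmi", "cca")}
        for c in cs:
            vals = {m: [] for m in med}
            for seed in range(20):
                gt = synth.simulate_state_paths(4, 4, c, dwell_mean_s=120,
                                                duration_s=3000, seed=seed)
                paths = gt.state_paths
                rng = np.random.default_rng(seed + 999)
                onehot = [np.eye(4)[p] + 0.05 * rng.standard_normal((3000, 4))
                          for p in paths]
                pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
                s = np.mean([cp.transition_synchrony(
                    np.flatnonzero(np.diff(paths[i]) != 0) + 0.5,
                    np.flatnonzero(np.diff(paths[j]) != 0) + 0.5)[2]
                    for i, j in pairs])
                n = np.mean([cp.nmi_labels(paths[i], paths[j]) for i, j in pairs])
                cc = np.mean([cp.cca_similarity(onehot[i], onehot[j])
                              for i, j in pairs])
                vals["sync"].append(s)
                vals["nmi"].append(n)
                vals["cca"].append(cc)
            for m in med:
                med[m].append(np.median(vals[m]))
        for m, series in med.items():
            assert all(b >= a - 1e-9 for a, b in zip(series, series[1:])), (m, series)
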