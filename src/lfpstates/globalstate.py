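"""Global state: concatenated per-channel NMF scores and their dimensionality.

Concatenating each channel's rescaled NMF score vector at every time window
yields one joint vector encoding the instantaneous state of all channels.
PCA on the joint score matrix quantifies how low-dimensional the global
dynamics are; comparing the cumulative explained-variance curve against
Markov-shuffled surrogates (which keep single-channel statistics but destroy
cross-channel coordination) shows how much of that compression is due to
genuine between-channel coupling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "GlobalStateMatrix",
    "concatenate_scores",
    "global_pca",
    "compare_null_dimensionality",
]


@dataclass
class GlobalStateMatrix:
    """Joint window x (sum of K_c) score matrix with column provenance."""

    scores: np.ndarray
    column_map: list  # list of (channel, component)

    @property
    def n_windows(self) -> int:
        return self.scores.shape[0]

    @property
    def dimension(self) -> int:
        return self.scores.shape[1]


def concatenate_scores(models, channel_ids=None) -> GlobalStateMatrix:
    """Column-concatenate per-channel rescaled score matrices.

    All models must share the window grid (same number of windows). No
    rescaling is applied beyond each model's unit-loading-norm convention.
    """
    if not models:
        raise ValueError("need at least one model")
    n = models[0].V.shape[0]
    if any(m.V.shape[0] != n for m in models):
        raise ValueError("window grids do not match across channels")
    if channel_ids is None:
        channel_ids = list(range(len(models)))
    cols = []
    cmap = []
    for ch, m in zip(channel_ids, models):
        cols.append(m.V)
        cmap.extend((ch, k) for k in range(m.V.shape[1]))
    return GlobalStateMatrix(scores=np.hstack(cols), column_map=cmap)


def _explained_variance(X: np.ndarray) -> np.ndarray:
    pca = PCA(svd_solver="full")
    pca.fit(X)
    return pca.explained_variance_ratio_


def global_pca(G: GlobalStateMatrix, variance_target: float = 0.8):
    """PCA of the mean-centered joint scores.

    Returns (n_components_needed, explained_variance_ratio, loadings,
    projections) where n_components_needed is the smallest count whose
    cumulative explained variance reaches ``variance_target``. Columns are
    centered but not variance-standardized: the unit-norm loading convention
    already puts per-channel scores on comparable scales.
    """
    X = G.scores
    if X.shape[0] < 2:
        raise ValueError("need at least 2 windows")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("joint score matrix is constant")
    pca = PCA(svd_solver="full")
    proj = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    n_needed = int(np.searchsorted(cum, variance_target) + 1)
    return n_needed, evr, pca.components_, proj


def projection_histogram(proj: np.ndarray, bins: int = 50):
    """2-D histogram of the first two PC projections over the 1st-99th pctile range."""
    x, y = proj[:, 0], proj[:, 1]
    xr = np.percentile(x, [1, 99])
    yr = np.percentile(y, [1, 99])
    H, xe, ye = np.histogram2d(x, y, bins=bins, range=[xr, yr])
    return H, xe, ye


def compare_null_dimensionality(G: GlobalStateMatrix, null_joint_matrices,
                                variance_target: float = 0.8,
                                ci: float = 95.0):
    """Observed vs surrogate cumulative explained-variance curves.

    ``null_joint_matrices`` is an iterable of joint score matrices built from
    Markov-shuffled surrogates (same dimension as the observed matrix).
    Returns a dict with the observed curve, the pointwise null median and CI
    band, the per-component exceedance (observed minus null upper limit),
    and the components-to-target counts for observed and null.
    """
    obs_evr = _explained_variance(G.scores)
    obs_cum = np.cumsum(obs_evr)
    null_cums = []
    for M in null_joint_matrices:
        M = np.asarray(M, dtype=float)
        if M.shape[1] != G.dimension:
            raise ValueError("surrogate dimension does not match observed")
        null_cums.append(np.cumsum(_explained_variance(M)))
    if len(null_cums) < 2:
        raise ValueError("need multiple surrogates for a CI band")
    null_cums = np.asarray(null_cums)
    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2
    band_lo = np.percentile(null_cums, lo_q, axis=0)
    band_hi = np.percentile(null_cums, hi_q, axis=0)
    n_obs = int(np.searchsorted(obs_cum, variance_target) + 1)
    n_null = [int(np.searchsorted(c, variance_target) + 1) for c in null_cums]
    return {
        "observed_cum": obs_cum,
        "null_median": np.median(null_cums, axis=0),
        "null_lo": band_lo,
        "null_hi": band_hi,
        "exceedance": obs_cum - band_hi,
        "n_components_observed": n_obs,
        "n_components_null": np.asarray(n_null),
    }
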