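"""Current source density from trial-averaged laminar evoked potentials.

The CSD at depth z is the convolution of the depth profile of the
trial-averaged potential with a smoothed second-spatial-derivative kernel

    K(z) = (z^2 - sigma^2) / (sigma^5 sqrt(2 pi)) * exp(-z^2 / (2 sigma^2)),

i.e. the second derivative of a Gaussian of scale sigma = 280 um (sigma is
the distance from the center at which the kernel changes sign). Sinks are
negative CSD values by convention. L4 is localized as the channel with the
earliest post-stimulus current sink; analysis channels are then picked at
fixed 140 um depth intervals above and below L4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import Recording

__all__ = [
    "CSDProfile",
    "csd_kernel",
    "compute_csd",
    "trial_average",
    "locate_l4",
    "select_channels",
]


@dataclass
class CSDProfile:
    """CSD matrix (depth x peri-stimulus time) with its grids.

    Units are uV/um^2 up to the (unknown) extracellular conductivity.
    ``times_ms`` is relative to stimulus onset; negative times are baseline.
    """

    csd: np.ndarray
    depths_um: np.ndarray
    times_ms: np.ndarray
    sigma_um: float = 280.0

    def __post_init__(self):
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if not np.all(np.diff(self.depths_um) > 0):
            raise ValueError("depths must be strictly increasing")
        if self.sigma_um <= 0:
            raise ValueError("kernel scale must be positive")


def csd_kernel(z_um, sigma_um: float = 280.0):
    """Second-derivative-of-Gaussian CSD kernel, negative for |z| < sigma."""
    if sigma_um <= 0:
        raise ValueError("sigma_um must be positive")
    z = np.asarray(z_um, dtype=float)
    return (z ** 2 - sigma_um ** 2) / (sigma_um ** 5 * np.sqrt(2 * np.pi)) * np.exp(
        -(z ** 2) / (2 * sigma_um ** 2)
    )


def trial_average(rec: Recording, stimulus_times_s, pre_ms: float = 50.0,
                  post_ms: float = 100.0):
    """Average LFP across stimuli into a (depth x peri-stimulus time) matrix.

    Returns (evoked_mean, times_ms). Trials whose window exceeds the
    recording bounds are skipped.
    """
    fs = rec.fs_hz
    pre = int(round(pre_ms / 1000.0 * fs))
    post = int(round(post_ms / 1000.0 * fs))
    snippets = []
    for t in np.asarray(stimulus_times_s):
        i = int(round(t * fs))
        if i - pre < 0 or i + post > rec.n_samples:
            continue
        snippets.append(rec.lfp[:, i - pre: i + post])
    if not snippets:
        raise ValueError("no stimulus falls fully inside the recording")
    mean = np.mean(snippets, axis=0)
    times_ms = (np.arange(-pre, post) / fs) * 1000.0
    return mean, times_ms


def compute_csd(evoked_mean: np.ndarray, depths_um, times_ms,
                sigma_um: float = 280.0) -> CSDProfile:
    """Convolve the laminar potential with the CSD kernel along depth.

    Edges use the truncated kernel with weights recentered to zero sum, so
    that depth-constant potentials map to zero everywhere without fabricating
    data beyond the probe.
    """
    depths = np.asarray(depths_um, dtype=float)
    if depths.size < 5:
        raise ValueError("need at least 5 depths")
    spacing = np.diff(depths)
    if not np.allclose(spacing, spacing[0], rtol=1e-6):
        raise ValueError("depths must be uniformly spaced")

    n = depths.size
    # weight matrix: row i holds the kernel sampled at z_i - z_j, recentered
    # to zero sum so constants are annihilated even where truncated
    zz = depths[:, None] - depths[None, :]
    w = csd_kernel(zz, sigma_um) * spacing[0]
    w = w - w.mean(axis=1, keepdims=True)
    csd = w @ np.asarray(evoked_mean, dtype=float)
    return CSDProfile(csd=csd, depths_um=depths, times_ms=times_ms, sigma_um=sigma_um)


def locate_l4(csd: CSDProfile, threshold_sd: float = 3.0,
              min_duration_ms: float = 3.0) -> int:
    """Channel index of the earliest post-stimulus current sink.

    For each depth, the crossing time is the first post-stimulus sample where
    the CSD drops below -threshold_sd times that depth's pre-stimulus SD and
    stays below it for ``min_duration_ms`` (guards against isolated noise
    excursions). The depth with the earliest crossing wins; ties (same time
    bin) go to the larger sink magnitude over the sustained run.
    """
    post = csd.times_ms >= 0
    pre = csd.times_ms < 0
    if not pre.any():
        raise ValueError("CSD profile must include pre-stimulus baseline")
    if csd.times_ms[post].max() < 50.0:
        raise ValueError("CSD profile must extend at least 50 ms post-stimulus")
    base_sd = csd.csd[:, pre].std(axis=1)
    base_sd = np.where(base_sd > 0, base_sd, np.finfo(float).tiny)
    thr = -threshold_sd * base_sd

    dt = np.median(np.diff(csd.times_ms))
    min_run = max(1, int(round(min_duration_ms / dt)))
    best = None  # (crossing_time, -magnitude, channel)
    post_idx = np.flatnonzero(post)
    for ch in range(csd.depths_um.size):
        below = csd.csd[ch, post_idx] < thr[ch]
        first = _first_sustained(below, min_run)
        if first is None:
            continue
        t_cross = csd.times_ms[post_idx[first]]
        mag = -csd.csd[ch, post_idx[first: first + min_run]].min()
        key = (t_cross, -mag, ch)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError("no sink detected: no channel crosses the threshold")
    return int(best[2])


def _first_sustained(below: np.ndarray, min_run: int):
    """Index of the first run of >= min_run consecutive True values."""
    if min_run <= 1:
        idx = np.flatnonzero(below)
        return int(idx[0]) if idx.size else None
    conv = np.convolve(below.astype(int), np.ones(min_run, int), mode="valid")
    hits = np.flatnonzero(conv == min_run)
    return int(hits[0]) if hits.size else None


def select_channels(l4_channel: int, depths_um, spacing_um: float = 140.0,
                    contact_pitch_um: float = None, max_channels: int = 10):
    """Analysis channels at fixed depth intervals around L4.

    Picks channels at L4 +/- k * spacing for all k fitting on the probe,
    sorted superficial to deep, capped at ``max_channels`` chosen
    symmetrically around L4 (L4 first, then alternating above/below).
    """
    depths = np.asarray(depths_um, dtype=float)
    if not 0 <= l4_channel < depths.size:
        raise ValueError("L4 channel outside the probe")
    pitch = contact_pitch_um
    if pitch is None:
        pitch = float(np.diff(depths)[0])
    step = spacing_um / pitch
    if abs(step - round(step)) > 1e-6:
        raise ValueError("spacing must be an integer multiple of the contact pitch")
    step = int(round(step))

    chosen = [l4_channel]
    k = 1
    while len(chosen) < max_channels:
        added = False
        up = l4_channel - k * step
        down = l4_channel + k * step
        if up >= 0 and len(chosen) < max_channels:
            chosen.append(up)
            added = True
        if down < depths.size and len(chosen) < max_channels:
            chosen.append(down)
            added = True
        if not added:
            break
        k += 1
    return sorted(chosen)
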