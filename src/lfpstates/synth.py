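"""Synthetic multichannel LFP with ground-truth coupled spectral states.

Each channel carries a hidden discrete state (1 s clock) drawn from a master
Markov chain with geometric dwell times; a single coupling parameter c in
[0, 1] controls how often a channel adopts the master's switches versus
switching on its own. Signals are sums of stochastic band-limited resonators
whose amplitudes follow the hidden state, over a 1/f background — realistic
enough that multitaper + NMF segmentation downstream is a nontrivial
recovery problem.

A separate generator injects laminar evoked responses with a known
current-sink depth for testing CSD-based layer localization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import Recording

__all__ = [
    "GroundTruth",
    "SpectralProfileSet",
    "EvokedSpec",
    "default_profiles",
    "simulate_state_paths",
    "synthesize_lfp",
    "synthesize_evoked",
    "simulate_recording",
]


@dataclass
class GroundTruth:
    """Hidden per-channel state paths and the parameters that produced them."""

    state_paths: np.ndarray  # (n_channels, duration_s) int, 1 s resolution
    master_path: np.ndarray  # (duration_s,) int
    coupling: float
    n_states: int
    dwell_mean_s: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "coupling": self.coupling,
                "n_states": self.n_states,
                "dwell_mean_s": self.dwell_mean_s,
                "seed": self.seed,
                "master_path": self.master_path.tolist(),
                "state_paths": self.state_paths.tolist(),
            }
        )


@dataclass
class SpectralProfileSet:
    """Per-state oscillatory content: (center_hz, bandwidth_hz, amplitude) triples.

    ``bands[k]`` lists the resonator bands active in state k. The 1/f
    background has spectral exponent ``background_exponent`` and amplitude
    ``background_amp``; per-channel multiplicative gains emulate electrode
    impedance differences.
    """

    bands: list  # list over states of list of (center_hz, bw_hz, amp)
    background_exponent: float = 1.0
    background_amp: float = 1.0
    channel_gain: np.ndarray = None

    def n_states(self) -> int:
        return len(self.bands)

    def max_freq(self) -> float:
        return max((c + bw for st in self.bands for (c, bw, a) in st), default=0.0)

    def validate(self, fs_hz: float) -> None:
        for st in self.bands:
            for c, bw, a in st:
                if a < 0:
                    raise ValueError("band amplitudes must be >= 0")
                if not 0 < c < fs_hz / 2:
                    raise ValueError(f"band center {c} Hz outside (0, Nyquist)")


@dataclass
class EvokedSpec:
    """Parameters of the injected laminar evoked response."""

    sink_depth_um: float
    latency_ms: float = 33.0
    n_trials: int = 50
    isi_range_s: tuple = (3.0, 5.0)
    sink_sigma_um: float = 200.0
    period_ms: float = 40.0
    amplitude_uv: float = 200.0
    noise_uv: float = 5.0


def default_profiles(n_states: int, seed: int = 0) -> SpectralProfileSet:
    """Band profiles emulating anesthetized cortical LFP states.

    States draw from a pool of physiologically motivated bands (slow ~1 Hz,
    delta ~2.5 Hz, spindle ~12 Hz, low gamma ~40 Hz, mid gamma ~70 Hz) with
    state-specific amplitude patterns, so that distinct states differ in at
    least one band amplitude.
    """
    rng = np.random.default_rng(seed)
    pool = [(1.0, 0.6), (2.5, 1.2), (6.0, 2.0), (12.0, 3.0), (25.0, 6.0),
            (40.0, 10.0), (70.0, 15.0)]
    bands = []
    for k in range(n_states):
        # each state has a distinctive dominant band (cycled through the
        # pool) plus a weaker secondary band, so states are separable but
        # share spectral structure
        primary = pool[k % len(pool)]
        secondary = pool[int(rng.integers(len(pool)))]
        st = [(primary[0], primary[1], float(2.5 + rng.random())),
              (secondary[0], secondary[1], float(0.8 + 0.4 * rng.random()))]
        bands.append(st)
    return SpectralProfileSet(bands=bands)


def _geometric_stay_prob(dwell_mean_s: float) -> float:
    # dwell counted in 1 s steps; geometric mean dwell = 1 / (1 - p_stay)
    return 1.0 - 1.0 / dwell_mean_s if dwell_mean_s > 1 else 0.0


def _simulate_chain(rng, n_steps: int, k: int, p_stay: float, init: int = None) -> np.ndarray:
    path = np.empty(n_steps, dtype=int)
    state = rng.integers(k) if init is None else init
    u = rng.random(n_steps)
    jumps = rng.integers(1, k, size=n_steps)  # offset to a different state
    for t in range(n_steps):
        if u[t] >= p_stay:
            state = (state + jumps[t]) % k
        path[t] = state
    return path


def simulate_state_paths(n_channels: int, K_true: int, coupling: float,
                         dwell_mean_s: float = 120.0, duration_s: float = 1200.0,
                         seed: int = 0) -> GroundTruth:
    """Simulate coupled hidden state paths at 1 s resolution.

    A master chain switches with geometric dwell (mean ``dwell_mean_s``).
    At each master transition every channel independently adopts the new
    master state with probability ``coupling``; between adoptions it runs its
    own chain with the same dwell statistics. c=1 forces all channels onto
    the master path; c=0 makes channels fully independent of it.
    """
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must lie in [0, 1]")
    if K_true < 2:
        raise ValueError("K_true must be >= 2")
    if dwell_mean_s <= 0 or duration_s <= 0:
        raise ValueError("dwell_mean_s and duration_s must be positive")

    n_steps = int(round(duration_s))
    p_stay = _geometric_stay_prob(dwell_mean_s)
    rng = np.random.default_rng(seed)

    master = _simulate_chain(rng, n_steps, K_true, p_stay)
    # master-segment boundaries; t=0 counts as a transition so that c=1
    # pins channels to the master over the whole duration
    seg_starts = np.concatenate([[0], np.flatnonzero(np.diff(master) != 0) + 1])
    seg_ends = np.concatenate([seg_starts[1:], [n_steps]])

    paths = np.empty((n_channels, n_steps), dtype=int)
    for ch in range(n_channels):
        ch_rng = np.random.default_rng((seed, 1, ch))
        own = _simulate_chain(ch_rng, n_steps, K_true, p_stay, init=int(master[0]))
        # at each master transition the channel locks onto the master state
        # for that master segment with probability `coupling`; otherwise it
        # shows its own independently evolving chain
        locked = ch_rng.random(seg_starts.size) < coupling
        path = own.copy()
        for t0, t1, lk in zip(seg_starts, seg_ends, locked):
            if lk:
                path[t0:t1] = master[t0]
        paths[ch] = path

    return GroundTruth(state_paths=paths, master_path=master, coupling=float(coupling),
                       n_states=K_true, dwell_mean_s=float(dwell_mean_s), seed=seed)


def _resonator_sos(center_hz: float, bw_hz: float, fs_hz: float):
    """Second-order resonator (bandpass biquad) at the given center/bandwidth."""
    lo = max(center_hz - bw_hz / 2, 1e-3)
    hi = min(center_hz + bw_hz / 2, fs_hz / 2 * 0.999)
    return signal.butter(2, [lo, hi], btype="bandpass", fs=fs_hz, output="sos")


def _one_over_f(rng, n: int, fs_hz: float, exponent: float) -> np.ndarray:
    """Seeded 1/f^exponent Gaussian noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    return x / (x.std() + 1e-12)


def synthesize_lfp(truth: GroundTruth, profiles: SpectralProfileSet,
                   fs_hz: float = 1000.0, seed: int = 0) -> Recording:
    """Render hidden state paths as multichannel LFP.

    Each band in the state profiles drives a stochastic resonator (white
    noise through a second-order bandpass); its output is gated by a
    state-dependent amplitude envelope aligned sample-accurately to the 1 s
    state clock. The 1/f background is always on.
    """
    profiles.validate(fs_hz)
    if fs_hz < 2 * profiles.max_freq():
        raise ValueError("fs_hz must be at least twice the maximum profile frequency")
    n_ch, n_sec = truth.state_paths.shape
    n = int(round(n_sec * fs_hz))
    gains = (profiles.channel_gain if profiles.channel_gain is not None
             else np.ones(n_ch))

    # collect the distinct bands used anywhere, with per-state amplitudes
    band_keys = sorted({(c, bw) for st in profiles.bands for (c, bw, a) in st})
    amp = np.zeros((profiles.n_states(), len(band_keys)))
    for k, st in enumerate(profiles.bands):
        for c, bw, a in st:
            amp[k, band_keys.index((c, bw))] = a

    lfp = np.empty((n_ch, n))
    upsample = int(round(fs_hz))  # samples per 1 s state step
    for ch in range(n_ch):
        rng = np.random.default_rng((seed, 2, ch))
        x = profiles.background_amp * _one_over_f(rng, n, fs_hz, profiles.background_exponent)
        env_states = truth.state_paths[ch]
        for bi, (c, bw) in enumerate(band_keys):
            a_per_state = amp[:, bi]
            if not a_per_state.any():
                continue
            sos = _resonator_sos(c, bw, fs_hz)
            osc = signal.sosfilt(sos, rng.standard_normal(n))
            osc /= osc.std() + 1e-12
            envelope = np.repeat(a_per_state[env_states], upsample)[:n]
            x = x + envelope * osc
        lfp[ch] = gains[ch] * 20.0 * x  # ~tens of microvolts

    depths = 140.0 * np.arange(n_ch)
    return Recording(lfp=lfp, fs_hz=fs_hz, channel_depth_um=depths,
                     region=np.array(["SIM"] * n_ch, dtype=object),
                     probe_id=np.zeros(n_ch, dtype=int))


def synthesize_evoked(spec: EvokedSpec, channel_depths_um, fs_hz: float = 1000.0,
                      seed: int = 0):
    """Simulate flash-evoked laminar potentials with a known sink depth.

    Each 10 ms stimulus injects a spatially Gaussian, temporally biphasic
    potential profile centered at ``sink_depth_um``. Because the analytic
    second spatial derivative of a positive Gaussian bump is negative at its
    center, the resulting CSD has its earliest negative extremum (the sink)
    at the injected depth and latency. Interstimulus intervals are uniform
    on ``isi_range_s``.

    Returns (Recording, stimulus_times_s).
    """
    depths = np.asarray(channel_depths_um, dtype=float)
    if depths.size < 5:
        raise ValueError("need at least 5 channels spanning the sink depth")
    if not depths.min() <= spec.sink_depth_um <= depths.max():
        raise ValueError("sink_depth_um outside the probe span")
    lo, hi = spec.isi_range_s
    if not lo < hi:
        raise ValueError("isi_range_s must satisfy low < high")

    rng = np.random.default_rng(seed)
    isis = rng.uniform(lo, hi, size=spec.n_trials)
    stim_times = 1.0 + np.cumsum(isis) - isis[0]
    duration_s = stim_times[-1] + 1.0
    n = int(round(duration_s * fs_hz))

    spatial = np.exp(-((depths - spec.sink_depth_um) ** 2) / (2 * spec.sink_sigma_um ** 2))

    period_samp = int(round(spec.period_ms / 1000.0 * fs_hz))
    tcourse = np.sin(2 * np.pi * np.arange(period_samp) / period_samp)  # biphasic
    onset_offset_samp = int(round(spec.latency_ms / 1000.0 * fs_hz)) - period_samp // 4

    lfp = spec.noise_uv * rng.standard_normal((depths.size, n))
    for t0 in stim_times:
        i0 = int(round(t0 * fs_hz)) + onset_offset_samp
        i1 = min(i0 + period_samp, n)
        if i0 < 0 or i0 >= n:
            continue
        lfp[:, i0:i1] += spec.amplitude_uv * spatial[:, None] * tcourse[: i1 - i0]

    rec = Recording(lfp=lfp, fs_hz=fs_hz, channel_depth_um=depths,
                    region=np.array(["V1"] * depths.size, dtype=object),
                    probe_id=np.zeros(depths.size, dtype=int))
    return rec, stim_times


def simulate_recording(n_channels: int = 8, K_true: int = 6, coupling: float = 0.5,
                       dwell_mean_s: float = 120.0, duration_s: float = 1200.0,
                       fs_hz: float = 1000.0, seed: int = 0,
                       profiles: SpectralProfileSet = None):
    """Convenience wrapper: state paths + LFP in one call.

    Returns (Recording, GroundTruth, SpectralProfileSet).
    """
    truth = simulate_state_paths(n_channels, K_true, coupling, dwell_mean_s,
                                 duration_s, seed)
    if profiles is None:
        profiles = default_profiles(K_true, seed=seed + 101)
    rec = synthesize_lfp(truth, profiles, fs_hz=fs_hz, seed=seed + 202)
    return rec, truth, profiles
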