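"""LFP conditioning: decimation, zero-phase FIR bandpass, rereferencing, masks.

The conditioning chain mirrors standard laminar-LFP practice: anti-aliased
decimation to 1 kHz, an acausal (zero-phase) 0.1-200 Hz FIR bandpass, and
rereferencing each laminar probe to the mean over its clean channels.

The burst-suppression/artifact detector shipped here (`mask_artifacts`) is a
documented RMS-floor placeholder, deliberately simple: real burst-suppression
detection is recording-specific and is expected to be supplied externally as a
mask and unioned in.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .recording import Recording

__all__ = ["condition_lfp", "mask_artifacts", "design_bandpass_fir"]


def _stage_factors(ratio: int) -> list:
    """Decompose an integer decimation ratio into stages <= 10."""
    factors = []
    r = ratio
    for p in (10, 9, 8, 7, 6, 5, 4, 3, 2):
        while r % p == 0 and r > 1:
            factors.append(p)
            r //= p
    if r != 1:  # large prime ratio: decimate in one go
        factors.append(r)
    return factors


def design_bandpass_fir(fs_hz: float, band_hz, transition_hz: float = 0.05,
                        max_taps: int = None) -> np.ndarray:
    """Windowed-sinc (Hamming) bandpass FIR.

    Tap count targets a ``transition_hz`` transition band at the low edge
    (Hamming main-lobe rule: N ~ 3.3 * fs / transition), optionally capped
    for short signals.
    """
    lo, hi = band_hz
    if not 0 < lo < hi < fs_hz / 2:
        raise ValueError(f"band {band_hz} outside (0, Nyquist={fs_hz / 2})")
    n_taps = int(np.ceil(3.3 * fs_hz / transition_hz))
    if max_taps is not None:
        n_taps = min(n_taps, max_taps)
    n_taps |= 1  # odd length -> symmetric, integer group delay
    return signal.firwin(n_taps, [lo, hi], pass_zero=False, fs=fs_hz, window="hamming")


def _zero_phase_fir(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Forward-backward FIR filtering along the last axis via FFT convolution.

    The kernel is symmetric, so each pass is linear-phase; applying it twice
    (forward then time-reversed) squares the magnitude response and cancels
    the phase exactly, matching filtfilt semantics without O(N*taps) cost.
    Edges are handled by reflect-padding one kernel length.
    """
    pad = min(len(h) - 1, x.shape[-1] - 1)
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    y = signal.fftconvolve(xp, h[np.newaxis, :] if x.ndim == 2 else h, mode="same", axes=-1)
    y = signal.fftconvolve(y, h[np.newaxis, ::-1] if x.ndim == 2 else h[::-1], mode="same", axes=-1)
    return y[..., pad: pad + x.shape[-1]]


def condition_lfp(rec: Recording, target_fs_hz: float = 1000.0,
                  band_hz=(0.1, 200.0), transition_hz: float = 0.05) -> Recording:
    """Decimate, zero-phase bandpass, and per-probe mean-rereference.

    Decimation runs in stages with per-stage anti-alias FIR filters (e.g.
    40 kHz -> 1 kHz as x8 then x5). The bandpass is a Hamming windowed-sinc
    applied forward-backward. Rereferencing subtracts, per probe and per
    sample, the mean over that probe's non-excluded channels; excluded
    channels are filtered and rereferenced too but stay flagged.
    """
    ratio = rec.fs_hz / target_fs_hz
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"target_fs_hz must divide fs_hz (ratio {ratio})")
    ratio = int(round(ratio))
    if band_hz[1] >= target_fs_hz / 2:
        raise ValueError("band upper edge must be below the target Nyquist")

    x = rec.lfp
    mask = rec.artifact_mask
    if ratio > 1:
        for q in _stage_factors(ratio):
            x = signal.decimate(x, q, ftype="fir", axis=-1, zero_phase=True)
        mask = mask[::ratio][: x.shape[1]]

    h = design_bandpass_fir(target_fs_hz, band_hz, transition_hz,
                            max_taps=max(3, x.shape[1] // 3))
    x = _zero_phase_fir(x, h)

    out = x.copy()
    clean = set(rec.clean_channels())
    for pid in np.unique(rec.probe_id):
        members = np.where(rec.probe_id == pid)[0]
        ref_ch = [c for c in members if c in clean]
        if not ref_ch:
            continue
        out[members] -= x[ref_ch].mean(axis=0, keepdims=True)

    return rec.copy_with(lfp=out, fs_hz=float(target_fs_hz), artifact_mask=mask)


def mask_artifacts(rec: Recording, power_floor: float, min_gap_s: float = 1.0,
                   window_s: float = 1.0, external_mask: np.ndarray = None) -> Recording:
    """Flag low-power (suppression-like) epochs and union with external masks.

    Samples where the channel-mean RMS in non-overlapping ``window_s`` windows
    falls strictly below ``power_floor`` are flagged; flags are then dilated
    by ``min_gap_s`` on each side. An externally supplied per-sample mask
    (e.g. from manual inspection or a bespoke burst-suppression detector) is
    OR-ed in. ``power_floor=0`` yields an empty detector mask.
    """
    if power_floor < 0:
        raise ValueError("power_floor must be >= 0")
    n = rec.n_samples
    win = max(1, int(round(window_s * rec.fs_hz)))
    n_win = n // win
    flags = np.zeros(n, dtype=bool)
    if n_win > 0 and power_floor > 0:
        seg = rec.lfp[:, : n_win * win].reshape(rec.n_channels, n_win, win)
        rms = np.sqrt((seg ** 2).mean(axis=(0, 2)))
        low = rms < power_floor
        flags[: n_win * win] = np.repeat(low, win)
        if n_win * win < n and low[-1]:
            flags[n_win * win:] = True
    if flags.any() and min_gap_s > 0:
        dil = int(round(min_gap_s * rec.fs_hz))
        idx = np.flatnonzero(flags)
        grown = np.zeros(n, dtype=bool)
        for start, stop in _runs(idx):
            grown[max(0, start - dil): min(n, stop + dil)] = True
        flags = grown
    combined = rec.artifact_mask | flags
    if external_mask is not None:
        external_mask = np.asarray(external_mask, dtype=bool)
        if external_mask.shape != (n,):
            raise ValueError("external mask length must match sample count")
        combined = combined | external_mask
    if combined.all():
        warnings.warn("artifact mask covers the entire recording")
    return rec.copy_with(artifact_mask=combined)


def _runs(idx: np.ndarray):
    """Yield (start, stop) half-open runs of consecutive indices."""
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    yield from zip(starts, stops)
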