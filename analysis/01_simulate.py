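#!/usr/bin/env python
"""Simulate the study's synthetic recordings: coupled spectral states + evoked.

Writes an 8-channel, 20 min LFP recording in the weak-coupling regime
(c = 0.5, 6 hidden states, 120 s mean dwell) to the HDF5 container, a
ground-truth sidecar JSON, and a laminar evoked recording with a known
700 um current sink for the CSD stage.
"""

import json
from pathlib import Path

import numpy as np

from lfpstates import save_recording, synth

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
SEED = 1


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    rec, truth, profiles = synth.simulate_recording(
        n_channels=8, K_true=6, coupling=0.5, dwell_mean_s=120.0,
        duration_s=1200.0, fs_hz=1000.0, seed=SEED)
    save_recording(OUT / "synthetic_lfp.h5", rec, seed=SEED)
    with open(OUT / "synthetic_truth.json", "w") as f:
        f.write(truth.to_json())
    n_trans = int((np.diff(truth.state_paths, axis=1) != 0).sum())
    print(f"wrote synthetic_lfp.h5: {rec.n_channels} channels, "
          f"{rec.duration_s:.0f} s, {n_trans} hidden transitions total")

    depths = 20.0 * np.arange(64)
    spec = synth.EvokedSpec(sink_depth_um=700.0, latency_ms=33.0, n_trials=40)
    evoked, stims = synth.synthesize_evoked(spec, depths, seed=SEED + 1)
    save_recording(OUT / "synthetic_evoked.h5", evoked, seed=SEED + 1)
    np.savetxt(OUT / "stimulus_times_s.csv", stims, header="stim_time_s")
    print(f"wrote synthetic_evoked.h5: {len(stims)} flashes, sink at 700 um")


if __name__ == "__main__":
    main()
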