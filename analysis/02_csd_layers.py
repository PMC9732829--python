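#!/usr/bin/env python
"""Localize L4 from the evoked CSD and select analysis channels at 140 um.

Reads the synthetic evoked recording from 01_simulate.py, computes the CSD
with the sigma = 280 um second-derivative kernel, finds the earliest current
sink, and writes the CSD matrix plus the selected channel list.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from lfpstates import csd, load_recording

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main():
    rec = load_recording(OUT / "synthetic_evoked.h5")
    stims = np.loadtxt(OUT / "stimulus_times_s.csv")
    ev, tms = csd.trial_average(rec, stims)
    prof = csd.compute_csd(ev, rec.channel_depth_um, tms)
    l4 = csd.locate_l4(prof)
    selected = csd.select_channels(l4, rec.channel_depth_um, spacing_um=140,
                                   contact_pitch_um=20)
    pd.DataFrame(prof.csd, index=prof.depths_um, columns=prof.times_ms).to_csv(
        OUT / "csd_matrix.csv")
    with open(OUT / "selected_channels.json", "w") as f:
        json.dump({"l4_channel": int(l4),
                   "l4_depth_um": float(rec.channel_depth_um[l4]),
                   "selected_channels": [int(c) for c in selected]}, f, indent=2)
    print(f"L4 at channel {l4} ({rec.channel_depth_um[l4]:.0f} um); "
          f"selected {len(selected)} channels at 140 um spacing")


if __name__ == "__main__":
    main()
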