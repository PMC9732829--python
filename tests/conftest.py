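import numpy as np
import pytest

from lfpstates import synth
from lfpstates.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def mini_bundle():
    """One small end-to-end pipeline run on strongly coupled synthetic LFP.

    Shared across integration tests: 3 channels, 3 planted states, c = 0.9,
    10 min of signal. Sizes are deliberately small so the whole suite stays
    desk-scale; the statistical properties asserted on it are scale-free.
    """
    cfg = PipelineConfig(n_channels=3, k_true=3, coupling=0.9,
                         dwell_mean_s=120.0, duration_s=600.0, step_s=1.0,
                         k_max=8, bicv_downsample=10, n_surrogates=60,
                         n_null_pca=20, master_seed=7)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def evoked_dataset():
    """Synthetic laminar evoked recording with a known 700 um sink."""
    depths = 20.0 * np.arange(64)
    spec = synth.EvokedSpec(sink_depth_um=700.0, latency_ms=33.0, n_trials=40)
    rec, stims = synth.synthesize_evoked(spec, depths, seed=3)
    return spec, depths, rec, stims
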