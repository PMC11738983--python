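import numpy as np
import pytest

import trapkin as tk


@pytest.fixture(scope="session")
def short_trace():
    """A 60 s synthetic trapping trace at reference conditions, rendered at
    a reduced 20 kHz sampling rate to keep the suite fast."""
    cfg = tk.SimConfig(duration_s=60.0, fs_hz=20_000.0, seed=101)
    return cfg, tk.simulate_trace(cfg)


@pytest.fixture(scope="session")
def filtered_trace(short_trace):
    _, trace = short_trace
    return tk.lowpass_filter(trace, cutoff_hz=3.0, decimate_to_hz=100.0)


@pytest.fixture()
def telegraph_segment():
    """A noiseless two-level telegraph at 100 Hz, wrapped as FilteredTrace."""
    cfg = tk.SimConfig(
        duration_s=30.0, fs_hz=100.0,
        sigma_unbound_V=0.0, sigma_bound_V=0.0, seed=7,
    )
    events = tk.simulate_event_sequence(
        cfg.k_off, cfg.k_on_eff, cfg.duration_s, seed=13
    )
    trace = tk.render_trace(events, cfg)
    return tk.FilteredTrace(
        values=trace.values, fs=trace.fs, true_state=trace.true_state,
        metadata=trace.metadata, cutoff_hz=np.nan, effective_fs=trace.fs,
    )
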