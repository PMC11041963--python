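import numpy as np
import pytest

from pulsetherm import rppg, sim


@pytest.fixture(scope="session")
def steady_beats():
    """5-min beat series at 72 BPM with mild LF/HF modulation."""
    return sim.generate_beat_series(
        300, 72, lf_amp_s=0.02, hf_amp_s=0.02, noise_sd_s=0.005, seed=7
    )


@pytest.fixture(scope="session")
def clean_traces(steady_beats):
    """Noise-free pulse-modulated RGB traces, 4 ROIs at 30 fps."""
    return sim.synthesize_rgb_traces(
        steady_beats, fps=30, n_rois=4, pulse_amp=0.01, noise_sd=0.0, seed=7
    )


def make_hr_series(values, hop_s=1.0, win_s=6.0):
    """Helper: wrap a list of BPM values as an HrSeries on a unit grid."""
    values = np.asarray(values, dtype=float)
    return rppg.HrSeries(
        t_center_s=win_s / 2 + hop_s * np.arange(len(values)),
        hr_bpm=values,
        win_s=win_s,
        hop_s=hop_s,
    )
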