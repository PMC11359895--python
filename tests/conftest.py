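import numpy as np
import pytest

from watchwalk.config import PipelineConfig
from watchwalk import simulate as sim


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def dev_cohort(cfg):
    """Small labelled development cohort shared by model-level tests."""
    records = sim.synthesize_development_cohort(6, seed=11, cfg=cfg)
    frames = [sim.labelled_frame(r, cfg) for r in records]
    return records, frames


@pytest.fixture(scope="session")
def trained(cfg, dev_cohort):
    """Classifier + speed models fitted on the small development cohort."""
    from watchwalk.classifier import train
    from watchwalk.speed import fit_speed

    _, frames = dev_cohort
    clf = train(frames, cfg, seed=11)
    spd = fit_speed(frames, cfg, seed=11)
    return clf, spd


def make_walk_window(
    cfg, cadence_spm=110.0, jitter_ms=0.0, seconds=None, seed=0, amp=0.35
):
    """One conditioned walking-norm stream (band-passed) for step tests."""
    from watchwalk.preprocess import bandpass

    fs = cfg.sampling_rate_hz
    dur = seconds if seconds is not None else cfg.window_s
    rng = np.random.default_rng(seed)
    T = 60.0 / cadence_spm
    n_steps = int(np.floor(dur / T))
    intervals = np.maximum(T + rng.normal(0, jitter_ms / 1000.0, n_steps), 0.25 * T)
    times = 0.5 * T + np.concatenate(([0.0], np.cumsum(intervals[1:])))
    t = np.arange(int(dur * fs)) / fs
    anchors_t = np.concatenate(([0.0], times, [dur]))
    anchors_p = np.concatenate(
        ([-2 * np.pi * times[0] / T],
         2 * np.pi * np.arange(n_steps),
         [2 * np.pi * (n_steps - 1 + (dur - times[-1]) / T)])
    )
    phase = np.interp(t, anchors_t, anchors_p)
    x = 1.0 + amp * np.sin(phase) + rng.normal(0, 0.01, t.size)
    return bandpass(x, cfg), times
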