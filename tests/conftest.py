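import dataclasses

import numpy as np
import pytest

import gutmotion as gm

SI_LIKE = gm.WaveParams(
    frequency=40.0, amplitude=0.4, velocity=15.0, baseline_diameter=2.0,
    drift_amplitude=0.5, drift_period=120.0, noise_sd=0.02, duration=60.0,
    fps=25.0, n_loci=30, segment_length=2.0,
)


def si_params(**overrides) -> gm.WaveParams:
    """SI-like study conditions with per-test overrides."""
    return dataclasses.replace(SI_LIKE, **overrides)


def make_map(amplitude: np.ndarray, fps: float = 25.0,
             segment_length_cm: float = 2.0) -> gm.SpatioTemporalMap:
    """Wrap a raw signed-amplitude matrix as a map (zero baseline)."""
    amplitude = np.asarray(amplitude, dtype=float)
    return gm.SpatioTemporalMap(
        amplitude=amplitude, baseline=np.zeros_like(amplitude),
        fps=fps, segment_length_cm=segment_length_cm)


def sine_map(amp_mm: float, period_s: float, duration_s: float,
             n_loci: int = 5, fps: float = 25.0) -> gm.SpatioTemporalMap:
    """Synchronous sinusoidal amplitude map (identical at every locus)."""
    t = np.arange(int(round(duration_s * fps))) / fps
    row = amp_mm * np.sin(2 * np.pi * t / period_s)
    return make_map(np.tile(row, (n_loci, 1)), fps=fps)


@pytest.fixture(scope="session")
def si_trace() -> gm.DiameterTrace:
    return gm.simulate_trace(si_params(seed=11))


@pytest.fixture(scope="session")
def si_map(si_trace) -> gm.SpatioTemporalMap:
    return gm.baseline_correct(si_trace, window_s=20.0)


@pytest.fixture(scope="session")
def spiked_matrix():
    design = gm.SpikeDesign(seed=7)
    matrix, truth = gm.simulate_count_matrix(design)
    return gm.normalize_counts(matrix), truth, design
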