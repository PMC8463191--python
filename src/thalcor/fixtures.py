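"""Analytic test traces with known regime labels.

These waveforms are synthetic: they are constructed directly from the
classifier's decision rule, not simulated from the model, and exercise each
branch of the four-state rule — constant traces at the two fixed-point
levels, single-tone oscillations inside and outside the absence band, and a
two-bump spike-wave composite whose fundamental carries two prominent
maxima per period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import StateLabel

__all__ = ["FixtureTrace", "synthetic_traces"]


@dataclass
class FixtureTrace:
    name: str
    trace: np.ndarray
    sample_rate: float
    expected_label: StateLabel
    expected_frequency: float   # Hz; 0 for fixed points


def synthetic_traces(seed: int = 0, duration: float = 20.0,
                     sample_rate: float = 500.0) -> list[FixtureTrace]:
    """Build the classifier fixture set.

    A small seeded noise floor (amplitude 1e-4) is superimposed on the
    oscillatory traces so that peak detection cannot rely on bit-exact
    smoothness.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration * sample_rate)) / sample_rate
    noise = lambda: 1e-4 * rng.standard_normal(t.size)

    # narrow spike riding a 3 Hz slow wave: exactly two prominent maxima
    # per fundamental period (the spike and the wave crest)
    period = 1.0 / 3.0
    phase = (t % period) / period
    spike_wave = (np.sin(2 * np.pi * phase)
                  + 1.5 * np.exp(-((phase - 0.75) * period) ** 2
                                 / (2 * 0.015 ** 2)))
    # weak phase-locked second harmonic: ripples the flanks without adding
    # a second prominent maximum -> still a simple oscillation
    rippled = (np.sin(2 * np.pi * 3.0 * t)
               + 0.8 * np.sin(2 * np.pi * 6.0 * t))
    return [
        FixtureTrace("constant_high", np.full(t.size, 0.46), sample_rate,
                     StateLabel.SATURATED, 0.0),
        FixtureTrace("constant_low", np.full(t.size, 0.16), sample_rate,
                     StateLabel.LOW_FIRING, 0.0),
        FixtureTrace("sine_3hz", 0.25 * np.sin(2 * np.pi * 3.0 * t) + noise(),
                     sample_rate, StateLabel.SIMPLE_OSCILLATION, 3.0),
        FixtureTrace("sine_8hz", 0.25 * np.sin(2 * np.pi * 8.0 * t) + noise(),
                     sample_rate, StateLabel.SIMPLE_OSCILLATION, 8.0),
        FixtureTrace("rippled_3hz", 0.25 * rippled + noise(),
                     sample_rate, StateLabel.SIMPLE_OSCILLATION, 3.0),
        FixtureTrace("spike_wave_3hz", 0.25 * spike_wave + noise(),
                     sample_rate, StateLabel.SWD, 3.0),
        FixtureTrace("two_tone_2p5hz",
                     2.0 * np.sin(2 * np.pi * 2.5 * t)
                     + 1.0 * np.sin(2 * np.pi * 7.5 * t) + noise(),
                     sample_rate, StateLabel.SWD, 2.5),
    ]
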