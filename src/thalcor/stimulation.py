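"""Therapy waveforms and target-gating schedules.

Four stimulation schemes are modelled, all built from a high-frequency
rectangular pulse train delivered to the thalamic reticular nuclei:

- **DBS** — continuous pulse train to both TRN populations simultaneously.
- **CBBP** — biphasic pulse per period: a brief anodic phase followed by a
  sustained cathodic phase (see :func:`cbbp_waveform` for the two amplitude
  conventions).
- **CRS m:n** — coordinated reset: time is divided into cycles; within a
  super-period of ``m + n`` cycles the first ``m`` are ON and the rest OFF,
  and ON cycles alternate their target between TRN1 and TRN2 (TRN1 first).
  1:0 is perpetual alternation; 3:2 stimulates for three cycles and pauses
  for two.

The gate functions beta1/beta2 are binary and mutually exclusive for CRS;
for DBS and CBBP both targets are driven identically (beta1 = beta2 = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Literal

import numpy as np

__all__ = [
    "StimulusProtocol",
    "dbs_waveform",
    "cbbp_waveform",
    "crs_gates",
    "stimulus_currents",
    "rms_current",
    "NONE",
    "DBS",
    "CBBP",
    "CRS_1_0",
    "CRS_3_2",
]

Kind = Literal["none", "dbs", "cbbp", "crs"]

#: Default coordinated-reset cycle length in seconds.  One cycle is one
#: stimulation epoch handed to a single target; following coordinated-reset
#: practice it is set to one period of the pathological ~3 Hz rhythm.  See
#: docs/methods.md for the sensitivity of the therapy maps to this choice.
DEFAULT_CRS_CYCLE = 1.0 / 3.0


@dataclass
class StimulusProtocol:
    """Waveform family plus its parameters.

    ``amplitude`` (mA-equivalent model units), ``frequency`` in Hz (the
    pulse period is ``1/frequency``) and ``pulse_width`` in seconds are
    shared by all families.  ``cbbp_period`` defaults to the pulse period.
    ``crs_m``/``crs_n`` are the ON/OFF cycle counts of the m:n schedule and
    ``crs_cycle_length`` the duration of one cycle in seconds.

    ``cbbp_literal`` selects the printed biphasic convention in which the
    anodic amplitude equals the pulse width (numerically) and the waveform
    carries a small net cathodic charge; when False the anodic amplitude is
    ``amplitude`` and the cathodic amplitude is set by exact charge balance.
    """

    kind: Kind = "none"
    amplitude: float = 3.0
    frequency: float = 130.0
    pulse_width: float = 0.004
    cbbp_period: float | None = None
    cbbp_literal: bool = True
    crs_m: int = 1
    crs_n: int = 0
    crs_cycle_length: float = DEFAULT_CRS_CYCLE

    def __post_init__(self) -> None:
        if self.kind not in ("none", "dbs", "cbbp", "crs"):
            raise ValueError(f"unknown stimulus kind: {self.kind!r}")
        if self.kind == "none":
            return
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.pulse_width <= 0:
            raise ValueError("pulse_width must be positive")
        if self.kind == "dbs" and self.pulse_width >= self.period:
            raise ValueError("pulse_width must be shorter than the period")
        if self.kind == "cbbp" and self.pulse_width >= self.cbbp_period_or_default:
            raise ValueError("pulse_width must be shorter than the biphasic period")
        if self.kind == "crs":
            if self.crs_m < 1:
                raise ValueError("crs_m must be at least 1")
            if self.crs_n < 0:
                raise ValueError("crs_n must be non-negative")
            if self.crs_cycle_length <= 0:
                raise ValueError("crs_cycle_length must be positive")

    @property
    def period(self) -> float:
        """Pulse period rho = 1/f in seconds."""
        return 1.0 / self.frequency

    @property
    def cbbp_period_or_default(self) -> float:
        return self.cbbp_period if self.cbbp_period is not None else self.period

    def replace(self, **kwargs) -> "StimulusProtocol":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(**d)


#: Bundled profiles matching the therapy-comparison experiment.
NONE = StimulusProtocol(kind="none")
DBS = StimulusProtocol(kind="dbs")
CBBP = StimulusProtocol(kind="cbbp")
CRS_1_0 = StimulusProtocol(kind="crs", crs_m=1, crs_n=0)
CRS_3_2 = StimulusProtocol(kind="crs", crs_m=3, crs_n=2)


def dbs_waveform(t, protocol: StimulusProtocol) -> np.ndarray:
    """Rectangular pulse train: amplitude for the first ``pulse_width``
    seconds of each period, zero otherwise.

    Equivalent to the Heaviside product form
    ``alpha * H[sin(2 pi t / rho)] * (1 - H[sin(2 pi (t + delta) / rho)])``
    for ``delta < rho/2``, and extends it consistently to wider pulses
    (the product form would truncate the pulse at half a period).
    """
    if protocol.kind != "dbs":
        raise ValueError("protocol.kind must be 'dbs'")
    t = np.asarray(t, dtype=float)
    phase = np.mod(t, protocol.period)
    return np.where(phase < protocol.pulse_width, protocol.amplitude, 0.0)


def cbbp_waveform(t, protocol: StimulusProtocol) -> np.ndarray:
    """Biphasic pulse: anodic phase of duration ``pulse_width`` then a
    cathodic phase filling the rest of each period ``T``.

    Two amplitude conventions are supported.  The default literal form uses
    an anodic amplitude numerically equal to ``pulse_width`` and cathodic
    amplitude ``-pulse_width / (T - pulse_width)``; its net charge per
    period is ``delta**2 - delta`` (slightly cathodic), and this is the form
    whose therapeutic effect on the seizure maps matches the reported
    outcomes.  With ``cbbp_literal=False`` the anodic amplitude is
    ``amplitude`` and the cathodic amplitude ``-amplitude * delta /
    (T - delta)``, making the net charge per period exactly zero.
    """
    if protocol.kind != "cbbp":
        raise ValueError("protocol.kind must be 'cbbp'")
    t = np.asarray(t, dtype=float)
    T = protocol.cbbp_period_or_default
    delta = protocol.pulse_width
    if protocol.cbbp_literal:
        anodic = delta
        cathodic = -delta / (T - delta)
    else:
        anodic = protocol.amplitude
        cathodic = -protocol.amplitude * delta / (T - delta)
    phase = np.mod(t, T)
    return np.where(phase < delta, anodic, cathodic)


def crs_gates(t, protocol: StimulusProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Binary gate traces (beta1, beta2) of the m:n coordinated-reset
    schedule evaluated at times ``t``.

    Cycle ``c = floor(t / cycle_length)``; within each super-period of
    ``m + n`` cycles the first ``m`` are ON.  The target of an ON cycle
    alternates with the *global* ON-cycle index (continuing across
    super-periods), TRN1 taking even indices.  The two gates are never
    simultaneously 1.
    """
    if protocol.kind != "crs":
        raise ValueError("protocol.kind must be 'crs'")
    t = np.asarray(t, dtype=float)
    m, n = protocol.crs_m, protocol.crs_n
    cyc = np.floor(t / protocol.crs_cycle_length).astype(np.int64)
    sp = m + n
    pos = cyc % sp
    on = pos < m
    global_on_index = (cyc // sp) * m + np.minimum(pos, m - 1)
    beta1 = (on & (global_on_index % 2 == 0)).astype(float)
    beta2 = (on & (global_on_index % 2 == 1)).astype(float)
    return beta1, beta2


def stimulus_currents(t, protocol: StimulusProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Gated currents (beta1*u, beta2*u) delivered to TRN1 and TRN2.

    DBS and CBBP drive both targets identically; CRS multiplies the pulse
    train by the alternating gates; ``kind='none'`` yields zeros.
    """
    t = np.asarray(t, dtype=float)
    if protocol.kind == "none":
        z = np.zeros_like(t)
        return z, z.copy()
    if protocol.kind == "dbs":
        u = dbs_waveform(t, protocol)
        return u, u.copy()
    if protocol.kind == "cbbp":
        u = cbbp_waveform(t, protocol)
        return u, u.copy()
    # crs: gates applied to the underlying pulse train
    pulse = protocol.replace(kind="dbs")
    u = dbs_waveform(t, pulse)
    beta1, beta2 = crs_gates(t, protocol)
    return beta1 * u, beta2 * u


def rms_current(samples) -> float:
    """Root-mean-square of a sampled current, sqrt(mean(u_k^2))."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("rms_current requires at least one sample")
    return float(np.sqrt(np.mean(np.square(samples))))
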