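"""Two-module thalamocortical neural mass model.

The model couples two copies of a four-population corticothalamic circuit
(pyramidal PY, interneuron IN, specific relay nucleus SRN, thalamic
reticular nucleus TRN).  Each population is described by one mean membrane
potential, giving an eight-dimensional ODE.  Within a module the circuit is
the classic corticothalamic loop; between modules a small number of
long-range projections (scaled by ``1/intermodule_scale``, default 1/6)
connect homologous cortical and thalamic populations in both directions.

State-vector layout (public contract)::

    index  0    1    2     3     4    5    6     7
    field  py1  in1  srn1  trn1  py2  in2  srn2  trn2

Cortical potentials feed through a steep sigmoid activation ``Q``; thalamic
potentials feed through a linear activation ``K``.  The right-hand side of
each equation is a relaxation term multiplied by a per-population rate
constant ``tau`` (units 1/s), plus the unscaled cross-module input, so the
cross-module projections act as weak, slow perturbations of the intra-module
loop.  External stimulation currents enter the two TRN equations only.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Literal

import numpy as np
from scipy.special import expit

__all__ = [
    "STATE_FIELDS",
    "N_POPULATIONS",
    "ModelParameters",
    "activation_sigmoid",
    "activation_linear",
    "rhs",
    "population_state",
]

#: Canonical ordering of the eight mean membrane potentials.
STATE_FIELDS = ("py1", "in1", "srn1", "trn1", "py2", "in2", "srn2", "trn2")
N_POPULATIONS = len(STATE_FIELDS)

# column indices, module I then module II
_PY1, _IN1, _SRN1, _TRN1, _PY2, _IN2, _SRN2, _TRN2 = range(8)

Topology = Literal["bidirectional", "unidirectional", "uncoupled"]


@dataclass
class ModelParameters:
    """Coupling strengths, inputs, rates and topology of the coupled model.

    ``h1..h9`` are the dimensionless synaptic coupling strengths of the
    corticothalamic loop; ``h7`` (PY->TRN) and ``h8`` (SRN->TRN) are the two
    excitatory pathways onto TRN that are swept in the seizure analysis and
    may be scalars or equally-shaped arrays (for vectorised parameter
    sweeps).  ``eps_*`` are the constant background inputs of each
    population and ``tau1..tau4`` the per-population rate constants in 1/s.

    ``intermodule_scale`` divides every cross-module coupling (6 for the
    long-range projections studied here; 3 would model short-range
    coupling).  ``topology`` selects which cross-module projections exist:

    - ``bidirectional``: all six two-way links,
    - ``unidirectional``: one-way links only, with the analysed module I
      as the receiver (module II runs autonomously),
    - ``uncoupled``: two independent modules.

    ``cross_in_tau`` moves the cross-module terms inside the tau-scaled
    relaxation bracket (sensitivity switch, off by default).
    ``stim_in_tau`` applies the TRN stimulation current inside that bracket,
    i.e. the current is scaled by ``tau4`` like the synaptic inputs; this is
    the default operating point of the therapy simulations.
    """

    h1: float = 1.8
    h2: float = 1.5
    h3: float = 1.0
    h4: float = 4.0
    h5: float = 3.0
    h6: float = 0.6
    h7: float | np.ndarray = 2.0
    h8: float | np.ndarray = 10.0
    h9: float = 0.2
    eps_py: float = -0.35
    eps_in: float = -3.4
    eps_srn: float = -2.0
    eps_trn: float = -5.0
    tau1: float = 26.0
    tau2: float = 32.5
    tau3: float = 2.6
    tau4: float = 2.6
    a: float = 2.8
    b: float = 0.5
    eps_sigmoid: float = 250000.0
    intermodule_scale: float = 6.0
    topology: Topology = "bidirectional"
    cross_in_tau: bool = False
    stim_in_tau: bool = True

    def __post_init__(self) -> None:
        for name in ("tau1", "tau2", "tau3", "tau4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.eps_sigmoid <= 1:
            raise ValueError("eps_sigmoid must exceed 1")
        if self.intermodule_scale <= 0:
            raise ValueError("intermodule_scale must be positive")
        if self.topology not in ("bidirectional", "unidirectional", "uncoupled"):
            raise ValueError(f"unknown topology: {self.topology!r}")

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("h7", "h8"):
            if isinstance(d[k], np.ndarray):
                d[k] = d[k].tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)


def activation_sigmoid(x, eps_sigmoid: float = 250000.0):
    """Sigmoid firing-rate activation Q(x) = 1 / (1 + eps^(-x)).

    Strictly increasing, maps the real line into (0, 1) with Q(0) = 1/2.
    ``eps_sigmoid`` sets the steepness; the default makes Q nearly a step.
    """
    if eps_sigmoid <= 1:
        raise ValueError("eps_sigmoid must exceed 1")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("activation_sigmoid requires finite input")
    # eps^(-x) = exp(-x ln eps); expit avoids overflow for large |x|
    return expit(np.log(eps_sigmoid) * x)


def activation_linear(y, a: float = 2.8, b: float = 0.5):
    """Linear firing-rate activation K(y) = a*y + b (no clipping)."""
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("activation_linear requires finite coefficients")
    return a * np.asarray(y, dtype=float) + b


def population_state(py1=0.0, in1=0.0, srn1=0.0, trn1=0.0,
                     py2=0.0, in2=0.0, srn2=0.0, trn2=0.0) -> np.ndarray:
    """Build a state vector in the canonical field order."""
    return np.array([py1, in1, srn1, trn1, py2, in2, srn2, trn2], dtype=float)


def rhs(state: np.ndarray, params: ModelParameters,
        stim_trn1=0.0, stim_trn2=0.0) -> np.ndarray:
    """Time derivative of the eight population potentials.

    ``state`` has shape ``(..., 8)`` with the canonical field layout; the
    computation is vectorised over leading axes so a whole batch of
    parameter-grid cells integrates in one call (``params.h7``/``h8`` may
    then be arrays broadcasting against the leading axes).

    ``stim_trn1``/``stim_trn2`` are the already-gated stimulation currents
    entering the two TRN equations (0 with no active protocol).
    """
    state = np.asarray(state, dtype=float)
    if state.shape[-1] != N_POPULATIONS:
        raise ValueError("state must have 8 components in the last axis")

    q = expit(np.log(params.eps_sigmoid) * state)
    k = params.a * state + params.b
    s = params.intermodule_scale

    if params.topology == "bidirectional":
        c1 = c2 = 1.0
    elif params.topology == "unidirectional":
        c1, c2 = 1.0, 0.0      # one-way link: module I receives, module II is autonomous
    else:                      # uncoupled
        c1 = c2 = 0.0

    p = params
    py1, in1, srn1, trn1 = state[..., _PY1], state[..., _IN1], state[..., _SRN1], state[..., _TRN1]
    py2, in2, srn2, trn2 = state[..., _PY2], state[..., _IN2], state[..., _SRN2], state[..., _TRN2]

    # intra-module relaxation brackets
    b_py1 = p.eps_py - py1 + p.h1 * q[..., _PY1] - p.h2 * q[..., _IN1] + p.h3 * q[..., _SRN1]
    b_py2 = p.eps_py - py2 + p.h1 * q[..., _PY2] - p.h2 * q[..., _IN2] + p.h3 * q[..., _SRN2]
    b_in1 = p.eps_in - in1 + p.h4 * q[..., _PY1]
    b_in2 = p.eps_in - in2 + p.h4 * q[..., _PY2]
    b_srn1 = p.eps_srn - srn1 + p.h5 * q[..., _PY1] - p.h6 * k[..., _TRN1]
    b_srn2 = p.eps_srn - srn2 + p.h5 * q[..., _PY2] - p.h6 * k[..., _TRN2]
    b_trn1 = p.eps_trn - trn1 + p.h7 * q[..., _PY1] + p.h8 * k[..., _SRN1] - p.h9 * k[..., _TRN1]
    b_trn2 = p.eps_trn - trn2 + p.h7 * q[..., _PY2] + p.h8 * k[..., _SRN2] - p.h9 * k[..., _TRN2]

    # cross-module inputs (module receiving <- module sending)
    x_py1 = c1 * ((p.h1 / s) * q[..., _PY2] - (p.h2 / s) * q[..., _IN2])
    x_py2 = c2 * ((p.h1 / s) * q[..., _PY1] - (p.h2 / s) * q[..., _IN1])
    x_in1 = c1 * (p.h4 / s) * q[..., _PY2]
    x_in2 = c2 * (p.h4 / s) * q[..., _PY1]
    x_srn1 = c1 * (-(p.h6 / s) * k[..., _TRN2])
    x_srn2 = c2 * (-(p.h6 / s) * k[..., _TRN1])
    x_trn1 = c1 * ((p.h8 / s) * k[..., _SRN2] - (p.h9 / s) * k[..., _TRN2])
    x_trn2 = c2 * ((p.h8 / s) * k[..., _SRN1] - (p.h9 / s) * k[..., _TRN1])

    u1 = np.asarray(stim_trn1, dtype=float)
    u2 = np.asarray(stim_trn2, dtype=float)
    if p.stim_in_tau:
        b_trn1 = b_trn1 + u1
        b_trn2 = b_trn2 + u2
        u1 = u2 = 0.0

    d = np.empty_like(state)
    if p.cross_in_tau:
        d[..., _PY1] = p.tau1 * (b_py1 + x_py1)
        d[..., _PY2] = p.tau1 * (b_py2 + x_py2)
        d[..., _IN1] = p.tau2 * (b_in1 + x_in1)
        d[..., _IN2] = p.tau2 * (b_in2 + x_in2)
        d[..., _SRN1] = p.tau3 * (b_srn1 + x_srn1)
        d[..., _SRN2] = p.tau3 * (b_srn2 + x_srn2)
        d[..., _TRN1] = p.tau4 * (b_trn1 + x_trn1) + u1
        d[..., _TRN2] = p.tau4 * (b_trn2 + x_trn2) + u2
    else:
        d[..., _PY1] = p.tau1 * b_py1 + x_py1
        d[..., _PY2] = p.tau1 * b_py2 + x_py2
        d[..., _IN1] = p.tau2 * b_in1 + x_in1
        d[..., _IN2] = p.tau2 * b_in2 + x_in2
        d[..., _SRN1] = p.tau3 * b_srn1 + x_srn1
        d[..., _SRN2] = p.tau3 * b_srn2 + x_srn2
        d[..., _TRN1] = p.tau4 * b_trn1 + x_trn1 + u1
        d[..., _TRN2] = p.tau4 * b_trn2 + x_trn2 + u2
    return d
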