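"""Steady state of the classical Bloch equations for the electron spin.

Under continuous microwave irradiation at offset Omega = omega_S - omega
from the electronic resonance, the steady-state transverse and longitudinal
electronic magnetizations are captured by three line-shape factors (units
of time)

    fy = R2S / (R2S^2 + Omega^2)        (absorptive)
    fx = (Omega / R2S) * fy             (dispersive)
    fz = 1 / (R1S + omega_1^2 * fy)

from which the electronic polarization factor p = R1S * fz in (0, 1], the
saturation factor s = 1 - p, and the rate of the allowed EPR transition
v1 = omega_1^2 fy / 2 follow.  The steady-state ratios are
sx/sz_eq = p*omega_1*fx and sy/sz_eq = -p*omega_1*fy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import SpinParams

__all__ = ["BlochSteadyState", "bloch_steady_state", "saturation_at_omega_half"]


@dataclass
class BlochSteadyState:
    """Steady-state factors of the classical Bloch equations.

    All fields are scalars or arrays matching the offset grid:
    ``fy``/``fx``/``fz`` in ns, polarization factor ``p`` and saturation
    ``sat = 1 - p`` dimensionless, allowed-transition rate ``v1`` in 1/ns.
    """

    fy: np.ndarray
    fx: np.ndarray
    fz: np.ndarray
    p: np.ndarray
    sat: np.ndarray
    v1: np.ndarray


def bloch_steady_state(params: SpinParams, Omega) -> BlochSteadyState:
    """Evaluate the Bloch steady state at offset(s) Omega (rad/ns).

    The degenerate point Omega = omega_1 = 0 is handled analytically
    (fx = 0, p = 1); fy and fz stay finite because R1S, R2S > 0.
    """
    Omega = np.asarray(Omega, dtype=float)
    R1S, R2S, w1 = params.R1S, params.R2S, params.omega_1
    fy = R2S / (R2S**2 + Omega**2)
    fx = (Omega / R2S) * fy
    fz = 1.0 / (R1S + w1**2 * fy)
    p = R1S * fz
    v1 = 0.5 * w1**2 * fy
    return BlochSteadyState(fy=fy, fx=fx, fz=fz, p=p, sat=1.0 - p, v1=v1)


def saturation_at_omega_half(params: SpinParams) -> float:
    """Saturation factor at the dispersive extrema Omega_1/2 = omega_1 sqrt(T1S/T2S).

    In the saturating regime omega_1 >> sqrt(R1S R2S) the result is 1/2 up
    to corrections of order (R1S R2S)/omega_1^2; a soft warning is emitted
    when that regime does not hold.
    """
    R1S, R2S, w1 = params.R1S, params.R2S, params.omega_1
    if w1 < 10.0 * np.sqrt(R1S * R2S):
        warnings.warn(
            "omega_1 is not large compared to sqrt(R1S*R2S); the saturation "
            "factor at Omega_1/2 will deviate from 1/2",
            stacklevel=2,
        )
    omega_half = w1 * np.sqrt(params.T1S / params.T2S)
    return float(bloch_steady_state(params, omega_half).sat)
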