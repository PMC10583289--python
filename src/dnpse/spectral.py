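"""Normalized Laplace-domain dipolar spectral densities j(s).

The dipolar autocorrelation function C(t) of the m=1 secular component of
the electron-nucleus dipolar coupling is normalized here to C(0) = 1, so
that every rate formula in the package reads ``<delta^2> * j(...)`` with

    j(s) = integral_0^inf exp(-s t) C(t) dt.

Three motional models are supported:

``solid``
    The coupling does not fluctuate, C(t) = 1, j(s) = 1/s.
``exponential``
    Mono-exponential decay with correlation time tau, j(s) = 1/(s + 1/tau).
``ffhs``
    Force-free hard spheres: translational diffusion of two spherical
    molecules carrying the spins at their centers, with contact distance b
    and relative diffusion coefficient D.  The single timescale is
    tau = b^2/D and, with x = s*tau,

        j(s) = tau * (sqrt(x) + 4) / (x^(3/2) + 4 x + 9 sqrt(x) + 9).

All j are evaluated for complex s with positive real part (the arguments
arising in practice are eigenvalues of a relaxation matrix, which have
positive real parts); square roots use the principal branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "SpectralDensity",
    "j_solid",
    "j_exponential",
    "j_ffhs",
    "tau_from_diffusion",
    "diffusion_from_tau",
]

MODELS = ("solid", "exponential", "ffhs")


def _check_halfplane(s) -> np.ndarray:
    s = np.asarray(s, dtype=complex)
    if not np.all(s.real > 0):
        raise ValueError("spectral densities require Re(s) > 0")
    return s


def j_solid(s):
    """Static-coupling limit: j(s) = 1/s (units of time for s a rate)."""
    s = _check_halfplane(s)
    out = 1.0 / s
    return out if out.shape else complex(out)


def j_exponential(s, tau: float):
    """Mono-exponential correlation decay: j(s) = 1/(s + 1/tau)."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    s = _check_halfplane(s)
    out = 1.0 / (s + 1.0 / tau)
    return out if out.shape else complex(out)


def j_ffhs(s, tau: float):
    """Force-free hard-sphere spectral density (principal branch).

    Limits: j -> (4/9) tau as s*tau -> 0, and j -> 1/s as s*tau -> inf,
    recovering the solid model for slow diffusion.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    s = _check_halfplane(s)
    x = s * tau
    rx = np.sqrt(x)  # principal branch; Re(x) > 0 keeps us off the cut
    out = tau * (rx + 4.0) / (x * rx + 4.0 * x + 9.0 * rx + 9.0)
    return out if out.shape else complex(out)


def tau_from_diffusion(b: float, D: float) -> float:
    """Characteristic diffusive timescale tau = b^2/D (ns) of the FFHS model.

    b in nm, D in nm^2/ns.
    """
    if b <= 0 or D <= 0:
        raise ValueError(f"b and D must be positive, got b={b}, D={D}")
    return b**2 / D


def diffusion_from_tau(b: float, tau: float) -> float:
    """Relative diffusion coefficient D = b^2/tau (nm^2/ns); inverse of
    :func:`tau_from_diffusion`."""
    if b <= 0 or tau <= 0:
        raise ValueError(f"b and tau must be positive, got b={b}, tau={tau}")
    return b**2 / tau


@dataclass
class SpectralDensity:
    """A motional model with its correlation time.

    Parameters
    ----------
    model : one of ``{"solid", "exponential", "ffhs"}``.
    tau : correlation time in ns; required for the motional models and
        absent (None) for ``solid``.
    """

    model: str
    tau: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown motional model {self.model!r}; choose from {MODELS}")
        if self.model == "solid":
            if self.tau is not None:
                raise ValueError("the solid model has no correlation time")
        else:
            if self.tau is None or self.tau <= 0:
                raise ValueError(f"model {self.model!r} requires tau > 0, got {self.tau}")

    @property
    def is_motional(self) -> bool:
        return self.model != "solid"

    def j(self, s):
        """Evaluate the normalized spectral density at complex rate(s) s."""
        if self.model == "solid":
            return j_solid(s)
        if self.model == "exponential":
            return j_exponential(s, self.tau)
        return j_ffhs(s, self.tau)
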