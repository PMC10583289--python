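"""Physical constants, unit conventions, and the dipolar interaction strength.

Internal unit system
--------------------
All times are in nanoseconds (ns) and all angular frequencies in rad/ns,
throughout the package.  Every timescale relevant to the solid effect in
viscous liquids -- electronic relaxation (tens of ns to tens of us),
diffusive correlation times (ns), nuclear relaxation (ms) -- is then
representable without under/overflow, and rates and frequencies can be
mixed freely.  Conversions to laboratory units (MHz, Gauss, ms, m^2/s)
happen only at I/O boundaries.

Constants are pinned to CODATA-2018 values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CONSTANTS",
    "GAMMA_S",
    "GAMMA_I_H",
    "GAMMA_RATIO_H",
    "D_DIP",
    "SpinParams",
    "DipolarSpec",
    "b1_to_omega1",
    "dipolar_strength",
    "mhz_to_rad_per_ns",
    "rad_per_ns_to_mhz",
]

#: Free-electron gyromagnetic ratio magnitude, rad s^-1 T^-1 (g = 2.0023...).
GAMMA_S = 1.76085963023e11
#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_I_H = 2.6752218744e8
#: |gamma_S| / gamma_I for the electron-proton pair.
GAMMA_RATIO_H = GAMMA_S / GAMMA_I_H  # ~658.211

_HBAR = 1.054571817e-34  # J s
_MU0_OVER_4PI = 1.0e-7  # T^2 m^3 / J
_N_AVOGADRO = 6.02214076e23  # mol^-1

#: Dipolar coupling prefactor (mu0/4pi) hbar gamma_S gamma_I in rad nm^3 / ns.
#: The 1e18 factor converts m^3/s to nm^3/ns.
D_DIP = _MU0_OVER_4PI * _HBAR * GAMMA_S * GAMMA_I_H * 1e18

#: Exported constants table (SI values, documented to 6 significant figures).
CONSTANTS = {
    "gamma_S_rad_per_s_T": GAMMA_S,
    "gamma_I_H_rad_per_s_T": GAMMA_I_H,
    "gamma_ratio_electron_proton": GAMMA_RATIO_H,
    "hbar_J_s": _HBAR,
    "mu0_over_4pi_T2_m3_per_J": _MU0_OVER_4PI,
    "avogadro_per_mol": _N_AVOGADRO,
    "D_dip_rad_nm3_per_ns": D_DIP,
}


def mhz_to_rad_per_ns(nu_mhz):
    """Convert an ordinary frequency in MHz to an angular frequency in rad/ns."""
    return 2.0 * np.pi * np.asarray(nu_mhz, dtype=float) * 1e-3


def rad_per_ns_to_mhz(omega):
    """Convert an angular frequency in rad/ns to an ordinary frequency in MHz."""
    return np.asarray(omega, dtype=float) / (2.0 * np.pi) * 1e3


def b1_to_omega1(B1: float) -> float:
    """Microwave nutation frequency omega_1 (rad/ns) from the field B1 (Gauss).

    Uses the free-electron gyromagnetic ratio (g = 2), so
    ``omega_1 = |gamma_S| * B1``; 6 G corresponds to omega_1/2pi ~ 16.8 MHz.
    """
    if B1 < 0:
        raise ValueError(f"B1 must be non-negative, got {B1}")
    # gamma_S in rad/(s G) is GAMMA_S*1e-4; times 1e-9 to land in rad/ns
    return GAMMA_S * 1e-13 * B1


def dipolar_strength(N: float, b: float) -> float:
    """Ensemble-averaged squared dipolar coupling <delta^2> in rad^2/ns^2.

    Parameters
    ----------
    N : radical concentration in mol/L.
    b : contact distance (distance of closest approach) in nm.

    Returns the static average over all electron-nucleus pairs,
    ``<delta^2> = D_dip^2 * (6 pi / 5) * N' / (3 b^3)`` with ``N'`` the
    radical number density in nm^-3.  This is the value reached in the
    solid-state limit with fast, efficient spin diffusion; its square root
    over 2 pi is ~22 kHz at N = 0.1 M, b = 1 nm.
    """
    if b <= 0:
        raise ValueError(f"contact distance b must be positive, got {b}")
    if N < 0:
        raise ValueError(f"concentration N must be non-negative, got {N}")
    number_density = N * _N_AVOGADRO * 1e-24  # nm^-3 (1 L = 1e24 nm^3)
    return D_DIP**2 * (6.0 * np.pi / 5.0) * number_density / (3.0 * b**3)


@dataclass
class SpinParams:
    """Spin-system parameters of one electron-nucleus pair.

    Attributes
    ----------
    T1S, T2S : electronic longitudinal / transverse relaxation times (ns).
    T1I : nuclear longitudinal relaxation time (ns).
    omega_I : nuclear Larmor angular frequency (rad/ns), positive.
    omega_1 : microwave nutation angular frequency (rad/ns), >= 0.
    gamma_ratio : |gamma_S|/gamma_I; defaults to the electron-proton value.
    """

    T1S: float
    T2S: float
    T1I: float
    omega_I: float
    omega_1: float
    gamma_ratio: float = GAMMA_RATIO_H

    def __post_init__(self) -> None:
        for name in ("T1S", "T2S", "T1I"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.omega_I <= 0:
            raise ValueError(f"omega_I must be positive, got {self.omega_I}")
        if self.omega_1 < 0:
            raise ValueError(f"omega_1 must be non-negative, got {self.omega_1}")
        if self.T1S < self.T2S / 2.0:
            warnings.warn(
                f"T1S={self.T1S} ns < T2S/2={self.T2S / 2.0} ns violates the "
                "physicality bound T1S >= T2S/2",
                stacklevel=2,
            )

    @property
    def R1S(self) -> float:
        return 1.0 / self.T1S

    @property
    def R2S(self) -> float:
        return 1.0 / self.T2S

    @property
    def R1I(self) -> float:
        return 1.0 / self.T1I


@dataclass
class DipolarSpec:
    """Radical concentration, contact distance, and the derived <delta^2>.

    ``delta2`` (rad^2/ns^2) is computed from N (mol/L) and b (nm) unless
    given explicitly; it scales linearly in N and as b^-3.
    """

    N: float
    b: float
    delta2: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.delta2 is None:
            self.delta2 = dipolar_strength(self.N, self.b)
        if self.delta2 < 0:
            raise ValueError(f"delta2 must be non-negative, got {self.delta2}")
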