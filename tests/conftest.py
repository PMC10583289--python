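import numpy as np
import pytest

from dnpse import FitConfig, SpinParams, b1_to_omega1, mhz_to_rad_per_ns

#: J-band fit ratios of the lipid-bilayer BDPA profile (FFHS model, B1=6 G)
ROW1 = (7.2, 30.4, 8.9)


@pytest.fixture(scope="session")
def j_band_config() -> FitConfig:
    """Fixed J-band experimental block: T2S=215 ns, T1I=50 ms, B1=6 G,
    proton Larmor frequency 400 MHz."""
    return FitConfig(T2S=215.0, T1I=50e6, B1=6.0, omega_I=mhz_to_rad_per_ns(400.0))


@pytest.fixture(scope="session")
def narrow_line_params() -> SpinParams:
    """Power-broadened narrow-line radical at X band: T2S=60 ns, T1S=9*T2S,
    B1=6 G, omega_I/2pi = 15 MHz."""
    return SpinParams(
        T1S=540.0,
        T2S=60.0,
        T1I=4.7e6,
        omega_I=mhz_to_rad_per_ns(15.0),
        omega_1=b1_to_omega1(6.0),
    )


def complex_transfer_scale(params: SpinParams, Omega) -> np.ndarray:
    """Magnitude scale of the complex transfer functions behind Ti/Tx/v+-.

    The public rates are real parts of strongly cancelling complex
    quantities, so agreement "to 1e-10 relative" is meaningful relative to
    |Fz|, |1/(R1S + i wI)| and |Fz * omega_1 * Fy'|, not to the (possibly
    vanishing) real parts themselves.
    """
    Omega = np.asarray(Omega, dtype=float)
    R1S, R2S, w1, wI = params.R1S, params.R2S, params.omega_1, params.omega_I
    q = R2S + 1j * wI
    Fy = q / (q**2 + Omega**2)
    Fz = 1.0 / (R1S + 1j * wI + w1**2 * Fy)
    Fyp = (2.0 * R2S + 1j * wI) / q * Fy
    return np.abs(Fz) * (1.0 + w1 * np.abs(Fyp)) + abs(1.0 / (R1S + 1j * wI))


def random_spin_params(rng: np.random.Generator) -> SpinParams:
    """Draw physically plausible spin parameters for randomized sweeps."""
    T2S = rng.uniform(10.0, 500.0)
    return SpinParams(
        T1S=T2S * rng.uniform(1.0, 50.0),
        T2S=T2S,
        T1I=rng.uniform(1e6, 1e8),
        omega_I=rng.uniform(0.05, 3.0),
        omega_1=rng.uniform(0.0, 0.3),
    )
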