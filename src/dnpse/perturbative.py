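"""Tilted-frame perturbative approximation to the eigenvalue problem.

When the electronic longitudinal and transverse relaxation rates are
equal, the generalized Bloch matrix B differs from a skew-symmetric (plus
scalar) matrix only by the uniform relaxation on its diagonal, and its
eigenvectors are those of the rotation about the effective microwave field
in the rotating frame.  With

    omega_eff = sqrt(Omega^2 + omega_1^2),
    cos(alpha) = Omega/omega_eff = c,   sin(alpha) = omega_1/omega_eff = s,

the unitary eigenvector matrix is

    U0 = [[ s, -c/sqrt(2), -c/sqrt(2)],
          [ 0,  i/sqrt(2), -i/sqrt(2)],
          [ c,  s/sqrt(2),  s/sqrt(2)]],

whose columns correspond to the eigenvalues R2S + i*wI (shifted by 0) and
R2S + i*(wI -/+ omega_eff).  Treating the difference R1S - R2S as a
first-order perturbation corrects only the eigenvalues:

    lambda~_0 = R1~ + i wI,       R1~ = R1S c^2 + R2S s^2,
    lambda~_-/+ = R2~ + i (wI -/+ omega_eff),
                                  R2~ = R2S (1 - s^2/2) + R1S s^2/2,

while keeping the unperturbed eigenvectors.  The approximate rates use
M~ = U0 diag(j(lambda~_n)) U0^H in place of the exact U diag(j(lambda))
U^-1; for a motional model this replaces each resonance width R2S by
R2S + (decay rate of the correlation), e.g. R2S + 1/tau for the
mono-exponential model.  The approximation is exact for T1S = T2S and its
error grows with T1S/T2S; it is reliable for the pumping rate v- but fails
for v+ at small offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bloch import BlochSteadyState
from .constants import SpinParams
from .rates import RateSet, _extract_rates
from .spectral import SpectralDensity

__all__ = ["TiltedFrame", "tilted_frame", "approx_rates", "omega_half"]


@dataclass
class TiltedFrame:
    """Tilted-frame quantities; array fields are stacked over offsets.

    ``U0`` has shape (..., 3, 3) with columns ordered (lambda~_0,
    lambda~_-, lambda~_+); ``lambda_tilde`` has shape (..., 3) in the same
    order.  ``R1_tilde``/``R2_tilde`` are the corrected relaxation rates.
    """

    omega_eff: np.ndarray
    alpha: np.ndarray
    c: np.ndarray
    s_: np.ndarray
    U0: np.ndarray
    lambda_tilde: np.ndarray
    R1_tilde: np.ndarray
    R2_tilde: np.ndarray


def tilted_frame(params: SpinParams, Omega) -> TiltedFrame:
    """Construct the tilted frame at offset(s) Omega (rad/ns).

    Raises if Omega and omega_1 are both zero anywhere (undefined tilt).
    """
    Omega = np.atleast_1d(np.asarray(Omega, dtype=float))
    R1S, R2S, w1, wI = params.R1S, params.R2S, params.omega_1, params.omega_I
    weff = np.sqrt(Omega**2 + w1**2)
    if np.any(weff == 0.0):
        raise ValueError("tilt angle undefined: Omega and omega_1 both zero")
    c = Omega / weff
    s = w1 / weff
    alpha = np.arctan2(s, c)
    n = Omega.shape[0]
    U0 = np.zeros((n, 3, 3), dtype=complex)
    rt2 = np.sqrt(2.0)
    U0[:, 0, 0] = s
    U0[:, 0, 1] = -c / rt2
    U0[:, 0, 2] = -c / rt2
    U0[:, 1, 1] = 1j / rt2
    U0[:, 1, 2] = -1j / rt2
    U0[:, 2, 0] = c
    U0[:, 2, 1] = s / rt2
    U0[:, 2, 2] = s / rt2
    R1t = R1S * c**2 + R2S * s**2
    R2t = R2S * (1.0 - s**2 / 2.0) + R1S * s**2 / 2.0
    lam = np.empty((n, 3), dtype=complex)
    lam[:, 0] = R1t + 1j * wI
    lam[:, 1] = R2t + 1j * (wI - weff)
    lam[:, 2] = R2t + 1j * (wI + weff)
    return TiltedFrame(
        omega_eff=weff, alpha=alpha, c=c, s_=s, U0=U0,
        lambda_tilde=lam, R1_tilde=R1t, R2_tilde=R2t,
    )


def approx_rates(
    frame: TiltedFrame,
    params: SpinParams,
    sd: SpectralDensity,
    delta2: float,
    bloch: BlochSteadyState,
    Omega=None,
) -> RateSet:
    """First-order perturbative rate set from M~ = U0 diag(j(lambda~)) U0^H.

    The extraction of v+/-, Ti, Tx from M~ is identical to the exact path,
    so the result coincides with :func:`dnpse.rates.forbidden_rates` when
    T1S = T2S (the perturbation vanishes) for every spectral density.
    """
    R1S, R2S, w1, wI = params.R1S, params.R2S, params.omega_1, params.omega_I
    if Omega is None:
        # recover the offsets from the tilt: |Omega| = c * omega_eff
        Omega = frame.c * frame.omega_eff

    def m_builder(om: np.ndarray) -> np.ndarray:
        if om is Omega:
            fr = frame
        else:
            fr = tilted_frame(params, om)
        jlam = sd.j(fr.lambda_tilde)
        U0H = np.conjugate(np.swapaxes(fr.U0, -1, -2))
        return fr.U0 @ (jlam[..., :, None] * U0H)

    return _extract_rates(m_builder, R1S, R2S, w1, wI, sd, delta2, bloch, Omega)


def omega_half(params: SpinParams) -> float:
    """Offset of the dispersive-line extrema, Omega_1/2 = omega_1 sqrt(T1S/T2S).

    At saturating microwave power these are also the offsets where the
    electronic saturation factor equals one half; they set the position of
    the non-canonical enhancement peaks.
    """
    return params.omega_1 * np.sqrt(params.T1S / params.T2S)
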