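"""Forbidden-transition rates from the generalized Bloch matrix.

The microwave-driven electron-nucleus flip-flop ("forbidden") transitions
are governed by the electron-nucleus coherences, whose steady state is
controlled by the 3x3 generalized Bloch matrix

    B = [[R2S + i wI,  Omega,      0      ],
         [-Omega,      R2S + i wI, omega_1],
         [0,           -omega_1,   R1S + i wI]],

i.e. the classical Bloch matrix with the nuclear Larmor frequency wI added
along the diagonal.  For an arbitrary motional model with normalized
spectral density j(s), the stationary analysis reduces to the matrix

    M = U diag(j(lambda_n)) U^-1,

where B = U diag(lambda_n) U^-1.  From M one reads off (per offset):

    Ti   = Re M33                      (flip-flop transfer time)
    Ti0  = Re j(R1S + i wI)            (microwave-independent part of Ti;
                                        <delta^2>*Ti0 is the dipolar
                                        contribution R1I^A to nuclear T1)
    v+   = <delta^2> (Ti - Ti0)
    v-   = <delta^2> Re{ i (M31 w1 fy + M32 w1 fx) }
    Tx   = v- / (<delta^2> w1 fx)      (so that p v- = <delta^2> p w1 fx Tx)

In the solid limit j(s) = 1/s, M = B^-1 and everything collapses to the
closed forms implemented in :func:`solid_closed_form`, which serves as an
independent check on the eigenvalue path.

For motional models v+ can become negative at offsets beyond the nuclear
Larmor frequency (prominently at low field); this is physical behavior of
the model, not an error, and leads to a nuclear cross-polarization factor
exceeding one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bloch import BlochSteadyState
from .constants import SpinParams
from .spectral import SpectralDensity

__all__ = [
    "GeneralizedBlochMatrix",
    "RateSet",
    "build_B",
    "forbidden_rates",
    "solid_closed_form",
]

_RECONSTRUCTION_RTOL = 1e-9
_DEGENERACY_NUDGE = 1e-9  # relative offset perturbation for defective B


@dataclass
class GeneralizedBlochMatrix:
    """Eigendecomposition of the generalized Bloch matrix.

    Fields are stacked over the offset grid: ``B``, ``U``, ``Uinv`` have
    shape (..., 3, 3) and ``eigenvalues`` shape (..., 3).  All eigenvalues
    have positive real part for physical relaxation rates.
    """

    B: np.ndarray
    eigenvalues: np.ndarray
    U: np.ndarray
    Uinv: np.ndarray


def _b_stack(R1S, R2S, w1, wI, Omega: np.ndarray) -> np.ndarray:
    n = Omega.shape[0]
    B = np.zeros((n, 3, 3), dtype=complex)
    B[:, 0, 0] = R2S + 1j * wI
    B[:, 0, 1] = Omega
    B[:, 1, 0] = -Omega
    B[:, 1, 1] = R2S + 1j * wI
    B[:, 1, 2] = w1
    B[:, 2, 1] = -w1
    B[:, 2, 2] = R1S + 1j * wI
    return B


def _reconstructs(B, lam, U, Uinv) -> bool:
    rec = U @ (lam[..., :, None] * Uinv)
    err = np.linalg.norm(rec - B, axis=(-2, -1))
    return bool(np.all(err <= _RECONSTRUCTION_RTOL * np.linalg.norm(B, axis=(-2, -1))))


def build_B(params: SpinParams, Omega) -> GeneralizedBlochMatrix:
    """Build and eigendecompose B at offset(s) Omega (rad/ns).

    Near-defective matrices (possible only at isolated parameter points)
    are handled by nudging the offset by one part in 1e9 and recomputing;
    a warning is emitted.  The decomposition is verified by reconstructing
    B from U diag(lambda) U^-1.
    """
    Omega = np.atleast_1d(np.asarray(Omega, dtype=float))
    R1S, R2S, w1, wI = params.R1S, params.R2S, params.omega_1, params.omega_I
    B = _b_stack(R1S, R2S, w1, wI, Omega)
    lam, U = np.linalg.eig(B)
    try:
        Uinv = np.linalg.inv(U)
    except np.linalg.LinAlgError:
        Uinv = None
    if Uinv is None or not _reconstructs(B, lam, U, Uinv):
        warnings.warn(
            "near-degenerate generalized Bloch matrix; nudging the offset "
            f"by 1 part in {1 / _DEGENERACY_NUDGE:g}",
            stacklevel=2,
        )
        scale = np.where(Omega == 0.0, w1 + R2S, np.abs(Omega))
        B = _b_stack(R1S, R2S, w1, wI, Omega + _DEGENERACY_NUDGE * scale)
        lam, U = np.linalg.eig(B)
        Uinv = np.linalg.inv(U)
    if not np.all(lam.real > 0):
        raise ValueError("eigenvalues of B must have positive real parts")
    return GeneralizedBlochMatrix(B=B, eigenvalues=lam, U=U, Uinv=Uinv)


@dataclass
class RateSet:
    """Per-offset forbidden-transition rates and transfer times.

    ``v_plus``/``v_minus`` in rad/ns, ``Ti``/``Ti0``/``Tx``/``Ts`` in ns,
    ``R1IA = <delta^2>*Ti0`` the dipolar contribution to the nuclear
    longitudinal relaxation rate (1/ns).  ``Ts = p * omega_1 * fx * Tx`` so
    that the pumping term of the nuclear rate equation is
    ``p * v_minus = <delta^2> * Ts``.
    """

    v_plus: np.ndarray
    v_minus: np.ndarray
    Ti: np.ndarray
    Ti0: np.ndarray
    Tx: np.ndarray
    Ts: np.ndarray
    R1IA: np.ndarray


def _extract_rates(m_builder, R1S, R2S, w1, wI, sd, delta2, bloch, Omega) -> RateSet:
    """Extract the rate set given a callable Omega-array -> stacked M.

    ``Tx`` lumps the absorptive (fy) pathway onto the dispersive one via
    fy/fx = R2S/Omega; the 0/0 at Omega = 0 is resolved by continuity,
    re-evaluating M at a relatively tiny offset.
    """
    Omega = np.atleast_1d(np.asarray(Omega, dtype=float))
    M = m_builder(Omega)
    Ti = M[..., 2, 2].real
    Ti0 = complex(sd.j(complex(R1S, wI))).real
    v_plus = delta2 * (Ti - Ti0)
    fy = np.atleast_1d(np.asarray(bloch.fy, dtype=float))
    fx = np.atleast_1d(np.asarray(bloch.fx, dtype=float))
    p = np.atleast_1d(np.asarray(bloch.p, dtype=float))
    v_minus = delta2 * (1j * (M[..., 2, 0] * w1 * fy + M[..., 2, 1] * w1 * fx)).real
    with np.errstate(divide="ignore", invalid="ignore"):
        Tx = (1j * ((R2S / Omega) * M[..., 2, 0] + M[..., 2, 1])).real
    zero = Omega == 0.0
    if np.any(zero):
        eps = _DEGENERACY_NUDGE * (R2S + w1 + wI)
        Mz = m_builder(np.full(int(np.count_nonzero(zero)), eps))
        Tx[zero] = (1j * ((R2S / eps) * Mz[..., 2, 0] + Mz[..., 2, 1])).real
    Ts = p * w1 * fx * Tx
    shape = Ti.shape
    return RateSet(
        v_plus=v_plus,
        v_minus=v_minus,
        Ti=Ti,
        Ti0=np.full(shape, Ti0),
        Tx=Tx,
        Ts=Ts,
        R1IA=np.full(shape, delta2 * Ti0),
    )


def forbidden_rates(
    gbm: GeneralizedBlochMatrix,
    sd: SpectralDensity,
    delta2: float,
    bloch: BlochSteadyState,
) -> RateSet:
    """Exact forbidden-transition rates for an arbitrary spectral density.

    Parameters
    ----------
    gbm : eigendecomposition from :func:`build_B`.
    sd : motional model providing the normalized spectral density j(s).
    delta2 : <delta^2> in rad^2/ns^2.
    bloch : classical Bloch steady state at the same offsets.
    """
    B0 = gbm.B.reshape(-1, 3, 3)[0]
    R2S, wI = B0[0, 0].real, B0[0, 0].imag
    R1S, w1 = B0[2, 2].real, B0[1, 2].real
    Omega = gbm.B[..., 0, 1].real

    def m_builder(om: np.ndarray) -> np.ndarray:
        if om is Omega:
            lam, U, Uinv = gbm.eigenvalues, gbm.U, gbm.Uinv
        else:
            B = _b_stack(R1S, R2S, w1, wI, om)
            lam, U = np.linalg.eig(B)
            Uinv = np.linalg.inv(U)
        jlam = sd.j(lam)
        return U @ (jlam[..., :, None] * Uinv)

    return _extract_rates(m_builder, R1S, R2S, w1, wI, sd, delta2, bloch, Omega)


def solid_closed_form(
    params: SpinParams, Omega, delta2: float, bloch: BlochSteadyState
) -> RateSet:
    """Closed-form rate set in the solid (static-coupling) limit.

    Uses the complex line-shape functions

        Fy  = (R2S + i wI) / ((R2S + i wI)^2 + Omega^2)
        Fx  = Omega / (R2S + i wI) * Fy
        Fz  = 1 / (R1S + i wI + omega_1^2 Fy)
        Fy' = (2 R2S + i wI) / (R2S + i wI) * Fy

    with Ti = Re Fz, Ti0 = Re (R1S + i wI)^-1, Tx = Re{i Fz omega_1 Fy'}.
    Agrees with :func:`forbidden_rates` using the solid spectral density to
    numerical precision (the two are mutual oracles in the test suite).
    """
    Omega = np.asarray(Omega, dtype=float)
    R1S, R2S, w1, wI = params.R1S, params.R2S, params.omega_1, params.omega_I
    q = R2S + 1j * wI
    Fy = q / (q**2 + Omega**2)
    Fz = 1.0 / (R1S + 1j * wI + w1**2 * Fy)
    Fyp = (2.0 * R2S + 1j * wI) / q * Fy
    Ti = np.asarray(Fz.real, dtype=float)
    Ti0 = (1.0 / (R1S + 1j * wI)).real
    Tx = (1j * Fz * w1 * Fyp).real
    v_minus = delta2 * w1 * bloch.fx * Tx
    Ts = bloch.p * w1 * bloch.fx * Tx
    return RateSet(
        v_plus=delta2 * (Ti - Ti0),
        v_minus=v_minus,
        Ti=Ti,
        Ti0=np.full(Ti.shape, Ti0),
        Tx=Tx,
        Ts=Ts,
        R1IA=np.full(Ti.shape, delta2 * Ti0),
    )
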