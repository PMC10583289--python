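"""Least-squares extraction of motional and relaxation parameters from a
DNP field profile.

The electronic T2S, the nuclear T1I, the microwave field B1 and the
nuclear Larmor frequency are taken from experiment and held fixed.  Three
dimensionless ratios are fitted:

    r1 = T1S / T2S        (>= 1; sets the dispersive extrema Omega_1/2)
    r2 = T2S / tau        (>= 1; sets the width of the solid-effect lines)
    r3 = (N / 3 b^3) / (N_ref / 3 b_ref^3)   (> 0; global amplitude scale)

with reference values N_ref = 0.1 M and b_ref = 1 nm.  The forward model
is evaluated with the exact eigenvalue path by default.  The fit minimizes
the unweighted sum of squared residuals over (log r1, log r2, log r3); a
deterministic multistart over a coarse logarithmic grid guards against the
local minima that trade line width against tail amplitude.

From the fitted ratios: T1S = r1*T2S, tau = T2S/r2, the contact distance
b = b_ref * (r3 * N_ref / N)^(-1/3) for an assumed radical concentration
N, and the relative diffusion coefficient D = b^2/tau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import (
    GAMMA_RATIO_H,
    DipolarSpec,
    SpinParams,
    b1_to_omega1,
    dipolar_strength,
    mhz_to_rad_per_ns,
)
from .profile import ProfileResult, enhancement_profile
from .spectral import SpectralDensity

__all__ = ["FitConfig", "FitResult", "model_profile", "fit_profile", "derived_quantities"]


class FitError(RuntimeError):
    """Raised when no optimizer start converges."""


@dataclass
class FitConfig:
    """Fixed experimental parameters and fitting options.

    Times in ns, B1 in Gauss, omega_I in rad/ns, N_ref in mol/L, b_ref in
    nm.  ``n_starts`` is the per-axis size of the multistart grid over the
    (log-spaced) bounds; ``n_refine`` of the best coarse starts are
    polished with a trust-region least-squares solver.  ``seed`` controls
    the optional jitter applied to the start grid (no jitter when None),
    keeping repeated fits bit-identical.
    """

    T2S: float
    T1I: float
    B1: float
    omega_I: float
    N_ref: float = 0.1
    b_ref: float = 1.0
    gamma_ratio: float = GAMMA_RATIO_H
    model: str = "ffhs"
    method: str = "exact"
    r1_bounds: Tuple[float, float] = (1.0, 1e3)
    r2_bounds: Tuple[float, float] = (1.0, 1e3)
    r3_bounds: Tuple[float, float] = (1e-2, 1e3)
    n_starts: int = 4
    n_refine: int = 4
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("T2S", "T1I", "B1", "omega_I", "N_ref", "b_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("r1_bounds", "r2_bounds", "r3_bounds"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"invalid {name}: {(lo, hi)}")

    @property
    def delta2_ref(self) -> float:
        return dipolar_strength(self.N_ref, self.b_ref)

    def spin_params(self, r1: float) -> SpinParams:
        return SpinParams(
            T1S=r1 * self.T2S,
            T2S=self.T2S,
            T1I=self.T1I,
            omega_I=self.omega_I,
            omega_1=b1_to_omega1(self.B1),
            gamma_ratio=self.gamma_ratio,
        )


@dataclass
class FitResult:
    """Best-fit ratios, goodness of fit, and derived physical parameters.

    ``residual`` is the root-mean-square misfit in enhancement units;
    ``derived`` holds T1S (ns), tau (ns), b (nm), D (nm^2/ns);
    ``covariance`` is the local Gauss-Newton estimate for (r1, r2, r3);
    ``B1_sqrt_r1`` reports the product B1*sqrt(r1) (G), which is pinned by
    the position of the non-canonical peaks and should stay constant when
    refitting with a different assumed B1.
    """

    r1: float
    r2: float
    r3: float
    residual: float
    derived: dict
    covariance: Optional[np.ndarray]
    B1_sqrt_r1: float
    residual_profile: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    n_converged: int = 0


def model_profile(
    r1: float,
    r2: float,
    r3: float,
    config: FitConfig,
    grid: np.ndarray,
) -> ProfileResult:
    """Forward model on an offset grid (rad/ns) for the fit ratios.

    Builds T1S = r1*T2S, tau = T2S/r2 and <delta^2> = r3*<delta_ref^2> and
    evaluates the enhancement profile with the configured motional model
    and method.
    """
    if r1 <= 0 or r2 <= 0 or r3 <= 0:
        raise ValueError(f"ratios must be positive, got {(r1, r2, r3)}")
    params = config.spin_params(r1)
    tau = None if config.model == "solid" else config.T2S / r2
    sd = SpectralDensity(config.model, tau)
    dip = DipolarSpec(N=config.N_ref, b=config.b_ref, delta2=r3 * config.delta2_ref)
    return enhancement_profile(params, dip, sd, grid, method=config.method)


def derived_quantities(
    r1: float, r2: float, r3: float, config: FitConfig, N: Optional[float] = None
) -> dict:
    """Physical parameters implied by the fitted ratios.

    ``N`` is the assumed radical concentration (mol/L); defaults to the
    reference value N_ref.
    """
    N = config.N_ref if N is None else N
    T1S = r1 * config.T2S
    tau = config.T2S / r2
    b = config.b_ref * (r3 * config.N_ref / N) ** (-1.0 / 3.0)
    return {"T1S_ns": T1S, "tau_ns": tau, "b_nm": b, "D_nm2_per_ns": b**2 / tau}


def _starts(config: FitConfig) -> np.ndarray:
    """Deterministic multistart grid in log-parameter space."""
    axes = [
        np.linspace(np.log(lo * 1.01), np.log(hi * 0.99), config.n_starts)
        for lo, hi in (config.r1_bounds, config.r2_bounds, config.r3_bounds)
    ]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if config.seed is not None:
        rng = np.random.default_rng(config.seed)
        steps = [(ax[1] - ax[0]) if len(ax) > 1 else 0.1 for ax in axes]
        grid = grid + rng.uniform(-0.05, 0.05, grid.shape) * np.asarray(steps)
        lo = np.log([config.r1_bounds[0], config.r2_bounds[0], config.r3_bounds[0]])
        hi = np.log([config.r1_bounds[1], config.r2_bounds[1], config.r3_bounds[1]])
        grid = np.clip(grid, lo, hi)
    return grid


def fit_profile(data, config: FitConfig) -> FitResult:
    """Fit (r1, r2, r3) to an experimental field profile.

    Parameters
    ----------
    data : a DataFrame with columns ``offset_MHz`` and ``enhancement``, or
        a pair of arrays (offsets in MHz, enhancements).
    config : fixed parameters and optimizer options.

    Raises :class:`FitError` if no start converges.  A warning-free fit
    needs at least 10 points covering both the canonical (|Omega| ~
    omega_I) and small-offset regions.
    """
    if isinstance(data, pd.DataFrame):
        off_mhz = np.asarray(data["offset_MHz"], dtype=float)
        eps = np.asarray(data["enhancement"], dtype=float)
    else:
        off_mhz, eps = (np.asarray(a, dtype=float) for a in data)
    if off_mhz.size != eps.size or off_mhz.size == 0:
        raise ValueError("offset and enhancement arrays must be non-empty and equal-length")
    if off_mhz.size < 10:
        warnings.warn("fewer than 10 data points; the fit is poorly constrained", stacklevel=2)
    wI_mhz = config.omega_I / (2 * np.pi) * 1e3
    if not (np.any(np.abs(off_mhz) > 0.5 * wI_mhz) and np.any(np.abs(off_mhz) < 0.5 * wI_mhz)):
        warnings.warn(
            "data do not span both the canonical and small-offset regions",
            stacklevel=2,
        )
    grid = mhz_to_rad_per_ns(off_mhz)

    def residuals(logr: np.ndarray) -> np.ndarray:
        r1, r2, r3 = np.exp(logr)
        # model-consistency warnings (e.g. R1I^A > R1I at extreme trial
        # parameters) are diagnostics of the final answer, not of every
        # point the optimizer visits
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model_profile(r1, r2, r3, config, grid).epsilon - eps

    lo = np.log([config.r1_bounds[0], config.r2_bounds[0], config.r3_bounds[0]])
    hi = np.log([config.r1_bounds[1], config.r2_bounds[1], config.r3_bounds[1]])
    starts = _starts(config)
    coarse = np.array([np.sum(residuals(x) ** 2) for x in starts])
    order = np.argsort(coarse)[: max(1, config.n_refine)]

    best = None
    n_converged = 0
    for idx in order:
        try:
            sol = least_squares(residuals, starts[idx], bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if not sol.success:
            continue
        n_converged += 1
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError(
            f"no convergence from any of {len(order)} refined starts "
            f"(coarse misfits: {np.sort(coarse)[:3]})"
        )
    r1, r2, r3 = np.exp(best.x)
    res = residuals(best.x)
    rms = float(np.sqrt(np.mean(res**2)))
    cov = _covariance(best, rms, (r1, r2, r3))
    return FitResult(
        r1=float(r1),
        r2=float(r2),
        r3=float(r3),
        residual=rms,
        derived=derived_quantities(r1, r2, r3, config),
        covariance=cov,
        B1_sqrt_r1=float(config.B1 * np.sqrt(r1)),
        residual_profile=res,
        n_converged=n_converged,
    )


def _covariance(sol, rms: float, r: Sequence[float]) -> Optional[np.ndarray]:
    """Local covariance of (r1, r2, r3) from the Gauss-Newton Hessian in
    log space, transformed back with the Jacobian d r / d log r = r."""
    J = sol.jac
    n, k = J.shape
    if n <= k:
        return None
    try:
        cov_log = np.linalg.inv(J.T @ J) * rms**2 * n / (n - k)
    except np.linalg.LinAlgError:
        return None
    scale = np.asarray(r)
    return cov_log * np.outer(scale, scale)
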