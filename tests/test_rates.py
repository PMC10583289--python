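import numpy as np
import pytest

from dnpse import (
    SpectralDensity,
    SpinParams,
    b1_to_omega1,
    bloch_steady_state,
    build_B,
    forbidden_rates,
    mhz_to_rad_per_ns,
    solid_closed_form,
)

from conftest import complex_transfer_scale, random_spin_params

ALL_SDS = [
    SpectralDensity("solid"),
    SpectralDensity("exponential", 12.0),
    SpectralDensity("ffhs", 12.0),
]


class TestBuildB:
    def test_block_decoupling_without_microwaves(self):
        params = SpinParams(T1S=540.0, T2S=60.0, T1I=5e7, omega_I=2.5, omega_1=0.0)
        Om = 0.7
        gbm = build_B(params, Om)
        expected = np.sort_complex(
            [
                params.R2S + 1j * (params.omega_I + Om),
                params.R2S + 1j * (params.omega_I - Om),
                params.R1S + 1j * params.omega_I,
            ]
        )
        np.testing.assert_allclose(np.sort_complex(gbm.eigenvalues[0]), expected, rtol=1e-12)

    def test_equal_relaxation_times_eigenvalues(self):
        # for T1S = T2S the spectrum is exactly R2S + i(wI -/+ 0, omega_eff)
        params = SpinParams(T1S=60.0, T2S=60.0, T1I=5e7, omega_I=2.5, omega_1=0.1)
        Om = 0.4
        weff = np.hypot(Om, params.omega_1)
        gbm = build_B(params, Om)
        expected = np.sort_complex(
            [
                params.R2S + 1j * params.omega_I,
                params.R2S + 1j * (params.omega_I - weff),
                params.R2S + 1j * (params.omega_I + weff),
            ]
        )
        np.testing.assert_allclose(np.sort_complex(gbm.eigenvalues[0]), expected, rtol=1e-12)

    def test_reconstruction_on_random_draws(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            params = random_spin_params(rng)
            gbm = build_B(params, rng.uniform(-5, 5))
            rec = gbm.U @ (gbm.eigenvalues[..., :, None] * gbm.Uinv)
            assert np.linalg.norm(rec - gbm.B) < 1e-10 * np.linalg.norm(gbm.B)
            assert np.all(gbm.eigenvalues.real > 0)


class TestEigenVsClosedForm:
    def test_randomized_equivalence(self):
        # the closed-form solid path and the eigen path with j(s)=1/s are
        # mutual oracles
        rng = np.random.default_rng(3)
        for _ in range(200):
            params = random_spin_params(rng)
            Om = rng.uniform(-5, 5, size=7)
            bloch = bloch_steady_state(params, Om)
            delta2 = 1e-8
            eig = forbidden_rates(build_B(params, Om), SpectralDensity("solid"), delta2, bloch)
            cf = solid_closed_form(params, Om, delta2, bloch)
            # the real parts Ti, Tx, v+/- arise from strongly cancelling
            # complex quantities; "1e-10 relative" refers to the magnitude
            # of those underlying complex transfer functions
            t_scale = np.max(complex_transfer_scale(params, Om))
            for fld in ("Ti", "Ti0", "Tx", "Ts"):
                np.testing.assert_allclose(
                    getattr(eig, fld), getattr(cf, fld), rtol=0, atol=1e-10 * t_scale
                )
            for fld in ("v_plus", "v_minus", "R1IA"):
                np.testing.assert_allclose(
                    getattr(eig, fld), getattr(cf, fld), rtol=0,
                    atol=1e-10 * delta2 * t_scale,
                )


def test_no_microwaves_kills_forbidden_rates():
    params = SpinParams(T1S=540.0, T2S=60.0, T1I=5e7, omega_I=2.5, omega_1=0.0)
    Om = np.linspace(-3, 3, 11)
    bloch = bloch_steady_state(params, Om)
    for sd in ALL_SDS:
        rs = forbidden_rates(build_B(params, Om), sd, 1e-8, bloch)
        np.testing.assert_allclose(rs.v_plus, 0.0, atol=1e-22)
        np.testing.assert_allclose(rs.v_minus, 0.0, atol=1e-22)
        np.testing.assert_allclose(rs.Ti, rs.Ti0, rtol=1e-10)


def test_exponential_nuclear_relaxation_closed_form():
    # dipolar nuclear relaxation for mono-exponential decay:
    # R1I^A = <delta^2> Re{(R1S + 1/tau + i wI)^-1}
    params = SpinParams(T1S=540.0, T2S=60.0, T1I=5e7, omega_I=2.5, omega_1=0.1)
    tau, d2 = 12.0, 1e-8
    bloch = bloch_steady_state(params, 1.0)
    rs = forbidden_rates(build_B(params, 1.0), SpectralDensity("exponential", tau), d2, bloch)
    expected = d2 * (1.0 / (params.R1S + 1.0 / tau + 1j * params.omega_I)).real
    assert rs.R1IA[0] == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("sd", ALL_SDS, ids=lambda sd: sd.model)
def test_parity_under_offset_reversal(sd, narrow_line_params):
    om = np.linspace(0.01, 1.2, 60)
    bp = bloch_steady_state(narrow_line_params, om)
    bm = bloch_steady_state(narrow_line_params, -om)
    rp = forbidden_rates(build_B(narrow_line_params, om), sd, 1e-8, bp)
    rm = forbidden_rates(build_B(narrow_line_params, -om), sd, 1e-8, bm)
    np.testing.assert_allclose(rm.v_plus, rp.v_plus, rtol=1e-9)
    np.testing.assert_allclose(rm.Ti, rp.Ti, rtol=1e-9)
    np.testing.assert_allclose(rm.v_minus, -rp.v_minus, rtol=1e-9)
    np.testing.assert_allclose(rm.Ts, -rp.Ts, rtol=1e-9)


def _v_minus_half_width(params, sd, d2):
    """Half-width at half-maximum of the v- peak near Omega = +omega_I."""
    om = np.linspace(0.5 * params.omega_I, 1.5 * params.omega_I, 4001)
    bloch = bloch_steady_state(params, om)
    v = forbidden_rates(build_B(params, om), sd, d2, bloch).v_minus
    ipk = int(np.argmax(np.abs(v)))
    half = 0.5 * np.abs(v[ipk])
    above = np.flatnonzero(np.abs(v) >= half)
    return om[above[-1]] - om[above[0]]


def test_motional_broadening_grows_with_motion():
    # faster motion (smaller tau) broadens the solid-effect line: widths
    # go as R2S + 1/tau for the exponential model
    params = SpinParams(
        T1S=540.0,
        T2S=60.0,
        T1I=5e7,
        omega_I=mhz_to_rad_per_ns(400.0),
        omega_1=b1_to_omega1(6.0),
    )
    w_fast = _v_minus_half_width(params, SpectralDensity("exponential", 3.0), 1e-8)
    w_slow = _v_minus_half_width(params, SpectralDensity("exponential", 60.0), 1e-8)
    assert w_fast > w_slow


@pytest.mark.parametrize("model,tau", [("exponential", 12.0), ("ffhs", 12.0)])
def test_v_plus_negative_beyond_larmor_at_low_field(model, tau, narrow_line_params):
    # documented model behavior at X band: v+ < 0 at offsets beyond
    # omega_I, which pushes the nuclear cross-polarization factor above 1
    params = narrow_line_params
    om = np.linspace(1.5 * params.omega_I, 4.0 * params.omega_I, 200)
    bloch = bloch_steady_state(params, om)
    rs = forbidden_rates(build_B(params, om), SpectralDensity(model, tau), 1e-8, bloch)
    assert np.min(rs.v_plus) < 0
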