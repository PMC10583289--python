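import warnings

import numpy as np
import pytest

from dnpse import (
    FitConfig,
    SyntheticSpec,
    derived_quantities,
    fit_profile,
    generate_profile,
    mhz_to_rad_per_ns,
    model_profile,
)

from conftest import ROW1

GRID_MHZ = np.linspace(-600.0, 600.0, 81)


def _fast_config(j_band_config, **over):
    kw = dict(
        T2S=j_band_config.T2S,
        T1I=j_band_config.T1I,
        B1=j_band_config.B1,
        omega_I=j_band_config.omega_I,
        n_starts=3,
        n_refine=2,
    )
    kw.update(over)
    return FitConfig(**kw)


class TestModelProfile:
    def test_r3_is_global_scale(self, j_band_config):
        grid = mhz_to_rad_per_ns(GRID_MHZ)
        base = model_profile(7.2, 30.4, 8.9, j_band_config, grid)
        # doubling the dipolar strength legitimately pushes the dipolar
        # contribution past the fixed 1/T1I, which the model flags
        with pytest.warns(UserWarning, match="R1I"):
            doubled = model_profile(7.2, 30.4, 2 * 8.9, j_band_config, grid)
        # the x2 scaling is exact only where the nucleus stays unsaturated
        keep = (np.abs(base.epsilon) > 0.05 * np.abs(base.epsilon).max()) & (
            doubled.pX > 0.995
        )
        assert keep.sum() > 10
        np.testing.assert_allclose(
            doubled.epsilon[keep], 2.0 * base.epsilon[keep], rtol=0.01
        )

    def test_faster_motion_smaller_canonical_peak(self, j_band_config):
        grid = mhz_to_rad_per_ns(np.linspace(300.0, 500.0, 201))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            slow = model_profile(7.2, 30.4, 8.9, j_band_config, grid)
            fast = model_profile(7.2, 3 * 30.4, 8.9, j_band_config, grid)
        assert np.abs(fast.epsilon).max() < np.abs(slow.epsilon).max()

    def test_rejects_nonpositive_ratios(self, j_band_config):
        with pytest.raises(ValueError):
            model_profile(-1.0, 30.4, 8.9, j_band_config, mhz_to_rad_per_ns(GRID_MHZ))


class TestDerivedQuantities:
    def test_j_band_table_row(self, j_band_config):
        d = derived_quantities(*ROW1, j_band_config)
        assert d["tau_ns"] == pytest.approx(7.07, abs=0.005)
        assert d["b_nm"] == pytest.approx(0.482, abs=0.001)
        assert d["T1S_ns"] / 1e3 == pytest.approx(1.5, abs=0.06)  # us
        assert d["D_nm2_per_ns"] == pytest.approx(0.033, abs=0.001)

    def test_assumed_concentration_rescales_contact_distance(self, j_band_config):
        half = derived_quantities(*ROW1, j_band_config, N=0.05)
        full = derived_quantities(*ROW1, j_band_config, N=0.1)
        assert half["b_nm"] == pytest.approx(full["b_nm"] / 2 ** (1 / 3), rel=1e-12)


class TestFitProfile:
    def test_noiseless_self_fit_recovers_exactly(self, j_band_config):
        cfg = _fast_config(j_band_config)
        data = generate_profile(SyntheticSpec(*ROW1, config=cfg, grid_MHz=GRID_MHZ))
        res = fit_profile(data, cfg)
        assert res.r1 == pytest.approx(ROW1[0], rel=1e-3)
        assert res.r2 == pytest.approx(ROW1[1], rel=1e-3)
        assert res.r3 == pytest.approx(ROW1[2], rel=1e-3)
        assert res.residual < 1e-8

    def test_self_consistency_on_random_draws(self, j_band_config):
        rng = np.random.default_rng(5)
        cfg = _fast_config(j_band_config)
        for _ in range(3):
            true = (rng.uniform(2, 20), rng.uniform(5, 80), rng.uniform(1, 30))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                data = generate_profile(SyntheticSpec(*true, config=cfg, grid_MHz=GRID_MHZ))
            res = fit_profile(data, cfg)
            assert np.allclose([res.r1, res.r2, res.r3], true, rtol=1e-3)

    def test_power_compensation_pattern(self, j_band_config):
        # refitting with B1 -> B1/sqrt(2) doubles r1, keeping B1*sqrt(r1)
        # (the dispersive-extremum position) fixed
        cfg = _fast_config(j_band_config)
        data = generate_profile(SyntheticSpec(*ROW1, config=cfg, grid_MHz=GRID_MHZ))
        cfg_low = _fast_config(j_band_config, B1=j_band_config.B1 / np.sqrt(2.0))
        res = fit_profile(data, cfg_low)
        assert res.r1 == pytest.approx(2.0 * ROW1[0], rel=0.1)
        assert res.B1_sqrt_r1 == pytest.approx(
            j_band_config.B1 * np.sqrt(ROW1[0]), rel=0.02
        )

    def test_model_discrimination_by_residuals(self, j_band_config):
        # hard-sphere-diffusion data fitted with the mono-exponential model
        # leave structured residuals: too-broad canonical lines, too-narrow
        # non-canonical peaks
        cfg = _fast_config(j_band_config)
        peak = np.abs(
            generate_profile(SyntheticSpec(*ROW1, config=cfg, grid_MHz=GRID_MHZ)).enhancement
        ).max()
        data = generate_profile(
            SyntheticSpec(*ROW1, config=cfg, grid_MHz=GRID_MHZ, noise_sigma=0.01 * peak, seed=4)
        )
        res_ffhs = fit_profile(data, cfg)
        res_exp = fit_profile(data, _fast_config(j_band_config, model="exponential"))
        assert res_exp.residual > 2.0 * res_ffhs.residual

    def test_warns_on_sparse_data(self, j_band_config):
        cfg = _fast_config(j_band_config)
        grid = np.linspace(-600.0, 600.0, 8)
        data = generate_profile(SyntheticSpec(*ROW1, config=cfg, grid_MHz=grid))
        with pytest.warns(UserWarning, match="10 data points"):
            fit_profile(data, cfg)
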