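"""Wake descriptors: spectra, Strouhal relations, L-moments, TKE."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wakekin as wk
from wakekin.wake_metrics import (
    NoDominantFrequencyError,
    l_kurtosis,
    sample_l_moments,
)

# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

class TestComputeSpectrum:
    dt = 0.01
    t = np.arange(0, 10, 0.01)

    def test_single_tone(self):
        spec = wk.compute_spectrum(np.sin(2 * np.pi * 2 * self.t), self.dt)
        assert spec.dominant_frequency == pytest.approx(2.0, abs=spec.resolution)
        assert spec.dominant_amplitude == pytest.approx(1.0, rel=1e-6)

    def test_larger_amplitude_wins(self):
        sig = np.sin(2 * np.pi * 3 * self.t) + 0.5 * np.sin(2 * np.pi * 5 * self.t)
        spec = wk.compute_spectrum(sig, self.dt)
        assert spec.dominant_frequency == pytest.approx(3.0, abs=spec.resolution)

    def test_constant_series_refused(self):
        with pytest.raises(NoDominantFrequencyError):
            wk.compute_spectrum(np.full(128, 3.7), self.dt)

    def test_too_short_refused(self):
        with pytest.raises(ValueError, match="64"):
            wk.compute_spectrum(np.sin(np.arange(32)), self.dt)

    def test_invariant_under_scaling_and_shift(self):
        sig = np.sin(2 * np.pi * 4 * self.t)
        a = wk.compute_spectrum(sig, self.dt)
        b = wk.compute_spectrum(5.0 * sig + 11.0, self.dt)
        assert b.dominant_frequency == a.dominant_frequency


class TestStrouhalRelations:
    def test_strouhal_printed_value(self):
        # the study's high-speed condition: f=8.85 Hz, D=1.9 cm, U=0.8009 m/s
        assert wk.strouhal_number(8.85, 0.019, 0.8009) == pytest.approx(0.21, abs=5e-3)

    def test_strouhal_identity_scale(self):
        assert wk.strouhal_number(1, 1, 1) == 1.0

    def test_strouhal_direct(self):
        assert wk.strouhal_number(5, 0.019, 0.5) == pytest.approx(0.19, abs=5e-3)

    def test_strouhal_zero_speed_refused(self):
        with pytest.raises(ValueError):
            wk.strouhal_number(5, 0.019, 0.0)

    def test_blockage_corrected_velocity(self):
        # back-substituting the printed shedding frequencies forces this U
        assert wk.blockage_corrected_velocity(0.74, 0.25, 0.019) == pytest.approx(
            0.8009, abs=1e-4
        )

    def test_blockage_no_cylinder(self):
        assert wk.blockage_corrected_velocity(0.5, 0.25, 0.0) == 0.5

    def test_blockage_wide_tank_limit(self):
        widths = [0.25, 0.5, 1.0, 5.0, 100.0]
        us = [wk.blockage_corrected_velocity(0.5, w, 0.019) for w in widths]
        assert all(a > b for a, b in zip(us, us[1:]))     # monotone from above
        assert all(u > 0.5 for u in us)
        assert us[-1] == pytest.approx(0.5, rel=1e-3)

    def test_blockage_refuses_wide_cylinder(self):
        with pytest.raises(ValueError):
            wk.blockage_corrected_velocity(0.5, 0.019, 0.25)

    @pytest.mark.parametrize(
        "st_num,expected", [(0.21, 8.85), (0.23, 9.69)], ids=["KVS", "PVS"]
    )
    def test_predicted_shedding_frequency(self, st_num, expected):
        f = wk.predict_shedding_frequency(st_num, 0.019, 0.74, 0.25)
        assert round(f, 2) == expected

    def test_predict_zero_st(self):
        assert wk.predict_shedding_frequency(0.0, 0.019, 0.74, 0.25) == 0.0

    def test_predict_linear_in_uf_and_st(self):
        base = wk.predict_shedding_frequency(0.2, 0.019, 0.4, 0.25)
        assert wk.predict_shedding_frequency(0.2, 0.019, 0.8, 0.25) == pytest.approx(
            2 * base
        )
        assert wk.predict_shedding_frequency(0.4, 0.019, 0.4, 0.25) == pytest.approx(
            2 * base
        )

    def test_reynolds(self):
        assert wk.reynolds_number(1, 1, 1) == 1.0
        # lowest experimental speed: ~3670 (reported rounded as ~3700)
        assert wk.reynolds_number(0.22, 0.019, 1.139e-6) == pytest.approx(3670, abs=5)
        assert wk.reynolds_number(0.44, 0.019, 1.139e-6) == pytest.approx(
            2 * wk.reynolds_number(0.22, 0.019, 1.139e-6)
        )

    def test_reynolds_zero_viscosity_refused(self):
        with pytest.raises(ValueError):
            wk.reynolds_number(1, 1, 0)


# ---------------------------------------------------------------------------
# L-moments
# ---------------------------------------------------------------------------

def brute_force_l_moments(values):
    """Independent oracle: b_r as the mean subset maximum over all
    (r+1)-subsets, divided by r+1 (the U-statistic form of the PWMs)."""
    x = sorted(values)
    n = len(x)
    b = []
    for r in range(4):
        maxima = [max(c) for c in itertools.combinations(x, r + 1)]
        b.append(sum(maxima) / len(maxima) / (r + 1))
    return (
        b[0],
        2 * b[1] - b[0],
        6 * b[2] - 6 * b[1] + b[0],
        20 * b[3] - 30 * b[2] + 12 * b[1] - b[0],
    )


class TestLMoments:
    def test_hand_computed_example(self):
        l1, l2, l3, l4 = sample_l_moments([1, 2, 3, 4])
        assert l1 == pytest.approx(2.5, abs=1e-12)
        assert l2 == pytest.approx(0.8333333333, abs=1e-9)
        assert l3 == pytest.approx(0.0, abs=1e-12)
        assert l4 == pytest.approx(0.0, abs=1e-12)

    def test_constant_sample(self):
        l1, l2, l3, l4 = sample_l_moments([7.0] * 4)
        assert l1 == pytest.approx(7.0, abs=1e-12)
        for lk in (l2, l3, l4):
            assert lk == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 9))
            x = rng.normal(0, 3, n)
            got = sample_l_moments(x)
            want = brute_force_l_moments(x)
            assert got == pytest.approx(want, abs=1e-12)

    def test_too_few_values_refused(self):
        with pytest.raises(ValueError):
            sample_l_moments([1.0, 2.0, 3.0], order=4)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
            min_size=2,
            max_size=12,
        )
    )
    def test_symmetric_sample_has_zero_l3(self, half):
        # mirror the sample about zero: exactly symmetric about its median
        x = np.array(half + [-v for v in half])
        l3 = sample_l_moments(x)[2]
        scale = max(np.max(np.abs(x)), 1.0)
        assert abs(l3) < 1e-10 * scale

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=5,
            max_size=12,
            unique=True,
        ),
        st.floats(min_value=0.01, max_value=100),
        st.floats(min_value=-50, max_value=50),
    )
    def test_affine_equivariance(self, xs, scale, shift):
        base = sample_l_moments(xs)
        moved = sample_l_moments([scale * v + shift for v in xs])
        tol = 1e-8 * max(1.0, abs(scale) * max(abs(v) for v in xs))
        assert moved[0] == pytest.approx(scale * base[0] + shift, abs=tol)
        for k in (1, 2, 3):
            assert moved[k] == pytest.approx(scale * base[k], abs=tol)


class TestLKurtosis:
    def test_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            score = l_kurtosis(rng.exponential(1.0, 50))
            assert abs(score.l_kurtosis) <= 1.0

    def test_flat_sample_undefined(self):
        score = l_kurtosis(np.full(40, 2.0))
        assert not score.defined

    def test_scale_invariant(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(1.0, 64)
        a = l_kurtosis(x).l_kurtosis
        b = l_kurtosis(517.3 * x).l_kurtosis
        assert b == pytest.approx(a, abs=1e-10)


# ---------------------------------------------------------------------------
# periodicity, wavelength, TKE on fields
# ---------------------------------------------------------------------------

def uniform_oscillation_field(a=0.3, freq=2.0, u0=0.5, n_periods=8, fs=64):
    t = np.arange(0, n_periods / freq, 1.0 / fs)
    x = np.linspace(0, 1, 8)
    y = np.linspace(-0.5, 0.5, 6)
    ux = u0 + a * np.sin(2 * np.pi * freq * t)[:, None, None] * np.ones((1, 6, 8))
    uy = np.zeros_like(ux)
    return wk.VelocityField(x=x, y=y, t=t, u_x=ux, u_y=uy)


class TestPeriodicityScore:
    def test_sine_beats_white_noise_in_every_pair(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 4, 1 / 128)
        wins = 0
        for _ in range(20):
            sine = np.sin(2 * np.pi * 5 * t) + 0.05 * rng.normal(size=t.size)
            noise = rng.normal(size=t.size)
            tau_s = l_kurtosis(wk.compute_spectrum(sine, 1 / 128).amplitudes)
            tau_n = l_kurtosis(wk.compute_spectrum(noise, 1 / 128).amplitudes)
            wins += tau_s.l_kurtosis > tau_n.l_kurtosis
        assert wins == 20

    def test_probe_outside_grid_refused(self, geometry):
        from tests.conftest import make_street

        field, _ = make_street(geometry)
        with pytest.raises(ValueError, match="outside grid"):
            wk.periodicity_score(field, (99.0, 0.0))

    def test_probe_series_scaling_leaves_tau4(self, geometry):
        from tests.conftest import make_street

        field, _ = make_street(geometry, noise_sd=0.01)
        probe = wk.default_probe(geometry)
        a = wk.periodicity_score(field, probe).l_kurtosis
        field.u_y *= 3.0
        b = wk.periodicity_score(field, probe).l_kurtosis
        assert b == pytest.approx(a, abs=1e-10)


class TestWakeWavelength:
    def test_injected_spatial_tone(self):
        x = np.linspace(0, 0.4, 128)
        y = np.linspace(-0.05, 0.05, 4)
        t = np.arange(0, 0.5, 0.25)
        uy = np.tile(np.sin(2 * np.pi * x / 0.05), (t.size, y.size, 1))
        field = wk.VelocityField(x=x, y=y, t=t, u_x=np.zeros_like(uy), u_y=uy)
        lam = wk.wake_wavelength(field, t=0.0, y_line=0.0)
        k_res = 1.0 / (x[-1] - x[0])
        k = 1.0 / lam
        assert abs(k - 1 / 0.05) <= k_res

    def test_uniform_flow_refused(self):
        x = np.linspace(0, 0.4, 128)
        y = np.linspace(-0.05, 0.05, 4)
        t = np.arange(0, 0.5, 0.25)
        shape = (t.size, y.size, x.size)
        field = wk.VelocityField(
            x=x, y=y, t=t, u_x=np.full(shape, 0.5), u_y=np.zeros(shape)
        )
        with pytest.raises(NoDominantFrequencyError, match="wavelength"):
            wk.wake_wavelength(field, t=0.0)


class TestTKE:
    def test_steady_field_zero(self):
        field = uniform_oscillation_field(a=0.0)
        assert wk.turbulent_kinetic_energy(field) == 0.0

    def test_uniform_oscillation_closed_form(self):
        a = 0.3
        field = uniform_oscillation_field(a=a)
        assert wk.turbulent_kinetic_energy(field) == pytest.approx(
            a**2 / 4, rel=0.01
        )

    def test_quadratic_scaling(self):
        f1 = uniform_oscillation_field(a=0.2)
        f2 = uniform_oscillation_field(a=0.6)
        r = wk.turbulent_kinetic_energy(f2) / wk.turbulent_kinetic_energy(f1)
        assert r == pytest.approx(9.0, abs=1e-10)

    def test_additivity_of_independent_fluctuations(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 1, 8)
        y = np.linspace(-0.5, 0.5, 6)
        t = np.arange(0, 8, 1 / 64)
        shape = (t.size, y.size, x.size)
        a = rng.normal(0, 0.2, shape)
        b = rng.normal(0, 0.1, shape)
        zero = np.zeros(shape)
        mk = lambda u: wk.VelocityField(x=x, y=y, t=t, u_x=u, u_y=zero)
        tke_a = wk.turbulent_kinetic_energy(mk(a))
        tke_b = wk.turbulent_kinetic_energy(mk(b))
        tke_ab = wk.turbulent_kinetic_energy(mk(a + b))
        assert tke_ab == pytest.approx(tke_a + tke_b, rel=0.05)

    def test_empty_region_refused(self):
        field = uniform_oscillation_field()
        with pytest.raises(ValueError, match="region"):
            wk.turbulent_kinetic_energy(field, region=(5.0, 6.0, 5.0, 6.0))
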