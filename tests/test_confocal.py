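"""Confocal transformation: transmission, probe width, depth response."""

import time

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from cmxrf import confocal, forward
from cmxrf.confocal import (
    CU_KA_KEV,
    CalibrationRanges,
    SetupCalibration,
    default_depth_grid,
    depth_response,
    optic_transmission,
    probe_sigma,
)
from cmxrf.samples import Composition


@pytest.fixture(scope="module")
def spectrum_and_comp():
    comp = Composition({19: 0.02, 26: 0.03, 38: 0.001}, 2.2)
    spec = forward.simulate_mxrf(comp)
    return spec, comp


# --------------------------------------------------------------- T(E)
def test_transmission_flat_limit():
    cal = SetupCalibration(T_A=0.0, T_B=1e9, T_M=0.8)
    e = np.linspace(1, 40, 50)
    np.testing.assert_allclose(optic_transmission(e, cal), 0.8, rtol=1e-6)


def test_transmission_band_pass_shape():
    cal = SetupCalibration()
    assert optic_transmission(2.0, cal) < optic_transmission(8.0, cal)
    assert optic_transmission(30.0, cal) < optic_transmission(8.0, cal)
    assert 0 < optic_transmission(8.0, cal) <= cal.T_M


def test_transmission_argmax_at_sqrt_tatb():
    cal = SetupCalibration()
    e = np.linspace(0.5, 40, 200_000)
    argmax = e[np.argmax(optic_transmission(e, cal))]
    assert argmax == pytest.approx(np.sqrt(cal.T_A * cal.T_B), rel=1e-3)


# --------------------------------------------------------------- sigma(E)
def test_probe_sigma_flat_when_amplitude_zero():
    cal = SetupCalibration(sigma_max=0.0)
    e = np.linspace(1, 40, 20)
    np.testing.assert_allclose(probe_sigma(e, cal), cal.sigma_off)


def test_default_depth_resolution_at_cu_ka():
    assert confocal.depth_fwhm(CU_KA_KEV) == pytest.approx(30.0, rel=0.01)


@settings(deadline=None, max_examples=50)
@given(
    sigma_max=st.floats(20.0, 80.0),
    sigma_exp=st.floats(0.2, 1.5),
    sigma_off=st.floats(0.5, 10.0),
)
def test_probe_shrinks_with_energy(sigma_max, sigma_exp, sigma_off):
    cal = SetupCalibration(sigma_max=sigma_max, sigma_exp=sigma_exp, sigma_off=sigma_off)
    assert probe_sigma(5.0, cal) > probe_sigma(15.0, cal)


# --------------------------------------------------------------- R(d)
def test_depth_response_limits():
    assert depth_response(1e4, 0.0, 10.0) == pytest.approx(1.0, abs=1e-12)
    assert depth_response(0.0, 0.0, 10.0) == pytest.approx(0.5, rel=1e-12)
    assert depth_response(-1e4, 0.0, 10.0) == pytest.approx(0.0, abs=1e-300)


def _quadrature_oracle(d, mu, sigma):
    val, err = integrate.quad(
        lambda t: np.exp(-mu * t) * stats.norm.pdf(t, loc=d, scale=sigma),
        0.0,
        np.inf,
        limit=400,
    )
    return val


def test_depth_response_against_quadrature_example():
    r = depth_response(20.0, 0.01, 12.0)
    assert r == pytest.approx(_quadrature_oracle(20.0, 0.01, 12.0), rel=1e-8)


def test_depth_response_overflow_guard():
    # large mu*sigma would overflow a naive erfc formulation
    r = depth_response(500.0, 1.0, 40.0)
    assert np.isfinite(r) and 0 <= r <= 1


def test_depth_response_input_validation():
    with pytest.raises(ValueError):
        depth_response(0.0, 0.01, -1.0)
    with pytest.raises(ValueError):
        depth_response(0.0, -0.01, 1.0)


# --------------------------------------------------------------- transform
def test_transform_default_grid_shape(spectrum_and_comp):
    spec, comp = spectrum_and_comp
    prof = confocal.transform(spec, comp, x0=60.0)
    assert prof.intensity.shape == (40, len(spec.energy_grid))
    assert len(prof.depth_grid) == 40
    np.testing.assert_allclose(np.diff(prof.depth_grid), 5.0)


def test_profiles_rise_then_decay(spectrum_and_comp):
    """Each channel rises from ~0 before the surface to a maximum and
    then decays (characteristic depth-profile shape); unimodality."""
    spec, comp = spectrum_and_comp
    prof = confocal.transform(spec, comp, x0=60.0)
    band = (spec.energy_grid >= 3.0) & (spec.energy_grid <= 20.0)
    for col in prof.intensity[:, band].T[::50]:
        peak = col.argmax()
        assert 0 < peak < len(col) - 1
        assert col[0] < 0.05 * col[peak]
        rising, falling = col[: peak + 1], col[peak:]
        assert np.all(np.diff(rising) >= -1e-9 * col[peak])
        assert np.all(np.diff(falling) <= 1e-9 * col[peak])


def test_centroid_hardens_with_depth(spectrum_and_comp):
    """Absorption shifts the spectral centroid to higher energies once
    the probing volume is fully submerged."""
    spec, comp = spectrum_and_comp
    cal = SetupCalibration()
    x0 = 40.0
    prof = confocal.transform(spec, comp, cal, x0=x0)
    cent = confocal.spectral_centroid(prof)
    margin = confocal.FWHM_FACTOR * probe_sigma(3.0, cal)  # probe fully inside
    deep = prof.depth_grid >= x0 + margin
    assert deep.sum() >= 5
    assert np.all(np.diff(cent[deep]) >= -1e-9)


def test_deep_region_slope_recovers_attenuation(spectrum_and_comp):
    """log Phi(E, x) for x >> x0 has slope -mu_bar(E) within 1%."""
    spec, comp = spectrum_and_comp
    cal = SetupCalibration()
    x0 = 5.0
    prof = confocal.transform(spec, comp, cal, x0=x0)
    e = spec.energy_grid
    usable = (e > 3.0) & (e <= 20.0) & (spec.intensity > 0)
    mu_bar = confocal.effective_linear_mu(comp, e[usable], cal)
    tail = prof.depth_grid >= 150.0
    x = prof.depth_grid[tail]
    logs = np.log(prof.intensity[tail][:, usable])
    slopes = np.polyfit(x, logs, 1)[0]
    np.testing.assert_allclose(-slopes, mu_bar, rtol=0.01)


def test_transform_factorizes_per_cell(spectrum_and_comp):
    """Any cell equals Phi_0(E) * T(E) * R(...) recomputed independently."""
    spec, comp = spectrum_and_comp
    cal = SetupCalibration()
    x0 = 62.5
    prof = confocal.transform(spec, comp, cal, x0=x0)
    rng = np.random.default_rng(3)
    e = spec.energy_grid
    for _ in range(20):
        i = rng.integers(0, 40)
        j = rng.integers(0, len(e))
        if e[j] <= 1.0:
            assert prof.intensity[i, j] == 0.0
            continue
        expected = (
            spec.intensity[j]
            * optic_transmission(e[j], cal)
            * depth_response(
                prof.depth_grid[i] - x0,
                confocal.effective_linear_mu(comp, e[j], cal),
                probe_sigma(e[j], cal),
            )
        )
        assert prof.intensity[i, j] == pytest.approx(expected, rel=1e-12)


def test_transform_shift_equivariance(spectrum_and_comp):
    spec, comp = spectrum_and_comp
    delta = 37.0
    grid = default_depth_grid()
    a = confocal.transform(spec, comp, x0=60.0, depth_grid=grid)
    b = confocal.transform(spec, comp, x0=60.0 + delta, depth_grid=grid + delta)
    np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)


def test_density_steepens_decay(spectrum_and_comp):
    spec, comp = spectrum_and_comp
    denser = Composition(dict(comp.mass_fractions), comp.density * 1.5)
    a = confocal.transform(spec, comp, x0=20.0)
    b = confocal.transform(spec, denser, x0=20.0)
    e = spec.energy_grid
    usable = (e > 3.0) & (e <= 20.0) & (spec.intensity > 0)
    # decay between two deep rows, per channel
    ratio_a = a.intensity[-1, usable] / a.intensity[-10, usable]
    ratio_b = b.intensity[-1, usable] / b.intensity[-10, usable]
    assert np.all(ratio_b < ratio_a)


def test_transform_throughput(spectrum_and_comp):
    spec, comp = spectrum_and_comp
    confocal.transform(spec, comp, x0=60.0)  # warm up
    t0 = time.time()
    for _ in range(5):
        confocal.transform(spec, comp, x0=60.0)
    assert (time.time() - t0) / 5 < 0.4  # well under 0.4 s per profile


# --------------------------------------------------- calibration drawing
def test_degenerate_ranges_reproduce_nominal():
    nominal = SetupCalibration()
    ranges = CalibrationRanges.relative(nominal, spread=0.0)
    cal = confocal.randomize_calibration(ranges, rng=0)
    assert cal == nominal


def test_randomized_calibrations_within_bounds():
    ranges = CalibrationRanges.relative(spread=0.2)
    rng = np.random.default_rng(1)
    for _ in range(1000):
        cal = confocal.randomize_calibration(ranges, rng)
        for name, (lo, hi) in ranges.bounds.items():
            assert lo <= getattr(cal, name) <= hi


def test_randomized_tm_uniform_mean():
    ranges = CalibrationRanges({"T_M": (0.5, 1.0)})
    rng = np.random.default_rng(2)
    draws = np.array(
        [confocal.randomize_calibration(ranges, rng).T_M for _ in range(10_000)]
    )
    se = 0.5 / np.sqrt(12) / np.sqrt(len(draws))
    assert abs(draws.mean() - 0.75) < 3 * se


def test_infeasible_ranges_raise():
    ranges = CalibrationRanges({"T_M": (1.5, 2.0)})  # violates T_M <= 1
    with pytest.raises(ValueError):
        confocal.randomize_calibration(ranges, rng=0)


# --------------------------------------------------------------- noise
def test_poisson_zero_stays_zero(spectrum_and_comp):
    spec, comp = spectrum_and_comp
    prof = confocal.transform(spec, comp, x0=60.0)
    noisy = confocal.add_poisson_noise(prof, rng=0)
    assert np.all(noisy.intensity[prof.intensity == 0] == 0)
    assert noisy.intensity.dtype.kind == "i"


def test_poisson_dispersion():
    prof = confocal.DepthProfile(
        np.arange(2) * 5.0,
        np.array([5.0, 6.0]),
        np.full((2, 2), 1e4),
        0.0,
        SetupCalibration(),
    )
    rng = np.random.default_rng(4)
    draws = np.array(
        [confocal.add_poisson_noise(prof, rng=rng).intensity[0, 0] for _ in range(1000)]
    )
    assert 0.9 < draws.var() / draws.mean() < 1.1


def test_poisson_same_seed_same_noise(spectrum_and_comp):
    spec, comp = spectrum_and_comp
    prof = confocal.transform(spec, comp, x0=60.0)
    a = confocal.add_poisson_noise(prof, rng=7)
    b = confocal.add_poisson_noise(prof, rng=7)
    np.testing.assert_array_equal(a.intensity, b.intensity)
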