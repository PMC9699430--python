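"""Spectral model: emission simulation, filtering, and band classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flossguard import fluorospec as fs


GRID = fs.default_grid()


def spectrum_from(intensities, excitation=310.0):
    return fs.EmissionSpectrum(GRID, np.asarray(intensities, float), excitation)


def zero_amplitude_model():
    return fs.FluorophoreModel(
        material_name="dark",
        kind=fs.MaterialKind.MEAT,
        cooking_state=fs.CookingState.RAW,
        calcium_mg_per_100g=0.0,
        components={310.0: (fs.GaussianComponent(500.0, 50.0, 0.0),)},
    )


# ---------------------------------------------------------------------------
# packaged library

REQUIRED_MATERIALS = [
    f"{fish}_{state}"
    for fish in ("swordfish", "salmon", "tuna", "cod")
    for state in ("raw", "steamed", "floss", "bone")
] + ["calcium_carbonate", "fingernail", "pvc", "emu", "rubber"]


def test_packaged_library_is_complete(materials):
    assert set(REQUIRED_MATERIALS) <= set(materials)
    for model in materials.values():
        assert 310.0 in model.excitations_nm
        for comps in model.components.values():
            for c in comps:
                assert 380.0 <= c.center_nm <= 800.0
                assert c.fwhm_nm > 0 and c.amplitude >= 0


# ---------------------------------------------------------------------------
# simulate_emission / peak_wavelength


def test_bone_under_uvb_peaks_near_410nm(materials):
    spectrum = fs.simulate_emission(materials["swordfish_bone"], 310.0)
    peak = fs.peak_wavelength(spectrum)
    assert abs(peak - 410.0) <= 2.0


def test_floss_under_uva_peaks_at_560nm(materials):
    spectrum = fs.simulate_emission(materials["swordfish_floss"], 365.0)
    assert fs.peak_wavelength(spectrum) == 560.0


def test_zero_amplitude_model_gives_zero_spectrum():
    spectrum = fs.simulate_emission(zero_amplitude_model(), 310.0)
    assert np.all(spectrum.intensities == 0.0)
    assert fs.peak_wavelength(spectrum) is None


def test_unknown_excitation_names_available(materials):
    with pytest.raises(KeyError, match=r"310"):
        fs.simulate_emission(materials["swordfish_bone"], 500.0)


def test_empty_grid_rejected(materials):
    with pytest.raises(ValueError, match="empty"):
        fs.simulate_emission(materials["swordfish_bone"], 310.0, np.array([]))


def test_peak_ties_break_toward_shortest_wavelength():
    intensities = np.zeros_like(GRID)
    intensities[GRID == 450.0] = 5.0
    intensities[GRID == 550.0] = 5.0
    assert fs.peak_wavelength(spectrum_from(intensities)) == 450.0


def test_single_component_peak_is_its_center():
    comp = fs.GaussianComponent(560.0, 40.0, 100.0)
    assert fs.peak_wavelength(spectrum_from(comp.evaluate(GRID))) == 560.0


# ---------------------------------------------------------------------------
# classification


@pytest.mark.parametrize(
    "peak, expected",
    [
        (410.0, fs.Band.SHORT),
        (560.0, fs.Band.LONG),
        (600.0, fs.Band.OTHER),  # half-open boundary
        (400.0, fs.Band.SHORT),
        (500.0, fs.Band.LONG),
        (399.9, fs.Band.OTHER),
    ],
)
def test_classify_band(peak, expected, criterion):
    assert fs.classify_band(peak, criterion) is expected


def test_exceeds_criterion(materials, criterion):
    bone = fs.simulate_emission(materials["swordfish_bone"], 310.0)
    floss = fs.simulate_emission(materials["tuna_floss"], 310.0)
    assert fs.exceeds_criterion(bone, criterion.short_band, criterion)
    assert not fs.exceeds_criterion(floss, criterion.short_band, criterion)
    zeros = spectrum_from(np.zeros_like(GRID))
    assert not fs.exceeds_criterion(zeros, criterion.short_band, criterion)
    with pytest.raises(ValueError, match="overlap"):
        fs.exceeds_criterion(bone, (900.0, 950.0), criterion)


@pytest.mark.parametrize(
    "name, expected",
    [
        ("cod_raw", fs.Band.SHORT),      # 16 mg/100 g, raw
        ("salmon_raw", fs.Band.SHORT),   # 7 mg/100 g, raw
        ("tuna_raw", fs.Band.LONG),      # 5 mg/100 g, below criterion
        ("cod_steamed", fs.Band.LONG),   # cooking leaches calcium
        ("swordfish_bone", fs.Band.SHORT),
        ("pvc", fs.Band.SHORT),
        ("fingernail", fs.Band.SHORT),
    ],
)
def test_expected_band_from_calcium(name, expected, materials, criterion):
    assert fs.expected_band_from_calcium(materials[name], criterion) is expected


def test_peak_band_matches_composition_for_every_material(materials, criterion):
    """Under UVB, each packaged material's simulated peak lands in the band
    its calcium content / material class predicts."""
    for model in materials.values():
        spectrum = fs.simulate_emission(model, 310.0)
        band = fs.classify_band(fs.peak_wavelength(spectrum), criterion)
        assert band is fs.expected_band_from_calcium(model, criterion), (
            model.material_name
        )


def test_uva_excitation_does_not_discriminate_bone_from_floss(materials, criterion):
    """Under 365 nm both bone and floss peak in the long band — the reason
    the system excites at 310 nm."""
    for name in ("swordfish_bone", "swordfish_floss"):
        spectrum = fs.simulate_emission(materials[name], 365.0)
        band = fs.classify_band(fs.peak_wavelength(spectrum), criterion)
        assert band is fs.Band.LONG


# ---------------------------------------------------------------------------
# filter / in-band signal


def test_transmit_at_center_and_half_maximum_points():
    filt = fs.BandpassFilterModel(peak_transmission=1.0)
    flat = spectrum_from(np.ones_like(GRID))
    out = fs.transmit(flat, filt)
    at = lambda wl: out.intensities[GRID == wl][0]
    assert at(405.0) == pytest.approx(1.0)
    assert at(400.0) == pytest.approx(0.5)
    assert at(410.0) == pytest.approx(0.5)


def test_rectangular_filter_half_maximum_at_edges():
    filt = fs.BandpassFilterModel(peak_transmission=0.8, shape="rectangular")
    flat = spectrum_from(np.ones_like(GRID))
    out = fs.transmit(flat, filt)
    at = lambda wl: out.intensities[GRID == wl][0]
    assert at(405.0) == pytest.approx(0.8)
    assert at(400.0) == pytest.approx(0.4)
    assert at(420.0) == 0.0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    scale=st.floats(0.0, 50.0),
    center=st.floats(420.0, 700.0),
    fwhm=st.floats(10.0, 150.0),
)
def test_transmit_is_linear_in_intensity(scale, center, fwhm, bandpass):
    base = fs.GaussianComponent(center, fwhm, 1000.0).evaluate(GRID)
    lhs = fs.transmit(spectrum_from(scale * base), bandpass).intensities
    rhs = scale * fs.transmit(spectrum_from(base), bandpass).intensities
    np.testing.assert_allclose(lhs, rhs, rtol=1e-12, atol=1e-9)


@pytest.mark.parametrize("name", ["swordfish_bone", "swordfish_floss", "cod_raw"])
def test_in_band_signal_matches_fine_riemann_sum(name, materials, bandpass):
    """The 1 nm trapezoid agrees within 1% with a 0.1 nm Riemann sum."""
    model = materials[name]
    coarse = fs.in_band_signal(fs.simulate_emission(model, 310.0), bandpass)
    fine_grid = fs.default_grid(step_nm=0.1)
    fine = fs.simulate_emission(model, 310.0, fine_grid)
    riemann = float(
        np.sum(fine.intensities * bandpass.transmission(fine_grid)) * 0.1
    )
    assert coarse == pytest.approx(riemann, rel=0.01)


def test_in_band_signal_monotone_in_amplitude(bandpass):
    base = fs.GaussianComponent(405.0, 30.0, 100.0).evaluate(GRID)
    bump = fs.GaussianComponent(450.0, 20.0, 10.0).evaluate(GRID)
    low = fs.in_band_signal(spectrum_from(base), bandpass)
    high = fs.in_band_signal(spectrum_from(base + bump), bandpass)
    assert high >= low


# ---------------------------------------------------------------------------
# band of maximum difference


def window_scan_oracle(a, b, window_nm):
    """Brute-force exhaustive scan over every window start position."""
    step = a.wavelengths_nm[1] - a.wavelengths_nm[0]
    n = int(round(window_nm / step))
    diff = np.abs(a.intensities - b.intensities)
    best, best_start = -1.0, None
    for i in range(a.wavelengths_nm.size - n):
        score = np.trapezoid(diff[i : i + n + 1], dx=step)
        if score > best:
            best, best_start = score, i
    lo = float(a.wavelengths_nm[best_start])
    return (lo, lo + n * step)


def test_bone_floss_contrast_is_maximal_in_400_410nm(materials):
    bone = fs.simulate_emission(materials["swordfish_bone"], 310.0)
    floss = fs.simulate_emission(materials["swordfish_floss"], 310.0)
    assert fs.band_of_max_difference(bone, floss, 10.0) == (400.0, 410.0)


def test_identical_spectra_tie_to_leftmost_window():
    s = spectrum_from(np.ones_like(GRID))
    assert fs.band_of_max_difference(s, s, 10.0) == (400.0, 410.0)


def test_window_locks_onto_larger_delta_peak():
    a = np.zeros_like(GRID)
    a[GRID == 450.0] = 100.0
    b = np.zeros_like(GRID)
    b[GRID == 700.0] = 60.0
    lo, hi = fs.band_of_max_difference(spectrum_from(a), spectrum_from(b), 10.0)
    assert lo <= 450.0 <= hi


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**16),
    window=st.sampled_from([5.0, 10.0, 25.0]),
)
def test_window_search_matches_exhaustive_scan(seed, window):
    rng = np.random.default_rng(seed)
    a = spectrum_from(rng.uniform(0, 1000, GRID.size))
    b = spectrum_from(rng.uniform(0, 1000, GRID.size))
    assert fs.band_of_max_difference(a, b, window) == window_scan_oracle(a, b, window)


def test_mismatched_grids_rejected():
    a = spectrum_from(np.ones_like(GRID))
    other = fs.EmissionSpectrum(
        fs.default_grid(step_nm=0.5), np.ones(fs.default_grid(0.5).size), 310.0
    )
    with pytest.raises(ValueError, match="grid"):
        fs.band_of_max_difference(a, other, 10.0)
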