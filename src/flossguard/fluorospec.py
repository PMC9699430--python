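"""Parametric UV-excited fluorescence emission, band-pass filtering, and
spectral classification.

The materials handled here are the ones relevant to foreign-body inspection
of fish floss: fish meat of four species (swordfish, salmon, tuna, cod) under
three cooking states (raw, steamed, floss), their bones, calcium carbonate
powder (a fingernail/bone proxy), human fingernail, and three plastic glove
materials (PVC, emulsion, rubber).

Emission is modelled as a sum of Gaussian components per excitation
wavelength.  Amplitudes are in spectrum-analyzer counts; the abnormality
criterion of 10,000 counts applies to that scale.  Calcium-based and plastic
materials fluoresce in the short visible band (400-500 nm) under 310 nm UVB
excitation, while meats and floss fluoresce in the long band (500-600 nm);
under 365 nm UVA excitation everything peaks near 560 nm, which is why the
inspection system excites at 310 nm and images through a 405 nm / 10 nm FWHM
band-pass filter.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "Band",
    "BandpassFilterModel",
    "CookingState",
    "EmissionSpectrum",
    "FluorophoreModel",
    "GaussianComponent",
    "MaterialKind",
    "SpectralCriterion",
    "band_of_max_difference",
    "classify_band",
    "default_grid",
    "exceeds_criterion",
    "expected_band_from_calcium",
    "get_material",
    "in_band_signal",
    "load_fluorophores",
    "material_names",
    "peak_wavelength",
    "simulate_emission",
    "transmit",
]

#: Visible-band wavelength limits (nm) every spectrum grid must cover.
GRID_MIN_NM = 400.0
GRID_MAX_NM = 800.0

#: Allowed range for emission component centers (nm).
COMPONENT_MIN_NM = 380.0
COMPONENT_MAX_NM = 800.0

#: How far (nm) a requested excitation may sit from a packaged one and still
#: be snapped to it.
EXCITATION_SNAP_NM = 30.0

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class CookingState(str, enum.Enum):
    RAW = "raw"
    STEAMED = "steamed"
    FLOSS = "floss"
    NOT_APPLICABLE = "n/a"


class MaterialKind(str, enum.Enum):
    MEAT = "meat"
    BONE = "bone"
    CALCIUM_POWDER = "calcium_powder"
    FINGERNAIL = "fingernail"
    PLASTIC = "plastic"


class Band(enum.Enum):
    """Spectral band of a fluorescence peak under the inspection criterion."""

    SHORT = "short"   # [400, 500) nm — calcium / plastic signature
    LONG = "long"     # [500, 600) nm — meat / floss signature
    OTHER = "other"


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian emission component: center (nm), FWHM (nm), amplitude
    (analyzer counts at the center)."""

    center_nm: float
    fwhm_nm: float
    amplitude: float

    def __post_init__(self) -> None:
        if not (COMPONENT_MIN_NM <= self.center_nm <= COMPONENT_MAX_NM):
            raise ValueError(
                f"component center {self.center_nm} nm outside "
                f"[{COMPONENT_MIN_NM}, {COMPONENT_MAX_NM}] nm"
            )
        if not self.fwhm_nm > 0:
            raise ValueError("component FWHM must be positive")
        if self.amplitude < 0:
            raise ValueError("component amplitude must be nonnegative")

    def evaluate(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        sigma = self.fwhm_nm * _FWHM_TO_SIGMA
        return self.amplitude * np.exp(
            -0.5 * ((wavelengths_nm - self.center_nm) / sigma) ** 2
        )


@dataclass(frozen=True)
class FluorophoreModel:
    """Excitation-dependent emission model of one material.

    ``components`` maps excitation wavelength (nm) to the Gaussian emission
    components observed under that excitation.  Every packaged model carries
    at least a 310 nm entry because the inspection system excites in UVB.
    """

    material_name: str
    kind: MaterialKind
    cooking_state: CookingState
    calcium_mg_per_100g: float
    components: Mapping[float, tuple[GaussianComponent, ...]]

    def __post_init__(self) -> None:
        if self.calcium_mg_per_100g < 0:
            raise ValueError("calcium content must be nonnegative")
        if not self.components:
            raise ValueError("model must define at least one excitation entry")
        if 310.0 not in {float(k) for k in self.components}:
            raise ValueError(
                f"{self.material_name}: a 310 nm excitation entry is required"
            )

    @property
    def excitations_nm(self) -> tuple[float, ...]:
        return tuple(sorted(float(k) for k in self.components))

    def components_for(self, excitation_nm: float) -> tuple[GaussianComponent, ...]:
        """Components for the packaged excitation nearest the requested one.

        The requested excitation must lie within ``EXCITATION_SNAP_NM`` of a
        packaged entry; otherwise the available excitations are named in the
        error.
        """
        if excitation_nm <= 0:
            raise ValueError("excitation wavelength must be positive")
        available = self.excitations_nm
        nearest = min(available, key=lambda x: abs(x - excitation_nm))
        if abs(nearest - excitation_nm) > EXCITATION_SNAP_NM:
            raise KeyError(
                f"{self.material_name}: no packaged excitation near "
                f"{excitation_nm} nm; available: {available}"
            )
        return tuple(self.components[nearest])


@dataclass(frozen=True)
class EmissionSpectrum:
    """A fluorescence emission spectrum on a uniform wavelength grid.

    The grid must be strictly increasing with constant spacing and cover at
    least the visible band [400, 800] nm; intensities are nonnegative
    analyzer counts.
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    excitation_nm: float

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", it)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid must be 1-D with >= 2 points")
        if it.shape != wl.shape:
            raise ValueError("wavelengths and intensities must have equal length")
        steps = np.diff(wl)
        if not np.all(steps > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9 * abs(steps[0])):
            raise ValueError("wavelength grid spacing must be constant")
        if wl[0] > GRID_MIN_NM or wl[-1] < GRID_MAX_NM:
            raise ValueError(
                f"grid must cover at least [{GRID_MIN_NM}, {GRID_MAX_NM}] nm"
            )
        if np.any(it < 0):
            raise ValueError("intensities must be nonnegative")
        if not self.excitation_nm > 0:
            raise ValueError("excitation wavelength must be positive")

    @property
    def step_nm(self) -> float:
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])


class FilterShape(str, enum.Enum):
    GAUSSIAN = "gaussian"
    RECTANGULAR = "rectangular"


@dataclass(frozen=True)
class BandpassFilterModel:
    """Optical band-pass filter in front of the camera.

    Defaults model the physical part: 405 nm center, 10 nm FWHM.  The
    transmission profile is Gaussian by default (which meets the FWHM
    definition exactly); a rectangular profile is selectable.
    """

    center_nm: float = 405.0
    fwhm_nm: float = 10.0
    peak_transmission: float = 0.9
    shape: FilterShape = FilterShape.GAUSSIAN

    def __post_init__(self) -> None:
        if not self.fwhm_nm > 0:
            raise ValueError("filter FWHM must be positive")
        if not (0.0 < self.peak_transmission <= 1.0):
            raise ValueError("peak transmission must be in (0, 1]")
        object.__setattr__(self, "shape", FilterShape(self.shape))

    def transmission(self, wavelengths_nm: np.ndarray | float) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=float)
        half = self.fwhm_nm / 2.0
        if self.shape is FilterShape.RECTANGULAR:
            inside = np.abs(wl - self.center_nm) < half
            edge = np.isclose(np.abs(wl - self.center_nm), half)
            t = np.where(inside, self.peak_transmission, 0.0)
            t = np.where(edge, self.peak_transmission / 2.0, t)
        else:
            sigma = self.fwhm_nm * _FWHM_TO_SIGMA
            t = self.peak_transmission * np.exp(
                -0.5 * ((wl - self.center_nm) / sigma) ** 2
            )
        return t


@dataclass(frozen=True)
class SpectralCriterion:
    """Spectral decision rules of the inspection method.

    ``intensity_threshold`` is the abnormality line in analyzer counts;
    ``short_band``/``long_band`` are half-open wavelength intervals;
    ``calcium_criterion_mg_per_100g`` separates raw meats whose peak moves
    into the short band from those that stay long.
    """

    intensity_threshold: float = 10_000.0
    short_band: tuple[float, float] = (400.0, 500.0)
    long_band: tuple[float, float] = (500.0, 600.0)
    calcium_criterion_mg_per_100g: float = 6.0

    def __post_init__(self) -> None:
        if not self.intensity_threshold > 0:
            raise ValueError("intensity threshold must be positive")
        lo_s, hi_s = self.short_band
        lo_l, hi_l = self.long_band
        if not (lo_s < hi_s and lo_l < hi_l):
            raise ValueError("bands must be nonempty intervals")
        if max(lo_s, lo_l) < min(hi_s, hi_l):
            raise ValueError("short and long bands must be disjoint")


def default_grid(step_nm: float = 1.0) -> np.ndarray:
    """The default visible-band evaluation grid: 400-800 nm inclusive."""
    n = int(round((GRID_MAX_NM - GRID_MIN_NM) / step_nm))
    return GRID_MIN_NM + step_nm * np.arange(n + 1)


# ---------------------------------------------------------------------------
# operations


def simulate_emission(
    model: FluorophoreModel,
    excitation_nm: float,
    grid: np.ndarray | None = None,
) -> EmissionSpectrum:
    """Evaluate a material's emission under the given excitation.

    The excitation is snapped to the nearest packaged entry (310 or 365 nm
    for the shipped library).  Intensities are the sum of the material's
    Gaussian components on the grid.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wavelength grid is empty")
    comps = model.components_for(excitation_nm)
    intensities = np.zeros_like(grid)
    for comp in comps:
        intensities += comp.evaluate(grid)
    return EmissionSpectrum(grid, intensities, float(excitation_nm))


def peak_wavelength(spectrum: EmissionSpectrum) -> float | None:
    """Grid wavelength of maximum intensity; ties break toward the shortest
    wavelength.  An all-zero spectrum has no peak and returns ``None``."""
    it = spectrum.intensities
    if not np.any(it > 0):
        return None
    return float(spectrum.wavelengths_nm[int(np.argmax(it))])


def classify_band(peak_nm: float, criterion: SpectralCriterion | None = None) -> Band:
    """Classify a peak wavelength into SHORT [400,500), LONG [500,600), or
    OTHER."""
    if criterion is None:
        criterion = SpectralCriterion()
    if not math.isfinite(peak_nm):
        raise ValueError("peak wavelength must be finite")
    lo, hi = criterion.short_band
    if lo <= peak_nm < hi:
        return Band.SHORT
    lo, hi = criterion.long_band
    if lo <= peak_nm < hi:
        return Band.LONG
    return Band.OTHER


def exceeds_criterion(
    spectrum: EmissionSpectrum,
    band: tuple[float, float],
    criterion: SpectralCriterion | None = None,
) -> bool:
    """True iff the maximum intensity inside the half-open ``band`` reaches
    the abnormality threshold."""
    if criterion is None:
        criterion = SpectralCriterion()
    lo, hi = band
    mask = (spectrum.wavelengths_nm >= lo) & (spectrum.wavelengths_nm < hi)
    if not np.any(mask):
        raise ValueError(f"band [{lo}, {hi}) nm does not overlap the grid")
    return bool(np.max(spectrum.intensities[mask]) >= criterion.intensity_threshold)


def transmit(
    spectrum: EmissionSpectrum, filter_model: BandpassFilterModel
) -> EmissionSpectrum:
    """Pointwise product of the spectrum with the filter transmission curve."""
    out = spectrum.intensities * filter_model.transmission(spectrum.wavelengths_nm)
    return replace(spectrum, intensities=out)


def in_band_signal(
    spectrum: EmissionSpectrum, filter_model: BandpassFilterModel
) -> float:
    """Trapezoidal integral of the transmitted spectrum over the grid
    (counts x nm) — the scalar that drives camera pixel values."""
    t = transmit(spectrum, filter_model)
    return float(np.trapezoid(t.intensities, t.wavelengths_nm))


def band_of_max_difference(
    spec_a: EmissionSpectrum,
    spec_b: EmissionSpectrum,
    window_nm: float,
) -> tuple[float, float]:
    """Contiguous window of the given width maximizing the integrated
    absolute difference between two spectra on the same grid.

    Ties break toward the shortest wavelength, so identical spectra return
    the leftmost window.
    """
    wl = spec_a.wavelengths_nm
    if wl.shape != spec_b.wavelengths_nm.shape or not np.allclose(
        wl, spec_b.wavelengths_nm
    ):
        raise ValueError("spectra must share an identical wavelength grid")
    step = spec_a.step_nm
    n = int(round(window_nm / step))
    if n < 1 or n >= wl.size:
        raise ValueError("window width must fit inside the grid")
    diff = np.abs(spec_a.intensities - spec_b.intensities)
    # cumulative trapezoid: C[i] = integral over wl[0:i+1]
    seg = 0.5 * (diff[1:] + diff[:-1]) * step
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    scores = cum[n:] - cum[:-n]
    i = int(np.argmax(scores))  # argmax returns the first (leftmost) maximum
    return (float(wl[i]), float(wl[i] + n * step))


def expected_band_from_calcium(
    model: FluorophoreModel, criterion: SpectralCriterion | None = None
) -> Band:
    """Band a material's UVB peak is expected in, from composition alone.

    Bones, calcium carbonate powder, fingernails, and plastics sit in the
    short band.  Meat sits in the short band only while raw and only when
    its calcium content reaches the criterion (cooking leaches calcium and
    shifts the peak long).
    """
    if criterion is None:
        criterion = SpectralCriterion()
    if model.kind in (
        MaterialKind.BONE,
        MaterialKind.CALCIUM_POWDER,
        MaterialKind.FINGERNAIL,
        MaterialKind.PLASTIC,
    ):
        return Band.SHORT
    if (
        model.cooking_state is CookingState.RAW
        and model.calcium_mg_per_100g >= criterion.calcium_criterion_mg_per_100g
    ):
        return Band.SHORT
    return Band.LONG


# ---------------------------------------------------------------------------
# packaged material library


def _parse_material(entry: dict) -> FluorophoreModel:
    comps: dict[float, tuple[GaussianComponent, ...]] = {}
    for exc, items in entry["emission"].items():
        comps[float(exc)] = tuple(
            GaussianComponent(
                center_nm=float(c["center_nm"]),
                fwhm_nm=float(c["fwhm_nm"]),
                amplitude=float(c["amplitude"]),
            )
            for c in items
        )
    return FluorophoreModel(
        material_name=str(entry["name"]),
        kind=MaterialKind(entry["kind"]),
        cooking_state=CookingState(str(entry["cooking_state"])),
        calcium_mg_per_100g=float(entry["calcium_mg_per_100g"]),
        components=comps,
    )


@lru_cache(maxsize=1)
def load_fluorophores() -> Mapping[str, FluorophoreModel]:
    """Load the packaged fluorophore library (name -> model)."""
    text = (
        resources.files("flossguard").joinpath("data/fluorophores.yaml").read_text()
    )
    doc = yaml.safe_load(text)
    models = {}
    for entry in doc["materials"]:
        model = _parse_material(entry)
        models[model.material_name] = model
    return models


def material_names() -> tuple[str, ...]:
    return tuple(load_fluorophores())


def get_material(name: str) -> FluorophoreModel:
    models = load_fluorophores()
    try:
        return models[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; known: {', '.join(sorted(models))}"
        ) from None
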