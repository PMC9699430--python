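"""Seeded synthetic fluorescence scenes with per-object ground truth.

A scene emulates what the filter-mounted camera sees through the open bottom
of the optical box: a black food-grade vinyl sheet (near-zero background),
optionally a layer of weak, granular floss fluorescence, and bright objects
(bones, fillets, fingernails, glove fingers).  Each object's pixel level is
its material's in-band fluorescence signal — the 405/10 nm filtered emission
integral — scaled by a fixed counts-per-signal factor and by the object's
exposure fraction (0 = fully buried under floss, 1 = fully exposed).

Coverage is deliberately a scalar multiplier on signal, not a radiative
model: the physical system treats bones as either exposed or covered, and
the scalar generalizes that binary state.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import draw

from .detector import Frame
from .fluorospec import (
    BandpassFilterModel,
    FluorophoreModel,
    get_material,
    in_band_signal,
    simulate_emission,
)

__all__ = [
    "FlossBackground",
    "GroundTruth",
    "GroundTruthObject",
    "ObjectShape",
    "ObjectSpec",
    "RenderConfig",
    "SceneSpec",
    "floss_background_mean",
    "make_fixture_suite",
    "material_signal",
    "render",
]

#: Default spatial sampling: 0.125 mm per pixel, so the smallest bone the
#: plant cares about (1 mm x 5 mm) covers ~250 px — just above the 200-px
#: area rule — while a 1 mm floss grain covers ~50 px, well below it.
DEFAULT_PIXEL_PITCH_MM = 0.125

#: Camera counts per unit of in-band signal (counts x nm).  0.1 puts a fully
#: exposed bone near 40% of the 16-bit scale and the floss layer near 3%.
DEFAULT_SIGNAL_SCALE = 0.1

#: Relative amplitude of the smoothed floss granularity field.
TEXTURE_FRACTION = 0.35


class ObjectShape(str, enum.Enum):
    ELLIPSE = "ellipse"
    RECTANGLE = "rectangle"


@dataclass(frozen=True)
class ObjectSpec:
    """One object placed in a scene.

    ``width_mm`` is the across-axis extent, ``length_mm`` the along-axis
    extent; at orientation 0 the length runs along image columns.
    ``position_px`` is the (row, col) center.  ``exposure_fraction`` scales
    the in-band signal: 0 for a bone buried under floss, 1 for full exposure.
    """

    material: str
    width_mm: float
    length_mm: float
    position_px: tuple[float, float]
    shape: ObjectShape = ObjectShape.ELLIPSE
    orientation_deg: float = 0.0
    exposure_fraction: float = 1.0
    name: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", ObjectShape(self.shape))
        if not (self.width_mm > 0 and self.length_mm > 0):
            raise ValueError("object dimensions must be positive")
        if not (0.0 <= self.exposure_fraction <= 1.0):
            raise ValueError("exposure fraction must lie in [0, 1]")

    @property
    def label(self) -> str:
        return self.name if self.name is not None else self.material


@dataclass(frozen=True)
class FlossBackground:
    """Floss layer statistics: mean in-band signal level (camera counts),
    additive pixel noise, and the granularity length scale."""

    mean_signal: float = 0.0
    noise_sd: float = 100.0
    texture_scale_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.mean_signal < 0:
            raise ValueError("background mean must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise standard deviation must be nonnegative")
        if self.texture_scale_mm < 0:
            raise ValueError("texture scale must be nonnegative")


@dataclass(frozen=True)
class SceneSpec:
    """Declarative synthetic scene."""

    height_px: int = 512
    width_px: int = 512
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM
    seed: int = 0
    objects: tuple[ObjectSpec, ...] = ()
    floss_background: FlossBackground = field(default_factory=FlossBackground)
    excitation_nm: float = 310.0

    def __post_init__(self) -> None:
        if self.height_px < 64 or self.width_px < 64:
            raise ValueError("scene dimensions must be at least 64 px")
        if not self.pixel_pitch_mm > 0:
            raise ValueError("pixel pitch must be positive")
        object.__setattr__(self, "objects", tuple(self.objects))


@dataclass(frozen=True)
class RenderConfig:
    """Rendering and detectability parameters.

    ``signal_scale`` converts in-band signal (counts x nm) to camera counts.
    An object is labelled ``expected_detectable`` when its exposed rendered
    area strictly exceeds ``min_region_px`` and its exposure-scaled signal
    clears the floss background by ``contrast_margin_sd`` noise standard
    deviations plus the texture amplitude.
    """

    signal_scale: float = DEFAULT_SIGNAL_SCALE
    bit_depth: int = 16
    min_region_px: int = 200
    contrast_margin_sd: float = 5.0

    def __post_init__(self) -> None:
        if not self.signal_scale > 0:
            raise ValueError("signal scale must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit depth must be 8 or 16")


@dataclass(frozen=True)
class GroundTruthObject:
    name: str
    material: str
    kind: str
    mask: np.ndarray  # bool, scene-sized
    bbox: tuple[int, int, int, int]  # 0-based half-open
    area_px: int
    exposure_fraction: float
    signal_counts: float  # exposure-scaled object level above background
    expected_detectable: bool


@dataclass(frozen=True)
class GroundTruth:
    objects: tuple[GroundTruthObject, ...]
    background_mean: float
    noise_sd: float


def material_signal(
    material: str | FluorophoreModel,
    filter_model: BandpassFilterModel | None = None,
    excitation_nm: float = 310.0,
    signal_scale: float = DEFAULT_SIGNAL_SCALE,
) -> float:
    """Camera counts a fully exposed patch of a material produces."""
    if filter_model is None:
        filter_model = BandpassFilterModel()
    model = get_material(material) if isinstance(material, str) else material
    spectrum = simulate_emission(model, excitation_nm)
    return in_band_signal(spectrum, filter_model) * signal_scale


def floss_background_mean(
    material: str = "swordfish_floss",
    filter_model: BandpassFilterModel | None = None,
    excitation_nm: float = 310.0,
    signal_scale: float = DEFAULT_SIGNAL_SCALE,
) -> float:
    """Default floss-layer mean level: the floss material's own in-band
    signal on the camera scale."""
    return material_signal(material, filter_model, excitation_nm, signal_scale)


def _object_mask(obj: ObjectSpec, scene: SceneSpec) -> np.ndarray:
    h, w = scene.height_px, scene.width_px
    pitch = scene.pixel_pitch_mm
    r, c = obj.position_px
    half_len = obj.length_mm / 2.0 / pitch
    half_wid = obj.width_mm / 2.0 / pitch
    theta = math.radians(obj.orientation_deg)
    # extent check: rotated half-extents along rows/cols
    ext_r = abs(half_len * math.sin(theta)) + abs(half_wid * math.cos(theta))
    ext_c = abs(half_len * math.cos(theta)) + abs(half_wid * math.sin(theta))
    if r - ext_r < 0 or r + ext_r > h - 1 or c - ext_c < 0 or c + ext_c > w - 1:
        raise ValueError(
            f"object {obj.label!r} extends outside the {h}x{w} px frame"
        )
    mask = np.zeros((h, w), dtype=bool)
    if obj.shape is ObjectShape.ELLIPSE:
        rr, cc = draw.ellipse(
            r, c, half_wid, half_len, shape=(h, w), rotation=theta
        )
    else:
        # rectangle corners in (row, col), length along columns at theta = 0
        corners = np.array(
            [
                [-half_wid, -half_len],
                [-half_wid, half_len],
                [half_wid, half_len],
                [half_wid, -half_len],
            ]
        )
        rot = np.array(
            [[math.cos(theta), math.sin(theta)], [-math.sin(theta), math.cos(theta)]]
        )
        pts = corners @ rot.T + np.array([r, c])
        rr, cc = draw.polygon(pts[:, 0], pts[:, 1], shape=(h, w))
    mask[rr, cc] = True
    return mask


def render(
    scene: SceneSpec,
    filter_model: BandpassFilterModel | None = None,
    config: RenderConfig | None = None,
) -> tuple[Frame, GroundTruth]:
    """Render a scene to a quantized frame plus per-object ground truth.

    The per-pixel signal is floss background (granular texture) plus each
    object's exposure-scaled in-band signal over its mask, plus additive
    Gaussian noise, clipped to [0, full scale] and quantized.  Identical
    (scene, seed) inputs give bit-identical frames.
    """
    if filter_model is None:
        filter_model = BandpassFilterModel()
    if config is None:
        config = RenderConfig()
    h, w = scene.height_px, scene.width_px
    rng = np.random.default_rng(scene.seed)
    bg = scene.floss_background

    # floss granularity: smoothed unit-variance field around the mean level;
    # texture_scale_mm = 0 disables granularity entirely
    field_img = np.full((h, w), bg.mean_signal, dtype=np.float64)
    if bg.mean_signal > 0 and bg.texture_scale_mm > 0:
        texture = rng.standard_normal((h, w))
        sigma_px = bg.texture_scale_mm / scene.pixel_pitch_mm / 2.0
        texture = ndimage.gaussian_filter(texture, sigma_px)
        sd = texture.std()
        if sd > 0:
            texture = texture / sd
        field_img *= np.clip(1.0 + TEXTURE_FRACTION * texture, 0.0, None)

    gt_objects = []
    for obj in scene.objects:
        mask = _object_mask(obj, scene)
        model = get_material(obj.material)
        signal = material_signal(
            model, filter_model, scene.excitation_nm, config.signal_scale
        )
        level = signal * obj.exposure_fraction
        field_img[mask] += level
        area = int(mask.sum())
        rows, cols = np.nonzero(mask)
        if area:
            bbox = (
                int(rows.min()),
                int(cols.min()),
                int(rows.max()) + 1,
                int(cols.max()) + 1,
            )
        else:
            bbox = (0, 0, 1, 1)
        required = (
            config.contrast_margin_sd * bg.noise_sd
            + TEXTURE_FRACTION * bg.mean_signal
        )
        detectable = (
            obj.exposure_fraction > 0
            and area > config.min_region_px
            and level > required
        )
        gt_objects.append(
            GroundTruthObject(
                name=obj.label,
                material=model.material_name,
                kind=model.kind.value,
                mask=mask,
                bbox=bbox,
                area_px=area,
                exposure_fraction=obj.exposure_fraction,
                signal_counts=level,
                expected_detectable=detectable,
            )
        )

    if bg.noise_sd > 0:
        field_img = field_img + rng.normal(0.0, bg.noise_sd, size=(h, w))
    max_value = (1 << config.bit_depth) - 1
    quantized = np.clip(np.rint(field_img), 0, max_value)
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    frame = Frame(
        pixels=quantized.astype(dtype),
        bit_depth=config.bit_depth,
        pixel_pitch_mm=scene.pixel_pitch_mm,
    )
    truth = GroundTruth(
        objects=tuple(gt_objects),
        background_mean=bg.mean_signal,
        noise_sd=bg.noise_sd,
    )
    return frame, truth


# ---------------------------------------------------------------------------
# canonical fixture scenes


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def make_fixture_suite(
    seed: int = 0,
    filter_model: BandpassFilterModel | None = None,
    config: RenderConfig | None = None,
) -> dict[str, tuple[Frame, GroundTruth, SceneSpec]]:
    """The canonical test scenes, deterministic for a given seed.

    Covers: floss alone; each raw fillet alone on the black sheet; one bone
    on top of floss; one bone fully buried under floss; a fingernail trio
    with a bone; and a three-finger glove scene for each plastic.
    """
    seeds = _child_seeds(seed, 12)
    floss_mean = floss_background_mean(filter_model=filter_model)
    floss_bg = FlossBackground(mean_signal=floss_mean)
    black_bg = FlossBackground(mean_signal=0.0)
    suite: dict[str, tuple[Frame, GroundTruth, SceneSpec]] = {}

    def add(name: str, scene: SceneSpec) -> None:
        frame, truth = render(scene, filter_model, config)
        suite[name] = (frame, truth, scene)

    add(
        "floss_only",
        SceneSpec(seed=seeds[0], floss_background=floss_bg),
    )
    for i, fish in enumerate(("swordfish", "salmon", "tuna", "cod")):
        fillet = ObjectSpec(
            material=f"{fish}_raw",
            shape=ObjectShape.RECTANGLE,
            width_mm=15.0,
            length_mm=15.0,
            position_px=(256.0, 256.0),
            name=f"{fish}_fillet",
        )
        add(
            f"raw_{fish}_fillet",
            SceneSpec(
                seed=seeds[1 + i],
                objects=(fillet,),
                floss_background=black_bg,
            ),
        )
    bone = ObjectSpec(
        material="swordfish_bone",
        width_mm=4.0,
        length_mm=14.0,
        position_px=(256.0, 256.0),
        orientation_deg=30.0,
        name="bone",
    )
    add(
        "bone_on_floss",
        SceneSpec(seed=seeds[5], objects=(bone,), floss_background=floss_bg),
    )
    add(
        "bone_under_floss",
        SceneSpec(
            seed=seeds[6],
            objects=(replace(bone, exposure_fraction=0.0),),
            floss_background=floss_bg,
        ),
    )
    nails = tuple(
        ObjectSpec(
            material="fingernail",
            width_mm=9.0,
            length_mm=11.0,
            position_px=(150.0, 140.0 + 120.0 * k),
            name=f"fingernail_{k}",
        )
        for k in range(3)
    )
    add(
        "fingernail_trio",
        SceneSpec(
            seed=seeds[7],
            objects=nails + (replace(bone, position_px=(360.0, 256.0)),),
            floss_background=black_bg,
        ),
    )
    for j, plastic in enumerate(("pvc", "emu", "rubber")):
        fingers = tuple(
            ObjectSpec(
                material=plastic,
                shape=ObjectShape.RECTANGLE,
                width_mm=13.0,
                length_mm=45.0,
                position_px=(256.0, 130.0 + 126.0 * k),
                orientation_deg=90.0,
                name=f"{plastic}_finger_{k}",
            )
            for k in range(3)
        )
        add(
            f"glove_{plastic}",
            SceneSpec(
                seed=seeds[8 + j],
                objects=fingers
            + (replace(bone, position_px=(470.0, 256.0), orientation_deg=0.0),),
                floss_background=black_bg,
            ),
        )
    return suite
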