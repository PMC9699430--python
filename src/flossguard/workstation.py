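"""Discrete-time simulation of the vibrating tilt-plate inspection line.

A run processes a mixture of fish bones and floss scoop by scoop (one
300 mL dipper at a time).  While the vibration motor runs, material advances
along the tilted plate and passes under the optical box, where two
separation mechanisms can expose a buried bone to the camera: air separation
(the dominant one — vibration momentarily spaces floss and bone in mid-air)
and downstream separation (density-driven segregation along the plate).
Each imaging pass renders the under-box region as a synthetic scene and runs
the marker detector; any marker stops the motor, the operator removes the
marked bones, and vibration restarts once the markers disappear.  Bones that
stay covered through their pass under the box flow into the collection box
undetected.

Time is discretized into imaging passes; the physical system's
millisecond-scale imaging versus minutes-scale manual removal appear only as
events in the timeline log.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass


import numpy as np

from .detector import (
    DetectionResult,
    DetectorConfig,
    MotorCommand,
    detect,
)
from .fluorospec import BandpassFilterModel
from .scenegen import (
    FlossBackground,
    GroundTruth,
    ObjectSpec,
    RenderConfig,
    SceneSpec,
    floss_background_mean,
    render,
)

__all__ = [
    "BonePosition",
    "BoneState",
    "ExposureState",
    "MixtureState",
    "RunReport",
    "SeparationMeasurement",
    "VibrationParams",
    "controller_update",
    "imaging_pass",
    "init_mixture",
    "measure_air_separation",
    "remove_marked",
    "run_full_test",
    "separation_efficiency",
    "step",
]

#: Assumed bulk density of the floss mixture, g per mL, used to convert the
#: 300 mL dipper into scooped mass.
MIXTURE_DENSITY_G_PER_ML = 1.0

#: Under-box imaging frame, pixels (320 px at 0.125 mm/px = 40 mm across).
PASS_FRAME_PX = 320


class BonePosition(str, enum.Enum):
    HOPPER = "hopper"
    PLATE_UPSTREAM = "plate_upstream"
    PLATE_UNDER_BOX = "plate_under_box"
    EXITED = "exited"
    REMOVED = "removed"


class ExposureState(str, enum.Enum):
    COVERED = "COVERED"
    AIR_EXPOSED = "AIR_EXPOSED"
    DOWNSTREAM_EXPOSED = "DOWNSTREAM_EXPOSED"


@dataclass
class BoneState:
    bone_id: int
    width_mm: float
    length_mm: float
    position: BonePosition = BonePosition.HOPPER
    exposure: ExposureState = ExposureState.COVERED
    detected: bool = False
    lost_after_detection: bool = False


@dataclass(frozen=True)
class Scoop:
    index: int
    bone_ids: tuple[int, ...]
    floss_g: float


@dataclass
class MixtureState:
    """Contents of one test mixture while it is being processed."""

    bones: list[BoneState]
    floss_mass_g: float
    scoop_queue: list[Scoop]
    plate_floss_g: float = 0.0
    exited_floss_g: float = 0.0

    def __post_init__(self) -> None:
        ids = [b.bone_id for b in self.bones]
        if len(ids) != len(set(ids)):
            raise ValueError("bone ids must be unique")

    def bones_at(self, position: BonePosition) -> list[BoneState]:
        return [b for b in self.bones if b.position is position]

    def bone(self, bone_id: int) -> BoneState:
        for b in self.bones:
            if b.bone_id == bone_id:
                return b
        raise KeyError(f"no bone with id {bone_id}")


@dataclass(frozen=True)
class VibrationParams:
    """Behavioural parameters of the vibration unit.

    ``p_air_expose`` is the probability that a covered bone under the optical
    box becomes air-exposed during one vibrating step; the default of 1.0
    encodes the observation that air separation exposed every bone in every
    physical test.  ``downstream_expose_range`` bounds how many bones per
    test the downstream mechanism exposes.  ``p_inertial_loss`` is the
    chance a detected bone slides off the plate into the collection box
    before the operator reaches it.
    """

    p_air_expose: float = 1.0
    downstream_expose_range: tuple[int, int] = (1, 5)
    p_inertial_loss: float = 0.0
    scoop_volume_ml: float = 300.0
    repetition_interval_s: float = 60.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_air_expose <= 1.0):
            raise ValueError("p_air_expose must be in [0, 1]")
        if not (0.0 <= self.p_inertial_loss <= 1.0):
            raise ValueError("p_inertial_loss must be in [0, 1]")
        lo, hi = self.downstream_expose_range
        if lo < 0 or hi < lo:
            raise ValueError("downstream_expose_range must be a valid interval")
        if not self.scoop_volume_ml > 0:
            raise ValueError("scoop volume must be positive")


@dataclass(frozen=True)
class SeparationMeasurement:
    """Separation efficiency Ia/I0: mean in-band bone fluorescence under air
    separation, normalized by the uncovered-bone value."""

    i0: float
    ia: float
    efficiency: float
    clamped: bool = False


@dataclass(frozen=True)
class RunReport:
    bones_total: int
    bones_detected: int
    bones_removed: int
    bones_lost_after_detection: int
    bones_exited_undetected: int
    downstream_exposed: int
    accuracy_pct: float | None
    seed: int
    n_scoops: int
    timeline: tuple[dict, ...] = ()

    @property
    def accuracy_defined(self) -> bool:
        return self.accuracy_pct is not None


# ---------------------------------------------------------------------------
# operations


def init_mixture(
    n_bones: int,
    floss_g: float,
    seed: int | np.random.Generator = 0,
    params: VibrationParams | None = None,
) -> MixtureState:
    """Assemble a test mixture and partition it into 300 mL scoops.

    Bones are assigned to scoops multinomially, proportionally to scooped
    mass; sizes are drawn uniformly from the plant's bone size range
    (width 1-10 mm, length 5-20 mm).  Deterministic for a given seed.
    """
    if n_bones < 0 or floss_g < 0:
        raise ValueError("mixture quantities must be nonnegative")
    if params is None:
        params = VibrationParams()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    scoop_mass = params.scoop_volume_ml * MIXTURE_DENSITY_G_PER_ML
    n_scoops = max(1, math.ceil(floss_g / scoop_mass)) if floss_g > 0 else 1
    masses = np.full(n_scoops, scoop_mass)
    if floss_g > 0:
        masses[-1] = floss_g - scoop_mass * (n_scoops - 1)
    else:
        masses[:] = 0.0
    probs = masses / masses.sum() if masses.sum() > 0 else np.full(n_scoops, 1.0 / n_scoops)
    counts = rng.multinomial(n_bones, probs) if n_bones else np.zeros(n_scoops, int)
    bones = []
    scoops = []
    next_id = 0
    for i in range(n_scoops):
        ids = []
        for _ in range(int(counts[i])):
            width = rng.uniform(1.0, 10.0)
            length = rng.uniform(5.0, 20.0)
            bones.append(BoneState(next_id, width_mm=width, length_mm=length))
            ids.append(next_id)
            next_id += 1
        scoops.append(Scoop(index=i, bone_ids=tuple(ids), floss_g=float(masses[i])))
    return MixtureState(bones=bones, floss_mass_g=float(floss_g), scoop_queue=scoops)


def step(
    state: MixtureState,
    params: VibrationParams,
    motor: MotorCommand,
    rng: np.random.Generator,
) -> MixtureState:
    """Advance the plate by one vibrating interval (in place).

    While the motor runs, upstream material moves under the optical box,
    material already under the box flows off into the collection box, and
    covered bones under the box become air-exposed with ``p_air_expose``.
    While the motor is stopped, every position freezes.  Stepping an empty
    state is a no-op.
    """
    if motor is MotorCommand.STOP:
        return state
    # under-box material exits first, then upstream material moves in
    for bone in state.bones_at(BonePosition.PLATE_UNDER_BOX):
        bone.position = BonePosition.EXITED
    state.exited_floss_g += state.plate_floss_g
    state.plate_floss_g = 0.0
    for bone in state.bones_at(BonePosition.PLATE_UPSTREAM):
        bone.position = BonePosition.PLATE_UNDER_BOX
        # air separation lifts everything under the box, including bones
        # that already surfaced downstream
        if (
            bone.exposure is not ExposureState.AIR_EXPOSED
            and rng.random() < params.p_air_expose
        ):
            bone.exposure = ExposureState.AIR_EXPOSED
    return state


def imaging_pass(
    state: MixtureState,
    seed: int,
    detector_config: DetectorConfig | None = None,
    filter_model: BandpassFilterModel | None = None,
    render_config: RenderConfig | None = None,
    bone_material: str = "swordfish_bone",
) -> tuple[DetectionResult, GroundTruth]:
    """Render the under-box region and run the marker detector.

    Exposed bones render with exposure fraction 1, covered bones with 0;
    the floss layer is always present.  Bone placement inside the frame is
    deterministic for the given seed.
    """
    if detector_config is None:
        detector_config = DetectorConfig()
    rng = np.random.default_rng(seed)
    bones = state.bones_at(BonePosition.PLATE_UNDER_BOX)
    objects = []
    margin = 90.0  # keeps the longest bone (20 mm = 160 px) inside the frame
    for bone in bones:
        row = rng.uniform(margin, PASS_FRAME_PX - margin)
        col = rng.uniform(margin, PASS_FRAME_PX - margin)
        theta = rng.uniform(0.0, 180.0)
        objects.append(
            ObjectSpec(
                material=bone_material,
                width_mm=bone.width_mm,
                length_mm=bone.length_mm,
                position_px=(row, col),
                orientation_deg=theta,
                exposure_fraction=(
                    0.0 if bone.exposure is ExposureState.COVERED else 1.0
                ),
                name=f"bone_{bone.bone_id}",
            )
        )
    scene = SceneSpec(
        height_px=PASS_FRAME_PX,
        width_px=PASS_FRAME_PX,
        seed=int(rng.integers(1 << 31)),
        objects=tuple(objects),
        floss_background=FlossBackground(
            mean_signal=floss_background_mean(filter_model=filter_model)
        ),
    )
    frame, truth = render(scene, filter_model, render_config)
    result = detect(frame, detector_config)
    return result, truth


def controller_update(motor: MotorCommand, result: DetectionResult) -> MotorCommand:
    """Marker-triggered motor logic: STOP while any marker is on screen,
    RUN as soon as the screen is clear.  Pure function of its inputs."""
    del motor  # the decision depends only on the current detection
    return MotorCommand.STOP if result.markers else MotorCommand.RUN


def remove_marked(
    state: MixtureState,
    result: DetectionResult,
    truth: GroundTruth,
    params: VibrationParams,
    rng: np.random.Generator,
) -> list[int]:
    """Operator removes every bone whose ground-truth box intersects a
    marker rectangle; with ``p_inertial_loss`` a detected bone instead
    slides off the plate into the collection box before it can be grabbed.
    Returns the ids of bones detected in this pass."""
    name_to_obj = {o.name: o for o in truth.objects}
    detected_ids = []
    for bone in state.bones_at(BonePosition.PLATE_UNDER_BOX):
        obj = name_to_obj.get(f"bone_{bone.bone_id}")
        if obj is None:
            continue
        if any(m.intersects(obj.bbox) for m in result.markers):
            bone.detected = True
            detected_ids.append(bone.bone_id)
            if rng.random() < params.p_inertial_loss:
                bone.lost_after_detection = True
                bone.position = BonePosition.EXITED
            else:
                bone.position = BonePosition.REMOVED
    return detected_ids


def separation_efficiency(ia: float, i0: float) -> float:
    """Ia/I0 — mean detected bone fluorescence under air separation over the
    uncovered value.  Ratios above 1 (measurement noise) are clamped to 1
    with a warning."""
    if not i0 > 0:
        raise ValueError("I0 must be positive")
    if ia < 0:
        raise ValueError("Ia must be nonnegative")
    ratio = ia / i0
    if ratio > 1.0:
        warnings.warn(
            "separation efficiency above 1 (measurement noise); clamping",
            stacklevel=2,
        )
        return 1.0
    return ratio


def measure_air_separation(
    exposure_fraction: float,
    bone_material: str = "swordfish_bone",
    filter_model: BandpassFilterModel | None = None,
    seed: int = 0,
) -> SeparationMeasurement:
    """Measure Ia/I0 on noise-free renders of one bone.

    I0 is the mean in-band pixel intensity over the bone mask with no cover
    (exposure 1); Ia is the same with the given air-separation exposure.
    """
    def bone_scene(exposure: float) -> tuple:
        scene = SceneSpec(
            height_px=256,
            width_px=256,
            seed=seed,
            objects=(
                ObjectSpec(
                    material=bone_material,
                    width_mm=4.0,
                    length_mm=14.0,
                    position_px=(128.0, 128.0),
                    exposure_fraction=exposure,
                    name="bone",
                ),
            ),
            floss_background=FlossBackground(mean_signal=0.0, noise_sd=0.0),
        )
        return render(scene, filter_model)

    frame0, truth0 = bone_scene(1.0)
    frame_a, truth_a = bone_scene(exposure_fraction)
    mask = truth0.objects[0].mask
    i0 = float(frame0.pixels[mask].mean())
    ia = float(frame_a.pixels[mask].mean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eff = separation_efficiency(ia, i0) if i0 > 0 else 0.0
    return SeparationMeasurement(i0=i0, ia=ia, efficiency=eff, clamped=ia > i0)


def run_full_test(
    n_bones: int = 20,
    floss_g: float = 2000.0,
    params: VibrationParams | None = None,
    seed: int = 0,
    detector_config: DetectorConfig | None = None,
    filter_model: BandpassFilterModel | None = None,
    render_config: RenderConfig | None = None,
    max_passes_per_scoop: int = 50,
) -> RunReport:
    """One complete workstation test: scoop, vibrate, image, stop on
    markers, remove, restart, until the mixture is exhausted.

    All randomness derives from ``seed`` through named substreams, so the
    report (including the timeline) is exactly reproducible.
    """
    if params is None:
        params = VibrationParams()
    ss = np.random.SeedSequence(seed)
    rng_mix, rng_down, rng_air, rng_scene, rng_removal = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    state = init_mixture(n_bones, floss_g, rng_mix, params)
    timeline: list[dict] = []
    t = 0

    # downstream separation: a per-test number of bones in the configured
    # range surfaces through density segregation along the plate
    lo, hi = params.downstream_expose_range
    n_down = 0
    if n_bones > 0 and hi > 0:
        lo_eff = min(max(lo, 1), n_bones)
        hi_eff = min(hi, n_bones)
        n_down = int(rng_down.integers(lo_eff, hi_eff + 1))
        down_ids = set(
            rng_down.choice([b.bone_id for b in state.bones], n_down, replace=False)
        )
    else:
        down_ids = set()

    for scoop in state.scoop_queue:
        t += 1
        timeline.append(
            {"t": t, "event": "scoop", "scoop": scoop.index, "floss_g": scoop.floss_g}
        )
        for bone_id in scoop.bone_ids:
            bone = state.bone(bone_id)
            bone.position = BonePosition.PLATE_UPSTREAM
            if bone_id in down_ids:
                bone.exposure = ExposureState.DOWNSTREAM_EXPOSED
                timeline.append(
                    {"t": t, "event": "expose", "mechanism": "downstream",
                     "bone": bone_id}
                )
        state.plate_floss_g += scoop.floss_g
        motor = MotorCommand.RUN

        passes = 0
        while True:
            passes += 1
            if passes > max_passes_per_scoop:
                raise RuntimeError("scoop did not clear the plate; check params")
            before_covered = {
                b.bone_id
                for b in state.bones
                if b.exposure is not ExposureState.AIR_EXPOSED
            }
            step(state, params, motor, rng_air)
            t += 1
            for b in state.bones_at(BonePosition.PLATE_UNDER_BOX):
                if (
                    b.bone_id in before_covered
                    and b.exposure is ExposureState.AIR_EXPOSED
                ):
                    timeline.append(
                        {"t": t, "event": "expose", "mechanism": "air",
                         "bone": b.bone_id}
                    )
            under_box = state.bones_at(BonePosition.PLATE_UNDER_BOX)
            if not under_box and state.plate_floss_g == 0.0:
                break
            result, truth = imaging_pass(
                state,
                seed=int(rng_scene.integers(1 << 31)),
                detector_config=detector_config,
                filter_model=filter_model,
                render_config=render_config,
            )
            timeline.append(
                {"t": t, "event": "detect", "markers": len(result.markers),
                 "threshold": result.threshold_used}
            )
            new_motor = controller_update(motor, result)
            if new_motor is MotorCommand.STOP:
                if motor is not MotorCommand.STOP:
                    timeline.append({"t": t, "event": "stop"})
                detected = remove_marked(state, result, truth, params, rng_removal)
                for bone_id in detected:
                    bone = state.bone(bone_id)
                    timeline.append(
                        {
                            "t": t,
                            "event": "remove" if not bone.lost_after_detection
                            else "exit",
                            "bone": bone_id,
                            "lost": bone.lost_after_detection,
                        }
                    )
                # marked bones are gone, so the markers have cleared and
                # the controller restarts the motor for the next interval
                motor = MotorCommand.RUN
                timeline.append({"t": t, "event": "restart"})
            else:
                motor = MotorCommand.RUN

    detected = sum(b.detected for b in state.bones)
    removed = sum(b.position is BonePosition.REMOVED for b in state.bones)
    lost = sum(b.lost_after_detection for b in state.bones)
    exited_undetected = sum(
        b.position is BonePosition.EXITED and not b.detected for b in state.bones
    )
    accuracy = 100.0 * detected / n_bones if n_bones > 0 else None
    return RunReport(
        bones_total=n_bones,
        bones_detected=detected,
        bones_removed=removed,
        bones_lost_after_detection=lost,
        bones_exited_undetected=exited_undetected,
        downstream_exposed=n_down,
        accuracy_pct=accuracy,
        seed=seed,
        n_scoops=len(state.scoop_queue),
        timeline=tuple(timeline),
    )
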