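"""High-level study scenarios: the cumulative voltage-sweep experiment.

The reference protocol applies seven pulse trains of increasing amplitude
(45, 85, 125, 170, 210, 255, 300 V) to the same field of view — 100 pulses
of 5 µs at 10 Hz per train, i.e. a 10 s treatment period each — so that
effects accumulate across trains.  These builders assemble the synthetic
scene, protocol sequence and imaging settings for that experiment, run the
simulator, and push the result through the analysis pipeline, which is what
parameter-recovery studies (can the pipeline recover the 210 V detachment
threshold implied by the force balance?) are built on.

Scenario geometry: the anode-side electrode edge sits inside the field of
view (the field plateau covers the left part of the frame and decays to the
right), matching the imaging geometry of the experiment where the electrode
border projections are visible in-frame and the upper-right corner of the
frame lies far enough beyond the gap that its filaments never detach — that
corner serves as the gain-reference background region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .electromechanics import (
    FieldCalibration,
    PulseProtocol,
    antibody_linear_density_at_detachment,
    field_from_voltage,
)
from .simulate import (
    FilamentScene,
    GroundTruth,
    ImagingParams,
    MotionModel,
    frame_shape,
    generate_scene,
)
from .simulate import simulate_experiment as _simulate
from .stack import ImageStack, RegionSpec

__all__ = [
    "SWEEP_VOLTAGES",
    "SweepDesign",
    "sweep_protocols",
    "default_calibration",
    "default_anchor_density_mean",
    "build_sweep_scene",
    "simulate_sweep",
]

SWEEP_VOLTAGES: tuple[float, ...] = (45.0, 85.0, 125.0, 170.0, 210.0, 255.0, 300.0)

F_AB_DEFAULT = 50e-12  # N per antibody


def default_anchor_density_mean(detach_voltage: float = 210.0,
                                f_ab: float = F_AB_DEFAULT) -> float:
    """Mean anchoring density (per µm) implied by the force balance.

    The population mean is pinned to the density at which a filament would
    detach exactly at ``detach_voltage`` in the plateau field (~209.6/µm for
    210 V with default constants), so roughly half the network releases at
    that train and the rest at the next.
    """
    return antibody_linear_density_at_detachment(field_from_voltage(detach_voltage),
                                                 f_ab=f_ab)


def default_calibration(fov_width_um: float = 60.0) -> FieldCalibration:
    """Gap geometry placing the anode-side electrode edge inside the FOV.

    The plateau ends at ~47% of the frame width; beyond it the field decays
    with the default 50 µm length scale, leaving the upper-right corner
    (>= 85% of the width) below the detachment balance even at 300 V.
    """
    edge_x = round(0.47 * fov_width_um)
    return FieldCalibration(gap_start_um=edge_x - 60.0, gap_width_um=60.0,
                            decay_length_um=50.0)


def sweep_protocols(
    voltages: Sequence[float] = SWEEP_VOLTAGES,
    pre_roll_s: float = 4.0,
    gap_s: float = 3.0,
    pulse_width_s: float = 5e-6,
    n_pulses: int = 100,
    repetition_rate_hz: float = 10.0,
) -> list[PulseProtocol]:
    """Cumulative pulse-train sequence: one train per voltage, in order."""
    protocols = []
    t = pre_roll_s
    for v in voltages:
        p = PulseProtocol(amplitude_v=v, pulse_width_s=pulse_width_s,
                          n_pulses=n_pulses, repetition_rate_hz=repetition_rate_hz,
                          start_time_s=t)
        protocols.append(p)
        t = p.end_time_s + gap_s
    return protocols


@dataclass(frozen=True)
class SweepDesign:
    """Everything needed to simulate and analyse one sweep run."""

    scene: FilamentScene
    protocols: tuple[PulseProtocol, ...]
    calibration: FieldCalibration
    motion: MotionModel
    imaging: ImagingParams
    f_ab: float
    duration_s: float
    regions: RegionSpec


def build_sweep_scene(
    seed: int,
    density_per_um2: float = 0.25,
    fov_um: tuple[float, float] = (60.0, 40.0),
    anchor_density_mean: float | None = None,
    crowding: bool = True,
    voltages: Sequence[float] = SWEEP_VOLTAGES,
    imaging: ImagingParams | None = None,
    motion: MotionModel | None = None,
    f_ab: float = F_AB_DEFAULT,
    pre_roll_s: float = 4.0,
    gap_s: float = 3.0,
) -> SweepDesign:
    """Assemble scene + protocols + imaging for one cumulative sweep run."""
    if anchor_density_mean is None:
        anchor_density_mean = default_anchor_density_mean(f_ab=f_ab)
    scene = generate_scene(
        density_per_um2=density_per_um2,
        fov_um=fov_um,
        anchor_density_mean=anchor_density_mean,
        crowding=crowding,
        seed=seed,
    )
    imaging = imaging or ImagingParams()
    motion = motion or MotionModel()
    protocols = tuple(sweep_protocols(voltages, pre_roll_s=pre_roll_s, gap_s=gap_s))
    duration = protocols[-1].end_time_s + gap_s
    regions = RegionSpec.default_for_shape(frame_shape(fov_um, imaging))
    return SweepDesign(
        scene=scene,
        protocols=protocols,
        calibration=default_calibration(fov_um[0]),
        motion=motion,
        imaging=imaging,
        f_ab=f_ab,
        duration_s=duration,
        regions=regions,
    )


def simulate_sweep(design: SweepDesign, seed: int) -> tuple[ImageStack, GroundTruth]:
    """Run the simulator for an assembled sweep design."""
    return _simulate(
        scene=design.scene,
        protocols=design.protocols,
        calibration=design.calibration,
        motion=design.motion,
        f_ab=design.f_ab,
        imaging=design.imaging,
        duration_s=design.duration_s,
        seed=seed,
    )
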