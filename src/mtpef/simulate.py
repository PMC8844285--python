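"""Synthetic TIRF time-lapse generator with exact ground truth.

The generator emulates the statistical structure of a µs-PEF experiment on a
dense, antibody-anchored microtubule network imaged by TIRF microscopy:

* a dense, partially aligned network of straight filaments with per-filament
  antibody anchoring drawn from a Poisson law (anchoring is statistically
  determined by the antibody surface density);
* pulse-train-driven dynamics: a bound filament detaches once the local
  electrophoretic force per unit length exceeds its anchoring force per unit
  length (``E * rho_MT > anchor_density * f_ab``); detached (mobile)
  filaments drift toward the anode during pulse-on time, arrest where the
  field profile drops below a threshold, and — without a crowding agent —
  leave the imaging plane with a fixed per-frame probability;
* camera artifacts: Gaussian PSF, planar background gradient, Poisson shot
  noise, Gaussian read noise, and a slow multiplicative auto-gain drift.

Detachment is permanent, so effects accumulate over a sequence of trains of
increasing voltage, and every state transition is recorded in an exact
``GroundTruth`` table that downstream analyses can be validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .electromechanics import FieldCalibration, PulseProtocol, mt_linear_charge_density
from .exceptions import InvalidParameterError, InvalidProtocolError
from .stack import ImageStack

__all__ = [
    "STATE_BOUND",
    "STATE_MOBILE",
    "STATE_ARRESTED",
    "STATE_DEPARTED",
    "STATE_NAMES",
    "Filament",
    "FilamentScene",
    "ImagingParams",
    "MotionModel",
    "GroundTruth",
    "generate_scene",
    "render_frame",
    "simulate_experiment",
]

STATE_BOUND, STATE_MOBILE, STATE_ARRESTED, STATE_DEPARTED = 0, 1, 2, 3
STATE_NAMES = {
    STATE_BOUND: "bound",
    STATE_MOBILE: "mobile",
    STATE_ARRESTED: "arrested",
    STATE_DEPARTED: "departed",
}
# allowed transitions: bound->mobile, mobile->arrested, mobile->departed
_ALLOWED = {(STATE_BOUND, STATE_MOBILE),
            (STATE_MOBILE, STATE_ARRESTED),
            (STATE_MOBILE, STATE_DEPARTED)}


@dataclass(frozen=True)
class Filament:
    """Single-filament view of the scene state (µm, lab frame)."""

    id: int
    endpoints: np.ndarray  # (2, 2): two (x, y) points
    length_um: float
    anchor_density: float  # antibodies per µm
    state: str
    intensity_per_um: float


@dataclass
class FilamentScene:
    """Vectorised state of every filament in the field of view.

    ``endpoints`` has shape (n, 2, 2) — filament, endpoint, (x, y) in µm.
    ``gap_axis`` is the unit direction of the electric field vector, pointing
    toward the anode (filaments drift along +gap_axis when mobile).
    Endpoints may lie partly outside the field of view; clipping happens at
    render time.
    """

    endpoints: np.ndarray
    anchor_density: np.ndarray
    intensity_per_um: np.ndarray
    states: np.ndarray
    fov_um: tuple[float, float]
    gap_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    alignment_kappa: float = 2.0
    crowding: bool = True

    def __post_init__(self) -> None:
        self.endpoints = np.asarray(self.endpoints, dtype=float).reshape(-1, 2, 2)
        self.anchor_density = np.asarray(self.anchor_density, dtype=float)
        self.intensity_per_um = np.asarray(self.intensity_per_um, dtype=float)
        self.states = np.asarray(self.states, dtype=np.int8)
        n = len(self.endpoints)
        for arr, name in ((self.anchor_density, "anchor_density"),
                          (self.intensity_per_um, "intensity_per_um"),
                          (self.states, "states")):
            if arr.shape != (n,):
                raise InvalidParameterError(f"{name} must have one entry per filament")
        if np.any(self.anchor_density < 0):
            raise InvalidParameterError("anchor densities must be >= 0")
        if self.fov_um[0] <= 0 or self.fov_um[1] <= 0:
            raise InvalidParameterError("field of view must be positive")
        axis = np.asarray(self.gap_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise InvalidParameterError("gap axis must be a nonzero direction")
        self.gap_axis = axis / norm

    def __len__(self) -> int:
        return len(self.endpoints)

    @property
    def lengths_um(self) -> np.ndarray:
        return np.linalg.norm(self.endpoints[:, 1] - self.endpoints[:, 0], axis=1)

    @property
    def midpoints_um(self) -> np.ndarray:
        return self.endpoints.mean(axis=1)

    def filament(self, i: int) -> Filament:
        return Filament(
            id=i,
            endpoints=self.endpoints[i].copy(),
            length_um=float(self.lengths_um[i]),
            anchor_density=float(self.anchor_density[i]),
            state=STATE_NAMES[int(self.states[i])],
            intensity_per_um=float(self.intensity_per_um[i]),
        )

    def copy(self) -> "FilamentScene":
        return FilamentScene(
            endpoints=self.endpoints.copy(),
            anchor_density=self.anchor_density.copy(),
            intensity_per_um=self.intensity_per_um.copy(),
            states=self.states.copy(),
            fov_um=self.fov_um,
            gap_axis=self.gap_axis.copy(),
            alignment_kappa=self.alignment_kappa,
            crowding=self.crowding,
        )

    def set_state(self, idx, new_state: int) -> None:
        """Transition filaments ``idx`` to ``new_state`` (legality-checked)."""
        idx = np.atleast_1d(idx)
        for old in np.unique(self.states[idx]):
            if int(old) != new_state and (int(old), new_state) not in _ALLOWED:
                raise InvalidParameterError(
                    f"illegal transition {STATE_NAMES[int(old)]} -> {STATE_NAMES[new_state]}"
                )
        self.states[idx] = new_state


@dataclass(frozen=True)
class ImagingParams:
    """Camera/optics parameters of the synthetic TIRF acquisition."""

    pixel_size_um: float = 0.217  # 13 µm camera pixel / 60x objective
    frame_rate: float = 2.47
    psf_sigma_um: float = 0.30
    background_level: float = 150.0  # counts
    background_gradient: tuple[float, float] = (0.4, 0.25)  # counts/µm along (x, y)
    shot_noise: bool = True
    read_noise_sigma: float = 6.0  # counts
    gain_drift_sigma: float = 0.01  # lognormal step per frame
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.frame_rate <= 0:
            raise InvalidParameterError("pixel size and frame rate must be > 0")
        if self.psf_sigma_um < 0 or self.read_noise_sigma < 0 or self.gain_drift_sigma < 0:
            raise InvalidParameterError("noise/PSF parameters must be >= 0")
        if self.bit_depth not in (8, 16):
            raise InvalidParameterError("bit depth must be 8 or 16")

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class MotionModel:
    """Electrophoretic drift and arrest/departure rules for mobile filaments.

    ``mobility_um_per_s_per_kv_cm`` converts local field strength into drift
    speed during pulse-on time only; the default (800) makes a mobile
    filament cross ~10 µm during one 100-pulse train at 300 V.  Filaments
    arrest where the field profile falls below ``arrest_field_kv_cm``
    (accumulation at the weak-field margin); without crowding, mobile
    filaments leave the imaging plane with ``depart_probability`` per frame.
    """

    mobility_um_per_s_per_kv_cm: float = 800.0
    arrest_field_kv_cm: float = 3.0
    depart_probability: float = 0.15

    def __post_init__(self) -> None:
        if self.mobility_um_per_s_per_kv_cm < 0 or self.arrest_field_kv_cm < 0:
            raise InvalidParameterError("mobility and arrest field must be >= 0")
        if not (0.0 <= self.depart_probability <= 1.0):
            raise InvalidParameterError("departure probability must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Exact per-filament and per-frame record of a simulated experiment.

    ``filaments`` columns: filament_id, length_um, anchor_density_per_um,
    detachment_voltage_v (NaN when never detached), displacement_um,
    final_state.  ``frames`` columns: frame, time_s, gain, active_voltage_v.
    """

    filaments: pd.DataFrame
    frames: pd.DataFrame


def generate_scene(
    density_per_um2: float,
    fov_um: tuple[float, float],
    length_dist_params: dict | None = None,
    alignment_kappa: float = 2.0,
    anchor_density_mean: float = 210.0,
    intensity_per_um: float = 12000.0,
    intensity_cv: float = 0.10,
    flow_axis_angle: float = np.pi / 2,
    crowding: bool = True,
    seed: int | None = None,
) -> FilamentScene:
    """Draw a random dense filament scene.

    ``round(density * area)`` filament midpoints are placed uniformly over
    the field of view.  Orientations are axial: half of a von Mises draw
    with concentration ``alignment_kappa`` about the flow axis, so kappa = 0
    gives an isotropic network and kappa ~ 2 the "partially oriented along
    the flow" look.  Filament lengths follow a lognormal law
    (``length_dist_params = {"mean_um": 8.0, "cv": 0.4}`` by default,
    a stated assumption — the assay's true length distribution is unknown).
    Per-filament anchoring is ``Poisson(anchor_density_mean * L) / L``
    anchors per µm: detachment is all-or-none per filament.
    """
    if density_per_um2 <= 0:
        raise InvalidParameterError("filament density must be > 0")
    if fov_um[0] <= 0 or fov_um[1] <= 0:
        raise InvalidParameterError("field of view must be positive")
    if seed is None:
        raise InvalidParameterError("a seed is required for reproducibility")
    params = {"mean_um": 8.0, "cv": 0.4}
    params.update(length_dist_params or {})
    rng = np.random.default_rng(seed)

    w, h = float(fov_um[0]), float(fov_um[1])
    n = int(round(density_per_um2 * w * h))
    mid = rng.uniform([0.0, 0.0], [w, h], size=(n, 2))

    # lognormal lengths with the requested mean and coefficient of variation
    cv = float(params["cv"])
    sigma2 = np.log1p(cv**2)
    mu = np.log(float(params["mean_um"])) - 0.5 * sigma2
    lengths = np.maximum(rng.lognormal(mu, np.sqrt(sigma2), size=n), 0.5)

    theta = flow_axis_angle + 0.5 * rng.vonmises(0.0, alignment_kappa, size=n)
    direction = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    half = 0.5 * lengths[:, None] * direction
    endpoints = np.stack([mid - half, mid + half], axis=1)

    counts = rng.poisson(anchor_density_mean * lengths)
    anchor_density = counts / lengths

    intensity = intensity_per_um * rng.lognormal(
        -0.5 * np.log1p(intensity_cv**2),
        np.sqrt(np.log1p(intensity_cv**2)),
        size=n,
    )
    return FilamentScene(
        endpoints=endpoints,
        anchor_density=anchor_density,
        intensity_per_um=intensity,
        states=np.zeros(n, dtype=np.int8),
        fov_um=(w, h),
        alignment_kappa=alignment_kappa,
        crowding=crowding,
    )


def _rasterize(scene: FilamentScene, imaging: ImagingParams, shape: tuple[int, int]) -> np.ndarray:
    """Deposit visible filaments onto a pixel grid as anti-aliased segments.

    Each filament is sampled at half-pixel steps along its axis and each
    sample's intensity (intensity_per_um * step length) is spread bilinearly
    over its four neighbouring pixels, so co-located filaments add and total
    deposited intensity is position-independent up to clipping at the frame
    edge.
    """
    h, w = shape
    img = np.zeros(h * w)
    visible = np.nonzero(scene.states != STATE_DEPARTED)[0]
    if visible.size == 0:
        return img.reshape(h, w)
    px = imaging.pixel_size_um
    p0 = scene.endpoints[visible, 0]
    p1 = scene.endpoints[visible, 1]
    lengths = np.linalg.norm(p1 - p0, axis=1)
    step = 0.5 * px
    nseg = np.maximum(np.ceil(lengths / step).astype(int), 1) + 1
    total = int(nseg.sum())
    fil = np.repeat(np.arange(visible.size), nseg)
    starts = np.concatenate([[0], np.cumsum(nseg)[:-1]])
    local = np.arange(total) - starts[fil]
    t = local / np.maximum(nseg[fil] - 1, 1)
    pts = p0[fil] + t[:, None] * (p1 - p0)[fil]
    weights = (scene.intensity_per_um[visible] * lengths / nseg)[fil]

    cx = pts[:, 0] / px
    cy = pts[:, 1] / px
    x0 = np.floor(cx).astype(int)
    y0 = np.floor(cy).astype(int)
    fx = cx - x0
    fy = cy - y0
    for dx, dy, wgt in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        xx = x0 + dx
        yy = y0 + dy
        ok = (xx >= 0) & (xx < w) & (yy >= 0) & (yy < h)
        np.add.at(img, yy[ok] * w + xx[ok], weights[ok] * wgt[ok])
    return img.reshape(h, w)


def _background_plane(imaging: ImagingParams, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    gx, gy = imaging.background_gradient
    x_um = np.arange(w) * imaging.pixel_size_um
    y_um = np.arange(h) * imaging.pixel_size_um
    return imaging.background_level + gx * x_um[None, :] + gy * y_um[:, None]


def frame_shape(fov_um: tuple[float, float], imaging: ImagingParams) -> tuple[int, int]:
    """Pixel grid covering the field of view (rows, cols)."""
    w = int(round(fov_um[0] / imaging.pixel_size_um))
    h = int(round(fov_um[1] / imaging.pixel_size_um))
    return h, w


def render_frame(
    scene: FilamentScene,
    imaging: ImagingParams,
    gain: float = 1.0,
    rng: np.random.Generator | int | None = None,
    signal: np.ndarray | None = None,
    quantize: bool = True,
) -> np.ndarray:
    """Render one camera frame of the current scene state.

    Pipeline: rasterize filaments (intensities of co-located filaments add)
    -> Gaussian PSF -> planar background -> optional Poisson shot noise ->
    Gaussian read noise -> multiplication by ``gain`` -> rounding and
    clipping to the camera bit depth.  ``signal`` short-circuits the
    rasterize+PSF stage with a precomputed noise-free signal image;
    ``quantize=False`` skips the final rounding/clipping (useful when exact
    linearity matters).
    """
    if gain <= 0:
        raise InvalidParameterError("gain must be > 0")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    shape = frame_shape(scene.fov_um, imaging)
    if signal is None:
        signal = render_signal(scene, imaging)
    img = signal + _background_plane(imaging, shape)
    if imaging.shot_noise:
        img = rng.poisson(np.maximum(img, 0.0)).astype(float)
    if imaging.read_noise_sigma > 0:
        img = img + rng.normal(0.0, imaging.read_noise_sigma, size=shape)
    img = img * gain
    if not quantize:
        return img
    return np.clip(np.rint(img), 0, imaging.max_count)


def render_signal(scene: FilamentScene, imaging: ImagingParams) -> np.ndarray:
    """Noise-free, background-free filament signal (rasterization + PSF)."""
    shape = frame_shape(scene.fov_um, imaging)
    raw = _rasterize(scene, imaging, shape)
    if imaging.psf_sigma_um > 0:
        raw = gaussian_filter(raw, imaging.psf_sigma_um / imaging.pixel_size_um)
    return raw


def simulate_experiment(
    scene: FilamentScene,
    protocols: Sequence[PulseProtocol],
    calibration: FieldCalibration,
    motion: MotionModel,
    f_ab: float,
    imaging: ImagingParams,
    duration_s: float,
    seed: int | None = None,
    quantize: bool = True,
) -> tuple[ImageStack, GroundTruth]:
    """Run the pulse-train experiment on a scene and record frames + truth.

    For every frame interval with pulse-on time: bound filaments whose local
    detachment balance ``E_local * rho_MT > anchor_density * f_ab`` is
    exceeded become mobile (E_local from the calibration's spatial profile
    at the filament midpoint); mobile filaments translate toward the anode
    by ``mobility * E_local * on_seconds``; mobile filaments arrest where
    ``E_local < arrest_field``; without crowding, mobile filaments depart
    with a fixed per-frame probability.  Detachment is permanent, so effects
    are cumulative across successive trains.
    """
    if seed is None:
        raise InvalidParameterError("a seed is required for reproducibility")
    if f_ab <= 0:
        raise InvalidParameterError("antibody holding force must be > 0")
    _check_non_overlapping(protocols)
    rng = np.random.default_rng(seed)
    work = scene.copy()
    n_fil = len(work)
    rho = mt_linear_charge_density()

    n_frames = max(int(np.ceil(duration_s * imaging.frame_rate)), 1)
    times = np.arange(n_frames) / imaging.frame_rate
    gains = np.exp(np.cumsum(rng.normal(0.0, imaging.gain_drift_sigma, size=n_frames)))

    detachment_v = np.full(n_fil, np.nan)
    displacement = np.zeros(n_fil)
    start_positions = work.midpoints_um.copy()

    frames = np.empty((n_frames,) + frame_shape(work.fov_um, imaging))
    active_voltage = np.zeros(n_frames)
    signal_cache: np.ndarray | None = None

    for k in range(n_frames):
        t0 = times[k - 1] if k > 0 else -np.inf
        t1 = times[k]
        moved = False
        for proto in protocols:
            on = proto.on_time_between(t0, t1)
            if on <= 0.0:
                continue
            active_voltage[k] = proto.amplitude_v
            x_along = work.midpoints_um @ work.gap_axis
            e_local = np.asarray(calibration.field_profile(x_along, proto.amplitude_v))

            bound = work.states == STATE_BOUND
            force = e_local * 1e5 * rho * 1e-6  # N per µm of filament length
            detach = bound & (force > work.anchor_density * f_ab)
            if np.any(detach):
                work.set_state(np.nonzero(detach)[0], STATE_MOBILE)
                detachment_v[detach] = proto.amplitude_v
                moved = True

            mobile = work.states == STATE_MOBILE
            if np.any(mobile):
                shift = motion.mobility_um_per_s_per_kv_cm * e_local[mobile] * on
                work.endpoints[mobile] += (shift[:, None] * work.gap_axis)[:, None, :]
                displacement[mobile] += shift
                moved = True

                # arrest where the field profile is too weak to keep pulling
                x_new = work.midpoints_um[mobile] @ work.gap_axis
                e_new = np.asarray(calibration.field_profile(x_new, proto.amplitude_v))
                arrest = np.nonzero(mobile)[0][e_new < motion.arrest_field_kv_cm]
                if arrest.size:
                    work.set_state(arrest, STATE_ARRESTED)

        if not work.crowding:
            mobile_idx = np.nonzero(work.states == STATE_MOBILE)[0]
            if mobile_idx.size:
                gone = mobile_idx[rng.random(mobile_idx.size) < motion.depart_probability]
                if gone.size:
                    work.set_state(gone, STATE_DEPARTED)
                    moved = True

        if moved or signal_cache is None:
            signal_cache = render_signal(work, imaging)
        frames[k] = render_frame(work, imaging, gain=gains[k], rng=rng,
                                 signal=signal_cache, quantize=quantize)

    truth = GroundTruth(
        filaments=pd.DataFrame(
            {
                "filament_id": np.arange(n_fil),
                "length_um": work.lengths_um,
                "anchor_density_per_um": work.anchor_density,
                "detachment_voltage_v": detachment_v,
                "displacement_um": displacement,
                "final_state": [STATE_NAMES[int(s)] for s in work.states],
                "start_x_um": start_positions[:, 0],
                "start_y_um": start_positions[:, 1],
            }
        ),
        frames=pd.DataFrame(
            {
                "frame": np.arange(n_frames),
                "time_s": times,
                "gain": gains,
                "active_voltage_v": active_voltage,
            }
        ),
    )
    stack = ImageStack(frames=frames, times=times, frame_rate=imaging.frame_rate,
                       pixel_size_um=imaging.pixel_size_um)
    return stack, truth


def _check_non_overlapping(protocols: Sequence[PulseProtocol]) -> None:
    if not protocols:
        return
    ordered = sorted(protocols, key=lambda p: p.start_time_s)
    for a, b in zip(ordered[:-1], ordered[1:]):
        if b.start_time_s < a.end_time_s:
            raise InvalidProtocolError(
                f"protocols overlap in time: train at {a.start_time_s} s "
                f"runs until {a.end_time_s} s, next starts at {b.start_time_s} s"
            )
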