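"""File I/O, configuration and the end-to-end analysis pipeline.

``run_analysis`` reproduces the full quantification chain on a recording
with a logged sequence of pulse trains: gain-correct once against the
background region, compute per-train endpoint MDI (frame before the train
vs frame after it) and overlap rates, the MDI-speed trace across the whole
record, and the displacement threshold voltage estimated from the per-train
speed peaks against the pre-pulse noise floor.

Stacks travel as multi-page TIFF plus a frame-metadata CSV sidecar (frame
index, time, gain, active voltage); configurations are single YAML files
with units spelled out in the key names.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .displacement import (
    correct_gain,
    estimate_threshold_voltage,
    mdi,
    mdi_speed_series,
)
from .electromechanics import PulseProtocol
from .exceptions import EventWindowError, InvalidInputError, StackFormatError
from .overlap import mor, otsu_threshold, count_supra_threshold
from .stack import ImageStack, RegionSpec

__all__ = [
    "read_stack",
    "write_stack",
    "AnalysisConfig",
    "AnalysisReport",
    "run_analysis",
    "write_report",
]


def write_stack(stack: ImageStack, path, bit_depth: int = 16,
                metadata: pd.DataFrame | None = None) -> None:
    """Write a stack as multi-page grayscale TIFF plus a times CSV sidecar.

    Pixel values are clipped and cast to the requested unsigned bit depth;
    the sidecar ``<path>.frames.csv`` carries frame index and time (plus any
    extra per-frame metadata columns passed in) so the time axis survives
    the round trip.
    """
    path = Path(path)
    if bit_depth not in (8, 16):
        raise InvalidInputError("bit depth must be 8 or 16")
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    data = np.clip(np.rint(stack.frames), 0, 2**bit_depth - 1).astype(dtype)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = pd.DataFrame({"frame": np.arange(len(stack)), "time_s": stack.times})
    if metadata is not None:
        extra = metadata.drop(columns=[c for c in ("frame", "time_s") if c in metadata],
                              errors="ignore")
        meta = pd.concat([meta, extra.reset_index(drop=True)], axis=1)
    meta.to_csv(sidecar_path(path), index=False)


def sidecar_path(path) -> Path:
    return Path(str(path) + ".frames.csv")


def read_stack(path, frame_rate: float = 2.47, pixel_size_um: float = 0.217) -> ImageStack:
    """Read a multi-page TIFF as an ImageStack.

    Frame times come from the ``<path>.frames.csv`` sidecar when present,
    otherwise from the uniform ``frame_rate``.  8- and 16-bit inputs are
    promoted to float without value change.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise StackFormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise StackFormatError(f"{path}: expected 2-D grayscale pages, got shape {data.shape}")
    times = None
    sc = sidecar_path(path)
    if sc.exists():
        meta = pd.read_csv(sc)
        if len(meta) != data.shape[0]:
            raise StackFormatError(
                f"{sc}: {len(meta)} metadata rows for {data.shape[0]} pages"
            )
        times = meta["time_s"].to_numpy(float)
        if len(times) > 1:
            frame_rate = float(1.0 / np.median(np.diff(times)))
    return ImageStack.from_frames(data, frame_rate=frame_rate,
                                  pixel_size_um=pixel_size_um, times=times)


@dataclass
class AnalysisConfig:
    """Declarative description of one analysis run (YAML-serialisable)."""

    stack_path: str
    voltages_v: list = field(default_factory=lambda: [45, 85, 125, 170, 210, 255, 300])
    train_starts_s: list | None = None
    pulse_width_us: float = 5.0
    n_pulses: int = 100
    repetition_rate_hz: float = 10.0
    roi: list | None = None  # [row_start, row_stop, col_start, col_stop]
    background: list | None = None
    threshold_policy: str = "t1"
    k_threshold: float = 3.0
    pre_margin_s: float = 0.5
    post_margin_s: float = 0.5
    pixel_size_um: float = 0.217
    frame_rate: float = 2.47
    output_dir: str = "."
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def protocols(self) -> list[PulseProtocol]:
        if self.train_starts_s is None:
            raise InvalidInputError("train_starts_s must list one start time per voltage")
        if len(self.train_starts_s) != len(self.voltages_v):
            raise InvalidInputError("one train start time per voltage required")
        return [
            PulseProtocol(
                amplitude_v=float(v),
                pulse_width_s=self.pulse_width_us * 1e-6,
                n_pulses=self.n_pulses,
                repetition_rate_hz=self.repetition_rate_hz,
                start_time_s=float(t),
            )
            for v, t in zip(self.voltages_v, self.train_starts_s)
        ]

    def hash(self) -> str:
        """Stable hash of the configuration for provenance tracking."""
        blob = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Per-voltage metrics, the MDI-speed trace and the threshold estimate."""

    per_voltage: pd.DataFrame
    speed_times_s: np.ndarray
    speed_values: np.ndarray
    noise_floor: float
    threshold_voltage_v: float | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "per_voltage": self.per_voltage.to_dict(orient="records"),
            "noise_floor": self.noise_floor,
            "threshold_voltage_v": self.threshold_voltage_v,
            "provenance": self.provenance,
        }


def _endpoint_indices(times: np.ndarray, proto: PulseProtocol,
                      pre_margin: float, post_margin: float) -> tuple[int, int]:
    pre_ok = np.nonzero(times <= proto.start_time_s - pre_margin)[0]
    post_ok = np.nonzero(times >= proto.end_time_s + post_margin)[0]
    if pre_ok.size == 0 or post_ok.size == 0:
        raise EventWindowError(
            f"train at {proto.start_time_s}-{proto.end_time_s} s has no "
            f"frames outside its margins within the recording"
        )
    return int(pre_ok[-1]), int(post_ok[0])


def run_analysis(
    stack: ImageStack,
    protocols: Sequence[PulseProtocol],
    regions: RegionSpec | None = None,
    threshold_policy: str = "t1",
    k_threshold: float = 3.0,
    pre_margin_s: float = 0.5,
    post_margin_s: float = 0.5,
    provenance: dict | None = None,
) -> AnalysisReport:
    """Run the full quantification chain on a recording.

    Per train: endpoint MDI and MOR between the last frame at least
    ``pre_margin_s`` before the train start and the first frame at least
    ``post_margin_s`` after its end (guards against mid-train frames), plus
    the cumulative MOR against the pre-first-train baseline frame and the
    peak MDI speed within the train window.  The noise floor is the median
    MDI speed before the first train; the threshold voltage is the first
    train whose peak exceeds ``k_threshold`` times that floor.
    """
    if not protocols:
        raise InvalidInputError("at least one pulse train required")
    regions = regions or RegionSpec.default_for_shape(stack.shape)
    regions.validate(stack.shape)
    ordered = sorted(protocols, key=lambda p: p.start_time_s)

    corrected = correct_gain(stack, regions)
    speed = mdi_speed_series(corrected, regions, gain_correct=False)

    pre_mask = speed.times < ordered[0].start_time_s
    if not np.any(pre_mask):
        raise EventWindowError("no pre-pulse frames to estimate the noise floor from")
    noise_floor = float(np.median(speed.values[pre_mask]))

    baseline_idx, _ = _endpoint_indices(corrected.times, ordered[0],
                                        pre_margin_s, post_margin_s)
    rows = []
    for proto in ordered:
        i_pre, i_post = _endpoint_indices(corrected.times, proto,
                                          pre_margin_s, post_margin_s)
        f_pre = corrected.frames[i_pre]
        f_post = corrected.frames[i_post]
        th = otsu_threshold(f_pre, regions.roi).threshold
        window = (speed.times >= proto.start_time_s) & (speed.times <= proto.end_time_s)
        peak = float(np.max(speed.values[window])) if np.any(window) else float("nan")
        rows.append(
            {
                "voltage_v": proto.amplitude_v,
                "t_pre_s": float(corrected.times[i_pre]),
                "t_post_s": float(corrected.times[i_post]),
                "endpoint_mdi": mdi(f_pre, f_post, regions.roi),
                "mor": mor(f_pre, f_post, regions.roi, threshold_policy),
                "mor_cumulative": mor(corrected.frames[baseline_idx], f_post,
                                      regions.roi, threshold_policy),
                "threshold_th": th,
                "count_pre": count_supra_threshold(f_pre, regions.roi, th),
                "count_post": count_supra_threshold(f_post, regions.roi, th),
                "peak_mdi_speed_per_s": peak,
            }
        )
    table = pd.DataFrame(rows)
    threshold_v = estimate_threshold_voltage(
        table["voltage_v"].to_numpy(),
        table["peak_mdi_speed_per_s"].to_numpy(),
        noise_floor,
        k=k_threshold,
    )
    prov = {
        "package_version": __version__,
        "n_frames": len(stack),
        "roi": list(regions.roi),
        "background": list(regions.background),
        "k_threshold": k_threshold,
        "threshold_policy": threshold_policy,
    }
    prov.update(provenance or {})
    return AnalysisReport(
        per_voltage=table,
        speed_times_s=speed.times,
        speed_values=speed.values,
        noise_floor=noise_floor,
        threshold_voltage_v=threshold_v,
        provenance=prov,
    )


def run_analysis_config(config: AnalysisConfig) -> AnalysisReport:
    """Config-file entry point: load the stack, analyse, write outputs."""
    stack = read_stack(config.stack_path, frame_rate=config.frame_rate,
                       pixel_size_um=config.pixel_size_um)
    if config.roi is not None and config.background is not None:
        regions = RegionSpec(roi=tuple(config.roi), background=tuple(config.background))
    else:
        regions = RegionSpec.default_for_shape(stack.shape)
    report = run_analysis(
        stack,
        config.protocols(),
        regions=regions,
        threshold_policy=config.threshold_policy,
        k_threshold=config.k_threshold,
        pre_margin_s=config.pre_margin_s,
        post_margin_s=config.post_margin_s,
        provenance={"config_hash": config.hash(), "seed": config.seed},
    )
    write_report(report, config.output_dir)
    return report


def write_report(report: AnalysisReport, output_dir) -> None:
    """Write per_voltage.csv, speed_series.csv and report.json."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.per_voltage.to_csv(out / "per_voltage.csv", index=False)
    pd.DataFrame(
        {"time_s": report.speed_times_s, "mdi_speed_per_s": report.speed_values}
    ).to_csv(out / "speed_series.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=float)
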