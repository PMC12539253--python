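"""Recording file I/O and TOML configuration.

Recordings are stored the way common raw ephys dumps are: a flat
little-endian signed-16-bit binary, sample-major (all channels of sample 0,
then sample 1, ...), with a JSON sidecar ``<file>.json`` carrying
``rate_hz``, ``n_channels``, ``scale_uv_per_bit`` and ``channel_order``.
μV conversion is applied on read.

Configuration files are TOML with a closed schema: unknown keys raise,
protecting calibration constants from typos.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path
from typing import Union

import numpy as np

from .gears import DriveConfig, GearStage, GearTrain, ScrewSpec
from .signal_chain import ChainConfig, DetectConfig, RecordingBlock
from .simulate import (
    ArtifactInjection,
    GainTestPlan,
    LineNoise,
    SimulationPlan,
    SpikeInjection,
    default_template,
)

__all__ = [
    "RecordingIOError",
    "ConfigError",
    "read_recording",
    "write_recording",
    "sidecar_path",
    "load_toml",
    "drive_config_from_dict",
    "chain_config_from_dict",
    "detect_config_from_dict",
    "simulation_plan_from_dict",
    "gain_test_plan_from_dict",
]


class RecordingIOError(IOError):
    """Recording file and sidecar metadata disagree or are malformed."""


class ConfigError(ValueError):
    """Malformed or unknown configuration keys."""


def sidecar_path(path: Union[str, Path]) -> Path:
    return Path(str(path) + ".json")


def write_recording(block: RecordingBlock, path: Union[str, Path]) -> None:
    """Write int16 binary + JSON sidecar (lossless at int16 resolution)."""
    path = Path(path)
    q = np.clip(np.rint(block.data / block.scale_uv_per_bit), -32768, 32767)
    q.astype("<i2").tofile(path)
    meta = {
        "rate_hz": block.rate_hz,
        "n_channels": block.n_channels,
        "scale_uv_per_bit": block.scale_uv_per_bit,
        "channel_order": block.channel_order.tolist(),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_recording(path: Union[str, Path]) -> RecordingBlock:
    """Read a flat int16 recording, validating size against the sidecar."""
    path = Path(path)
    meta_path = sidecar_path(path)
    if not meta_path.exists():
        raise RecordingIOError(f"missing sidecar metadata file {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("rate_hz", "n_channels", "scale_uv_per_bit"):
        if key not in meta:
            raise RecordingIOError(f"sidecar {meta_path} is missing '{key}'")
    n_channels = int(meta["n_channels"])
    size = path.stat().st_size
    frame_bytes = n_channels * 2
    if size % frame_bytes != 0:
        raise RecordingIOError(
            f"{path}: file size {size} bytes is not a whole number of "
            f"{n_channels}-channel frames ({frame_bytes} bytes each)"
        )
    raw = np.fromfile(path, dtype="<i2").reshape(-1, n_channels)
    return RecordingBlock(
        data=raw.astype(np.float64) * float(meta["scale_uv_per_bit"]),
        rate_hz=float(meta["rate_hz"]),
        channel_order=np.asarray(meta.get("channel_order", range(n_channels))),
        scale_uv_per_bit=float(meta["scale_uv_per_bit"]),
    )


# ---------------------------------------------------------------------------
# TOML configuration


def load_toml(path: Union[str, Path]) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


def drive_config_from_dict(cfg: dict) -> DriveConfig:
    """Build a DriveConfig from `[screw]` and `[[stages]]` tables."""
    _check_keys(cfg, {"screw", "stages"}, "drive config")
    screw_tbl = cfg.get("screw", {})
    _check_keys(screw_tbl, {"pitch_mm"}, "[screw]")
    if "pitch_mm" not in screw_tbl:
        raise ConfigError("[screw] must define pitch_mm")
    stages = []
    for i, tbl in enumerate(cfg.get("stages", [])):
        _check_keys(tbl, {"sun_teeth", "ring_teeth", "planet_teeth"}, f"[[stages]] #{i}")
        stages.append(
            GearStage(
                sun_teeth=int(tbl["sun_teeth"]),
                ring_teeth=int(tbl["ring_teeth"]),
                planet_teeth=(
                    int(tbl["planet_teeth"]) if "planet_teeth" in tbl else None
                ),
            )
        )
    return DriveConfig(
        screw=ScrewSpec(pitch_mm=float(screw_tbl["pitch_mm"])),
        train=GearTrain(stages=tuple(stages)),
    )


_CHAIN_KEYS = {
    "artifact_z",
    "car_neighbors",
    "bp_low_hz",
    "bp_high_hz",
    "filter_order",
    "artifact_guard_ms",
    "car_mode",
}

_DETECT_KEYS = {
    "threshold_uv",
    "peak_z_min",
    "clip_ms",
    "footprint_neighbors",
    "lockout_samples",
}


def chain_config_from_dict(cfg: dict) -> ChainConfig:
    _check_keys(cfg, _CHAIN_KEYS, "[chain]")
    return ChainConfig(**cfg)


def detect_config_from_dict(cfg: dict) -> DetectConfig:
    _check_keys(cfg, _DETECT_KEYS, "[detect]")
    return DetectConfig(**cfg)


_RECORDING_KEYS = {
    "n_channels",
    "duration_s",
    "rate_hz",
    "noise_sd_uv",
    "seed",
    "scale_uv_per_bit",
}
_SPIKE_KEYS = {"channel", "time_s", "trough_uv", "decay_per_channel"}
_ARTIFACT_KEYS = {"time_s", "amplitude_sd_units", "width_ms", "channel"}
_LINE_KEYS = {"freq_hz", "amplitude_uv"}


def simulation_plan_from_dict(cfg: dict, seed: int | None = None) -> SimulationPlan:
    """Build a SimulationPlan from `[recording]`, `[[spikes]]`,
    `[[artifacts]]` and optional `[line_noise]` tables.  ``seed`` overrides
    the plan's seed when given."""
    _check_keys(
        cfg, {"recording", "spikes", "artifacts", "line_noise"}, "simulation plan"
    )
    rec = dict(cfg.get("recording", {}))
    _check_keys(rec, _RECORDING_KEYS, "[recording]")
    if seed is not None:
        rec["seed"] = seed
    rate = float(rec.get("rate_hz", 30_000.0))
    spikes = []
    for i, tbl in enumerate(cfg.get("spikes", [])):
        _check_keys(tbl, _SPIKE_KEYS, f"[[spikes]] #{i}")
        spikes.append(
            SpikeInjection(
                channel=int(tbl["channel"]),
                time_s=float(tbl["time_s"]),
                template=default_template(
                    rate,
                    trough_uv=float(tbl.get("trough_uv", -150.0)),
                    decay_per_channel=float(tbl.get("decay_per_channel", 0.6)),
                ),
            )
        )
    artifacts = []
    for i, tbl in enumerate(cfg.get("artifacts", [])):
        _check_keys(tbl, _ARTIFACT_KEYS, f"[[artifacts]] #{i}")
        artifacts.append(ArtifactInjection(**tbl))
    line = None
    if "line_noise" in cfg:
        _check_keys(cfg["line_noise"], _LINE_KEYS, "[line_noise]")
        line = LineNoise(**cfg["line_noise"])
    return SimulationPlan(
        spikes=tuple(spikes), artifacts=tuple(artifacts), line_noise=line, **rec
    )


_GAIN_KEYS = {
    "n_pulses",
    "pulse_width_us",
    "pulse_spacing_ms",
    "true_amplitude_uv",
    "nominal_gain",
    "actual_gain",
    "noise_sd_uv",
    "rate_hz",
    "lead_s",
    "seed",
    "scale_uv_per_bit",
}


def gain_test_plan_from_dict(cfg: dict, seed: int | None = None) -> GainTestPlan:
    tbl = dict(cfg.get("gain_test", cfg))
    _check_keys(tbl, _GAIN_KEYS, "[gain_test]")
    if seed is not None:
        tbl["seed"] = seed
    return GainTestPlan(**tbl)
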