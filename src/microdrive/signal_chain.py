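"""Multichannel pre-processing and threshold spike detection.

The processing chain runs three ordered stages on a raw extracellular
recording, then detects spikes channel by channel:

1. artifact removal — samples whose z-score against the whole channel
   exceeds a threshold (default 10 SD) are masked, together with a guard
   window, and replaced by the channel median so timestamps stay aligned;
2. local common averaging — from each channel subtract the mean of up to a
   fixed number of physically neighboring channels above and below it
   (default 7 per side), which cancels signal common to the shank;
3. band-pass filtering — zero-phase (forward-backward) Butterworth,
   default 2nd order, 300–5000 Hz, isolating the action-potential band.

Detection finds contiguous runs of samples below a voltage threshold
(default −80 μV), keeps the most negative sample of each run as the peak,
prunes peaks whose |z| against the whole channel falls below a secondary
z threshold (default 1), and cuts an inverted, odd-length clip (default
1.7 ms) with the peak as the exact middle sample.  A spike's cross-channel
footprint re-applies the same criterion in the clip window on the nearest
channels above and below (default 4 per side), recording the decayed copy
where it is found.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "RecordingBlock",
    "ChainConfig",
    "DetectConfig",
    "SpikeEvent",
    "Footprint",
    "SignalChainError",
    "remove_artifacts",
    "local_average_reference",
    "bandpass",
    "detect_spikes",
    "average_waveform",
    "cross_channel_footprint",
    "run_chain",
    "clip_length_samples",
]


class SignalChainError(ValueError):
    """Invalid recording, configuration, or stage input."""


@dataclass
class RecordingBlock:
    """A samples × channels extracellular recording in μV.

    ``channel_order`` lists data-column indices in physical order along the
    shank, so adjacent entries are adjacent electrodes; it defaults to the
    identity.  ``scale_uv_per_bit`` records the int16 quantization step of
    the backing file.
    """

    data: np.ndarray
    rate_hz: float
    channel_order: Optional[np.ndarray] = None
    scale_uv_per_bit: float = 0.195

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise SignalChainError("data must be a samples x channels matrix")
        if self.rate_hz <= 0:
            raise SignalChainError("sampling rate must be positive")
        if self.channel_order is None:
            self.channel_order = np.arange(self.n_channels)
        self.channel_order = np.asarray(self.channel_order, dtype=np.int64)
        if sorted(self.channel_order.tolist()) != list(range(self.n_channels)):
            raise SignalChainError(
                "channel_order must be a permutation of 0..n_channels-1"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RecordingBlock":
        return RecordingBlock(
            data=data,
            rate_hz=self.rate_hz,
            channel_order=self.channel_order.copy(),
            scale_uv_per_bit=self.scale_uv_per_bit,
        )


@dataclass(frozen=True)
class ChainConfig:
    """Pre-processing parameters (defaults follow the rig's offline chain)."""

    artifact_z: float = 10.0
    car_neighbors: int = 7
    bp_low_hz: float = 300.0
    bp_high_hz: float = 5000.0
    filter_order: int = 2
    #: guard window masked on each side of a flagged artifact sample
    artifact_guard_ms: float = 2.0
    #: "per_side": up to car_neighbors above AND below (<= 2k total);
    #: "total": the nearest car_neighbors channels overall.
    car_mode: str = "per_side"

    def __post_init__(self) -> None:
        if self.artifact_z <= 0:
            raise SignalChainError("artifact_z must be positive")
        if not 0 < self.bp_low_hz < self.bp_high_hz:
            raise SignalChainError("need 0 < bp_low_hz < bp_high_hz")
        if self.car_neighbors < 0 or self.filter_order < 1:
            raise SignalChainError("car_neighbors >= 0 and filter_order >= 1")
        if self.car_mode not in ("per_side", "total"):
            raise SignalChainError("car_mode must be 'per_side' or 'total'")


@dataclass(frozen=True)
class DetectConfig:
    """Spike-detection parameters."""

    threshold_uv: float = -80.0
    peak_z_min: float = 1.0
    clip_ms: float = 1.7
    footprint_neighbors: int = 4
    #: dead time after an accepted peak; None = one clip length
    lockout_samples: Optional[int] = None

    def __post_init__(self) -> None:
        if self.threshold_uv >= 0:
            raise SignalChainError("threshold_uv must be negative")
        if self.clip_ms <= 0:
            raise SignalChainError("clip_ms must be positive")
        if self.footprint_neighbors < 0:
            raise SignalChainError("footprint_neighbors must be >= 0")


@dataclass
class SpikeEvent:
    """One detected spike.

    ``clip`` is the inverted waveform (spike trough becomes the maximum)
    of odd length with the peak as the exact middle sample.
    """

    channel: int
    peak_sample: int
    peak_uv: float
    clip: np.ndarray


@dataclass
class Footprint:
    """A spike's appearance on physically neighboring channels.

    Keys are signed physical-channel offsets (−k..+k, 0 excluded); offsets
    where the detection criterion was not met are absent.
    """

    event: SpikeEvent
    neighbor_clips: dict[int, np.ndarray] = field(default_factory=dict)
    neighbor_peak_uv: dict[int, float] = field(default_factory=dict)


def clip_length_samples(clip_ms: float, rate_hz: float) -> int:
    """Clip length in samples, forced odd so a true middle sample exists."""
    n = int(round(clip_ms * 1e-3 * rate_hz))
    if n % 2 == 0:
        n += 1
    return max(n, 1)


# ---------------------------------------------------------------------------
# stage 1: artifact removal


def remove_artifacts(
    block: RecordingBlock,
    artifact_z: float = 10.0,
    guard_ms: float = 2.0,
) -> tuple[RecordingBlock, np.ndarray]:
    """Mask extreme samples and replace them with the channel median.

    Per channel, samples with |z| >= ``artifact_z`` (z against the whole
    channel's mean/SD) are flagged; the flag is dilated by ``guard_ms`` on
    each side; flagged samples are set to the channel median.  Returns the
    cleaned block and the boolean mask for audit.  A zero-variance channel
    is left untouched (z undefined, treated as 0) with a warning.
    """
    if block.n_samples == 0:
        raise SignalChainError("empty block")
    data = block.data.copy()
    mask = np.zeros(data.shape, dtype=bool)
    guard = int(round(guard_ms * 1e-3 * block.rate_hz))
    structure = np.ones(2 * guard + 1, dtype=bool)
    for ch in range(block.n_channels):
        x = data[:, ch]
        sd = x.std()
        if sd == 0 or x.max() == x.min():  # constant channel: z undefined
            warnings.warn(
                f"channel {ch} has zero variance; artifact z undefined, skipped",
                stacklevel=2,
            )
            continue
        flagged = np.abs((x - x.mean()) / sd) >= artifact_z
        if guard > 0 and flagged.any():
            flagged = ndimage.binary_dilation(flagged, structure=structure)
        if flagged.any():
            data[flagged, ch] = np.median(x)
            mask[:, ch] = flagged
    return block.with_data(data), mask


# ---------------------------------------------------------------------------
# stage 2: local common averaging


def _neighbor_positions(pos: int, n: int, k: int, mode: str) -> np.ndarray:
    if mode == "per_side":
        lo = max(0, pos - k)
        hi = min(n - 1, pos + k)
        neigh = [p for p in range(lo, hi + 1) if p != pos]
    else:  # nearest k channels overall; ties broken toward the lower channel
        others = sorted(
            (p for p in range(n) if p != pos),
            key=lambda p: (abs(p - pos), p),
        )
        neigh = others[:k]
    return np.asarray(neigh, dtype=np.int64)


def local_average_reference(
    block: RecordingBlock,
    car_neighbors: int = 7,
    car_mode: str = "per_side",
) -> RecordingBlock:
    """Subtract from each channel the mean of its physical neighbors.

    Neighborhoods follow ``channel_order`` (physical shank order).  Edge
    channels use only the available side; a single-channel block is
    returned unchanged.
    """
    if block.n_channels < 1:
        raise SignalChainError("need at least one channel")
    if block.n_channels == 1 or car_neighbors == 0:
        return block.with_data(block.data.copy())
    order = block.channel_order
    referenced = block.data.copy()
    for pos in range(block.n_channels):
        neigh = _neighbor_positions(pos, block.n_channels, car_neighbors, car_mode)
        if neigh.size:
            reference = block.data[:, order[neigh]].mean(axis=1)
            referenced[:, order[pos]] = block.data[:, order[pos]] - reference
    return block.with_data(referenced)


# ---------------------------------------------------------------------------
# stage 3: band-pass


def bandpass(
    block: RecordingBlock,
    low_hz: float = 300.0,
    high_hz: float = 5000.0,
    order: int = 2,
) -> RecordingBlock:
    """Zero-phase Butterworth band-pass (forward-backward application).

    The effective magnitude response is the square of the designed
    ``order``-th order filter; zero phase preserves spike peak timing,
    which clip centering depends on.
    """
    nyquist = block.rate_hz / 2.0
    if not 0 < low_hz < high_hz < nyquist:
        raise SignalChainError(
            f"band edges ({low_hz}, {high_hz}) Hz must satisfy "
            f"0 < low < high < Nyquist ({nyquist} Hz)"
        )
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=block.rate_hz, output="sos"
    )
    return block.with_data(signal.sosfiltfilt(sos, block.data, axis=0))


# ---------------------------------------------------------------------------
# detection


def _runs_below(x: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Contiguous [start, stop) index runs where x <= threshold."""
    idx = np.flatnonzero(x <= threshold)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return [(int(a), int(b)) for a, b in zip(starts, stops)]


def detect_spikes(
    block: RecordingBlock,
    channel: int,
    config: DetectConfig = DetectConfig(),
) -> list[SpikeEvent]:
    """Threshold spike detection on one (pre-processed) channel.

    A candidate is a contiguous run of samples at or below
    ``threshold_uv``; its peak is the most negative sample (earliest on
    ties).  Peaks within the lockout after an accepted peak are skipped, as
    are peaks whose |z| against the whole channel is below ``peak_z_min``
    or whose clip would overrun the block edge.
    """
    if not 0 <= channel < block.n_channels:
        raise SignalChainError(
            f"channel {channel} out of range 0..{block.n_channels - 1}"
        )
    x = block.data[:, channel]
    n_clip = clip_length_samples(config.clip_ms, block.rate_hz)
    half = n_clip // 2
    lockout = config.lockout_samples if config.lockout_samples is not None else n_clip
    mean = x.mean()
    sd = x.std()
    events: list[SpikeEvent] = []
    last_accepted = -np.inf
    for start, stop in _runs_below(x, config.threshold_uv):
        segment = x[start:stop]
        peak = start + int(np.argmin(segment))  # argmin returns the first tie
        if peak - last_accepted <= lockout:
            continue
        if sd > 0 and abs((x[peak] - mean) / sd) < config.peak_z_min:
            continue
        if peak - half < 0 or peak + half + 1 > block.n_samples:
            continue
        clip = -x[peak - half : peak + half + 1].copy()
        events.append(
            SpikeEvent(
                channel=channel,
                peak_sample=peak,
                peak_uv=float(x[peak]),
                clip=clip,
            )
        )
        last_accepted = peak
    return events


def average_waveform(events: list[SpikeEvent]) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and SD across peak-centered clips."""
    if not events:
        raise SignalChainError("need at least one event")
    lengths = {e.clip.shape[0] for e in events}
    if len(lengths) != 1:
        raise SignalChainError(f"clips have unequal lengths: {sorted(lengths)}")
    stack = np.stack([e.clip for e in events])
    return stack.mean(axis=0), stack.std(axis=0)


def cross_channel_footprint(
    block: RecordingBlock,
    event: SpikeEvent,
    config: DetectConfig = DetectConfig(),
) -> Footprint:
    """Apply the detection criterion around the event on neighbor channels.

    For each physical offset ±1..±footprint_neighbors present on the shank,
    the clip window centered at the event's peak sample is examined: if its
    minimum is at or below ``threshold_uv`` and passes the |z| filter
    against that whole channel, the (inverted) window and its peak
    amplitude are recorded; otherwise the offset is absent.
    """
    order = block.channel_order
    positions = {int(order[p]): p for p in range(block.n_channels)}
    pos = positions[event.channel]
    n_clip = clip_length_samples(config.clip_ms, block.rate_hz)
    half = n_clip // 2
    lo = event.peak_sample - half
    hi = event.peak_sample + half + 1
    footprint = Footprint(event=event)
    if lo < 0 or hi > block.n_samples:
        return footprint
    for offset in range(-config.footprint_neighbors, config.footprint_neighbors + 1):
        if offset == 0:
            continue
        npos = pos + offset
        if not 0 <= npos < block.n_channels:
            continue
        col = int(order[npos])
        y = block.data[:, col]
        window = y[lo:hi]
        wmin = window.min()
        if wmin > config.threshold_uv:
            continue
        sd = y.std()
        if sd > 0 and abs((wmin - y.mean()) / sd) < config.peak_z_min:
            continue
        footprint.neighbor_clips[offset] = -window.copy()
        footprint.neighbor_peak_uv[offset] = float(wmin)
    return footprint


# ---------------------------------------------------------------------------
# full chain


def run_chain(
    block: RecordingBlock,
    chain_config: ChainConfig = ChainConfig(),
    detect_config: DetectConfig = DetectConfig(),
    skip_artifacts: bool = False,
) -> tuple[dict[int, list[SpikeEvent]], list[Footprint], dict]:
    """Run artifacts -> local averaging -> band-pass -> detection.

    Returns per-channel events, footprints for every event, and an audit
    log recording the stage order, parameters, masked-sample counts, and
    per-channel event counts.  ``skip_artifacts`` disables stage 1 (useful
    for linearity checks); the canonical order is always recorded.
    """
    nyquist = block.rate_hz / 2.0
    if chain_config.bp_high_hz >= nyquist:
        raise SignalChainError(
            f"band-pass upper edge {chain_config.bp_high_hz} Hz violates the "
            f"Nyquist limit {nyquist} Hz"
        )
    audit: dict = {
        "stage_order": ["artifacts", "local_average_reference", "bandpass", "detect"],
        "chain_config": chain_config,
        "detect_config": detect_config,
        "rate_hz": block.rate_hz,
        "n_samples": block.n_samples,
        "n_channels": block.n_channels,
    }
    if skip_artifacts:
        stage1, mask = block, np.zeros(block.data.shape, dtype=bool)
        audit["stage_order"] = audit["stage_order"][1:]
    else:
        stage1, mask = remove_artifacts(
            block, chain_config.artifact_z, chain_config.artifact_guard_ms
        )
    audit["artifact_samples_masked"] = int(mask.sum())
    audit["artifact_mask"] = mask
    stage2 = local_average_reference(
        stage1, chain_config.car_neighbors, chain_config.car_mode
    )
    stage3 = bandpass(
        stage2,
        chain_config.bp_low_hz,
        chain_config.bp_high_hz,
        chain_config.filter_order,
    )
    events_by_channel: dict[int, list[SpikeEvent]] = {}
    footprints: list[Footprint] = []
    for ch in range(stage3.n_channels):
        events = detect_spikes(stage3, ch, detect_config)
        events_by_channel[ch] = events
        for event in events:
            footprints.append(cross_channel_footprint(stage3, event, detect_config))
    audit["event_counts"] = {ch: len(ev) for ch, ev in events_by_channel.items()}
    audit["processed"] = stage3
    return events_by_channel, footprints, audit
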