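"""Seeded synthetic extracellular recordings with known ground truth.

Emulates what the implant's saline-bath bench and an in-vivo session hand
to the processing chain: per-channel Gaussian background noise,
negative-dominant biphasic spikes whose amplitude decays geometrically
across neighboring channels, large rectangular artifacts, optional 50/60 Hz
line interference, and the saline-bath gain-test pulse train (100 square
pulses of 100 μs, spaced 250 ms apart, nominal gain 1000).  Everything is
driven by one seed and quantized to int16 last, so identical plans produce
bit-identical recordings and every injected event is logged for
recall/precision scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .signal_chain import RecordingBlock, SpikeEvent

__all__ = [
    "SpikeTemplate",
    "SpikeInjection",
    "ArtifactInjection",
    "LineNoise",
    "SimulationPlan",
    "GainTestPlan",
    "SimulationError",
    "default_template",
    "simulate_recording",
    "simulate_gain_test",
    "estimate_gain",
    "evaluate_detection",
    "quantize",
]


class SimulationError(ValueError):
    """Invalid simulation plan or schedule."""


@dataclass(frozen=True)
class SpikeTemplate:
    """Unit-amplitude negative-dominant spike shape.

    ``waveform`` has its global extremum at −1; scaling by ``-trough_uv``
    puts the trough at ``trough_uv`` (negative μV).  ``decay_per_channel``
    is the multiplicative amplitude factor per physical channel step,
    symmetric above and below the main channel.
    """

    waveform: np.ndarray
    trough_uv: float = -150.0
    decay_per_channel: float = 0.6

    def __post_init__(self) -> None:
        wf = np.asarray(self.waveform, dtype=np.float64)
        object.__setattr__(self, "waveform", wf)
        if wf.ndim != 1 or wf.size < 2:
            raise SimulationError("waveform must be a 1-D array")
        if not np.isclose(wf.min(), -1.0):
            raise SimulationError("waveform extremum must be -1 (unit amplitude)")
        if abs(wf.min()) < wf.max():
            raise SimulationError("waveform must be negative-dominant")
        if self.trough_uv >= 0:
            raise SimulationError("trough_uv must be negative")
        if not 0 <= self.decay_per_channel <= 1:
            raise SimulationError("decay_per_channel must lie in [0, 1]")

    @property
    def trough_index(self) -> int:
        return int(np.argmin(self.waveform))

    def scaled(self) -> np.ndarray:
        """Waveform in μV (trough at ``trough_uv``)."""
        return self.waveform * (-self.trough_uv)


def default_template(
    rate_hz: float,
    trough_uv: float = -150.0,
    decay_per_channel: float = 0.6,
    duration_ms: float = 1.2,
) -> SpikeTemplate:
    """Difference-of-Gaussians biphasic template, trough at 1/3 of duration.

    Any fixed negative-dominant shape satisfies the chain's assumptions;
    this one gives a sharp trough followed by a slower positive rebound,
    the qualitative shape of an extracellular action potential.
    """
    n = max(int(round(duration_ms * 1e-3 * rate_hz)), 4)
    t = np.arange(n) / rate_hz * 1e3  # ms
    t_trough = duration_ms / 3.0
    sigma_neg = duration_ms / 12.0
    sigma_pos = duration_ms / 7.0
    t_rebound = t_trough + 2.5 * sigma_neg
    wf = -np.exp(-0.5 * ((t - t_trough) / sigma_neg) ** 2) + 0.35 * np.exp(
        -0.5 * ((t - t_rebound) / sigma_pos) ** 2
    )
    wf /= abs(wf.min())
    return SpikeTemplate(
        waveform=wf, trough_uv=trough_uv, decay_per_channel=decay_per_channel
    )


@dataclass(frozen=True)
class SpikeInjection:
    """Schedule one spike: trough lands at ``time_s`` on ``channel``."""

    channel: int
    time_s: float
    template: SpikeTemplate


@dataclass(frozen=True)
class ArtifactInjection:
    """Rectangular artifact in units of the background SD, on all channels
    (or one channel if given)."""

    time_s: float
    amplitude_sd_units: float = 15.0
    width_ms: float = 10.0
    channel: Optional[int] = None


@dataclass(frozen=True)
class LineNoise:
    """Mains interference added to every channel."""

    freq_hz: float = 60.0
    amplitude_uv: float = 10.0

    def __post_init__(self) -> None:
        if self.freq_hz not in (50.0, 60.0):
            raise SimulationError("line frequency must be 50 or 60 Hz")


@dataclass
class SimulationPlan:
    """Full description of one synthetic recording.

    The same plan and seed always produce a bit-identical recording.
    """

    n_channels: int = 16
    duration_s: float = 2.0
    rate_hz: float = 30_000.0
    noise_sd_uv: float = 8.0
    seed: int = 0
    spikes: Sequence[SpikeInjection] = field(default_factory=tuple)
    artifacts: Sequence[ArtifactInjection] = field(default_factory=tuple)
    line_noise: Optional[LineNoise] = None
    scale_uv_per_bit: float = 0.195

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.duration_s <= 0 or self.rate_hz <= 0:
            raise SimulationError("n_channels, duration_s, rate_hz must be positive")
        if self.noise_sd_uv < 0:
            raise SimulationError("noise_sd_uv must be non-negative")


def quantize(data: np.ndarray, scale_uv_per_bit: float) -> np.ndarray:
    """Round μV data to the int16 grid and return it in μV."""
    q = np.clip(np.rint(data / scale_uv_per_bit), -32768, 32767)
    return q * scale_uv_per_bit


def simulate_recording(plan: SimulationPlan) -> tuple[RecordingBlock, pd.DataFrame]:
    """Generate a recording plus a ground-truth log of injected events.

    The log has one row per scheduled spike (kind='spike': main channel,
    trough sample, trough amplitude in μV) and per artifact
    (kind='artifact').  int16 quantization is applied last.
    """
    rng = np.random.default_rng(plan.seed)
    n = int(round(plan.duration_s * plan.rate_hz))
    data = (
        rng.normal(0.0, plan.noise_sd_uv, size=(n, plan.n_channels))
        if plan.noise_sd_uv > 0
        else np.zeros((n, plan.n_channels))
    )
    if plan.line_noise is not None and plan.line_noise.amplitude_uv > 0:
        t = np.arange(n) / plan.rate_hz
        phase = rng.uniform(0, 2 * np.pi)
        data += (
            plan.line_noise.amplitude_uv
            * np.sin(2 * np.pi * plan.line_noise.freq_hz * t + phase)
        )[:, None]

    truth_rows = []
    for spk in plan.spikes:
        if not 0 <= spk.channel < plan.n_channels:
            raise SimulationError(f"spike channel {spk.channel} out of range")
        trough_sample = int(round(spk.time_s * plan.rate_hz))
        wf = spk.template.scaled()
        start = trough_sample - spk.template.trough_index
        stop = start + wf.size
        if start < 0 or stop > n:
            raise SimulationError(
                f"spike at {spk.time_s} s does not fit in the {plan.duration_s} s block"
            )
        for ch in range(plan.n_channels):
            factor = spk.template.decay_per_channel ** abs(ch - spk.channel)
            if factor > 0:
                data[start:stop, ch] += wf * factor
        truth_rows.append(
            {
                "kind": "spike",
                "channel": spk.channel,
                "sample": trough_sample,
                "amplitude_uv": spk.template.trough_uv,
            }
        )
    for art in plan.artifacts:
        start = int(round(art.time_s * plan.rate_hz))
        width = max(int(round(art.width_ms * 1e-3 * plan.rate_hz)), 1)
        if start < 0 or start + width > n:
            raise SimulationError(
                f"artifact at {art.time_s} s does not fit in the block"
            )
        amplitude = art.amplitude_sd_units * plan.noise_sd_uv
        cols = slice(None) if art.channel is None else art.channel
        data[start : start + width, cols] += amplitude
        truth_rows.append(
            {
                "kind": "artifact",
                "channel": -1 if art.channel is None else art.channel,
                "sample": start,
                "amplitude_uv": amplitude,
            }
        )
    data = quantize(data, plan.scale_uv_per_bit)
    block = RecordingBlock(
        data=data, rate_hz=plan.rate_hz, scale_uv_per_bit=plan.scale_uv_per_bit
    )
    truth = pd.DataFrame(
        truth_rows, columns=["kind", "channel", "sample", "amplitude_uv"]
    )
    return block, truth


# ---------------------------------------------------------------------------
# saline-bath gain test


@dataclass
class GainTestPlan:
    """Saline-bath pulse train for bench-testing probe gain.

    Defaults are the bench routine: 100 square pulses of 100 μs spaced
    250 ms apart, nominal gain 1000.  ``true_amplitude_uv`` is the pulse
    amplitude set on the stimulator; the recorded deflection is
    ``true_amplitude_uv × actual_gain`` μV, so a perfectly calibrated
    front end (``actual_gain == nominal_gain``) deviates only through
    noise and quantization.
    """

    n_pulses: int = 100
    pulse_width_us: float = 100.0
    pulse_spacing_ms: float = 250.0
    true_amplitude_uv: float = 1.0
    nominal_gain: float = 1000.0
    actual_gain: Optional[float] = None
    noise_sd_uv: float = 25.0
    rate_hz: float = 30_000.0
    lead_s: float = 0.05
    seed: int = 0
    scale_uv_per_bit: float = 0.195

    def __post_init__(self) -> None:
        if self.actual_gain is None:
            self.actual_gain = self.nominal_gain
        if self.n_pulses < 0 or self.true_amplitude_uv <= 0:
            raise SimulationError("n_pulses >= 0 and true_amplitude_uv > 0 required")

    @property
    def duration_s(self) -> float:
        return self.n_pulses * self.pulse_spacing_ms * 1e-3 + 2 * self.lead_s


def simulate_gain_test(plan: GainTestPlan) -> RecordingBlock:
    """Single-channel recording of the pulse train plus Gaussian noise."""
    rng = np.random.default_rng(plan.seed)
    n = int(round(plan.duration_s * plan.rate_hz))
    x = (
        rng.normal(0.0, plan.noise_sd_uv, size=n)
        if plan.noise_sd_uv > 0
        else np.zeros(n)
    )
    width = max(int(round(plan.pulse_width_us * 1e-6 * plan.rate_hz)), 1)
    amplitude = plan.true_amplitude_uv * plan.actual_gain
    spacing = plan.pulse_spacing_ms * 1e-3
    for i in range(plan.n_pulses):
        start = int(round((plan.lead_s + i * spacing) * plan.rate_hz))
        x[start : start + width] += amplitude
    data = quantize(x[:, None], plan.scale_uv_per_bit)
    return RecordingBlock(
        data=data, rate_hz=plan.rate_hz, scale_uv_per_bit=plan.scale_uv_per_bit
    )


def estimate_gain(
    block: RecordingBlock,
    true_amplitude_uv: float,
    nominal_gain: float = 1000.0,
) -> tuple[float, float]:
    """Measured gain and its relative deviation from nominal.

    Pulses are located by thresholding at half the expected deflection
    (``true_amplitude × nominal_gain / 2``); the measured amplitude is the
    median of per-pulse peak deflections, gain = measured / true, and the
    deviation is |gain − nominal| / nominal (the bench criterion accepts
    deviations up to 0.10).
    """
    x = block.data[:, 0]
    threshold = true_amplitude_uv * nominal_gain / 2.0
    idx = np.flatnonzero(x > threshold)
    if idx.size == 0:
        raise SimulationError(
            f"no pulses found above {threshold} μV; check amplitude and gain"
        )
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    peaks = np.array([x[a:b].max() for a, b in zip(starts, stops)])
    measured = float(np.median(peaks))
    gain = measured / true_amplitude_uv
    deviation = abs(gain - nominal_gain) / nominal_gain
    return gain, deviation


# ---------------------------------------------------------------------------
# detection scoring


def _event_pairs(events) -> list[tuple[int, int]]:
    pairs = []
    for e in events:
        if isinstance(e, SpikeEvent):
            pairs.append((e.channel, e.peak_sample))
        else:
            ch, s = e
            pairs.append((int(ch), int(s)))
    return pairs


def evaluate_detection(
    events,
    truth: Union[pd.DataFrame, Sequence[tuple[int, int]]],
    tolerance_samples: int,
) -> tuple[float, float, list[tuple[int, int]]]:
    """Greedy nearest matching of detected events against the truth log.

    Events and truth entries match when on the same channel within
    ``tolerance_samples``; closest pairs are matched first and each side is
    used at most once.  Returns (recall, precision, matched index pairs
    (truth_idx, event_idx)).  Recall/precision are 1.0 for an empty truth
    or event list respectively.
    """
    if tolerance_samples < 0:
        raise SimulationError("tolerance_samples must be >= 0")
    if isinstance(truth, pd.DataFrame):
        spikes = truth[truth["kind"] == "spike"] if "kind" in truth else truth
        truth_pairs = list(zip(spikes["channel"].astype(int), spikes["sample"].astype(int)))
    else:
        truth_pairs = [(int(c), int(s)) for c, s in truth]
    event_pairs = _event_pairs(events)
    candidates = [
        (abs(ts - es), ti, ei)
        for ti, (tc, ts) in enumerate(truth_pairs)
        for ei, (ec, es) in enumerate(event_pairs)
        if tc == ec and abs(ts - es) <= tolerance_samples
    ]
    candidates.sort()
    used_truth: set[int] = set()
    used_events: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, ti, ei in candidates:
        if ti in used_truth or ei in used_events:
            continue
        used_truth.add(ti)
        used_events.add(ei)
        matches.append((ti, ei))
    recall = len(matches) / len(truth_pairs) if truth_pairs else 1.0
    precision = len(matches) / len(event_pairs) if event_pairs else 1.0
    return recall, precision, matches
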