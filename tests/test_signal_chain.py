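"""Pre-processing stages and threshold spike detection."""

import numpy as np
import pytest

from microdrive.signal_chain import (
    ChainConfig,
    DetectConfig,
    RecordingBlock,
    SignalChainError,
    average_waveform,
    bandpass,
    clip_length_samples,
    cross_channel_footprint,
    detect_spikes,
    local_average_reference,
    remove_artifacts,
    run_chain,
)
from microdrive.simulate import (
    ArtifactInjection,
    LineNoise,
    SimulationPlan,
    SpikeInjection,
    default_template,
    evaluate_detection,
    simulate_recording,
)

RATE = 30_000.0


def _block(data, rate=RATE, **kw):
    return RecordingBlock(data=np.asarray(data, dtype=float), rate_hz=rate, **kw)


def _template_block(
    trough_uv=-100.0,
    trough_sample=3000,
    n=6000,
    n_channels=1,
    channel=0,
    noise_sd=0.0,
    seed=0,
    decay=0.6,
):
    rng = np.random.default_rng(seed)
    data = rng.normal(0, noise_sd, (n, n_channels)) if noise_sd else np.zeros((n, n_channels))
    tpl = default_template(RATE, trough_uv=trough_uv, decay_per_channel=decay)
    wf = tpl.scaled()
    start = trough_sample - tpl.trough_index
    for ch in range(n_channels):
        data[start : start + wf.size, ch] += wf * decay ** abs(ch - channel)
    return _block(data)


# -- artifact removal ---------------------------------------------------------


def test_gaussian_noise_is_essentially_unmasked():
    rng = np.random.default_rng(11)
    block = _block(rng.normal(0, 10, (100_000, 2)))
    cleaned, mask = remove_artifacts(block, artifact_z=10)
    assert mask.sum() == 0  # P(|z| >= 10) ~ 1e-23 per sample
    np.testing.assert_array_equal(cleaned.data, block.data)


def test_rectangular_artifact_is_fully_masked_and_rest_untouched():
    rng = np.random.default_rng(7)
    n = 90_000  # 3 s: artifact duty cycle low enough not to hide itself
    data = rng.normal(0, 5, (n, 1))
    start, width = 30_000, 300  # 10 ms
    data[start : start + width, 0] += 15 * 5  # +15 SD rectangle
    cleaned, mask = remove_artifacts(_block(data), artifact_z=10, guard_ms=2.0)
    guard = int(round(2.0e-3 * RATE))
    assert mask[start : start + width, 0].all()  # every artifact sample masked
    # nothing masked outside artifact +/- guard
    outside = np.ones(n, dtype=bool)
    outside[start - guard : start + width + guard] = False
    assert not mask[outside, 0].any()
    np.testing.assert_array_equal(cleaned.data[outside, 0], data[outside, 0])


def test_constant_channel_is_left_unchanged_with_warning():
    data = np.full((1000, 1), 3.3)
    with pytest.warns(UserWarning, match="zero variance"):
        cleaned, mask = remove_artifacts(_block(data), artifact_z=10)
    assert mask.sum() == 0
    np.testing.assert_array_equal(cleaned.data, data)


def test_masked_samples_are_replaced_by_channel_median():
    rng = np.random.default_rng(3)
    data = rng.normal(0, 5, (90_000, 1))
    data[45_000:45_300, 0] += 100 * 5
    cleaned, mask = remove_artifacts(_block(data), artifact_z=10)
    assert np.all(cleaned.data[mask[:, 0], 0] == np.median(data[:, 0]))


# -- local common averaging ---------------------------------------------------


def test_common_mode_signal_is_annihilated():
    rng = np.random.default_rng(5)
    common = rng.normal(0, 50, 10_000)
    block = _block(np.tile(common[:, None], (1, 12)))
    out = local_average_reference(block, car_neighbors=7)
    assert np.abs(out.data).max() <= 1e-9


def test_single_channel_block_is_unchanged():
    rng = np.random.default_rng(6)
    data = rng.normal(0, 10, (1000, 1))
    out = local_average_reference(_block(data), car_neighbors=7)
    np.testing.assert_array_equal(out.data, data)


def test_isolated_signal_spreads_negatively_to_neighbors():
    """Signal on channel 7 of 15: each channel within 7 positions gets
    -signal/k where k is its own neighbor count; channel 7 is unchanged."""
    n, c = 2000, 7
    sig = np.sin(np.linspace(0, 20, n))
    data = np.zeros((n, 15))
    data[:, c] = sig
    out = local_average_reference(_block(data), car_neighbors=7)
    np.testing.assert_allclose(out.data[:, c], sig, atol=1e-12)
    for ch in range(15):
        if ch == c:
            continue
        lo, hi = max(0, ch - 7), min(14, ch + 7)
        k = hi - lo  # neighbor count (self excluded)
        expected = -sig / k if lo <= c <= hi else np.zeros(n)
        np.testing.assert_allclose(out.data[:, ch], expected, atol=1e-12)


def test_car_respects_channel_order():
    """Physical neighbors are defined by channel_order, not column index."""
    n = 500
    sig = np.ones(n)
    data = np.zeros((n, 3))
    data[:, 2] = sig  # column 2 is physically in the middle
    order = np.array([0, 2, 1])
    out = local_average_reference(_block(data, channel_order=order), car_neighbors=1)
    # physical layout: col0, col2, col1 -> col0 and col1 each have col2 as
    # their single neighbor; col2's neighbors (col0, col1) are silent
    np.testing.assert_allclose(out.data[:, 0], -sig)
    np.testing.assert_allclose(out.data[:, 1], -sig)
    np.testing.assert_allclose(out.data[:, 2], sig)


# -- band-pass ----------------------------------------------------------------


def _sine_block(freq, n_seconds=1.0, rate=RATE):
    t = np.arange(int(n_seconds * rate)) / rate
    return _block(np.sin(2 * np.pi * freq * t)[:, None], rate=rate)


def test_dc_is_removed():
    block = _block(np.full((30_000, 1), 500.0))
    out = bandpass(block)
    margin = int(0.05 * out.n_samples)
    assert np.abs(out.data[margin:-margin]).max() < 1e-6 * 500.0


def test_passband_tone_is_preserved():
    out = bandpass(_sine_block(1000.0))
    central = out.data[3000:-3000, 0]
    gain = np.abs(central).max()
    assert 0.95 <= gain <= 1.0


def test_low_frequency_tone_is_attenuated():
    out = bandpass(_sine_block(10.0))
    central = out.data[3000:-3000, 0]
    assert np.abs(central).max() < 0.05


def test_band_edges_must_respect_nyquist():
    block = _sine_block(100.0, rate=8000.0)
    with pytest.raises(SignalChainError, match="Nyquist"):
        bandpass(block, 300.0, 5000.0)


# -- detection ----------------------------------------------------------------


def test_flat_trace_yields_no_events():
    assert detect_spikes(_block(np.zeros((10_000, 1))), 0) == []


def test_single_template_detected_at_trough():
    block = _template_block(trough_uv=-100.0, trough_sample=3000, noise_sd=5.0)
    events = detect_spikes(block, 0)
    assert len(events) == 1
    ev = events[0]
    assert ev.peak_sample == 3000
    assert ev.peak_uv == pytest.approx(-100.0, abs=2.0)
    mid = len(ev.clip) // 2
    assert int(np.argmax(ev.clip)) == mid  # inverted clip peaks at the center
    assert len(ev.clip) % 2 == 1
    assert ev.clip[mid] == -ev.peak_uv


def test_subthreshold_template_is_ignored():
    block = _template_block(trough_uv=-70.0, trough_sample=3000, noise_sd=5.0)
    assert detect_spikes(block, 0) == []


def test_clip_length_is_odd():
    assert clip_length_samples(1.7, 30_000.0) == 51
    assert clip_length_samples(1.0, 30_000.0) == 31  # 30 rounded odd
    assert clip_length_samples(0.001, 30_000.0) == 1


def test_channel_out_of_range_is_an_error():
    with pytest.raises(SignalChainError, match="out of range"):
        detect_spikes(_block(np.zeros((100, 2))), 5)


def test_lockout_suppresses_immediate_redetection():
    n = 6000
    data = np.zeros((n, 1))
    data[3000, 0] = -120.0
    data[3010, 0] = -120.0  # within one clip length of the first peak
    data[4000, 0] = -120.0  # beyond lockout
    events = detect_spikes(_block(data), 0, DetectConfig(peak_z_min=0.5))
    assert [e.peak_sample for e in events] == [3000, 4000]


def test_peak_z_filter_prunes_crossings_on_high_variance_channels():
    rng = np.random.default_rng(9)
    data = rng.normal(0, 100, (30_000, 1))  # threshold is < 1 SD here
    cfg = DetectConfig(threshold_uv=-80.0, peak_z_min=3.0)
    events = detect_spikes(_block(data), 0, cfg)
    x = data[:, 0]
    for ev in events:
        assert abs((ev.peak_uv - x.mean()) / x.std()) >= 3.0


def test_edge_overrunning_clip_is_dropped():
    data = np.zeros((100, 1))
    data[5, 0] = -120.0  # too close to the start for a 51-sample clip
    assert detect_spikes(_block(data), 0) == []


# -- average waveform ---------------------------------------------------------


def test_average_of_identical_clips_is_the_clip():
    block = _template_block(trough_uv=-120.0, trough_sample=3000)
    ev = detect_spikes(block, 0, DetectConfig(peak_z_min=0))[0]
    from microdrive.signal_chain import SpikeEvent

    clones = [SpikeEvent(0, ev.peak_sample, ev.peak_uv, ev.clip.copy()) for _ in range(5)]
    mean, sd = average_waveform(clones)
    np.testing.assert_allclose(mean, ev.clip, rtol=1e-14, atol=1e-14)
    assert np.abs(sd).max() <= 1e-13


def test_average_of_two_clips_is_pointwise_mean():
    from microdrive.signal_chain import SpikeEvent

    a = SpikeEvent(0, 50, -100.0, np.linspace(0, 1, 51))
    b = SpikeEvent(0, 80, -90.0, np.linspace(1, 0, 51))
    mean, _ = average_waveform([a, b])
    np.testing.assert_allclose(mean, (a.clip + b.clip) / 2)


def test_average_waveform_converges_to_template():
    """Mean over 100 noisy copies approaches the template (CLT bound)."""
    rng = np.random.default_rng(13)
    sigma = 4.0
    tpl = default_template(RATE, trough_uv=-150.0)
    wf = tpl.scaled()
    from microdrive.signal_chain import SpikeEvent

    clip_template = np.zeros(51)
    start = 25 - tpl.trough_index
    clip_template[start : start + wf.size] = -wf  # inverted, trough-centered
    events = [
        SpikeEvent(0, 100, -150.0, clip_template + rng.normal(0, sigma, 51))
        for _ in range(100)
    ]
    mean, _ = average_waveform(events)
    assert np.abs(mean - clip_template).max() <= 4 * sigma / np.sqrt(100)


def test_empty_event_list_is_an_error():
    with pytest.raises(SignalChainError):
        average_waveform([])


# -- footprints ---------------------------------------------------------------


def test_footprint_on_single_channel_block_is_empty():
    block = _template_block(trough_uv=-120.0, trough_sample=3000, n_channels=1)
    ev = detect_spikes(block, 0, DetectConfig(peak_z_min=0))[0]
    fp = cross_channel_footprint(block, ev, DetectConfig(peak_z_min=0))
    assert fp.neighbor_clips == {}


def test_footprint_follows_geometric_decay_and_threshold():
    """-150 μV trough decaying 0.6/step: +/-1 (-90) detected, +/-2 (-54) absent."""
    block = _template_block(
        trough_uv=-150.0, trough_sample=3000, n_channels=9, channel=4, decay=0.6
    )
    cfg = DetectConfig(peak_z_min=0)
    ev = detect_spikes(block, 4, cfg)[0]
    fp = cross_channel_footprint(block, ev, cfg)
    assert set(fp.neighbor_peak_uv) == {-1, 1}
    for off in (-1, 1):
        assert fp.neighbor_peak_uv[off] == pytest.approx(-90.0, abs=0.5)
        clip = fp.neighbor_clips[off]
        assert np.argmax(clip) == len(clip) // 2  # decayed copy is trough-aligned


def test_footprint_ignores_uncorrelated_noise_neighbors():
    rng = np.random.default_rng(21)
    n = 30_000
    data = rng.normal(0, 5, (n, 5))  # P(sample <= -80 μV) ~ Phi(-16) ~ 0
    tpl = default_template(RATE, trough_uv=-150.0)
    wf = tpl.scaled()
    start = 15_000 - tpl.trough_index
    data[start : start + wf.size, 2] += wf
    block = _block(data)
    ev = detect_spikes(block, 2)[0]
    fp = cross_channel_footprint(block, ev)
    assert fp.neighbor_peak_uv == {}


# -- full chain ---------------------------------------------------------------


def test_zero_block_produces_zero_events():
    block = _block(np.zeros((30_000, 4)))
    with pytest.warns(UserWarning):  # zero-variance channels in stage 1
        events, footprints, audit = run_chain(block)
    assert sum(audit["event_counts"].values()) == 0
    assert footprints == []


def test_chain_recovers_injected_spikes_on_distinct_channels():
    """k supra-threshold spikes on distinct channels -> exactly k events at
    the injected positions, on a background with common line interference."""
    tpl = default_template(RATE, trough_uv=-150.0, decay_per_channel=0.4)
    spikes = tuple(
        SpikeInjection(channel=ch, time_s=0.3 + 0.11 * i, template=tpl)
        for i, ch in enumerate([2, 5, 8, 11])
    )
    plan = SimulationPlan(
        n_channels=12,
        duration_s=1.5,
        noise_sd_uv=6.0,
        seed=42,
        spikes=spikes,
        line_noise=LineNoise(freq_hz=60.0, amplitude_uv=120.0),
    )
    block, truth = simulate_recording(plan)
    events_by_channel, footprints, audit = run_chain(block)
    events = [e for evs in events_by_channel.values() for e in evs]
    recall, precision, _ = evaluate_detection(events, truth, tolerance_samples=30)
    assert recall == 1.0 and precision == 1.0
    assert audit["stage_order"][0] == "artifacts"  # canonical order contract


def test_chain_is_linear_without_artifact_stage():
    rng = np.random.default_rng(17)
    a = rng.normal(0, 10, (20_000, 6))
    b = rng.normal(0, 10, (20_000, 6))
    chain_cfg = ChainConfig()

    def processed(data):
        _, _, audit = run_chain(_block(data), chain_cfg, skip_artifacts=True)
        return audit["processed"].data

    lhs = processed(a + b)
    rhs = processed(a) + processed(b)
    assert np.abs(lhs - rhs).max() <= 1e-6


def test_chain_rejects_band_violating_nyquist():
    block = _block(np.zeros((1000, 2)), rate=8000.0)
    with pytest.raises(SignalChainError):
        run_chain(block)


# -- config validation --------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(artifact_z=0),
        dict(bp_low_hz=5000.0, bp_high_hz=300.0),
        dict(car_mode="diagonal"),
    ],
)
def test_invalid_chain_config_rejected(kwargs):
    with pytest.raises(SignalChainError):
        ChainConfig(**kwargs)


@pytest.mark.parametrize("kwargs", [dict(threshold_uv=80.0), dict(clip_ms=0)])
def test_invalid_detect_config_rejected(kwargs):
    with pytest.raises(SignalChainError):
        DetectConfig(**kwargs)


def test_channel_order_must_be_permutation():
    with pytest.raises(SignalChainError):
        RecordingBlock(
            data=np.zeros((10, 3)), rate_hz=RATE, channel_order=np.array([0, 1, 1])
        )
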