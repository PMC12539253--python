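# Methods

## Gear and screw kinematics

A planetary stage with the sun as input, carrier as output, and fixed ring
has turn ratio `S / (R + S)`; cascaded stages multiply. Ratios are stored as
exact rationals (`fractions.Fraction`) and only converted to floating point
when a distance in millimetres is produced, so the kit's 25:1 train is exact
and cumulative ledger sums cannot drift. Planet tooth counts do not enter
the ratio; when supplied they are checked against the meshing constraint
`R = S + 2·planet`, and a violation warns rather than raises (the counter
stage 5/20/45 satisfies it, and the ratio is well defined either way).

Sign convention: positive turns are counterclockwise at the drive screw and
extend the probe out of the implant base (descend into tissue). The
convention is carried in `DriveConfig` so hardware with opposite handedness
can flip it by negating turns.

Defaults match the kit hardware: 0.3 mm pitch screw (a finer pitch prevents
thread skipping; anything ≤ 0.5 mm preserves micron-level resolution), two
8/32 planetary stages (25:1, 12 μm per input turn), and a 10:1 counter
stage (5/20/45) that displays input turns without altering the drive.

## Depth ledger

Depth is the dorsoventral coordinate DV, negative below the surface;
adjustments into tissue are negative distances, so a "60 μm advance" is
stored as −0.060 mm. The tip depth is always `DV0 + Σ Dᵢ` recomputed from
the full record (`math.fsum`, which also makes the sum exactly
permutation-invariant); nothing incremental is trusted. Records are
append-only; each stores both the turns applied and the signed distance, and
loading a persisted ledger re-verifies that |distance| matches the kinematic
conversion of the turns to 1e-9 mm.

The usable shank guard defaults to 9.5 mm (a 10 mm shank minus the 0.5 mm
bottom wall) and refuses draws or adjustments past it. Planning quantizes to
whole geared input turns by default — whole turns are what the counter disk
displays — with quarter-turn resolution available to match the counter
knob's 0.25/0.5/0.75 marks; half-step ties round toward fewer turns, so the
planner never overshoots a target on a tie. Dates and scheduling cadence are
free-text notes, not enforced logic.

Persistence is a CSV with `#`-prefixed metadata lines (DV0, geometry, screw
pitch, stage tooth counts, shank guard) above the record table. Floats are
serialized with `repr`, which round-trips IEEE doubles exactly, so
write→read→write is byte-identical.

Calibration: counting the counterclockwise turns needed for the tip to reach
the 3 mm reference mark and subtracting the 10-turn reference gives the
error turns ET; `ED = pitch × ET` is the print-tolerance gap, and pre-turning
ET after full retraction zeroes it. In the idealized shuttle model
(position = −gap + pitch × turns) this correction is exact for any gap, which
the tests verify across gaps in [0, 3] mm.

## Signal chain

Stage order is fixed: artifact removal → local common averaging → band-pass
→ detection. The audit log returned by `run_chain` records the order, the
parameters, the artifact mask, and per-channel event counts.

**Artifact removal** computes each channel's mean and SD over the whole
recording and masks samples with |z| ≥ 10, dilated by a ±2 ms guard window;
masked samples are replaced by the channel median rather than dropped so
sample indices stay aligned across stages. Replacing rather than excising is
a deliberate choice: downstream clip extraction and footprint windows index
by sample. Because the z-score uses the plain (not robust) SD of the whole
channel, an artifact can partially hide itself if it occupies a large
fraction of the block; the threshold works as intended when artifacts are
rare relative to the block length, which is the regime it is meant for. A
constant channel has no defined z and is skipped with a warning.

**Local common averaging** subtracts, from each channel, the mean of up to 7
physically neighboring channels per side (self excluded, truncated at the
shank ends; neighborhoods follow `channel_order`, not column index). Any
signal common to all channels is annihilated exactly. An alternative
"nearest-k-total" neighborhood is selectable in the config. A single-channel
block passes through unchanged.

**Band-pass** is a 2nd-order Butterworth, 300–5000 Hz, applied
forward-backward (`sosfiltfilt`). Zero-phase filtering preserves the trough
timing that clip centering depends on; the effective magnitude response is
the square of the designed filter. Band edges violating Nyquist raise.

**Detection** treats each contiguous run of samples at or below −80 μV as one
candidate, takes the most negative sample as the peak (earliest on ties),
enforces a dead time of one clip length after each accepted peak (the
source procedure states no dead time; one clip length is the shortest
lockout that prevents a single spike from producing two overlapping clips),
and prunes candidates whose |z| against the whole channel is below 1. The
secondary z filter is interpreted as a peak-amplitude criterion — a sanity
check that prunes bare threshold crossings on high-variance channels; this
interpretation is a configurable decision, not ground truth from the source
procedure. Clips are `round(clip_ms × rate)` samples forced odd (51 at
30 kHz), inverted, with the trough as the exact middle sample; clips that
would overrun the block edge drop the event.

**Footprints** re-apply the same criterion (threshold + |z| filter) inside
the clip window on the nearest 4 channels per side, recording the inverted
window and its peak amplitude where the criterion is met and leaving the
offset absent otherwise.

## Synthetic recordings

The generator emulates what the chain sees in practice: per-channel Gaussian
background noise, biphasic negative-dominant spikes whose amplitude decays
geometrically per channel step (symmetric above/below the main channel),
rectangular high-amplitude artifacts, optional 50/60 Hz common line
interference, and int16 quantization (default 0.195 μV/bit, typical of
front-end ADCs) applied last. Identical plan + seed is bit-identical; every
injected event is logged with channel, trough sample and amplitude.

The default spike template is a difference of Gaussians, 1.2 ms long with
the trough at one third of the duration — any fixed negative-dominant shape
satisfies the chain's assumptions, and this one has the qualitative
sharp-trough/slow-rebound form of an extracellular action potential.
Geometric decay (default 0.6 per channel step) is the simplest model that
reproduces amplitude falling off with electrode distance.

Realism choice that matters for interpreting the tests: raw in-vivo
recordings are dominated by large common components (LFP, mains pickup), so
a 10 SD artifact threshold on the raw signal sits far above spike
amplitudes. A synthetic background of only quiet AP-band noise would invert
that relationship and the artifact stage would mask genuine spikes.
End-to-end detection benchmarks therefore include 60 Hz interference of
120 μV amplitude in the background — restoring the realistic SD ordering —
which the chain itself then removes (common averaging cancels the common
sinusoid; the band-pass removes the residue). The detection benchmark uses
−150 μV troughs on 8 μV noise with decay 0.4 per step, so a spike's copies
on neighboring channels (−60 μV) are below the −80 μV threshold: the
ground-truth log names one channel per spike, and sub-threshold neighbors
keep "detected on the neighbor" from being scored as a false positive. The
footprint tests use decay 0.6, where ±1 neighbors (−90 μV) are detectable
and ±2 (−54 μV) are not.

What passing these benchmarks does **not** show about real data: no
biophysical neuron or electrode-impedance model, no drift, no overlapping
spikes from distinct units, no spike sorting; amplitudes and noise are
stationary. The benchmarks validate the chain's mechanics (masking,
referencing, filtering, thresholding, alignment, scoring), not its
selectivity among real units.

## Saline-bath gain test

The bench routine is 100 square pulses of 100 μs (3 samples at 30 kHz),
spaced 250 ms apart, nominal gain 1000. The source procedure prints no
measured gain or true amplitude, only the ≤ 10% acceptance bound, so the
generator's defaults were fixed once: true amplitude 1 μV giving 1000 μV
recorded deflections, and noise SD 25 μV (2.5% of the pulse amplitude, a
quiet but not noiseless bath). Pulses are located by thresholding at half
the expected deflection; the measured amplitude is the median of per-pulse
peaks, gain = measured/true, deviation = |gain − nominal|/nominal. Taking
the per-pulse *peak* of 3 noisy samples biases the estimate upward by
roughly E[max of 3 N(0, σ)] ≈ 0.85 σ (≈ 2% of the pulse here) — a faithful
rendering of reading an amplitude off an acquisition window, and well inside
the 10% criterion.

## Problem sizes

The detection benchmark runs 208 spikes over 16 channels × ~12 s at 30 kHz;
the gain bench runs 20 seeds × 100 pulses (~25 s of single-channel signal
each); kinematic and ledger checks are closed-form. These sizes give the
recall/precision and deviation estimates comfortable margins while keeping
the full suite fast.

## Known limitations

- The artifact z-score is non-robust by design (it mirrors the offline
  procedure it reimplements); long artifacts in short blocks inflate the SD
  and can partially escape masking.
- Detection is per-channel; a unit visible on several channels is detected
  independently on each channel that crosses threshold (footprints relate
  them but nothing deduplicates).
- The ledger models depth only — no anteroposterior/mediolateral transforms
  or per-animal anatomy.
- Torque, backlash and thread-skip are outside the kinematic model; the
  gear math assumes ideal meshing.
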