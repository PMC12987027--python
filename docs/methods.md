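# Methods

This note documents the signal models, measurement conventions, and
numerical choices behind cardioqt, and what its synthetic-data tests do and
do not demonstrate about real recordings.

## Signal path and units

All analysis runs at a fixed sampling rate (default 500 Hz) on microvolt
signals. Raw device counts are scaled by the converter LSB, computed as
`2·V_ref / 2^24` with `V_ref = 2.4 V` at unity gain (≈ 0.2861 µV/count);
the constant is derived at run time, never hard-coded. Sample indexing is
0-based; intervals are reported in ms as `(end − start)/fs × 1000`; all
search windows are half-open `[start, end)`.

## Packet protocol

Frames are 40 bytes: sync word `AA FF F1`, length byte `0x22` (34 payload
bytes), eight int32 little-endian samples in channel order I, II, V1–V6,
two lead-off flag bytes (bit *i* of byte 0 marks channel *i* disconnected;
byte 1 is opaque and preserved verbatim), and two checksum bytes.
Checksum 1 is the sum of bytes 0–37 modulo 256. Checksum 2 is defined here
as the running modulo-256 sum of all checksum-1 values since stream start,
reset per session — the simplest stateful reading of a "cumulative"
checksum; it is carried on decoded packets for stream-level auditing but
not verified per frame. Decoding never raises: bad header, bad length, or
bad checksum produce typed reject values so the resynchronizer can advance
one byte and continue. This guarantees that a single corrupted byte in the
covered region is always detected, and that any true frame following up to
39 junk bytes is recovered.

## Conditioning

The chain is a 2nd-order Butterworth high-pass at 0.5 Hz (DC/baseline), an
IIR notch at the mains frequency (default 50 Hz, Q = 30, ≈ 1.7 Hz
bandwidth), and a 4th-order Butterworth low-pass at 125 Hz — each applied
forward-backward (`sosfiltfilt`) so fiducial latencies are exactly
preserved. Reflection padding of 6 s is used because the 0.5 Hz high-pass
transient decays over ≈ 0.5 s and shorter padding leaves percent-level edge
ripple in band. Filtering is segment-wise over contiguous valid runs;
samples flagged invalid never enter filter state, and valid runs shorter
than 1 s (too short to settle) are themselves invalidated. Lead-off runs
are widened by a 250 ms guard band on each side before masking — the scale
of amplifier/filter settling after a contact change. Derived limb leads
inherit the union of their source channels' invalid samples.

## R-peak detection

A Pan–Tompkins-style chain: zero-phase band-pass 5–25 Hz, squaring, 150 ms
moving-window integration, then a block-adaptive threshold (per 10 s block,
20 % of the block maximum, floored at 5 % of the global maximum — the
detector runs offline, so a non-causal threshold is acceptable and far more
stable on short records than a causal running estimate). Candidates are
refined to the largest absolute band-passed deflection within ±100 ms,
which makes detection polarity-robust. The refractory rule keeps the
candidate with the larger integrated energy whenever two refined peaks fall
strictly closer than 0.4 s; a spacing of exactly 0.4 s is accepted. The
boundary is deliberate: the minimum inter-peak interval the detector
enforces is 0.4 s, and the threshold gap at which a shrinking two-beat
train is first fully detected equals 0.4 s.

## Delineation

Each beat needs 300 ms of context before R and 700 ms after; truncated or
partially masked windows are excluded as `masked_segment`. Within the beat
window, slopes are estimated with Savitzky–Golay derivatives at two scales:
18 ms (degree 3) for the narrow QRS edges and 50 ms for the broad T wave.
The two scales matter: a single window either over-smooths the Q/S edges
(biasing Q onset late) or leaves the T-wave slope estimate noise-limited
(biasing the tangent steep and T end early).

* **Q onset / QRS offset** — backward/forward march from R (within 120 ms)
  until the absolute smoothed slope stays below 3 % of the QRS peak slope
  for 6 ms. The threshold is relative, so fiducial positions are invariant
  to amplitude scaling.
* **Baseline** — mean of the 40 ms PQ window ending at Q onset, per beat.
* **T peak** — largest absolute baseline deviation of the smoothed signal
  in `[J + 80 ms, J + 400 ms)`.
* **T end** — tangent method: the steepest post-peak tangent (within
  250 ms of T peak, slope sign opposite to T polarity) extrapolated to the
  baseline. For a Gaussian T wave this lands exactly 2σ past the peak,
  which is also the generator's ground-truth convention, making "true QT"
  well defined.
* **Exclusions** — `low_t_amplitude` when |T| < max(50 µV, 3 × noise RMS);
  `ambiguous_morphology` when the T window contains large deflections of
  both polarities (biphasic T) or a same-sign deflection ≥ 25 % of the T
  amplitude appears within 200 ms after the tentative T end (U-wave
  suspicion); `tend_undetectable` when the tangent never returns to
  baseline in time. The opposite-polarity (biphasic) threshold reuses the
  max(50 µV, 3 × noise) floor: with a noise-free input the estimated noise
  RMS is numerically ~0 and a bare 3×-noise rule would flag every beat on
  filter ripple alone.
* **Noise RMS** — per lead, 1.4826 × MAD of PQ-segment residuals about
  their window means, over all detected beats.

## Rhythm, morphology, repolarization

RR intervals come from consecutive R peaks; HR = 60/mean(RR); SDNN is the
sample standard deviation (N−1) of RR in ms. Morphology (P duration, QRS
width, T amplitude, ST shift) is the per-lead median over valid beats; ST
level is averaged over `[J + 60 ms, J + 80 ms]` against the PQ baseline.

Per-beat QT values per lead pass through robust outlier filtering: the MAD
rule drops values farther than 3 × 1.4826 × MAD from the median, falling
back to the 1.5 × IQR fence when the MAD collapses to zero (as it does
when more than half the values tie). A lead is eligible when its retained
count reaches 30, or at least 50 % of all cycles in the fragment — read as
a disjunction, so either branch suffices. QT dispersion is max − min of
eligible leads' medians over I, II, V1–V6 and is NA whenever fewer than 6
leads are eligible; NA is never imputed downstream. The recording-level QT
is the lead II median (the standard rhythm lead), and QTc uses Bazett's
formula with the fragment's mean RR rather than per-beat RR, since one
corrected value is reported per recording. Recordings from different
postures are processed independently and never pooled.

Reference-range flagging uses inclusive lower and exclusive upper bounds
(`QTc < 450 ms` means 450 ms is out of range), except the ST band
(±0.1 mV), which is inclusive. When sex is unspecified the stricter QTc
bound (450 ms) applies, avoiding false reassurance.

## Synthetic generator

Beats are sums of Gaussian bumps. Conventions: Q and S bumps sit at
∓0.3 × QRS width with σ = QRS/10; R at the beat time with σ = QRS/7; QRS
onset/offset are defined 2.5σ outside the Q/S centers. The T wave has
σ = 40 ms and is centered at `q_onset + QT − 2σ`, so the tangent T-end
convention reproduces the requested QT analytically. An optional ST
plateau rises 10 ms after J and decays before the T upstroke; an optional
U wave (fraction of T amplitude) sits 150 ms past the true T end. The RR
sequence is `60000/HR + N(0, jitter)` ms with a floor that prevents beat
overlap. Disturbances are per-channel Gaussian noise (default 10 µV RMS),
a 0.2 Hz sinusoidal baseline wander (50 µV), and a mains sinusoid (20 µV),
with seed-determined phases. Default sessions emulate the acquisition
protocol: 60 s, 500 Hz, eight channels, HR 60, 15 ms RR jitter. Lead-off
episodes zero the channel (open circuit) and set the packet flag bit, so a
masking failure is visible downstream. µV→count conversion uses
round-half-even, giving an exact ±half-LSB round-trip bound.

What the generator does **not** emulate: real T-wave asymmetry and
rate-adaptation (QT/RR hysteresis), respiratory baseline modulation,
muscle-artifact bursts, electrode motion transients, ectopy, or atrial
fibrillation. Passing recovery tests therefore demonstrates correctness of
the measurement conventions and robustness to stationary Gaussian-type
disturbances — not clinical-grade delineation accuracy on pathological
morphologies.

## Problem sizes and determinism

The test suite and the acceptance script work at desk scale: 60 s sessions
at 500 Hz (30 000 samples × 8 channels), sweeps of 8 full-pipeline runs
for the eligible-lead threshold, 31 two-beat trains for the refractory
sweep, and 20 seeded sessions for parameter recovery (QT within ±8 ms, QTc
within ±10 ms, QTd mean absolute error < 12 ms). Every stochastic input is
driven by an explicit seed; identical seeds give byte-identical recordings
and bit-reproducible features.

## Known limitations

* Very long QT at short RR (e.g., QT > 500 ms at RR ≤ 0.8 s) pushes the T
  end into the next beat's P wave; the U-wave suspicion window then
  legitimately excludes many beats and slow precordial leads may become
  ineligible. This is the intended conservative behavior of the exclusion
  rules, but it limits recovery at extreme parameter combinations.
* The P-wave bounds (5 % amplitude crossings) systematically measure a few
  percent short of the generator's nominal P duration; P duration carries
  no reference range and is reported as-is.
* Checksum 2 semantics and the second flag byte's bit assignment are not
  defined by the wire format description available; the implementations
  here (running checksum-1 sum; opaque carry) are documented choices.
* The detector's block-adaptive threshold assumes an offline record; it is
  not a streaming implementation.
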