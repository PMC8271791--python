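# Methods

This note documents the models, conventions and numerical choices behind
the package: what the simulator computes, which parts of the wire protocol
are defined here rather than by hardware, and what the test suite does and
does not demonstrate about real silicon.

## Interface model and wire dialect

The digital interface is modelled exactly at its published rates: 16 lines
at 50 MHz, one 16-bit word per clock tick (bit *i* = line *i*), 40 kHz
channel sampling, so 1250 ticks per sampling period and 2.5×10⁷ words per
0.5 s chunk (10⁸ bytes — 95.37 MiB — per second of stream). Lines 0–7 each
belong to one 64-channel chip; lines 8–15 are binary trigger lines held at
their level for a full sampling period.

The original chips' bit-level framing is proprietary; the dialect
implemented in `neurostim.protocol` is an explicit stand-in that reproduces
every published rate and ordering constraint (see the module docstring for
the exact field layout). Choices worth calling out:

* **One 1250-bit frame per line per sampling period.** A frame is either a
  no-op (all zeros — which makes an undriven line indistinguishable from an
  idle one, as on real hardware) or a real-time data command: an opcode
  byte followed by 64 twelve-bit channel control words.
* **State-change records ride in frame padding.** Register assignments are
  32-bit records packed into the unused tail of the *leading* frames of a
  chunk, with a strict prefix rule (a frame's record region may be used
  only when all earlier regions are full). Logically every state command
  therefore precedes every real-time command of its chunk — the ordering
  the chip's command parser assumes — while a fully-populated chunk still
  carries exactly 40,000 real-time commands per second per line. The parser
  enforces both the prefix rule and opcode validity and reports word
  offsets for violations.
* **Sync ids are chunk metadata**, carried in a JSON sidecar on disk, never
  in-band; −1 marks a keep-alive repetition of the previous chunk and is
  dropped by `demux.sync_filter` before any further processing.
* **MiB convention.** The published "95.37 MB/s" and "19.84 MB" figures are
  binary mebibytes of the exact byte counts (10⁸ B and 520·20,000·2 B).

## Chip behavioral model

`neurostim.asic` replaces the silicon with a per-channel signal model:

* **Current DACs.** `Io = dac10·dac7·dac4 / (1023·127·15) · 15 µA`, sign
  from the polarity bit. The model is exactly multilinear in the three
  codes; no DNL/INL is simulated.
* **Loopback.** Test mode feeds `Io · R_loop` into the channel input;
  `R_loop` defaults to exactly 5500 Ω (the hardware value is "~5.5 kΩ" with
  unstated tolerance; it is configurable per channel).
* **Band-pass + gain.** `K(s) = K₀ sT_H / ((1+sT_H)(1+sT_L))` discretized
  with the bilinear transform at 40 kHz. Bilinear preserves the DC zero and
  the low-frequency response where the characterization fits operate; its
  known cost is a mild warping near Nyquist (≈0.2% at 1 kHz, larger toward
  20 kHz). Filter state persists across chunks inside a simulator instance,
  so multi-chunk runs behave as one continuous recording.
* **Register → cut-off map.** The 5-bit filter registers map
  logarithmically onto the calibrated ranges 0.6–7 Hz (high-pass) and
  1050 Hz–20 kHz (low-pass), register 1 at the measured low end, register
  31 at the specified top; register 0 aliases 1. The true silicon map is
  unpublished — this one is a documented convention, and per-channel
  `ChannelModelParams` can override `T_H`/`T_L` (and the gain) to model
  mismatch.
* **ADC.** `code = round_half_up((v + 1.8)/3.6 · 4095)`, clipped to
  0–4095; 0 V maps to code 2048, which is also the constant carried by
  vacant chip slots. Saturation is hard clipping only — no slewing or
  recovery dynamics.
* **Noise**, referred to the output: a white floor (default 10 µV RMS,
  keeping the density at 10 kHz comfortably under the 20 µV RMS scale of
  the bench measurements), an optional 1/f term generated by FFT spectral
  shaping, and an optional 10 kHz spur tone (off by default). All noise
  comes from one seeded generator; seeded runs are bit-reproducible.

What the simulator deliberately does **not** emulate: transistor-level
nonlinearity, the real chips' mismatch statistics (a gain/offset profile
can be injected but none is hard-coded as truth), stimulation artefacts
through tissue, and electrode electrochemistry. Tests that "recover ground
truth" therefore demonstrate that the *analyses* are correct and unbiased
at realistic signal scales — not that any particular silicon meets spec.

## Stimulation building

Pulse shapes are per-period DAC code triples. Amplitudes given in amperes
are quantized by exhaustive search over the (dac7, dac4) grid, with the
relative error reported and a 5% default tolerance before the request is
refused. Arbitrary waveforms quantize onto the signed 7-bit space
(128 magnitudes × 2 polarities = 256 levels) with round-half-away-from-zero,
which preserves the antisymmetry of bipolar pulses; the 4-bit DAC is kept
free as an amplitude multiplier. Overlapping pulses on one channel are a
scheduling error rather than silently truncated, because truncation would
corrupt charge balance. Trigger lines are raised for the full duration of
each pulse. The keep-alive queue holds 4 s of stream (8 standard chunks)
and re-issues the last chunk tagged −1 when starved.

The pulse-rate stress protocol draws its "pseudo-random" pulse times
stratified per 0.5 s window (non-overlapping, with at least one idle period
between pulses), which is what makes the per-chunk pulse count an exact
protocol constant rather than a Poisson variate.

## Characterization procedures and their scaling

* **Amplitude scan.** 26 series (7-bit DAC 2→127 in steps of 5, 4-bit DAC
  at 15), gain × 10-bit-DAC held at 12,000, 10 ms periods of two unipolar
  pulses. The period's quarter-segment layout (+pulse, off, −pulse, off) is
  a convention of this package — the original timing diagram is not
  dimensioned. Per-period amplitudes subtract the adjacent baselines and
  average both polarities; five guard samples are skipped at each segment
  head to keep filter edge transients out of the means. The remaining
  systematic is the high-pass droop over each 2.5 ms pulse, ≈0.5% at the
  0.6 Hz setting — visible as the ≈+0.4% gain bias in the worked example
  and well inside the 1% recovery requirement.
* **Gain fit.** Plain least squares of the mean amplitudes against
  `Io · R_loop`, after dropping points with |V̄| > 0.8 × 1.8 V as
  amplifier-saturated (the 0.8 fraction is configurable; the bench data
  show distributions narrowing near 825 mV but publish no cut).
* **Noise PSD.** `scipy.signal.welch`, Hann window, one-sided density,
  10 s segments with 5 s overlap. A 3 h recording yields 2159 averaged
  periodograms. (Note that at exactly 10,000 s the segment arithmetic gives
  1999, so the "≥2000 periodograms" figure presumes the longer actual
  recordings.)
* **Filter cut-offs.** The response to a 0.1 Hz, 92 nA bipolar square wave
  is folded into the average absolute half-period response (the first,
  half-height transition is discarded; alternate halves are sign-aligned
  before averaging so the near-zero tail is not rectified into a bias). The
  fold's time axis is placed at mid-sample: the digitized chain tracks the
  continuous step response at sampling-interval midpoints, and ignoring
  that half-sample shifts the fitted low-pass cut-off by ≈8%. The
  two-exponential model is then fitted in log-parameter space
  (`curve_fit`, tight tolerances), initialized from the peak position and
  the tail's log-slope; the model is symmetric under swapping the two time
  constants, so the fit canonicalizes `T_H > T_L`. On an exact synthetic
  curve the parameters come back to better than six significant digits.
* **Spike fidelity.** Recorded repetitions of the quantized reference are
  averaged and normalized to unit peak before residuals are taken, so only
  waveform *shape* is compared; amplitude scaling across the 4-bit DAC
  sweep (1/15 … 1 of full scale) is checked separately from the DAC law.

Test and acceptance runs scale the published procedures down — 5–10
repetitions per scan amplitude instead of 1000, 10 square-wave periods
instead of 500, seconds of noise instead of hours — sizes chosen so every
recovery criterion is exercised with comfortable statistical margin on a
single CPU. The stress-protocol pulse count runs at full scale (one second
of real 0.5 s chunks).

## Visualization DSP

Min–max decimation emits each block's extrema in temporal order, never
invents values, and preserves global extrema exactly. Trigger alignment
uses rising edges, skips events whose window would leave the data, and
multiple trigger lines combine by logical OR (the original "arbitrary
combination" operator is unspecified). Amplitude clipping is applied before
decimation. Band splitting uses a single-pass causal Butterworth — the
textbook −3 dB point at the cut-off, at the price of nonlinear phase;
first-order low/high pairs at the same cut-off are exactly complementary,
higher orders are not (documented limitation). Spectra are plain one-sided
rFFT magnitudes.

## Archiving

Datasets are single HDF5 files: per-chunk 520 × N uint16 matrices (stored
chunk-aligned so gzip, when enabled, compresses the constant vacant
channels very effectively), optional float32 stimulation waveforms, and the
full setup (register images + experiment-protocol JSON) — a dataset without
its setup is refused. The replay player re-emits the chunks overlapping a
requested time window and allows one active replay at a time.

## Known limitations

* The wire dialect matches the published rates and constraints but is not
  the proprietary bit layout; captures from real hardware cannot be parsed.
* The filter-register map and the scan-period pulse layout are documented
  conventions (see above), not measured silicon properties.
* The band-pass model is strictly first order per branch; real channels
  showing higher-order roll-off would fit with small systematic residuals.
* No real-time pacing, multiprocessing or network distribution: throughput
  figures of the production system are out of scope, only the data
  contracts of each stage are implemented.
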