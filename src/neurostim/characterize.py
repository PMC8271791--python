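"""Channel characterization: amplitude response, gain linearity, noise PSD,
band-pass cut-off extraction and arbitrary-waveform (spike) fidelity.

These are the desk analyses run on loopback test recordings, in which each
channel samples its own stimulation current injected through the ~5.5 kOhm
loop resistor:

* **amplitude scan** — square pulses of stepped amplitude (7-bit DAC swept
  2..127 in steps of 5 at fixed 4-bit DAC = 15) with the gain x 10-bit-DAC
  product held at 12,000 so every gain setting spans the same ADC range;
  per-period mean amplitudes are taken over the in-pulse samples minus the
  no-stimulation baselines;
* **gain fit** — the per-current mean amplitudes against ``Io * R_loop``
  fitted by a line, slope = actual gain ``g_fit``, intercept = offset
  ``o_fit``; dividing by the unamplified curve ``Io * R_loop`` exposes any
  amplitude dependence of the gain;
* **noise PSD** — Welch averaging with 10 s segments / 5 s overlap;
* **filter cut-offs** — the channel's averaged absolute response to the half
  periods of a slow (0.1 Hz) bipolar square wave follows the first-order
  band-pass step response

      Y(t) = K0 * TH / (TL - TH) * (exp(-t/TL) - exp(-t/TH)),

  which is fitted by nonlinear least squares; cut-offs are reported as
  ``fc_hp = 1/(2 pi TH)`` and ``fc_lp = 1/(2 pi TL)``;
* **spike reproduction** — recorded repetitions of a quantized reference
  waveform are averaged, normalized to peak 1 and compared sample-by-sample
  with the normalized reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.signal

from . import demux as demux_mod
from . import stim
from .asic import (
    ADC_RAIL,
    AsicState,
    ChannelModelParams,
    R_LOOP_DEFAULT,
    SystemSimulator,
    adc_quantize,
    io_current,
    signal_chain,
    time_constants,
)
from .errors import AlignmentError, FitError
from .protocol import CHANNELS_PER_ASIC, SAMPLE_RATE
from .stim import PulseShape, StimEvent, StimulationSchedule

# gain / 10-bit-DAC pairs keeping g * dac10bit = 12,000
GAIN_DAC_PAIRS: tuple[tuple[int, int], ...] = (
    (100, 120), (150, 80), (200, 60), (250, 48), (300, 40), (400, 30), (500, 24),
)
GAIN_DAC_PRODUCT = 12_000


@dataclass(frozen=True)
class GainScanConfig:
    """Amplitude-scan protocol: 26 series x N repetitions of 10 ms periods.

    Each 10 ms period holds two unipolar pulses in its first and third
    quarters; the second and fourth quarters are the no-stimulation
    baselines.
    """

    gain_dac_pairs: tuple[tuple[int, int], ...] = GAIN_DAC_PAIRS
    dac7_start: int = 2
    dac7_stop: int = 127
    dac7_step: int = 5
    dac4bit: int = 15
    repetitions: int = 1000
    period: float = 0.01  # s

    @property
    def dac7_values(self) -> np.ndarray:
        return np.arange(self.dac7_start, self.dac7_stop + 1, self.dac7_step)

    @property
    def n_series(self) -> int:
        return len(self.dac7_values)

    def dac10_for_gain(self, gain: int) -> int:
        for g, d in self.gain_dac_pairs:
            if g == gain:
                return d
        raise KeyError(f"no 10-bit DAC pairing for gain {gain}")

    def currents(self, dac10bit: int) -> np.ndarray:
        """Stimulation current of each series (A)."""
        return io_current(dac10bit, self.dac7_values, self.dac4bit, 1)

    def period_samples(self, fs: float = SAMPLE_RATE) -> int:
        n = self.period * fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("period is not a whole number of samples")
        return int(round(n))

    def segment_slices(self, fs: float = SAMPLE_RATE, guard: int = 5):
        """(positive pulse, baseline 1, negative pulse, baseline 2) slices.

        ``guard`` samples are skipped at each segment head to keep filter
        edge transients out of the means.
        """
        q = self.period_samples(fs) // 4
        return (
            slice(guard, q),
            slice(q + guard, 2 * q),
            slice(2 * q + guard, 3 * q),
            slice(3 * q + guard, 4 * q),
        )


def gain_scan_schedule(
    cfg: GainScanConfig, channel: int = 0, repetitions: int | None = None
) -> StimulationSchedule:
    """One channel's scan schedule: series-major, repetition-minor periods."""
    reps = cfg.repetitions if repetitions is None else repetitions
    n_per = cfg.period_samples()
    q = n_per // 4
    shapes: dict[str, PulseShape] = {}
    events: list[StimEvent] = []
    for s, d7 in enumerate(cfg.dac7_values):
        name = f"scan_d7_{int(d7)}"
        dac7 = np.zeros(n_per, np.uint8)
        dac4 = np.zeros(n_per, np.uint8)
        pol = np.ones(n_per, np.uint8)
        dac7[:q] = d7
        dac4[:q] = cfg.dac4bit
        dac7[2 * q:3 * q] = d7
        dac4[2 * q:3 * q] = cfg.dac4bit
        pol[2 * q:3 * q] = 0
        shapes[name] = PulseShape(name, dac7, dac4, pol)
        for r in range(reps):
            events.append(StimEvent((s * reps + r) * cfg.period, channel, name))
    return StimulationSchedule(shapes, events)


def response_amplitudes(
    trace: np.ndarray,
    cfg: GainScanConfig,
    repetitions: int | None = None,
    fs: float = SAMPLE_RATE,
) -> np.ndarray:
    """Per-period mean amplitudes of an amplitude-scan recording.

    ``trace`` is the stimulated channel's voltage starting at the scan
    onset.  Returns ``(n_series, repetitions)``: per period, the mean of the
    in-pulse samples minus the mean of the adjacent baseline samples,
    averaged over both pulse polarities.
    """
    reps = cfg.repetitions if repetitions is None else repetitions
    n_per = cfg.period_samples(fs)
    needed = cfg.n_series * reps * n_per
    trace = np.asarray(trace, dtype=np.float64)
    if trace.size < needed:
        raise AlignmentError(
            f"trace has {trace.size} samples, scan needs {needed} "
            f"({cfg.n_series} series x {reps} repetitions x {n_per})"
        )
    periods = trace[:needed].reshape(cfg.n_series, reps, n_per)
    pos, b1, neg, b2 = cfg.segment_slices(fs)
    return 0.5 * (
        (periods[:, :, pos].mean(axis=2) - periods[:, :, b1].mean(axis=2))
        - (periods[:, :, neg].mean(axis=2) - periods[:, :, b2].mean(axis=2))
    )


def fit_gain_offset(
    mean_amplitudes: np.ndarray,
    currents: np.ndarray,
    r_loop: float = R_LOOP_DEFAULT,
    saturation_fraction: float = 0.8,
    rail: float = ADC_RAIL,
) -> tuple[float, float]:
    """Least-squares line V = g_fit * (Io * R_loop) + o_fit.

    Points with |V| above ``saturation_fraction * rail`` are excluded as
    amplifier-saturated before fitting.
    """
    v = np.asarray(mean_amplitudes, dtype=np.float64)
    x = np.asarray(currents, dtype=np.float64) * r_loop
    keep = np.abs(v) <= saturation_fraction * rail
    if len(np.unique(x[keep])) < 2:
        raise FitError("gain fit needs at least two distinct unsaturated currents")
    gfit, ofit = np.polyfit(x[keep], v[keep], 1)
    return float(gfit), float(ofit)


def normalized_gain_curve(
    mean_amplitudes: np.ndarray,
    currents: np.ndarray,
    r_loop: float = R_LOOP_DEFAULT,
) -> np.ndarray:
    """Amplitudes divided by the unamplified curve ``Io * R_loop``.

    Zero-current points are excluded; a perfectly linear channel yields a
    constant curve at its true gain.
    """
    v = np.asarray(mean_amplitudes, dtype=np.float64)
    io = np.asarray(currents, dtype=np.float64)
    keep = io != 0
    return v[keep] / (io[keep] * r_loop)


# --- noise -------------------------------------------------------------------


@dataclass(frozen=True)
class PsdEstimate:
    frequencies: np.ndarray   # Hz
    psd: np.ndarray           # V^2/Hz, one-sided density
    n_segments: int


def noise_psd(
    trace: np.ndarray,
    fs: float = SAMPLE_RATE,
    segment_seconds: float = 10.0,
    overlap_seconds: float = 5.0,
) -> PsdEstimate:
    """Welch PSD with Hann window, 10 s segments, 5 s overlap (defaults)."""
    trace = np.asarray(trace, dtype=np.float64)
    nperseg = int(round(segment_seconds * fs))
    noverlap = int(round(overlap_seconds * fs))
    if trace.size < 2 * nperseg:
        raise AlignmentError(
            f"trace of {trace.size / fs:.1f} s is shorter than two segments "
            f"({2 * segment_seconds:.0f} s)"
        )
    f, psd = scipy.signal.welch(
        trace, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap
    )
    n_segments = 1 + (trace.size - nperseg) // (nperseg - noverlap)
    return PsdEstimate(f, psd, int(n_segments))


# --- band-pass step response -------------------------------------------------


def bandpass_step_model(t, k0, th, tl):
    """Closed-form unit-step response of the first-order active band-pass:
    Y(t) = K0 TH/(TL-TH) (exp(-t/TL) - exp(-t/TH))."""
    t = np.asarray(t, dtype=np.float64)
    return k0 * th / (tl - th) * (np.exp(-t / tl) - np.exp(-t / th))


def step_response_peak_time(th: float, tl: float) -> float:
    """argmax of the step response: ln(TH/TL) / (1/TL - 1/TH)."""
    return float(np.log(th / tl) / (1.0 / tl - 1.0 / th))


def average_step_response(
    trace: np.ndarray, fw: float, fs: float = SAMPLE_RATE, discard_first: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Fold a square-wave response into the mean absolute half-period response.

    Half periods are sign-aligned and averaged (skipping ``discard_first``
    half periods: the very first transition is a half-height step from
    rest); returns ``(t, y)`` with ``t`` starting at the step edge, ``y``
    the averaged response to the full +-2A transitions.  The time axis is
    placed at mid-sample (``(k + 1/2)/fs``): the digitized response of the
    bilinear-discretized chain tracks the continuous step response at the
    sampling-interval midpoints, and a half-sample error would bias the
    fast (low-pass) time constant by several percent.
    """
    half = fs / (2 * fw)
    if abs(half - round(half)) > 1e-6:
        raise ValueError("half period is not a whole number of samples")
    half = int(round(half))
    trace = np.asarray(trace, dtype=np.float64)
    n_half = trace.size // half
    if n_half < discard_first + 1:
        raise AlignmentError("trace shorter than one usable half period")
    segs = trace[: n_half * half].reshape(n_half, half)
    signs = np.where(np.arange(n_half) % 2 == 0, 1.0, -1.0)
    folded = (segs[discard_first:] * signs[discard_first:, None]).mean(axis=0)
    t = (np.arange(half) + 0.5) / fs
    return t, np.abs(folded)


@dataclass(frozen=True)
class BandpassFit:
    k0: float
    th: float              # s
    tl: float              # s
    fc_hp: float           # Hz, 1/(2 pi TH)
    fc_lp: float           # Hz, 1/(2 pi TL)
    residual_rms: float


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Heuristic (K0, TH, TL) from the peak position and tail log-slope."""
    ipk = int(np.argmax(y))
    tpk = max(t[max(ipk, 1)], t[1])
    ypk = y[ipk]
    tail = (t > 5 * tpk) & (y > ypk * 1e-3)
    if np.count_nonzero(tail) >= 10:
        slope = np.polyfit(t[tail], np.log(y[tail]), 1)[0]
        th0 = -1.0 / slope if slope < 0 else t[-1]
    else:
        th0 = t[-1] / 3
    th0 = max(th0, 3 * tpk)
    tl0 = tpk / 3
    for _ in range(50):  # solve tpk = ln(TH/TL) * TL*TH/(TH-TL) for TL
        u = tpk / np.log(th0 / tl0)
        tl0 = u * th0 / (th0 + u)
    peak_model = bandpass_step_model(tpk, 1.0, th0, tl0)
    k00 = ypk / peak_model if peak_model > 0 else ypk
    return k00, th0, tl0


def fit_bandpass_response(
    y: np.ndarray, t: np.ndarray, p0: tuple[float, float, float] | None = None
) -> BandpassFit:
    """Nonlinear least-squares fit of the band-pass step response.

    ``t`` starts at the step edge.  Parameters are fitted in log space for
    robustness; initial values come from peak/tail heuristics unless ``p0``
    (K0, TH, TL) is given.  Non-convergence raises :class:`FitError` with
    residual diagnostics attached.
    """
    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if not np.any(y > 0):
        raise FitError("response has no positive samples to fit", residuals=y)
    if p0 is None:
        p0 = _initial_guess(t, y)

    def model(tt, logk, logth, logtl):
        return bandpass_step_model(tt, np.exp(logk), np.exp(logth), np.exp(logtl))

    try:
        popt, _ = scipy.optimize.curve_fit(
            model,
            t,
            y,
            p0=np.log(p0),
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
        )
    except RuntimeError as exc:
        resid = y - model(t, *np.log(p0))
        raise FitError(
            f"band-pass fit did not converge: {exc}; initial-guess residual "
            f"RMS {np.sqrt(np.mean(resid**2)):.3e}",
            residuals=resid,
        ) from exc
    k0, th, tl = np.exp(popt)
    if not th > tl:
        th, tl = tl, th  # the model is symmetric under swap with sign flip
    resid = y - bandpass_step_model(t, k0, th, tl)
    return BandpassFit(
        k0=float(k0),
        th=float(th),
        tl=float(tl),
        fc_hp=float(1.0 / (2 * np.pi * th)),
        fc_lp=float(1.0 / (2 * np.pi * tl)),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


# --- spike-reproduction fidelity --------------------------------------------


@dataclass(frozen=True)
class SpikeFidelity:
    average: np.ndarray        # mean recorded waveform (V)
    normalized: np.ndarray     # average / max |average|
    reference_normalized: np.ndarray
    residual: np.ndarray       # normalized - reference_normalized

    @property
    def max_abs_residual(self) -> float:
        return float(np.max(np.abs(self.residual)))


def spike_reproduction(
    recorded: np.ndarray, reference: np.ndarray
) -> SpikeFidelity:
    """Average recorded repetitions, normalize to peak |1| and compare.

    ``recorded`` is ``(n_repetitions, n_samples)`` (or a single trace);
    both the average and the reference are divided by their maximum
    absolute value so waveform shapes compare directly.
    """
    rec = np.atleast_2d(np.asarray(recorded, dtype=np.float64))
    ref = np.asarray(reference, dtype=np.float64)
    avg = rec.mean(axis=0)
    peak = np.max(np.abs(avg))
    if peak == 0:
        raise ValueError("all-zero recording cannot be normalized")
    ref_peak = np.max(np.abs(ref))
    if ref_peak == 0:
        raise ValueError("all-zero reference cannot be normalized")
    norm = avg / peak
    ref_norm = ref / ref_peak
    return SpikeFidelity(avg, norm, ref_norm, norm - ref_norm)


# --- orchestration helpers ---------------------------------------------------


@dataclass
class ChannelCharacterization:
    """Fitted per-channel figures collected by the full procedure."""

    gfit: float
    ofit: float
    fc_hp: float | None = None
    fc_lp: float | None = None
    k0: float | None = None
    psd: PsdEstimate | None = None


def run_gain_scan(
    gain: int = 250,
    channel: int = 0,
    repetitions: int = 10,
    cfg: GainScanConfig | None = None,
    channel_params: ChannelModelParams | None = None,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the amplitude-scan procedure end to end through the full pipeline
    (schedule -> output chunks -> chip simulation -> demultiplexing) on one
    channel and return ``(mean_amplitudes, currents, per_period_amplitudes)``.

    The chip is configured for its widest band (high-pass register 1,
    low-pass register 31) and the Table-matched 10-bit DAC for the gain.
    """
    cfg = cfg or GainScanConfig(repetitions=repetitions)
    dac10 = cfg.dac10_for_gain(gain)
    asic, slot = divmod(channel, CHANNELS_PER_ASIC)
    state = AsicState(
        dac10bit=dac10, hp_reg=1, lp_reg=31, gain=gain, stim_enable=True
    )
    schedule = gain_scan_schedule(cfg, channel, repetitions)
    chunks = stim.build_chunks(schedule, {asic: state})
    sim = SystemSimulator(
        enabled=(asic,), channel_params=channel_params, seed=seed
    )
    pieces = []
    for chunk in chunks:
        input_chunk, _ = sim.simulate_chunk(chunk)
        pcd = demux_mod.demultiplex(input_chunk)
        volts, _ = demux_mod.codes_to_volts(pcd)
        pieces.append(volts[channel])
    trace = np.concatenate(pieces)
    amps = response_amplitudes(trace, cfg, repetitions)
    return amps.mean(axis=1), cfg.currents(dac10), amps


def run_filter_characterization(
    fc_hp: float = 0.6,
    fc_lp: float = 1050.0,
    gain: float = 250.0,
    amplitude: float = 92e-9,
    fw: float = 0.1,
    n_periods: int = 10,
    noise_rms: float = 0.0,
    r_loop: float = R_LOOP_DEFAULT,
    fs: float = SAMPLE_RATE,
    seed: int | None = 0,
) -> BandpassFit:
    """Square-wave filter test on one simulated channel, returning the fit.

    A continuous +-``amplitude`` bipolar square wave of frequency ``fw``
    drives the channel's analogue chain in loopback; the digitized response
    is folded into the average absolute half-period response and fitted.
    The returned ``k0`` is already referred to the unit step (divided by the
    2A transition height).
    """
    th, tl = time_constants(fc_hp, fc_lp)
    half = int(round(fs / (2 * fw)))
    one_period = np.concatenate([np.ones(half), -np.ones(half)])
    x = np.tile(one_period, n_periods) * amplitude * r_loop
    y = signal_chain(x, k0=gain, th=th, tl=tl, fs=fs)
    if noise_rms > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_rms, y.size)
    codes = adc_quantize(y)
    volts = codes.astype(np.float64) / 4095 * (2 * ADC_RAIL) - ADC_RAIL
    t, folded = average_step_response(volts, fw, fs)
    fit = fit_bandpass_response(folded, t)
    step = 2 * amplitude * r_loop
    return BandpassFit(
        k0=fit.k0 / step,
        th=fit.th,
        tl=fit.tl,
        fc_hp=fit.fc_hp,
        fc_lp=fit.fc_lp,
        residual_rms=fit.residual_rms,
    )


def run_spike_reproduction(
    reference: np.ndarray,
    fc_lp: float = 20000.0,
    fc_hp: float = 0.6,
    gain: float = 100.0,
    dac10bit: int = 120,
    dac4bit: int = 15,
    repetitions: int = 5,
    period: float = 1.0,
    noise_rms: float = 0.0,
    full_scale_current: float | None = None,
    r_loop: float = R_LOOP_DEFAULT,
    fs: float = SAMPLE_RATE,
    seed: int | None = 0,
) -> SpikeFidelity:
    """Quantize a reference waveform to the signed 7-bit code space, play it
    repeatedly through one simulated channel and measure shape fidelity.

    ``reference`` is the desired waveform (arbitrary units); its peak maps
    to the full 7-bit code.  The 4-bit DAC scales the output amplitude.
    """
    shape = stim.quantize_waveform(
        reference, float(np.max(np.abs(reference))), "spike"
    ).with_dac4bit(dac4bit)
    currents = shape.currents(dac10bit)
    n_shape = len(shape)
    n_per = int(round(period * fs))
    th, tl = time_constants(fc_hp, fc_lp)
    x = np.zeros(repetitions * n_per)
    for r in range(repetitions):
        x[r * n_per: r * n_per + n_shape] = currents * r_loop
    y = signal_chain(x, k0=gain, th=th, tl=tl, fs=fs)
    if noise_rms > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_rms, y.size)
    volts, _ = demux_mod.codes_to_volts(adc_quantize(y))
    recorded = volts[: repetitions * n_per].reshape(repetitions, n_per)[:, :n_shape]
    return spike_reproduction(recorded, np.asarray(reference, dtype=np.float64))
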