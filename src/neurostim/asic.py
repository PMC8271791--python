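"""Behavioral model of the 64-channel stimulation/recording ASIC.

Each chip holds a global 10-bit current-scale register, 5-bit high-/low-pass
filter registers and per-channel gain / stimulation-enable state.  During
every 25 µs sampling period a real-time command sets, per channel, the 7-bit
and 4-bit current DAC codes and the polarity bit ``p``; the instantaneous
output current is

    Io = dac10bit * dac7bit * dac4bit / ((2^10-1)(2^7-1)(2^4-1)) * 15 µA

with the sign flipped when ``p = 0``.  In the built-in test (loopback) mode
that current flows through a ~5.5 kOhm resistor into the channel's analogue
front end: a first-order active band-pass

    K(s) = K0 * s*TH / ((1 + s*TH)(1 + s*TL))

(TH, TL the high-/low-pass time constants, K0 the mid-band gain) followed by
a 12-bit ADC spanning -1.8 V..+1.8 V.  The simulator discretizes K(s) with
the bilinear transform at the 40 kHz sampling rate, which preserves the DC
zero and the low-frequency response where the characterization procedures
operate, adds a configurable output-referred noise model (white floor plus
optional 1/f term and 10 kHz spur), quantizes, and multiplexes all channels
onto the chip's serial line.  Filter memory persists across chunks so long
runs behave like one continuous recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import scipy.signal

from . import protocol
from .errors import RegisterRangeError
from .protocol import (
    CHANNELS_PER_ASIC,
    GAIN_LEVELS,
    N_CHANNELS,
    N_DATA_LINES,
    SAMPLE_RATE,
    BitstreamChunk,
    InputChunk,
    RealTimeDataCommand,
    StateCommand,
)

FULL_SCALE_CURRENT = 15e-6      # A, all DAC codes at maximum
R_LOOP_DEFAULT = 5500.0         # Ohm, internal loopback resistor
ADC_RAIL = 1.8                  # V, analogue readout range is +-1.8 V
ADC_LSB = 2 * ADC_RAIL / protocol.ADC_MAX_CODE
IDLE_CODE = 2048                # ADC code for 0 V (and for vacant channels)

_DAC_NORM = (2**10 - 1) * (2**7 - 1) * (2**4 - 1)

# register-value 1 maps to the measured low end of each filter range,
# register-value 31 to the specified top; interpolation is logarithmic.
HP_CUTOFF_RANGE = (0.6, 7.0)        # Hz
LP_CUTOFF_RANGE = (1050.0, 20000.0)  # Hz


def io_current(dac10bit, dac7bit, dac4bit, polarity):
    """Instantaneous output current in amperes from the three DAC codes.

    Separately linear in each code; odd in polarity (``p = 0`` negates).
    Accepts scalars or broadcastable arrays.
    """
    d10 = np.asarray(dac10bit)
    d7 = np.asarray(dac7bit)
    d4 = np.asarray(dac4bit)
    p = np.asarray(polarity)
    for name, a, hi in (
        ("dac10bit", d10, 1023), ("dac7bit", d7, 127), ("dac4bit", d4, 15),
    ):
        if a.min(initial=0) < 0 or a.max(initial=0) > hi:
            raise RegisterRangeError(name, [int(a.min()), int(a.max())], 0, hi)
    if ((p != 0) & (p != 1)).any():
        raise RegisterRangeError("polarity", polarity, 0, 1)
    sign = 2.0 * p - 1.0
    out = (
        d10.astype(np.float64) * d7 * d4 / _DAC_NORM * FULL_SCALE_CURRENT * sign
    )
    return out if out.ndim else float(out)


def expected_amplitude(gain, io, r_loop: float = R_LOOP_DEFAULT):
    """Expected recorded amplitude (V) for gain ``g`` and loopback current."""
    out = np.asarray(gain, dtype=np.float64) * np.asarray(io) * r_loop
    return out if out.ndim else float(out)


def register_cutoffs(hp_reg: int, lp_reg: int) -> tuple[float, float]:
    """Map 5-bit filter registers to (fc_hp, fc_lp) in Hz.

    Logarithmic interpolation between the calibrated end points; register 0
    is treated as 1 (the lowest usable setting).
    """
    def _map(reg, lo, hi):
        r = max(1, int(reg))
        return lo * (hi / lo) ** ((r - 1) / 30.0)

    return (_map(hp_reg, *HP_CUTOFF_RANGE), _map(lp_reg, *LP_CUTOFF_RANGE))


def time_constants(fc_hp: float, fc_lp: float) -> tuple[float, float]:
    """(TH, TL) from cut-off frequencies; TH = 1/(2 pi fc_hp) etc."""
    return 1.0 / (2 * np.pi * fc_hp), 1.0 / (2 * np.pi * fc_lp)


@dataclass
class AsicState:
    """Register image of one simulated chip (global + per-channel)."""

    dac10bit: int = 0
    hp_reg: int = 1
    lp_reg: int = 1
    gain: np.ndarray = field(
        default_factory=lambda: np.full(CHANNELS_PER_ASIC, GAIN_LEVELS[0], dtype=np.int64)
    )
    stim_enable: np.ndarray = field(
        default_factory=lambda: np.zeros(CHANNELS_PER_ASIC, dtype=bool)
    )
    sample_rate: int = SAMPLE_RATE

    def __post_init__(self):
        self.gain = np.asarray(self.gain, dtype=np.int64)
        if self.gain.ndim == 0:
            self.gain = np.full(CHANNELS_PER_ASIC, int(self.gain), dtype=np.int64)
        self.stim_enable = np.asarray(self.stim_enable, dtype=bool)
        if self.stim_enable.ndim == 0:
            self.stim_enable = np.full(CHANNELS_PER_ASIC, bool(self.stim_enable))
        if not 0 <= self.dac10bit <= 1023:
            raise RegisterRangeError("dac10bit", self.dac10bit, 0, 1023)
        if not 0 <= self.hp_reg <= 31:
            raise RegisterRangeError("hp_reg", self.hp_reg, 0, 31)
        if not 0 <= self.lp_reg <= 31:
            raise RegisterRangeError("lp_reg", self.lp_reg, 0, 31)
        if not np.isin(self.gain, GAIN_LEVELS).all():
            raise RegisterRangeError("gain", self.gain.tolist(), GAIN_LEVELS, GAIN_LEVELS)
        if self.sample_rate != SAMPLE_RATE:
            raise RegisterRangeError("sample_rate", self.sample_rate, SAMPLE_RATE, SAMPLE_RATE)

    def copy(self) -> "AsicState":
        return AsicState(
            self.dac10bit, self.hp_reg, self.lp_reg,
            self.gain.copy(), self.stim_enable.copy(), self.sample_rate,
        )

    def set_gain(self, gain: int, channel: int | None = None) -> None:
        """Convenience setter: per channel, or chip-wide when channel is None."""
        if gain not in GAIN_LEVELS:
            raise RegisterRangeError("gain", gain, GAIN_LEVELS, GAIN_LEVELS)
        if channel is None:
            self.gain[:] = gain
        else:
            self.gain[channel] = gain

    def setup_commands(self, asic: int = 0) -> list[StateCommand]:
        """Command list reproducing this register image from reset."""
        cmds = [
            StateCommand("dac10bit", self.dac10bit, asic=asic),
            StateCommand("hp_reg", self.hp_reg, asic=asic),
            StateCommand("lp_reg", self.lp_reg, asic=asic),
        ]
        if np.all(self.gain == self.gain[0]):
            cmds.append(StateCommand("gain", int(self.gain[0]), asic=asic))
        else:
            cmds += [
                StateCommand("gain", int(g), channel=c, asic=asic)
                for c, g in enumerate(self.gain)
            ]
        if self.stim_enable.all() or not self.stim_enable.any():
            cmds.append(
                StateCommand("stim_enable", int(self.stim_enable[0]), asic=asic)
            )
        else:
            cmds += [
                StateCommand("stim_enable", int(e), channel=c, asic=asic)
                for c, e in enumerate(self.stim_enable)
            ]
        return cmds


def apply_command(state: AsicState, command) -> AsicState:
    """Pure state transition: returns a new state, never mutates the input.

    Real-time commands do not touch registers.
    """
    new = state.copy()
    if isinstance(command, RealTimeDataCommand):
        return new
    if not isinstance(command, StateCommand):
        raise TypeError(f"not a command: {command!r}")
    if command.register in ("dac10bit", "hp_reg", "lp_reg"):
        setattr(new, command.register, command.value)
    elif command.register == "gain":
        if command.channel is None:
            new.gain[:] = command.value
        else:
            new.gain[command.channel] = command.value
    elif command.register == "stim_enable":
        if command.channel is None:
            new.stim_enable[:] = bool(command.value)
        else:
            new.stim_enable[command.channel] = bool(command.value)
    return new


# --- analogue chain ----------------------------------------------------------


@dataclass(frozen=True)
class ChannelModelParams:
    """Ground-truth analogue parameters of one simulated channel.

    ``true_gain``, ``TH`` and ``TL`` default to the values programmed in the
    chip registers; set them explicitly to model mismatch.  Noise is referred
    to the output: ``white_rms`` is the broadband floor, ``pink_rms`` the RMS
    of an additional 1/f component, ``spur_amplitude`` the amplitude of a
    10 kHz interference tone (off by default).
    """

    true_gain: float | None = None
    offset: float = 0.0          # V, added at the output
    TH: float | None = None      # s, high-pass time constant
    TL: float | None = None      # s, low-pass time constant
    r_loop: float = R_LOOP_DEFAULT
    white_rms: float = 10e-6     # V RMS
    pink_rms: float = 0.0        # V RMS
    spur_amplitude: float = 0.0  # V, 10 kHz tone
    spur_freq: float = 10_000.0

    def __post_init__(self):
        if self.TH is not None and self.TL is not None and not self.TH > self.TL > 0:
            raise ValueError(
                f"need TH > TL > 0, got TH={self.TH}, TL={self.TL}"
            )
        if self.r_loop <= 0:
            raise ValueError("r_loop must be positive")
        if self.true_gain is not None and self.true_gain <= 0:
            raise ValueError("true_gain must be positive")

    def resolved(self, state: AsicState, channel: int) -> tuple[float, float, float]:
        """(K0, TH, TL) with register-derived defaults filled in."""
        fc_hp, fc_lp = register_cutoffs(state.hp_reg, state.lp_reg)
        th_reg, tl_reg = time_constants(fc_hp, fc_lp)
        k0 = self.true_gain if self.true_gain is not None else float(state.gain[channel])
        th = self.TH if self.TH is not None else th_reg
        tl = self.TL if self.TL is not None else tl_reg
        if not th > tl > 0:
            raise ValueError(f"need TH > TL > 0, got TH={th}, TL={tl}")
        return k0, th, tl


def bandpass_coefficients(
    k0: float, th: float, tl: float, fs: float = SAMPLE_RATE
) -> tuple[np.ndarray, np.ndarray]:
    """Digital (b, a) of K(s) = k0 s TH / ((1+s TH)(1+s TL)), bilinear at fs."""
    if not th > tl > 0:
        raise ValueError(f"need TH > TL > 0, got TH={th}, TL={tl}")
    return scipy.signal.bilinear([k0 * th, 0.0], [th * tl, th + tl, 1.0], fs)


def signal_chain(
    x: np.ndarray,
    params: ChannelModelParams | None = None,
    *,
    k0: float | None = None,
    th: float | None = None,
    tl: float | None = None,
    fs: float = SAMPLE_RATE,
) -> np.ndarray:
    """Band-pass + gain response of one channel to a sampled input voltage.

    Either pass ``params`` with explicit ``true_gain``/``TH``/``TL`` or the
    ``k0``/``th``/``tl`` keywords.  Noise-free and stateless (filter starts
    at rest); the simulator keeps its own running filter memory.
    """
    if params is not None:
        if params.true_gain is None or params.TH is None or params.TL is None:
            raise ValueError(
                "signal_chain needs explicit true_gain, TH and TL on params"
            )
        k0, th, tl = params.true_gain, params.TH, params.TL
    if k0 is None or th is None or tl is None:
        raise ValueError("k0, th and tl are required")
    b, a = bandpass_coefficients(k0, th, tl, fs)
    return scipy.signal.lfilter(b, a, np.asarray(x, dtype=np.float64))


def adc_quantize(v) -> np.ndarray:
    """12-bit ADC: -1.8 V -> 0, +1.8 V -> 4095, round-half-up, rail-clipped."""
    v = np.asarray(v, dtype=np.float64)
    codes = np.floor((v + ADC_RAIL) / (2 * ADC_RAIL) * protocol.ADC_MAX_CODE + 0.5)
    codes = np.clip(codes, 0, protocol.ADC_MAX_CODE)
    out = codes.astype(np.uint16)
    return out if out.ndim else np.uint16(out)


def _pink_noise(rng: np.random.Generator, n: int, rms: float) -> np.ndarray:
    """1/f-shaped noise with the requested RMS (FFT spectral shaping)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


# --- system simulator --------------------------------------------------------


@dataclass
class SimulationInfo:
    """Per-chunk simulator by-products: state snapshots and the ideal
    (noise-free, pre-chain) stimulation current waveforms per channel."""

    states: dict[int, AsicState]
    waveforms: dict[int, np.ndarray]   # asic -> (n_periods, 64) float32, amperes


class SystemSimulator:
    """Drives up to eight simulated chips from parsed output chunks.

    Parameters
    ----------
    enabled : iterable of int
        ASIC slots (lines) populated with a simulated chip; vacant slots
        produce constant mid-rail data, like unconnected hardware lines.
    states : mapping asic -> AsicState, optional
        Initial register images (defaults to reset state).
    channel_params : ChannelModelParams or mapping, optional
        One set for every channel, or ``{asic: ChannelModelParams}`` or
        ``{asic: [64 ChannelModelParams]}`` for mismatch modelling.
    seed : int, optional
        Seeds the noise generator; seeded runs are bit-reproducible.
    """

    def __init__(
        self,
        enabled: Iterable[int] = (0,),
        states: Mapping[int, AsicState] | None = None,
        channel_params: ChannelModelParams | Mapping | None = None,
        seed: int | None = None,
    ):
        self.enabled = sorted(set(int(a) for a in enabled))
        for a in self.enabled:
            if not 0 <= a < N_DATA_LINES:
                raise RegisterRangeError("asic", a, 0, N_DATA_LINES - 1)
        self.states: dict[int, AsicState] = {
            a: (states[a].copy() if states and a in states else AsicState())
            for a in self.enabled
        }
        self._params = channel_params
        self._rng = np.random.default_rng(seed)
        self._zi: dict[tuple[int, int], np.ndarray] = {}

    def channel_params(self, asic: int, channel: int) -> ChannelModelParams:
        p = self._params
        if p is None:
            return ChannelModelParams()
        if isinstance(p, ChannelModelParams):
            return p
        entry = p.get(asic, ChannelModelParams())
        if isinstance(entry, ChannelModelParams):
            return entry
        return entry[channel]

    def simulate_chunk(
        self,
        chunk: BitstreamChunk,
        external_input: Mapping[int, np.ndarray] | None = None,
        external_triggers: np.ndarray | None = None,
    ) -> tuple[InputChunk, SimulationInfo]:
        """Run one output chunk through every enabled chip.

        ``external_input`` optionally adds a per-chip ``(n_periods, 64)``
        voltage trace at the channel inputs (on top of the loopback current
        times the loop resistor).  Returns the multiplexed input chunk and
        the simulation by-products.
        """
        parsed = protocol.parse_chunk(chunk)
        n = chunk.n_periods
        codes = np.full((n, N_CHANNELS), IDLE_CODE, dtype=np.uint16)
        waveforms: dict[int, np.ndarray] = {}
        for asic in self.enabled:
            state = self.states[asic]
            for cmd in parsed.state_commands:
                if cmd.asic == asic:
                    state = apply_command(state, cmd)
            self.states[asic] = state

            currents = np.zeros((n, CHANNELS_PER_ASIC), dtype=np.float64)
            stream = parsed.realtime.get(asic)
            if stream is not None and len(stream):
                io = io_current(
                    state.dac10bit, stream.dac7bit, stream.dac4bit, stream.polarity
                )
                io = io * state.stim_enable[None, :]
                currents[stream.periods] = io
            waveforms[asic] = currents.astype(np.float32)

            ext = None
            if external_input is not None:
                ext = external_input.get(asic)
            out = np.empty_like(currents)
            for c in range(CHANNELS_PER_ASIC):
                p = self.channel_params(asic, c)
                k0, th, tl = p.resolved(state, c)
                b, a = bandpass_coefficients(k0, th, tl)
                x = currents[:, c] * p.r_loop
                if ext is not None:
                    x = x + ext[:, c]
                zi = self._zi.setdefault((asic, c), np.zeros(max(len(a), len(b)) - 1))
                y, zf = scipy.signal.lfilter(b, a, x, zi=zi)
                self._zi[(asic, c)] = zf
                y = y + p.offset
                if p.white_rms > 0:
                    y = y + self._rng.normal(0.0, p.white_rms, n)
                if p.pink_rms > 0:
                    y = y + _pink_noise(self._rng, n, p.pink_rms)
                if p.spur_amplitude > 0:
                    t = np.arange(n) / SAMPLE_RATE
                    y = y + p.spur_amplitude * np.sin(2 * np.pi * p.spur_freq * t)
                out[:, c] = y
            codes[:, asic * CHANNELS_PER_ASIC:(asic + 1) * CHANNELS_PER_ASIC] = (
                adc_quantize(out)
            )

        triggers = parsed.triggers.copy()
        if external_triggers is not None:
            triggers |= np.asarray(external_triggers, dtype=bool)
        input_chunk = protocol.pack_samples(
            codes, triggers, chunk.duration, chunk.sync_id
        )
        info = SimulationInfo(
            states={a: s.copy() for a, s in self.states.items()},
            waveforms=waveforms,
        )
        return input_chunk, info


def simulate_chunk(
    chunk: BitstreamChunk,
    state: AsicState | Mapping[int, AsicState] | None = None,
    external_input: Mapping[int, np.ndarray] | None = None,
    channel_params: ChannelModelParams | Mapping | None = None,
    seed: int | None = None,
) -> tuple[InputChunk, SimulationInfo]:
    """One-shot convenience wrapper around :class:`SystemSimulator`."""
    if state is None or isinstance(state, AsicState):
        states = {0: state} if isinstance(state, AsicState) else None
        enabled = (0,)
    else:
        states = dict(state)
        enabled = tuple(states)
    sim = SystemSimulator(
        enabled=enabled, states=states, channel_params=channel_params, seed=seed
    )
    return sim.simulate_chunk(chunk, external_input)
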