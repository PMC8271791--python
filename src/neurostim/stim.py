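"""Stimulation protocol building: pulse shapes, schedules and chunked streams.

A stimulation protocol is a library of pulse shapes (per-sampling-period DAC
code triples) plus a schedule saying when each channel outputs which pulse.
This module turns protocols — explicit schedules, continuous square waves,
or prebuilt JSON experiment files — into the ordered 0.5 s output chunks the
generation side streams to the hardware (here: to the simulator), inserting
trigger bits and applying the keep-alive queue semantics.
"""

from __future__ import annotations

import json
import warnings
from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import protocol
from .asic import AsicState, io_current
from .errors import (
    CapacityError,
    QuantizationError,
    SchedulingError,
)
from .protocol import (
    CHANNELS_PER_ASIC,
    CHUNK_SECONDS,
    N_CHANNELS,
    SAMPLE_RATE,
    BitstreamChunk,
    RtBlock,
)

SAMPLE_PERIOD = 1.0 / SAMPLE_RATE  # 25 µs


# --- pulse shapes ------------------------------------------------------------


@dataclass(frozen=True)
class PulseShape:
    """A sampled stimulation pulse: one DAC code triple per 25 µs period."""

    name: str
    dac7bit: np.ndarray
    dac4bit: np.ndarray
    polarity: np.ndarray

    def __post_init__(self):
        for attr in ("dac7bit", "dac4bit", "polarity"):
            object.__setattr__(
                self, attr, np.atleast_1d(np.asarray(getattr(self, attr), dtype=np.uint8))
            )
        n = len(self.dac7bit)
        if len(self.dac4bit) != n or len(self.polarity) != n:
            raise ValueError("code arrays must have equal length")
        if self.dac7bit.max(initial=0) > 127:
            raise ValueError("dac7bit codes exceed 127")
        if self.dac4bit.max(initial=0) > 15:
            raise ValueError("dac4bit codes exceed 15")
        if self.polarity.max(initial=0) > 1:
            raise ValueError("polarity must be 0/1")

    def __len__(self) -> int:
        return len(self.dac7bit)

    @property
    def duration(self) -> float:
        return len(self) * SAMPLE_PERIOD

    def currents(self, dac10bit: int) -> np.ndarray:
        """Ideal per-sample output current (A) at the given global scale."""
        return io_current(dac10bit, self.dac7bit, self.dac4bit, self.polarity)

    def net_charge(self, dac10bit: int) -> float:
        """Signed charge (C) delivered by one pulse; 0 for balanced shapes.

        The signed DAC-code products are summed as integers before scaling,
        so a charge-balanced shape yields exactly zero.
        """
        signed = (
            self.dac7bit.astype(np.int64)
            * self.dac4bit.astype(np.int64)
            * (2 * self.polarity.astype(np.int64) - 1)
        )
        scale = dac10bit / ((2**10 - 1) * (2**7 - 1) * (2**4 - 1)) * 15e-6
        return float(int(signed.sum()) * scale * SAMPLE_PERIOD)

    def with_dac4bit(self, dac4bit: int) -> "PulseShape":
        """Copy with the 4-bit amplitude multiplier replaced everywhere."""
        return replace(
            self,
            name=f"{self.name}@d4={dac4bit}",
            dac4bit=np.full(len(self), dac4bit, dtype=np.uint8),
        )

    @classmethod
    def biphasic(
        cls,
        name: str,
        dac7bit: int,
        dac4bit: int,
        phase_samples: int,
        positive_first: bool = True,
    ) -> "PulseShape":
        """Charge-balanced biphasic pulse with equal-length, equal-code phases."""
        n = 2 * phase_samples
        pol = np.empty(n, dtype=np.uint8)
        pol[:phase_samples] = 1 if positive_first else 0
        pol[phase_samples:] = 0 if positive_first else 1
        return cls(
            name,
            np.full(n, dac7bit, np.uint8),
            np.full(n, dac4bit, np.uint8),
            pol,
        )


def quantize_waveform(
    reference: np.ndarray, full_scale: float, name: str = "quantized"
) -> PulseShape:
    """Approximate a sampled waveform with the signed 7-bit code space.

    The 7-bit magnitude DAC and the polarity bit give 128 x 2 = 256 signed
    code combinations; samples are mapped with round-half-away-from-zero,
    which preserves the antisymmetry of bipolar pulses.  The 4-bit DAC is
    left at its maximum as a separate amplitude multiplier
    (see :meth:`PulseShape.with_dac4bit`).  Samples beyond ``full_scale``
    clip with a warning.
    """
    x = np.asarray(reference, dtype=np.float64) / full_scale
    clipped = int(np.count_nonzero(np.abs(x) > 1.0))
    if clipped:
        warnings.warn(f"{clipped} samples clipped to full scale", stacklevel=2)
        x = np.clip(x, -1.0, 1.0)
    signed = np.sign(x) * np.floor(np.abs(x) * 127 + 0.5)
    return PulseShape(
        name,
        dac7bit=np.abs(signed).astype(np.uint8),
        dac4bit=np.full(len(x), 15, dtype=np.uint8),
        polarity=(signed >= 0).astype(np.uint8),
    )


def nearest_dac_codes(
    amplitude: float, dac10bit: int, tolerance: float = 0.05
) -> tuple[int, int, float]:
    """Exhaustive (dac7bit, dac4bit) search minimizing |Io - amplitude|.

    Returns ``(dac7bit, dac4bit, relative_error)``; raises
    :class:`QuantizationError` (naming the nearest code) when the best
    relative error exceeds ``tolerance``.
    """
    if amplitude <= 0:
        raise QuantizationError("amplitude must be positive")
    d7 = np.arange(128)
    d4 = np.arange(16)
    io = io_current(dac10bit, d7[:, None], d4[None, :], 1)
    best = np.unravel_index(np.argmin(np.abs(io - amplitude)), io.shape)
    rel_err = abs(io[best] - amplitude) / amplitude
    if rel_err > tolerance:
        raise QuantizationError(
            f"amplitude {amplitude:.3e} A not representable at dac10bit="
            f"{dac10bit}; nearest code (dac7bit={best[0]}, dac4bit={best[1]}) "
            f"gives {io[best]:.3e} A ({rel_err:.1%} off)"
        )
    return int(best[0]), int(best[1]), float(rel_err)


# --- schedules ---------------------------------------------------------------


@dataclass(frozen=True)
class StimEvent:
    time: float       # s, pulse onset
    channel: int      # 0-511 system channel
    shape: str        # key into the shape library

    @property
    def start_period(self) -> int:
        return int(round(self.time * SAMPLE_RATE))


@dataclass
class StimulationSchedule:
    """Shape library plus the table of (time, channel, shape) events."""

    shapes: dict[str, PulseShape] = field(default_factory=dict)
    events: list[StimEvent] = field(default_factory=list)
    trigger_line: int | None = None  # 1-8, raised for each pulse's duration

    def validate(self) -> None:
        if self.trigger_line is not None and not 1 <= self.trigger_line <= 8:
            raise SchedulingError(f"trigger line must be 1-8, got {self.trigger_line}")
        spans: dict[int, list[tuple[int, int, float]]] = {}
        for ev in self.events:
            if ev.time < 0:
                raise SchedulingError(f"negative event time {ev.time}")
            if not 0 <= ev.channel < N_CHANNELS:
                raise SchedulingError(f"channel {ev.channel} out of range")
            if ev.shape not in self.shapes:
                raise SchedulingError(f"unknown pulse shape {ev.shape!r}")
            start = ev.start_period
            spans.setdefault(ev.channel, []).append(
                (start, start + len(self.shapes[ev.shape]), ev.time)
            )
        for channel, chan_spans in spans.items():
            chan_spans.sort()
            for (s0, e0, t0), (s1, e1, t1) in zip(chan_spans, chan_spans[1:]):
                if s1 < e0:
                    raise SchedulingError(
                        f"overlapping pulses on channel {channel} at "
                        f"t={t0:.6f} s and t={t1:.6f} s"
                    )

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def duration(self) -> float:
        """End time of the last pulse, in seconds."""
        if not self.events:
            return 0.0
        return max(
            (ev.start_period + len(self.shapes[ev.shape])) * SAMPLE_PERIOD
            for ev in self.events
        )


@dataclass(frozen=True)
class SquareWaveConfig:
    """Continuous time- and amplitude-symmetric bipolar square wave."""

    frequency: float                    # Hz
    duration: float                     # s
    channels: tuple[int, ...] = (0,)
    dac7bit: int | None = None          # explicit codes, or ...
    dac4bit: int | None = None
    amplitude: float | None = None      # ... target current in amperes
    dac10bit: int = 0                   # needed to quantize an amplitude
    tolerance: float = 0.05

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")


def build_square_wave(cfg: SquareWaveConfig) -> StimulationSchedule:
    """Expand a square-wave config into a whole-period schedule.

    Each whole period becomes one event referencing a single full-period
    shape (positive half then negative half, equal lengths); partial final
    periods are not emitted, so the event count per channel is
    ``duration x frequency`` for commensurate inputs.
    """
    half = SAMPLE_RATE / (2 * cfg.frequency)
    if abs(half - round(half)) > 1e-6:
        raise SchedulingError(
            f"half period of {cfg.frequency} Hz is not a whole number of "
            f"sampling periods"
        )
    half = int(round(half))
    if cfg.dac7bit is not None and cfg.dac4bit is not None:
        d7, d4 = cfg.dac7bit, cfg.dac4bit
    elif cfg.amplitude is not None:
        d7, d4, _ = nearest_dac_codes(cfg.amplitude, cfg.dac10bit, cfg.tolerance)
    else:
        raise QuantizationError("need either explicit DAC codes or an amplitude")
    shape = PulseShape.biphasic("square_period", d7, d4, half)
    n_periods = int(np.floor(cfg.duration * cfg.frequency + 1e-9))
    events = [
        StimEvent(k / cfg.frequency, ch, "square_period")
        for ch in cfg.channels
        for k in range(n_periods)
    ]
    return StimulationSchedule({"square_period": shape}, events)


def schedule_alternating(
    n_arrays: int,
    electrodes_per_array: int,
    interval: float,
    amplitudes: Sequence[tuple[int, int]] | None = None,
    repetitions: int = 1,
    phase_samples: int = 4,
    trigger_line: int | None = None,
) -> StimulationSchedule:
    """Alternating-array stimulation: one pulse every ``interval`` seconds,
    cycling arrays first, then electrodes, so each electrode is revisited
    every ``n_arrays * electrodes_per_array * interval`` seconds.

    ``amplitudes`` is a sequence of (dac7bit, dac4bit) pairs, each applied
    ``repetitions`` times to every electrode; array ``a`` occupies chip slot
    ``a`` (channels ``a*64 .. a*64+electrodes_per_array-1``).
    """
    if n_arrays < 1 or electrodes_per_array < 1:
        raise SchedulingError("counts must be >= 1")
    if electrodes_per_array > CHANNELS_PER_ASIC:
        raise SchedulingError("at most 64 electrodes per array")
    if amplitudes is None:
        amplitudes = [(127, 15)]
    shapes = {
        f"pulse_a{i}": PulseShape.biphasic(f"pulse_a{i}", d7, d4, phase_samples)
        for i, (d7, d4) in enumerate(amplitudes)
    }
    cycle = n_arrays * electrodes_per_array
    events = []
    block = 0
    for _ in range(repetitions):
        for i in range(len(amplitudes)):
            for k in range(cycle):
                array = k % n_arrays
                electrode = k // n_arrays
                events.append(
                    StimEvent(
                        (block * cycle + k) * interval,
                        array * CHANNELS_PER_ASIC + electrode,
                        f"pulse_a{i}",
                    )
                )
            block += 1
    return StimulationSchedule(shapes, events, trigger_line)


def revisit_period(schedule: StimulationSchedule, channel: int | None = None) -> float:
    """Time between consecutive pulses on one electrode, in seconds."""
    if channel is None:
        channel = schedule.events[0].channel
    times = sorted(ev.time for ev in schedule.events if ev.channel == channel)
    if len(times) < 2:
        raise SchedulingError(f"channel {channel} is stimulated fewer than twice")
    gaps = np.diff(times)
    return float(gaps[0])


def stress_protocol(
    pulses_per_second: int = 1000,
    channels: Sequence[int] | None = None,
    duration: float = 1.0,
    dac7bit: int = 100,
    dac4bit: int = 15,
    seed: int | None = 0,
) -> StimulationSchedule:
    """Pulse-rate stress protocol: pseudo-randomly timed 250 µs biphasic
    pulses at a fixed per-channel rate on a set of non-adjacent channels.

    Placement is stratified per 0.5 s window (the per-window pulse count is
    part of the protocol definition), non-overlapping with at least one idle
    period between pulses on a channel.
    """
    if channels is None:
        channels = tuple(3 * i for i in range(20))  # 20 non-adjacent channels
    shape = PulseShape.biphasic("stress_250us", dac7bit, dac4bit, phase_samples=5)
    pulse_len = len(shape)          # 10 sampling periods
    block = pulse_len + 2           # pulse + guaranteed idle gap
    periods_per_window = int(CHUNK_SECONDS * SAMPLE_RATE)
    n_blocks = periods_per_window // block
    per_window = int(pulses_per_second * CHUNK_SECONDS)
    if per_window > n_blocks:
        raise SchedulingError(
            f"{pulses_per_second} pulses/s do not fit without overlap"
        )
    n_windows = int(round(duration / CHUNK_SECONDS))
    rng = np.random.default_rng(seed)
    events = []
    for w in range(n_windows):
        for ch in channels:
            blocks = rng.choice(n_blocks, size=per_window, replace=False)
            jitter = rng.integers(0, block - pulse_len, size=per_window)
            starts = w * periods_per_window + blocks * block + jitter
            events.extend(
                StimEvent(int(s) * SAMPLE_PERIOD, ch, "stress_250us")
                for s in np.sort(starts)
            )
    return StimulationSchedule({"stress_250us": shape}, events)


# --- chunk building ----------------------------------------------------------


def build_chunks(
    schedule: StimulationSchedule,
    asic_setup: AsicState | dict[int, AsicState] | None = None,
    n_chunks: int | None = None,
    chunk_seconds: float = CHUNK_SECONDS,
) -> list[BitstreamChunk]:
    """Compile a schedule into ordered output chunks with sync ids 0,1,2,...

    Setup commands (full register image of every involved chip) ride in the
    leading frames of chunk 0 only; every later chunk is pure real-time
    data.  Each pulse starts in the chunk covering its onset time, at its
    exact sampling period, and may continue into the next chunk.  When a
    trigger line is configured it is raised for the full duration of every
    pulse.
    """
    schedule.validate()
    periods_per_chunk = protocol.chunk_period_count(chunk_seconds)
    if n_chunks is None:
        n_chunks = max(1, int(np.ceil(schedule.duration / chunk_seconds - 1e-9)))
    total_periods = n_chunks * periods_per_chunk

    if asic_setup is None:
        asic_setup = {}
    elif isinstance(asic_setup, AsicState):
        asic_setup = {0: asic_setup}
    asics = sorted(
        set(asic_setup) | {ev.channel // CHANNELS_PER_ASIC for ev in schedule.events}
    )
    if not asics:
        asics = [0]

    setup_commands = [
        cmd for a in sorted(asic_setup) for cmd in asic_setup[a].setup_commands(a)
    ]

    # events sorted by start period, bucketed per chunk lazily
    events = sorted(schedule.events, key=lambda ev: ev.start_period)
    for ev in events:
        end = ev.start_period + len(schedule.shapes[ev.shape])
        if end > total_periods:
            raise CapacityError(
                f"event at t={ev.time} s extends past the {n_chunks}-chunk stream"
            )

    chunks: list[BitstreamChunk] = []
    ev_idx = 0
    active: list[StimEvent] = []  # events still running into this chunk
    for c in range(n_chunks):
        c_start = c * periods_per_chunk
        c_end = c_start + periods_per_chunk
        blocks = {a: RtBlock.idle(periods_per_chunk) for a in asics}
        triggers = np.zeros((periods_per_chunk, 8), dtype=bool)

        carried = active
        active = []
        while ev_idx < len(events) and events[ev_idx].start_period < c_end:
            carried.append(events[ev_idx])
            ev_idx += 1
        for ev in carried:
            shape = schedule.shapes[ev.shape]
            s, e = ev.start_period, ev.start_period + len(shape)
            lo, hi = max(s, c_start), min(e, c_end)
            if lo >= hi:
                continue
            a, slot = divmod(ev.channel, CHANNELS_PER_ASIC)
            rows = slice(lo - c_start, hi - c_start)
            part = slice(lo - s, hi - s)
            blocks[a].dac7bit[rows, slot] = shape.dac7bit[part]
            blocks[a].dac4bit[rows, slot] = shape.dac4bit[part]
            blocks[a].polarity[rows, slot] = shape.polarity[part]
            if schedule.trigger_line is not None:
                triggers[rows, schedule.trigger_line - 1] = True
            if e > c_end:
                active.append(ev)

        chunks.append(
            protocol.pack_chunk_arrays(
                blocks,
                setup_commands if c == 0 else (),
                triggers,
                chunk_seconds,
                sync_id=c,
            )
        )
    return chunks


def extract_pulses(
    chunks: BitstreamChunk | Sequence[BitstreamChunk],
) -> list[tuple[int, int]]:
    """(start_period, system_channel) of every pulse in a chunk stream.

    A pulse is a maximal run of sampling periods with nonzero commanded
    current on one channel.  When a sequence of chunks is given they are
    treated as one continuous stream, so a pulse spanning a chunk boundary
    counts once, attributed to the period (and hence chunk) of its onset.
    """
    if isinstance(chunks, BitstreamChunk):
        chunks = [chunks]
    activity: dict[int, list[np.ndarray]] = {}
    n_total = 0
    for chunk in chunks:
        parsed = protocol.parse_chunk(chunk)
        for asic in set(activity) | set(parsed.realtime):
            acts = activity.setdefault(asic, [])
            missing = n_total - sum(a.shape[0] for a in acts)
            if missing:
                acts.append(np.zeros((missing, CHANNELS_PER_ASIC), dtype=bool))
            on = np.zeros((chunk.n_periods, CHANNELS_PER_ASIC), dtype=bool)
            stream = parsed.realtime.get(asic)
            if stream is not None:
                on[stream.periods] = (stream.dac7bit > 0) & (stream.dac4bit > 0)
            acts.append(on)
        n_total += chunk.n_periods
    out: list[tuple[int, int]] = []
    for asic, acts in activity.items():
        on = np.concatenate(acts)
        rising = np.diff(
            np.concatenate([np.zeros((1, CHANNELS_PER_ASIC), bool), on]).astype(np.int8),
            axis=0,
        ) == 1
        starts, slots = np.nonzero(rising)
        out.extend(
            (int(s), asic * CHANNELS_PER_ASIC + int(ch))
            for s, ch in zip(starts, slots)
        )
    return sorted(out)


def count_pulses(chunks: BitstreamChunk | Sequence[BitstreamChunk]) -> int:
    """Number of stimulation pulses starting in the given chunk stream."""
    return len(extract_pulses(chunks))


# --- keep-alive queue --------------------------------------------------------


class ChunkQueue:
    """Bounded output-chunk queue with keep-alive repetition semantics.

    Holds at most 4 s of stream (8 standard chunks).  ``next_chunk`` hands
    out fresh chunks with consecutive nonnegative sync ids; once starved it
    re-issues the last chunk tagged ``sync_id = -1`` so the hardware link
    stays alive while downstream knows to drop the data.
    """

    CAPACITY_SECONDS = 4.0

    def __init__(self, chunks: Iterable[BitstreamChunk] = ()):
        self._queue: deque[BitstreamChunk] = deque()
        self._next_id = 0
        self._last: BitstreamChunk | None = None
        for c in chunks:
            self.push(c)

    def __len__(self) -> int:
        return len(self._queue)

    @property
    def capacity(self) -> int:
        head = self._queue[0] if self._queue else None
        duration = head.duration if head else CHUNK_SECONDS
        return int(self.CAPACITY_SECONDS / duration)

    def push(self, chunk: BitstreamChunk) -> None:
        if len(self._queue) >= self.capacity:
            raise CapacityError(
                f"queue holds at most {self.CAPACITY_SECONDS} s of stream "
                f"({self.capacity} chunks)"
            )
        self._queue.append(chunk)

    def next_chunk(self) -> tuple[BitstreamChunk, int]:
        """Next fresh chunk with its sync id, or the last chunk re-tagged -1."""
        if self._queue:
            chunk = self._queue.popleft()
            sync_id = self._next_id
            self._next_id += 1
            self._last = chunk
            chunk.sync_id = sync_id
            return chunk, sync_id
        if self._last is None:
            # nothing was ever enqueued: keep the link alive with idle data
            self._last = protocol.pack_chunk_arrays(
                {0: RtBlock.idle(protocol.chunk_period_count(CHUNK_SECONDS))}
            )
        repeat = BitstreamChunk(self._last.words, self._last.duration, sync_id=-1)
        return repeat, -1


def next_chunk(queue: ChunkQueue) -> tuple[BitstreamChunk, int]:
    """Module-level convenience wrapper over :meth:`ChunkQueue.next_chunk`."""
    return queue.next_chunk()


# --- experiment JSON ---------------------------------------------------------

_EXPERIMENT_VERSION = 1


def _state_to_dict(state: AsicState) -> dict:
    return {
        "dac10bit": int(state.dac10bit),
        "hp_reg": int(state.hp_reg),
        "lp_reg": int(state.lp_reg),
        "gain": state.gain.tolist(),
        "stim_enable": state.stim_enable.astype(int).tolist(),
    }


def _state_from_dict(d: dict) -> AsicState:
    return AsicState(
        dac10bit=int(d["dac10bit"]),
        hp_reg=int(d["hp_reg"]),
        lp_reg=int(d["lp_reg"]),
        gain=np.asarray(d["gain"]),
        stim_enable=np.asarray(d["stim_enable"], dtype=bool),
    )


def experiment_to_dict(
    schedule: StimulationSchedule, asic_setup: dict[int, AsicState] | None = None
) -> dict:
    return {
        "version": _EXPERIMENT_VERSION,
        "asics": {
            str(a): _state_to_dict(s) for a, s in (asic_setup or {}).items()
        },
        "shapes": {
            name: {
                "dac7bit": s.dac7bit.tolist(),
                "dac4bit": s.dac4bit.tolist(),
                "polarity": s.polarity.tolist(),
            }
            for name, s in schedule.shapes.items()
        },
        "schedule": {
            "trigger_line": schedule.trigger_line,
            "events": [
                {"time": ev.time, "channel": ev.channel, "shape": ev.shape}
                for ev in schedule.events
            ],
        },
    }


def experiment_from_dict(d: dict) -> tuple[StimulationSchedule, dict[int, AsicState]]:
    if d.get("version") != _EXPERIMENT_VERSION:
        raise ValueError(f"unsupported experiment version {d.get('version')!r}")
    for key in ("shapes", "schedule"):
        if key not in d:
            raise ValueError(f"experiment file missing {key!r} section")
    shapes = {
        name: PulseShape(name, s["dac7bit"], s["dac4bit"], s["polarity"])
        for name, s in d["shapes"].items()
    }
    sched = d["schedule"]
    schedule = StimulationSchedule(
        shapes,
        [StimEvent(ev["time"], ev["channel"], ev["shape"]) for ev in sched["events"]],
        sched.get("trigger_line"),
    )
    schedule.validate()
    states = {int(a): _state_from_dict(s) for a, s in d.get("asics", {}).items()}
    return schedule, states


def save_experiment(
    path: str | Path,
    schedule: StimulationSchedule,
    asic_setup: dict[int, AsicState] | None = None,
) -> Path:
    """Write the prebuilt-experiment JSON file (protocol + pulses + setup)."""
    path = Path(path)
    path.write_text(json.dumps(experiment_to_dict(schedule, asic_setup), indent=1))
    return path


def load_experiment(path: str | Path) -> tuple[StimulationSchedule, dict[int, AsicState]]:
    return experiment_from_dict(json.loads(Path(path).read_text()))
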